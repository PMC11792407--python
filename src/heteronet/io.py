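"""Plain-text readers and writers for the package's TSV/CSV/GMT dialects."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, PlantedTruth


def write_expression(x: ExpressionMatrix, outdir, prefix: str = "expression") -> dict:
    """Write an ExpressionMatrix as TSVs; returns {role: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mat = outdir / f"{prefix}_{x.kind}.tsv"
    x.values.to_csv(mat, sep="\t", index_label="gene")
    paths["matrix"] = mat
    meta = outdir / f"{prefix}_metadata.tsv"
    x.meta.to_csv(meta, sep="\t", index_label="sample")
    paths["metadata"] = meta
    if x.lengths is not None:
        p = outdir / f"{prefix}_gene_lengths.tsv"
        x.lengths.rename("length_bp").to_csv(p, sep="\t", index_label="gene")
        paths["lengths"] = p
    if x.libsizes is not None:
        p = outdir / f"{prefix}_library_sizes.tsv"
        x.libsizes.rename("mapped_fragments").to_csv(p, sep="\t", index_label="sample")
        paths["libsizes"] = p
    return paths


def read_expression(matrix_path, metadata_path, kind: str = "fpkm",
                    lengths_path=None, libsizes_path=None) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    libsizes = None
    if libsizes_path is not None:
        libsizes = pd.read_csv(libsizes_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=values, meta=meta, kind=kind,
                            lengths=lengths, libsizes=libsizes)


def write_phenotypes(ph: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ph.to_csv(path, index=False)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    ph = pd.read_csv(path)
    required = {"hen", "group", "window", "egg_number"}
    missing = required - set(ph.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return ph


def write_truth(truth: PlantedTruth, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
    return path


def read_truth(path) -> PlantedTruth:
    return PlantedTruth.from_json_dict(json.loads(Path(path).read_text()))


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> gene...

    Returns an ordered mapping name -> list of genes.
    """
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >=3 fields): {line[:60]!r}")
        name, _desc, *genes = fields
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    path.write_text("\n".join(lines) + "\n")
    return path
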