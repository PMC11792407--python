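"""Core in-memory containers shared across the analysis chain.

Expression data travel as a genes x samples :class:`pandas.DataFrame` wrapped
in :class:`ExpressionMatrix` together with per-sample metadata (genetic group,
laying stage, replicate) and, for count data, per-gene transcript lengths and
per-sample library sizes. Phenotypes are plain tidy DataFrames (one row per
hen per 4-week window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("WW", "YY", "WY", "YW")
CROSSES = ("WY", "YW")
PARENTS = ("WW", "YY")

#: metadata columns every ExpressionMatrix carries per sample
META_COLUMNS = ("group", "stage", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene ID, columns by sample ID. Non-negative.
    meta : DataFrame
        Indexed by sample ID, with columns ``group``, ``stage``,
        ``replicate``. Must cover every sample in ``values``.
    kind : str
        ``"counts"`` or ``"fpkm"``.
    lengths : Series, optional
        Per-gene transcript length in bp (required to convert counts).
    libsizes : Series, optional
        Per-sample mapped fragments (required to convert counts).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    kind: str = "fpkm"
    lengths: pd.Series | None = None
    libsizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs in expression matrix")
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = self.values.columns.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if self.kind not in ("counts", "fpkm"):
            raise ValueError(f"unknown value kind {self.kind!r}")
        # keep metadata aligned and restricted to the matrix samples
        self.meta = self.meta.loc[self.values.columns]

    # -- convenience ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        lengths = self.lengths.loc[genes] if self.lengths is not None else None
        return replace(self, values=self.values.loc[genes], lengths=lengths)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        libsizes = self.libsizes.loc[samples] if self.libsizes is not None else None
        return replace(
            self,
            values=self.values.loc[:, samples],
            meta=self.meta.loc[samples],
            libsizes=libsizes,
        )

    def for_group(self, group: str) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["group"] == group]
        if not len(keep):
            raise ValueError(f"no samples for group {group!r}")
        return self.subset_samples(keep)

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(value + pseudocount), the working scale for PCA/networks."""
        return np.log2(self.values + pseudocount)


@dataclass
class PlantedTruth:
    """Ground truth written alongside every synthetic fixture."""

    gene_module: dict = field(default_factory=dict)
    gene_action: dict = field(default_factory=dict)  # (gene, stage) -> category
    heterosis_by_window: dict = field(default_factory=dict)  # window -> H

    def to_json_dict(self) -> dict:
        return {
            "gene_module": self.gene_module,
            "gene_action": {f"{g}|{s}": c for (g, s), c in self.gene_action.items()},
            "heterosis_by_window": {str(w): h for w, h in self.heterosis_by_window.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PlantedTruth":
        action = {}
        for key, cat in d.get("gene_action", {}).items():
            g, s = key.rsplit("|", 1)
            action[(g, int(s))] = cat
        return cls(
            gene_module=dict(d.get("gene_module", {})),
            gene_action=action,
            heterosis_by_window={int(w): h for w, h in d.get("heterosis_by_window", {}).items()},
        )
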