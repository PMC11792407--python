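"""Synthetic purebred/crossbred data with planted ground truth.

The generator emulates the study design this package targets: two purebred
chicken lines (WW = White Leghorn, YY = Beijing You) and their reciprocal
crosses (WY, YW), phenotyped for egg number in 4-week windows (~300 hens per
group) and expression-profiled in the ovary at 5 laying stages with 6
replicates per group x stage.

Three kinds of ground truth are planted and written alongside every fixture:

* a per-window heterosis trajectory H_w — crossbred window means are
  ``(1 + H_w) * mid-parent mean`` in expectation;
* latent-factor co-expression modules — genes in a module share a factor so
  the within-module Pearson correlation hits a target value;
* per-gene x stage gene-action modes (the 12 roman-numeral categories of
  additivity / dominance / overdominance) planted as group-mean shifts on the
  log2 scale in units of the per-gene SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CROSSES, GROUPS, ExpressionMatrix, PlantedTruth

# ---------------------------------------------------------------------------
# gene-action categories
# ---------------------------------------------------------------------------

#: supercategory for each roman-numeral category
SUPERCATEGORY = {
    "I": "overdominance-above",
    "VII": "overdominance-below",
    "II": "overdominance-above",
    "XII": "overdominance-above",
    "VI": "overdominance-below",
    "VIII": "overdominance-below",
    "III": "high-parent dominance",
    "XI": "high-parent dominance",
    "V": "low-parent dominance",
    "IX": "low-parent dominance",
    "IV": "additivity",
    "X": "additivity",
    "none": "none",
}

#: roman numeral under a WW<->YY parent-label swap (supercategory invariant)
MIRROR = {
    "I": "I", "VII": "VII",
    "II": "XII", "XII": "II",
    "VI": "VIII", "VIII": "VI",
    "III": "XI", "XI": "III",
    "V": "IX", "IX": "V",
    "IV": "X", "X": "IV",
    "none": "none",
}

# (shift_WW, shift_YY, shift_F1) in units of delta = effect * per-gene SD.
# Convention: the first numeral of each mirrored pair is the case mu_YY >
# mu_WW. I and VII have equal parents.
_CATEGORY_SHIFTS = {
    "IV": (-0.5, +0.5, 0.0),       # additivity, YY high
    "X": (+0.5, -0.5, 0.0),        # additivity, WW high
    "III": (-0.5, +0.5, +0.5),     # high-parent dominance (F1 = YY)
    "XI": (+0.5, -0.5, +0.5),      # high-parent dominance (F1 = WW)
    "V": (-0.5, +0.5, -0.5),       # low-parent dominance (F1 = WW)
    "IX": (+0.5, -0.5, -0.5),      # low-parent dominance (F1 = YY)
    "I": (0.0, 0.0, +1.0),         # above-parent overdominance
    "VII": (0.0, 0.0, -1.0),       # below-parent overdominance
    "II": (-0.5, +0.5, +1.5),      # above high-parent
    "XII": (+0.5, -0.5, +1.5),
    "VI": (-0.5, +0.5, -1.5),      # below low-parent
    "VIII": (+0.5, -0.5, -1.5),
    "none": (0.0, 0.0, 0.0),
}


def category_shifts(category: str, effect: float) -> dict:
    """Per-group mean shifts (log2 scale, SD units) implied by a category.

    The F1 shift applies to both reciprocal crosses.
    """
    if category not in _CATEGORY_SHIFTS:
        raise ValueError(f"unknown gene-action category {category!r}")
    if category != "none" and effect <= 0:
        raise ValueError(
            f"category {category!r} requires a positive effect size "
            "(its defining inequalities need groups to differ)")
    if effect < 0:
        raise ValueError("effect sizes must be >= 0")
    ww, yy, f1 = (s * effect for s in _CATEGORY_SHIFTS[category])
    return {"WW": ww, "YY": yy, "WY": f1, "YW": f1}


# ---------------------------------------------------------------------------
# simulation spec
# ---------------------------------------------------------------------------

def _default_baselines(windows: int) -> dict:
    """Purebred egg numbers per 4-week window: WW the better layer, both
    declining over the laying life."""
    w = np.arange(windows)
    frac = w / max(windows - 1, 1)
    return {
        "WW": list(26.0 - 12.0 * frac),
        "YY": list(20.0 - 12.0 * frac),
    }


def _default_heterosis(windows: int) -> list:
    """Window trajectory echoing the laying-stage profile: strong around
    onset, weaker through the persistent stages, strongest when prolonged."""
    stage_h = [0.074, 0.040, 0.030, 0.027, 0.10]
    idx = np.minimum((np.arange(windows) * 5) // max(windows, 1), 4)
    return [stage_h[i] for i in idx]


@dataclass
class SimulationSpec:
    """All knobs of the synthetic study, with the study design as defaults."""

    seed: int = 0
    # phenotypes
    n_hens_per_group: int = 300
    windows: int = 20
    baseline_mean: dict | None = None          # group -> per-window means
    heterosis_trajectory: list | float | None = None
    phenotype_cv: float = 0.10
    # expression
    n_genes: int = 2000
    module_sizes: tuple = (100, 100, 100, 100, 100)
    module_cor: float = 0.6
    samples_per_cell: int = 6
    stages: int = 5
    stage_amplitude: float = 0.5
    action_plan: list = field(default_factory=list)  # (gene, stage, category, effect)
    noise_sd: float = 0.35
    baseline_log2_range: tuple = (2.0, 7.0)
    gene_length_range: tuple = (300, 10000)
    mean_libsize: float = 2.0e7

    def __post_init__(self) -> None:
        if self.n_hens_per_group < 2:
            raise ValueError("n_hens_per_group must be >= 2 (SD undefined below)")
        if not (0.0 <= self.module_cor < 1.0):
            raise ValueError("module_cor must lie in [0, 1)")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if self.baseline_mean is None:
            self.baseline_mean = _default_baselines(self.windows)
        if self.heterosis_trajectory is None:
            self.heterosis_trajectory = _default_heterosis(self.windows)
        if np.isscalar(self.heterosis_trajectory):
            self.heterosis_trajectory = [float(self.heterosis_trajectory)] * self.windows
        self.heterosis_trajectory = [float(h) for h in self.heterosis_trajectory]
        if len(self.heterosis_trajectory) != self.windows:
            raise ValueError("heterosis_trajectory length must equal windows")
        if any(h <= -1.0 for h in self.heterosis_trajectory):
            raise ValueError("heterosis_trajectory entries must be > -1")
        for gene, stage, category, effect in self.action_plan:
            category_shifts(category, effect)  # validates
            if not (1 <= int(stage) <= self.stages):
                raise ValueError(f"action plan stage {stage} outside 1..{self.stages}")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(spec: SimulationSpec) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-hen egg numbers per 4-week window for all four genetic groups.

    Crossbred window means are ``(1 + H_w) * mid-parent mean``; each hen's
    record is normal with SD = cv * mean, truncated at zero (a clip — at the
    default cv of 0.10 the sub-zero mass is negligible). Oviduct length and
    body weight are emitted as per-hen traits constant across windows.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hens_per_group
    ww = np.asarray(spec.baseline_mean["WW"], dtype=float)
    yy = np.asarray(spec.baseline_mean["YY"], dtype=float)
    mpv = (ww + yy) / 2.0
    h = np.asarray(spec.heterosis_trajectory, dtype=float)
    group_means = {"WW": ww, "YY": yy, "WY": (1 + h) * mpv, "YW": (1 + h) * mpv}

    # per-hen stable traits: group means chosen so crosses sit near mid-parent
    trait_means = {
        "OL": {"WW": 62.0, "YY": 55.0, "WY": 60.0, "YW": 60.0},
        "BW": {"WW": 1.75, "YY": 1.45, "WY": 1.65, "YW": 1.65},
    }

    records = []
    for group in GROUPS:
        means = group_means[group]
        hen_ids = [f"{group}_{i + 1:04d}" for i in range(n)]
        ol = np.clip(rng.normal(trait_means["OL"][group],
                                0.05 * trait_means["OL"][group], size=n), 0, None)
        bw = np.clip(rng.normal(trait_means["BW"][group],
                                0.05 * trait_means["BW"][group], size=n), 0, None)
        # one draw block per window for a stable layout
        draws = rng.normal(means[None, :], spec.phenotype_cv * means[None, :],
                           size=(n, spec.windows))
        draws = np.clip(draws, 0.0, None)
        for w in range(spec.windows):
            for i, hen in enumerate(hen_ids):
                records.append((hen, group, w + 1, draws[i, w], ol[i], bw[i]))
    ph = pd.DataFrame(records, columns=["hen", "group", "window", "egg_number",
                                        "oviduct_length", "body_weight"])
    truth = PlantedTruth(heterosis_by_window={w + 1: float(h[w]) for w in range(spec.windows)})
    return ph, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _module_labels(spec: SimulationSpec) -> pd.Series:
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    labels = np.full(spec.n_genes, "background", dtype=object)
    pos = 0
    for m, size in enumerate(spec.module_sizes):
        labels[pos:pos + size] = f"M{m + 1}"
        pos += size
    return pd.Series(labels, index=pd.Index(genes, name="gene"))


def latent_log2_signal(rng: np.random.Generator, module_of_gene: np.ndarray,
                       n_samples: int, module_cor: float, noise_sd: float,
                       stage_of_sample: np.ndarray | None = None,
                       stage_amplitude: float = 0.0,
                       n_stages: int = 5,
                       hub_gradient: float = 0.15) -> np.ndarray:
    """Zero-mean log2-scale signal (genes x samples) from a latent-factor
    module model.

    A gene of module m gets ``noise_sd * (rho_g * f_m + sqrt(1-rho_g^2) *
    eps)`` where ``f_m`` is the module factor per sample (standard normal
    plus an optional stage-specific sinusoidal mean shift) and ``rho_g`` is
    the gene's loading, spaced evenly around sqrt(module_cor) with
    half-width ``hub_gradient``. Loadings differ between genes so modules
    have hub structure (strongly loaded genes are intramodular hubs) while
    the mean pairwise within-module correlation stays at ``module_cor``
    (E[rho_g rho_h] = mean(rho)^2 for g != h). The loading grid is a
    deterministic function of a gene's position in its module, so
    independently drawn datasets share the same hub ordering — a gene-level
    property of the planted structure, not of one sample draw. Background
    genes (module id < 0) get pure noise.
    """
    n_genes = module_of_gene.shape[0]
    module_ids = sorted({m for m in module_of_gene if m >= 0})
    signal = np.zeros((n_genes, n_samples))
    factors = {}
    for m in module_ids:
        f = rng.normal(size=n_samples)
        if stage_of_sample is not None and stage_amplitude > 0:
            phase = 2 * np.pi * m / max(len(module_ids), 1)
            f = f + stage_amplitude * np.sin(
                2 * np.pi * (stage_of_sample - 1) / n_stages + phase)
        factors[m] = f
    rho_bar = np.sqrt(module_cor)
    width = min(hub_gradient, (1.0 - rho_bar) * 0.9, rho_bar)
    rank_in_module = np.zeros(n_genes, dtype=int)
    module_size = {m: int((module_of_gene == m).sum()) for m in module_ids}
    seen: dict[int, int] = {}
    for g in range(n_genes):
        m = module_of_gene[g]
        if m >= 0:
            rank_in_module[g] = seen.get(m, 0)
            seen[m] = rank_in_module[g] + 1
    for g in range(n_genes):
        eps = rng.normal(size=n_samples)
        m = module_of_gene[g]
        if m >= 0:
            size = module_size[m]
            frac = rank_in_module[g] / (size - 1) if size > 1 else 0.5
            rho = rho_bar - width + 2 * width * frac
            signal[g] = noise_sd * (rho * factors[m] + np.sqrt(1 - rho ** 2) * eps)
        else:
            signal[g] = noise_sd * eps
    return signal


@dataclass
class ExpressionSim:
    """Bundle returned by :func:`simulate_expression`."""
    fpkm: ExpressionMatrix
    counts: ExpressionMatrix
    truth: PlantedTruth


def simulate_expression(spec: SimulationSpec) -> ExpressionSim:
    """Genes x (group x stage x replicate) FPKM and count matrices.

    Module structure is shared by all four genetic groups (each sample draws
    its own factor values), so per-group networks see the same planted
    modules. Gene-action modes from ``spec.action_plan`` are planted as
    group x stage mean shifts on the log2 scale; the count matrix is the
    exact inverse image of the FPKM matrix under the FPKM formula given the
    emitted gene lengths and library sizes.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _module_labels(spec)
    genes = labels.index
    module_index = {f"M{m + 1}": m for m in range(spec.n_modules)}
    module_of_gene = np.array([module_index.get(l, -1) for l in labels], dtype=int)

    samples, groups_arr, stage_arr = [], [], []
    for group in GROUPS:
        for stage in range(1, spec.stages + 1):
            for rep in range(1, spec.samples_per_cell + 1):
                samples.append(f"{group}_s{stage}_r{rep}")
                groups_arr.append(group)
                stage_arr.append(stage)
    meta = pd.DataFrame({
        "group": groups_arr,
        "stage": stage_arr,
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    }, index=pd.Index(samples, name="sample"))

    baseline = rng.uniform(*spec.baseline_log2_range, size=spec.n_genes)
    signal = latent_log2_signal(
        rng, module_of_gene, len(samples), spec.module_cor, spec.noise_sd,
        stage_of_sample=np.asarray(stage_arr), stage_amplitude=spec.stage_amplitude,
        n_stages=spec.stages)
    log2x = baseline[:, None] + signal

    gene_pos = {g: i for i, g in enumerate(genes)}
    truth_action = {}
    for gene, stage, category, effect in spec.action_plan:
        if gene not in gene_pos:
            raise ValueError(f"action plan names unknown gene {gene!r}")
        shifts = category_shifts(category, effect)
        gi = gene_pos[gene]
        mask = (meta["stage"].values == int(stage))
        for group, shift in shifts.items():
            sel = mask & (meta["group"].values == group)
            log2x[gi, sel] += shift * spec.noise_sd
        truth_action[(gene, int(stage))] = category

    fpkm_values = pd.DataFrame(np.exp2(log2x), index=genes, columns=meta.index)
    lengths = pd.Series(
        rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1,
                     size=spec.n_genes),
        index=genes, name="length_bp").astype(float)
    libsizes = pd.Series(
        spec.mean_libsize * np.exp(rng.normal(0, 0.1, size=len(samples))),
        index=meta.index, name="mapped_fragments")
    # counts solve FPKM = counts * 1e9 / (libsize * length) exactly
    counts_values = fpkm_values * libsizes.values[None, :] * lengths.values[:, None] / 1e9

    truth = PlantedTruth(
        gene_module={g: l for g, l in labels.items()},
        gene_action=truth_action,
    )
    fpkm = ExpressionMatrix(values=fpkm_values, meta=meta, kind="fpkm",
                            lengths=lengths, libsizes=libsizes)
    counts = ExpressionMatrix(values=counts_values, meta=meta, kind="counts",
                              lengths=lengths, libsizes=libsizes)
    return ExpressionSim(fpkm=fpkm, counts=counts, truth=truth)


def simulate_single_dataset(seed: int, n_genes: int, module_sizes: tuple,
                            module_cor: float, n_samples: int,
                            noise_sd: float = 1.0,
                            baseline_log2_range: tuple = (2.0, 7.0)) -> tuple[ExpressionMatrix, pd.Series]:
    """One group-less expression dataset from the latent-factor model.

    Convenience for network/preservation studies that need a single matrix
    (e.g. reference vs test datasets). Returns the FPKM-scale matrix and the
    planted gene -> module label series ("background" for noise genes).
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module_sizes sum exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i + 1:05d}" for i in range(n_genes)], name="gene")
    labels = np.full(n_genes, "background", dtype=object)
    module_of_gene = np.full(n_genes, -1, dtype=int)
    pos = 0
    for m, size in enumerate(module_sizes):
        labels[pos:pos + size] = f"M{m + 1}"
        module_of_gene[pos:pos + size] = m
        pos += size
    baseline = rng.uniform(*baseline_log2_range, size=n_genes)
    signal = latent_log2_signal(rng, module_of_gene, n_samples, module_cor, noise_sd)
    values = pd.DataFrame(np.exp2(baseline[:, None] + signal), index=genes,
                          columns=[f"s{j + 1:03d}" for j in range(n_samples)])
    meta = pd.DataFrame({"group": "NA", "stage": 1, "replicate": range(1, n_samples + 1)},
                        index=values.columns)
    return (ExpressionMatrix(values=values, meta=meta, kind="fpkm"),
            pd.Series(labels, index=genes))
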