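"""Signed weighted co-expression network construction and module detection.

The chain, for one genetic group:

1. signed adjacency  a_ij = ((1 + r_ij) / 2) ** beta  from Pearson r on
   log2(FPKM + 1);
2. soft threshold beta chosen by the scale-free topology criterion over
   powers 1..30 (smallest power whose signed fit R^2 reaches the target);
3. topological overlap matrix (TOM); 1 - TOM is the clustering
   dissimilarity;
4. average-linkage hierarchical clustering cut at a fixed dendrogram height
   (0.995) with a minimum module size (50); leftover genes are 'grey';
5. module eigengenes (first principal component of the standardized module
   expression) and iterative merging of modules whose eigengene
   dissimilarity (1 - cor) falls below 0.25;
6. module-trait correlation with the Student-t p-value for a correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

#: fixed ordered palette, assigned to modules by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class NetworkConfig:
    """Parameters of per-group network construction."""

    power: int | None = None            # None -> choose by scale-free fit
    signed: bool = True
    min_module_size: int = 50
    detect_cut_height: float = 0.995
    merge_cut_height: float = 0.25
    rsq_target: float = 0.8
    deep_split: int = 0
    powers: tuple = tuple(range(1, 31))

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise ValueError("power must be >= 1")
        for h in (self.detect_cut_height, self.merge_cut_height):
            if not (0 < h <= 1):
                raise ValueError("cut heights must lie in (0, 1]")


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes and provenance."""

    labels: pd.Series                      # gene -> color; 'grey' = unassigned
    eigengenes: pd.DataFrame               # samples x modules
    var_explained: pd.Series               # module -> fraction
    linkage: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def modules(self) -> list:
        return [m for m in self.eigengenes.columns]

    def module_genes(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def _working_frame(x) -> pd.DataFrame:
    """Genes x samples working matrix: log2(FPKM + 1) for ExpressionMatrix
    input, pass-through for an already-transformed DataFrame."""
    if isinstance(x, ExpressionMatrix):
        return x.log2()
    return pd.DataFrame(x)


def gene_correlation(data) -> pd.DataFrame:
    """Pearson correlation between gene profiles; errors on constant genes."""
    frame = _working_frame(data)
    sd = frame.std(axis=1)
    bad = sd.index[sd == 0]
    if len(bad):
        raise ValueError(f"constant gene(s) break the correlation: {list(bad)[:5]}")
    r = np.corrcoef(frame.to_numpy())
    return pd.DataFrame(r, index=frame.index, columns=frame.index)


def signed_adjacency(data, beta: int, r: pd.DataFrame | None = None) -> pd.DataFrame:
    """a_ij = ((1 + r_ij) / 2) ** beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if r is None:
        r = gene_correlation(data)
    a = ((1.0 + r.to_numpy()) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=r.index, columns=r.columns)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit R^2 from a connectivity vector.

    k is discretized into equal-width bins; within non-empty bins the mean
    connectivity and the fraction of nodes p(k) are computed, and
    log10 p(k) is regressed on log10 mean(k). Returns -sign(slope) * R^2;
    NaN when fewer than 3 non-empty bins remain.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return float("nan")
    slope, _, rvalue, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * rvalue ** 2)


def scale_free_fit(data, powers=tuple(range(1, 31)), rsq_target: float = 0.8,
                   n_bins: int = 10) -> tuple[pd.DataFrame, int]:
    """Scan soft-threshold powers; returns (scan table, chosen power).

    Chosen power is the smallest one whose signed R^2 reaches
    ``rsq_target``; if none does, the power maximizing signed R^2 is used
    and flagged in the table's ``chosen_by`` column.
    """
    r = gene_correlation(data)
    half = (1.0 + r.to_numpy()) / 2.0
    np.fill_diagonal(half, 1.0)
    rows = []
    for beta in powers:
        a = half ** beta
        k = a.sum(axis=0) - 1.0  # exclude self-adjacency
        rows.append({
            "power": int(beta),
            "signed_r2": scale_free_fit_index(k, n_bins=n_bins),
            "mean_connectivity": float(k.mean()),
            "median_connectivity": float(np.median(k)),
            "max_connectivity": float(k.max()),
        })
    scan = pd.DataFrame(rows)
    reaching = scan.loc[scan["signed_r2"] >= rsq_target, "power"]
    if len(reaching):
        chosen = int(reaching.iloc[0])
        scan["chosen_by"] = "rsq_target"
    else:
        chosen = int(scan.loc[scan["signed_r2"].idxmax(), "power"])
        scan["chosen_by"] = "max_r2_fallback"
        logger.warning("no power reached signed R^2 >= %.2f; using %d",
                       rsq_target, chosen)
    scan["chosen"] = scan["power"] == chosen
    return scan, chosen


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u!=i,j a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Diagonal is 1; entries stay in [0, 1] for adjacency in [0, 1].
    """
    a = adj.to_numpy(dtype=float)
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    l = a @ a - 2.0 * a  # removes the u=i and u=j terms (a_ii = a_jj = 1)
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _clusters_from_linkage(link: np.ndarray, height: float) -> np.ndarray:
    return fcluster(link, t=height, criterion="distance")


def _split_oversized(diss: np.ndarray, members: np.ndarray,
                     min_module_size: int, depth: int) -> list:
    """Recursive sub-branch splitting for oversized branches (the deeper
    split setting): re-cluster the branch and cut it at the highest height
    that separates at least two children of minimum module size, recursing
    up to ``depth`` rounds. Genes falling outside every min-size child at
    that cut are peripheral and drop back to grey. A higher depth splits
    more aggressively, mirroring the deepSplit knob of dynamic tree cutting.
    """
    if depth <= 0 or len(members) <= 3 * min_module_size:
        return [members]
    sub = diss[np.ix_(members, members)]
    link = average(squareform(sub, checks=False))
    heights = np.unique(link[:, 2])[::-1]
    for lo, hi in zip(heights[1:], heights[:-1]):
        assign = fcluster(link, t=(lo + hi) / 2.0, criterion="distance")
        counts = np.bincount(assign)
        big = np.flatnonzero(counts >= min_module_size)
        if len(big) >= 2:
            out = []
            for c in big:
                part = members[assign == c]
                out.extend(_split_oversized(diss, part, min_module_size,
                                            depth - 1))
            return out
    return [members]


def cut_modules(diss: pd.DataFrame, config: NetworkConfig | None = None) -> ModulePartition:
    """Average-linkage clustering of a dissimilarity (1 - TOM) and a fixed
    height cut; branches with >= min_module_size leaves become modules,
    everything else is grey.

    ``config.deep_split >= 1`` adds one round of sub-branch splitting for
    branches larger than 3x the minimum module size (the consensus-detection
    setting). Color labels are assigned by decreasing module size.
    """
    config = config or NetworkConfig()
    d = diss.to_numpy(dtype=float)
    genes = diss.index
    n = len(genes)
    if n < config.min_module_size:
        logger.warning("fewer genes (%d) than min module size (%d): all grey",
                       n, config.min_module_size)
        labels = pd.Series(GREY, index=genes)
        return ModulePartition(labels=labels, eigengenes=pd.DataFrame(),
                               var_explained=pd.Series(dtype=float),
                               linkage=None, config=config.__dict__.copy())
    link = average(squareform(d, checks=False))
    assign = _clusters_from_linkage(link, config.detect_cut_height)
    groups = []
    for c in np.unique(assign):
        members = np.flatnonzero(assign == c)
        if len(members) < config.min_module_size:
            continue
        groups.extend(_split_oversized(d, members, config.min_module_size,
                                       config.deep_split))
    # deterministic color order: by decreasing size, ties by first gene index
    groups.sort(key=lambda m: (-len(m), int(m.min())))
    labels = pd.Series(GREY, index=genes, dtype=object)
    for i, members in enumerate(groups):
        color = MODULE_COLORS[i % len(MODULE_COLORS)]
        if i >= len(MODULE_COLORS):
            color = f"{color}.{i // len(MODULE_COLORS)}"
        labels.iloc[members] = color
    return ModulePartition(labels=labels, eigengenes=pd.DataFrame(),
                           var_explained=pd.Series(dtype=float),
                           linkage=link, config=config.__dict__.copy())


def _standardize_rows(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = frame.index[~keep]
    if len(dropped):
        logger.warning("dropping %d constant gene(s) from eigengene computation",
                       len(dropped))
    frame = frame.loc[keep]
    return frame.sub(frame.mean(axis=1), axis=0).div(sd[keep], axis=0)


def module_eigengenes(data, labels: pd.Series, include_grey: bool = False
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Returns (eigengenes samples x modules, variance explained per module).
    Eigengenes are unit-norm right singular vectors, sign-aligned so each
    correlates non-negatively with the module's mean standardized profile.
    """
    frame = _working_frame(data)
    labels = labels.loc[frame.index]
    mes, var = {}, {}
    modules = [m for m in labels.unique() if include_grey or m != GREY]
    # deterministic module order: by decreasing size then name
    modules.sort(key=lambda m: (-(labels == m).sum(), m))
    for module in modules:
        sub = frame.loc[labels.index[labels == module]]
        z = _standardize_rows(sub)
        if z.shape[0] < 1:
            logger.warning("module %s has no usable genes; skipped", module)
            continue
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0).to_numpy()
        if np.dot(me, mean_profile) < 0:
            me = -me
        mes[module] = me
        var[module] = float(s[0] ** 2 / (s ** 2).sum())
    eigengenes = pd.DataFrame(mes, index=frame.columns)
    return eigengenes, pd.Series(var, dtype=float)


def merge_close_modules(data, labels: pd.Series, merge_cut_height: float = 0.25,
                        max_iter: int = 20) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Merge modules whose eigengene dissimilarity (1 - cor) clusters below
    the cut height; recompute eigengenes and iterate to a fixpoint.

    A merged module keeps the color of its largest member. Returns
    (labels, eigengenes, variance explained).
    """
    frame = _working_frame(data)
    labels = labels.copy()
    for _ in range(max_iter):
        mes, var = module_eigengenes(frame, labels)
        modules = list(mes.columns)
        if len(modules) < 2:
            return labels, mes, var
        diss = 1.0 - np.corrcoef(mes.to_numpy().T)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip(diss, 0.0, None)
        link = average(squareform(diss, checks=False))
        assign = fcluster(link, t=merge_cut_height, criterion="distance")
        merged_any = False
        for c in np.unique(assign):
            members = [modules[i] for i in np.flatnonzero(assign == c)]
            if len(members) < 2:
                continue
            sizes = {m: int((labels == m).sum()) for m in members}
            keep = max(sorted(members), key=lambda m: sizes[m])
            for m in members:
                if m != keep:
                    labels[labels == m] = keep
            merged_any = True
        if not merged_any:
            return labels, mes, var
    mes, var = module_eigengenes(frame, labels)
    return labels, mes, var


def cor_pvalue_student(r, n: int):
    """Two-sided Student-t p-value for a Pearson correlation with df = n - 2.

    t = r * sqrt(n - 2) / sqrt(1 - r^2); |r| = 1 maps to p = 0. Accepts
    scalars or arrays.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    r_arr = np.asarray(r, dtype=float)
    if (np.abs(r_arr) > 1 + 1e-12).any():
        raise ValueError("|r| must be <= 1")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt(n - 2) / np.sqrt(1.0 - r_arr ** 2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, p)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(p)
    return p


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    ``traits`` must be indexed by the same samples as the eigengenes.
    Returns a tidy table with r, p and a significance flag.
    """
    if not eigengenes.index.equals(traits.index):
        if set(eigengenes.index) != set(traits.index):
            raise ValueError("traits are not aligned to the eigengene samples")
        traits = traits.loc[eigengenes.index]
    n = eigengenes.shape[0]
    rows = []
    for module in eigengenes.columns:
        me = eigengenes[module].to_numpy()
        for trait in traits.columns:
            tv = traits[trait].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = float(np.corrcoef(me, tv)[0, 1])  # NaN for constant traits
            p = float(cor_pvalue_student(r, n))
            rows.append({"module": module, "trait": trait, "r": r, "p": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


class CoexpressionModules(BaseEstimator):
    """Signed weighted co-expression module detection, estimator-style.

    Parameters mirror :class:`NetworkConfig`; ``power=None`` selects the
    soft threshold by the scale-free criterion. ``fit`` accepts an
    :class:`ExpressionMatrix` (log2(FPKM+1) is applied) or an
    already-transformed genes x samples DataFrame.

    Attributes (after fit)
    ----------------------
    power_ : chosen soft-threshold power
    scale_free_table_ : per-power scan (empty when power was fixed)
    labels_ : gene -> module color ('grey' = unassigned)
    eigengenes_ : samples x modules
    var_explained_ : per-module fraction of variance explained
    tom_ : topological overlap matrix
    linkage_ : scipy linkage of 1 - TOM
    """

    def __init__(self, power=None, signed=True, min_module_size=50,
                 detect_cut_height=0.995, merge_cut_height=0.25,
                 rsq_target=0.8, deep_split=0):
        self.power = power
        self.signed = signed
        self.min_module_size = min_module_size
        self.detect_cut_height = detect_cut_height
        self.merge_cut_height = merge_cut_height
        self.rsq_target = rsq_target
        self.deep_split = deep_split

    def _config(self, power: int) -> NetworkConfig:
        return NetworkConfig(power=power, signed=self.signed,
                             min_module_size=self.min_module_size,
                             detect_cut_height=self.detect_cut_height,
                             merge_cut_height=self.merge_cut_height,
                             rsq_target=self.rsq_target,
                             deep_split=self.deep_split)

    def fit(self, X, y=None):
        frame = _working_frame(X)
        if self.power is None:
            self.scale_free_table_, self.power_ = scale_free_fit(
                frame, rsq_target=self.rsq_target)
        else:
            self.scale_free_table_ = pd.DataFrame()
            self.power_ = int(self.power)
        adj = signed_adjacency(frame, self.power_)
        self.tom_ = topological_overlap(adj)
        partition = cut_modules(1.0 - self.tom_, self._config(self.power_))
        self.linkage_ = partition.linkage
        labels, mes, var = merge_close_modules(
            frame, partition.labels, self.merge_cut_height)
        self.labels_ = labels
        self.eigengenes_ = mes
        self.var_explained_ = var
        return self

    def partition_(self) -> ModulePartition:
        return ModulePartition(labels=self.labels_, eigengenes=self.eigengenes_,
                               var_explained=self.var_explained_,
                               linkage=self.linkage_,
                               config=self._config(self.power_).__dict__.copy())
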