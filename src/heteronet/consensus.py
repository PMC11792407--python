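"""Consensus-module detection across genetic groups, kME/hub-gene calling,
module-overlap tests and eigengene networks.

Per-group TOMs are brought onto a common scale by quantile power-scaling,
combined elementwise at a low quantile (0 = minimum, so an edge must be
supported in every group), clustered like a single-group network (with the
deeper split setting), and merged using a consensus (0.25-quantile across
groups) of the eigengene correlations. Module membership (kME) is the
biweight midcorrelation between a gene and its module eigengene; hub genes
pass kME > 0.70 and P < 1e-5 in a group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .network import (GREY, NetworkConfig, ModulePartition, _working_frame,
                      cor_pvalue_student, cut_modules, module_eigengenes,
                      signed_adjacency, topological_overlap)

logger = logging.getLogger(__name__)


@dataclass
class ConsensusConfig:
    """Parameters of consensus-module detection."""

    consensus_quantile: float = 0.0
    deep_split: int = 2
    detect_cut_height: float = 0.995
    min_module_size: int = 50
    merge_cut_height: float = 0.25
    merge_consensus_quantile: float = 0.25
    scaling_quantile: float = 0.95
    power: int = 12

    def __post_init__(self) -> None:
        for q in (self.consensus_quantile, self.merge_consensus_quantile,
                  self.scaling_quantile):
            if not (0.0 <= q <= 1.0):
                raise ValueError("quantiles must lie in [0, 1]")


# ---------------------------------------------------------------------------
# TOM scaling and consensus
# ---------------------------------------------------------------------------

def _offdiag_quantile(tom: pd.DataFrame, q: float) -> float:
    a = tom.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.quantile(a[iu], q))


def scale_tom_quantile(ref_tom: pd.DataFrame, test_tom: pd.DataFrame,
                       q: float = 0.95) -> pd.DataFrame:
    """Power-scale ``test_tom`` so its q-th off-diagonal quantile matches the
    reference: exponent = log(Q_ref) / log(Q_test), scaled = test ** exponent.

    The map is monotone, so entry ranks are preserved and [0, 1] maps to
    [0, 1]. Degenerate quantiles (0 or 1 in either matrix) are an error.
    """
    if not ref_tom.index.equals(test_tom.index):
        raise ValueError("TOMs must share the same genes in the same order")
    q_ref = _offdiag_quantile(ref_tom, q)
    q_test = _offdiag_quantile(test_tom, q)
    for name, val in (("reference", q_ref), ("test", q_test)):
        if val <= 0.0 or val >= 1.0:
            raise ValueError(f"degenerate {name} TOM quantile {val}")
    exponent = np.log(q_ref) / np.log(q_test)
    scaled = test_tom.to_numpy() ** exponent
    np.fill_diagonal(scaled, 1.0)
    return pd.DataFrame(scaled, index=test_tom.index, columns=test_tom.columns)


def scale_toms_symmetric(toms: dict, q: float = 0.95) -> dict:
    """Scale every TOM so its q-quantile hits the geometric mean of the
    per-group quantiles — a reference-free target, so the result does not
    depend on group order."""
    quantiles = {g: _offdiag_quantile(t, q) for g, t in toms.items()}
    for g, val in quantiles.items():
        if val <= 0.0 or val >= 1.0:
            raise ValueError(f"degenerate TOM quantile {val} for group {g!r}")
    target = float(np.exp(np.mean([np.log(v) for v in quantiles.values()])))
    out = {}
    for g, t in toms.items():
        exponent = np.log(target) / np.log(quantiles[g])
        scaled = t.to_numpy() ** exponent
        np.fill_diagonal(scaled, 1.0)
        out[g] = pd.DataFrame(scaled, index=t.index, columns=t.columns)
    return out


def consensus_tom(toms: list, quantile: float = 0.0,
                  intersect_genes: bool = False) -> pd.DataFrame:
    """Elementwise quantile of aligned TOMs; quantile 0 is the elementwise
    minimum, giving a consensus that every group must support."""
    if len(toms) < 2:
        raise ValueError("consensus needs at least 2 matrices")
    first = toms[0]
    if intersect_genes:
        common = first.index
        for t in toms[1:]:
            common = common.intersection(t.index)
        toms = [t.loc[common, common] for t in toms]
        first = toms[0]
    for t in toms[1:]:
        if not t.index.equals(first.index):
            raise ValueError("TOM gene sets are misaligned "
                             "(pass intersect_genes=True to intersect)")
    stack = np.stack([t.to_numpy() for t in toms])
    cons = np.quantile(stack, quantile, axis=0)
    return pd.DataFrame(cons, index=first.index, columns=first.columns)


# ---------------------------------------------------------------------------
# consensus module detection
# ---------------------------------------------------------------------------

def _consensus_me_correlation(frames: dict, labels: pd.Series,
                              quantile: float) -> tuple[pd.DataFrame, dict]:
    """Consensus (elementwise quantile across groups) of per-group eigengene
    correlation matrices; returns (consensus cor, per-group MEs)."""
    mes = {}
    cors = []
    modules = None
    for g in sorted(frames):
        me, _ = module_eigengenes(frames[g], labels)
        mes[g] = me
        if modules is None:
            modules = list(me.columns)
        me = me[modules]
        cors.append(np.corrcoef(me.to_numpy().T))
    cons = np.quantile(np.stack(cors), quantile, axis=0)
    return pd.DataFrame(cons, index=modules, columns=modules), mes


def detect_consensus_modules(datasets: dict, config: ConsensusConfig | None = None
                             ) -> tuple[ModulePartition, dict]:
    """Consensus modules (CMs) across >= 2 group datasets.

    ``datasets`` maps group -> ExpressionMatrix or working DataFrame; all
    must share the gene universe. Returns the CM partition (labels over
    genes, consensus provenance in ``config``) and per-group eigengenes.
    """
    config = config or ConsensusConfig()
    if len(datasets) < 2:
        raise ValueError("consensus detection needs at least 2 groups")
    frames = {g: _working_frame(x) for g, x in sorted(datasets.items())}
    genes = None
    for g, f in frames.items():
        genes = f.index if genes is None else genes.intersection(f.index)
    frames = {g: f.loc[genes] for g, f in frames.items()}

    toms = {g: topological_overlap(signed_adjacency(f, config.power))
            for g, f in frames.items()}
    scaled = scale_toms_symmetric(toms, q=config.scaling_quantile)
    cons = consensus_tom([scaled[g] for g in sorted(scaled)],
                         quantile=config.consensus_quantile)
    net_cfg = NetworkConfig(power=config.power,
                            min_module_size=config.min_module_size,
                            detect_cut_height=config.detect_cut_height,
                            merge_cut_height=config.merge_cut_height,
                            deep_split=config.deep_split)
    partition = cut_modules(1.0 - cons, net_cfg)
    labels = partition.labels

    # iterative merging on the consensus of ME correlations
    for _ in range(20):
        non_grey = [m for m in labels.unique() if m != GREY]
        if len(non_grey) < 2:
            break
        cons_cor, _ = _consensus_me_correlation(
            frames, labels, config.merge_consensus_quantile)
        diss = np.clip(1.0 - cons_cor.to_numpy(), 0.0, None)
        np.fill_diagonal(diss, 0.0)
        link = average(squareform(diss, checks=False))
        from scipy.cluster.hierarchy import fcluster
        assign = fcluster(link, t=config.merge_cut_height, criterion="distance")
        modules = list(cons_cor.index)
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
            break

    _, group_mes = _consensus_me_correlation(frames, labels,
                                             config.merge_consensus_quantile)
    # variance explained per group is secondary; report the mean across groups
    var = pd.Series({
        m: float(np.mean([
            module_eigengenes(frames[g].loc[labels.index[labels == m]],
                              labels[labels == m])[1].get(m, np.nan)
            for g in frames]))
        for m in labels.unique() if m != GREY
    }, dtype=float)
    me_any = group_mes[sorted(group_mes)[0]]
    result = ModulePartition(labels=labels, eigengenes=me_any,
                             var_explained=var, linkage=partition.linkage,
                             config={**config.__dict__, "groups": sorted(frames)})
    return result, group_mes


# ---------------------------------------------------------------------------
# biweight midcorrelation and kME
# ---------------------------------------------------------------------------

def _bicor_weights(x: np.ndarray, c: float = 9.0):
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (c * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(u, v, c: float = 9.0) -> float:
    """Biweight midcorrelation with tuning constant 9.

    Deviations from the median are downweighted by (1 - u^2)^2 and zeroed
    beyond 9 MADs. If either vector has zero MAD the Pearson correlation is
    returned instead (logged).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if u.size < 3:
        raise ValueError("need at least 3 observations")
    a = _bicor_weights(u, c)
    b = _bicor_weights(v, c)
    if a is None or b is None:
        logger.warning("zero MAD in bicor input; falling back to Pearson")
        if np.std(u) == 0 or np.std(v) == 0:
            return float("nan")
        return float(np.corrcoef(u, v)[0, 1])
    denom = np.sqrt((a ** 2).sum()) * np.sqrt((b ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def kme_table(datasets: dict, labels: pd.Series, group_mes: dict | None = None
              ) -> pd.DataFrame:
    """Per-gene module membership per group: kME = bicor(gene, own-module ME)
    with the Student-t p-value. Grey genes are skipped."""
    frames = {g: _working_frame(x) for g, x in sorted(datasets.items())}
    if group_mes is None:
        group_mes = {g: module_eigengenes(f, labels.loc[f.index])[0]
                     for g, f in frames.items()}
    rows = []
    for g, frame in frames.items():
        mes = group_mes[g]
        n = frame.shape[1]
        for gene, module in labels.items():
            if module == GREY or module not in mes.columns or gene not in frame.index:
                continue
            k = bicor(frame.loc[gene].to_numpy(), mes[module].to_numpy())
            p = float(cor_pvalue_student(k, n)) if np.isfinite(k) else float("nan")
            rows.append({"gene": gene, "module": module, "group": g,
                         "kME": k, "p": p})
    return pd.DataFrame(rows)


@dataclass
class HubGeneSet:
    """Hub genes per group plus intersection counts across groups."""

    per_group: dict = field(default_factory=dict)     # group -> set of genes
    intersections: dict = field(default_factory=dict)  # tuple(groups) -> count
    shared: set = field(default_factory=set)          # genes hub in all groups


def kme_and_hubs(datasets: dict, labels: pd.Series, kme_min: float = 0.70,
                 p_max: float = 1e-5, group_mes: dict | None = None
                 ) -> tuple[pd.DataFrame, HubGeneSet]:
    """kME table plus hub-gene calls (kME > kme_min AND p < p_max, both
    strict) per group, with upset-style intersection counts."""
    table = kme_table(datasets, labels, group_mes=group_mes)
    table["hub"] = (table["kME"] > kme_min) & (table["p"] < p_max)
    groups = sorted(table["group"].unique())
    per_group = {g: set(table.loc[(table["group"] == g) & table["hub"], "gene"])
                 for g in groups}
    inter = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set.intersection(*(per_group[g] for g in combo)) if combo else set()
            outside = set.union(*(per_group[g] for g in groups if g not in combo),
                                *[set()])
            inter[combo] = len(inside - outside)
    shared = set.intersection(*per_group.values()) if per_group else set()
    return table, HubGeneSet(per_group=per_group, intersections=inter, shared=shared)


# ---------------------------------------------------------------------------
# module overlap and eigengene networks
# ---------------------------------------------------------------------------

def module_overlap_fisher(partition_a: pd.Series, partition_b: pd.Series,
                          universe=None) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test of overlap for every
    (module-in-a, module-in-b) pair over a shared gene universe.

    Returns a tidy table with the 2x2 counts, odds ratio, p and -log10 p.
    """
    if universe is None:
        universe = partition_a.index.intersection(partition_b.index)
    universe = pd.Index(universe)
    a = partition_a.loc[universe]
    b = partition_b.loc[universe]
    n_total = len(universe)
    rows = []
    for ma in sorted(a.unique()):
        set_a = set(universe[a == ma])
        for mb in sorted(b.unique()):
            set_b = set(universe[b == mb])
            k = len(set_a & set_b)
            if len(set_a) == 0 or len(set_b) == 0:
                logger.warning("empty module in overlap test: %s/%s", ma, mb)
                p = 1.0
            else:
                # upper tail of the hypergeometric: P(X >= k)
                p = float(stats.hypergeom.sf(k - 1, n_total, len(set_a), len(set_b)))
            table = np.array([
                [k, len(set_a) - k],
                [len(set_b) - k, n_total - len(set_a) - len(set_b) + k],
            ])
            odds = float(stats.contingency.odds_ratio(table, kind="sample").statistic) \
                if table.min() >= 0 and k > 0 else 0.0
            rows.append({"module_a": ma, "module_b": mb, "overlap": k,
                         "size_a": len(set_a), "size_b": len(set_b),
                         "universe": n_total, "odds_ratio": odds, "p": p,
                         "neg_log10_p": float(-np.log10(max(p, 1e-300)))})
    return pd.DataFrame(rows)


def eigengene_network(group_mes: dict) -> dict:
    """Per group: bicor matrix between module eigengenes and the average-
    linkage dendrogram of 1 - cor."""
    out = {}
    for g, mes in sorted(group_mes.items()):
        cols = list(mes.columns)
        if len(cols) < 2:
            raise ValueError("eigengene network needs at least 2 eigengenes")
        m = np.ones((len(cols), len(cols)))
        for i, j in itertools.combinations(range(len(cols)), 2):
            r = bicor(mes[cols[i]].to_numpy(), mes[cols[j]].to_numpy())
            m[i, j] = m[j, i] = r
        cor = pd.DataFrame(m, index=cols, columns=cols)
        diss = np.clip(1.0 - m, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        link = average(squareform(diss, checks=False))
        out[g] = {"cor": cor, "linkage": link}
    return out


class ConsensusModules(BaseEstimator):
    """Consensus module detection, estimator-style.

    ``fit`` takes a dict of group -> ExpressionMatrix (or working
    DataFrame). Fitted attributes: ``labels_``, ``eigengenes_`` (per group),
    ``partition_``.
    """

    def __init__(self, power=12, consensus_quantile=0.0, deep_split=2,
                 detect_cut_height=0.995, min_module_size=50,
                 merge_cut_height=0.25, merge_consensus_quantile=0.25,
                 scaling_quantile=0.95):
        self.power = power
        self.consensus_quantile = consensus_quantile
        self.deep_split = deep_split
        self.detect_cut_height = detect_cut_height
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.merge_consensus_quantile = merge_consensus_quantile
        self.scaling_quantile = scaling_quantile

    def fit(self, X, y=None):
        config = ConsensusConfig(
            consensus_quantile=self.consensus_quantile,
            deep_split=self.deep_split,
            detect_cut_height=self.detect_cut_height,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
            merge_consensus_quantile=self.merge_consensus_quantile,
            scaling_quantile=self.scaling_quantile,
            power=self.power)
        self.partition_, self.eigengenes_ = detect_consensus_modules(X, config)
        self.labels_ = self.partition_.labels
        return self
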