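"""Permutation-based module preservation between a reference and a test
expression dataset, summarized as Zsummary.

For every reference module the observed statistics in the test data are

density family
    * meanAdj — mean off-diagonal signed adjacency among module genes;
    * propVarExplained — variance explained by the module's first principal
      component computed from the test data;

connectivity family
    * cor.kIM — correlation of intramodular connectivity between reference
      and test networks over module genes;
    * cor.adj — correlation of the within-module adjacency entries between
      the two networks.

The null distribution permutes module membership: ``n_perm`` random gene
sets of the same size are drawn from the network genes and the statistics
recomputed. Z = (observed - null mean) / null SD per statistic;
Zdensity / Zconnectivity are the medians within each family and
Zsummary = (Zdensity + Zconnectivity) / 2. The interpretation thresholds:
Zsummary > 10 strong preservation, 2 < Zsummary <= 10 weak to moderate,
<= 2 none.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import GREY, _working_frame, signed_adjacency

logger = logging.getLogger(__name__)

STRONG_THRESHOLD = 10.0
WEAK_THRESHOLD = 2.0

_STATS = ("meanAdj", "propVarExplained", "cor.kIM", "cor.adj")
_DENSITY = ("meanAdj", "propVarExplained")
_CONNECTIVITY = ("cor.kIM", "cor.adj")


def preservation_call(zsummary: float) -> str:
    if not np.isfinite(zsummary):
        return "undefined"
    if zsummary > STRONG_THRESHOLD:
        return "strong"
    if zsummary > WEAK_THRESHOLD:
        return "weak-to-moderate"
    return "none"


def _prop_var_explained(z_frame: np.ndarray) -> float:
    """Share of variance along the first PC of a gene-standardized
    genes x samples block."""
    sd = z_frame.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        return float("nan")
    z = (z_frame[keep] - z_frame[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    s = np.linalg.svd(z, compute_uv=False)
    return float(s[0] ** 2 / (s ** 2).sum())


def _module_stats(idx_ref: np.ndarray, idx_test: np.ndarray,
                  adj_ref: np.ndarray, adj_test: np.ndarray,
                  test_values: np.ndarray) -> dict:
    """Preservation statistics for a module.

    ``idx_ref`` indexes the module genes on the reference side; ``idx_test``
    on the test side. Observed statistics use the same genes on both sides;
    the permutation null replaces the test side with a random gene set of
    the same size (permuted module labels in the test network), which breaks
    the gene correspondence the connectivity statistics measure.
    """
    sub_ref = adj_ref[np.ix_(idx_ref, idx_ref)]
    sub_test = adj_test[np.ix_(idx_test, idx_test)]
    m = len(idx_ref)
    iu = np.triu_indices(m, k=1)
    mean_adj = float(sub_test[iu].mean())
    pve = _prop_var_explained(test_values[idx_test])
    kim_ref = sub_ref.sum(axis=0) - 1.0
    kim_test = sub_test.sum(axis=0) - 1.0
    with np.errstate(invalid="ignore"):
        cor_kim = float(np.corrcoef(kim_ref, kim_test)[0, 1])
        cor_adj = float(np.corrcoef(sub_ref[iu], sub_test[iu])[0, 1])
    return {"meanAdj": mean_adj, "propVarExplained": pve,
            "cor.kIM": cor_kim, "cor.adj": cor_adj}


def module_preservation(reference, labels: pd.Series, test, power: int = 6,
                        n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per-module preservation report of reference modules in test data.

    ``reference`` and ``test`` are ExpressionMatrix or working DataFrames;
    genes are intersected. Modules overlapping the test data in fewer than 3
    genes are skipped. Returns one row per module with the observed
    statistics, their permutation Z scores, Zdensity, Zconnectivity,
    Zsummary and the threshold call.
    """
    ref_frame = _working_frame(reference)
    test_frame = _working_frame(test)
    common = ref_frame.index.intersection(test_frame.index)
    if len(common) < 3:
        raise ValueError("reference and test gene universes barely overlap")
    ref_frame = ref_frame.loc[common]
    test_frame = test_frame.loc[common]
    labels = labels.reindex(common).fillna(GREY)

    adj_ref = signed_adjacency(ref_frame, power).to_numpy()
    adj_test = signed_adjacency(test_frame, power).to_numpy()
    test_values = test_frame.to_numpy()
    pos = {g: i for i, g in enumerate(common)}

    rng = np.random.default_rng(seed)
    n_genes = len(common)
    rows = []
    modules = sorted(m for m in labels.unique() if m != GREY)
    for module in modules:
        genes = labels.index[labels == module]
        idx = np.array([pos[g] for g in genes])
        if len(idx) < 3:
            logger.warning("module %s overlaps test data in <3 genes; skipped",
                           module)
            continue
        observed = _module_stats(idx, idx, adj_ref, adj_test, test_values)
        null = {s: np.empty(n_perm) for s in _STATS}
        for b in range(n_perm):
            perm = rng.choice(n_genes, size=len(idx), replace=False)
            st = _module_stats(idx, perm, adj_ref, adj_test, test_values)
            for s in _STATS:
                null[s][b] = st[s]
        z = {}
        for s in _STATS:
            mu = np.nanmean(null[s])
            sd = np.nanstd(null[s], ddof=1)
            if not np.isfinite(sd) or sd == 0:
                logger.warning("zero null SD for %s in module %s", s, module)
                z[s] = float("nan")
            else:
                z[s] = float((observed[s] - mu) / sd)
        z_density = float(np.nanmedian([z[s] for s in _DENSITY]))
        z_connectivity = float(np.nanmedian([z[s] for s in _CONNECTIVITY]))
        z_summary = (z_density + z_connectivity) / 2.0
        row = {"module": module, "moduleSize": int(len(idx))}
        row.update({f"obs.{s}": observed[s] for s in _STATS})
        row.update({f"Z.{s}": z[s] for s in _STATS})
        row.update({"Zdensity": z_density, "Zconnectivity": z_connectivity,
                    "Zsummary": z_summary, "n_permutations": int(n_perm),
                    "seed": int(seed), "call": preservation_call(z_summary)})
        rows.append(row)
    return pd.DataFrame(rows)


def separability_check(labels: pd.Series, test, cor_max: float = 0.9
                       ) -> pd.DataFrame:
    """Eigengene correlation between every module pair in the test data;
    a pair is non-separable when |cor| exceeds ``cor_max``.

    Reported separately from Zsummary (which combines only the density and
    connectivity families).
    """
    from .network import module_eigengenes

    frame = _working_frame(test)
    mes, _ = module_eigengenes(frame, labels.reindex(frame.index).fillna(GREY))
    modules = list(mes.columns)
    if len(modules) < 2:
        raise ValueError("separability needs at least 2 modules")
    rows = []
    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            r = float(np.corrcoef(mes[modules[i]], mes[modules[j]])[0, 1])
            rows.append({"module_a": modules[i], "module_b": modules[j],
                         "me_cor": r, "separable": abs(r) <= cor_max})
    return pd.DataFrame(rows)


class ModulePreservation(BaseEstimator):
    """Estimator wrapper: fix the permutation scheme at construction, fit on
    the reference (data + labels), then ``evaluate`` test datasets."""

    def __init__(self, power=6, n_permutations=100, random_state=0):
        self.power = power
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        """X: reference expression; y: gene -> module labels."""
        self.reference_ = X
        self.labels_ = pd.Series(y) if not isinstance(y, pd.Series) else y
        return self

    def evaluate(self, X_test) -> pd.DataFrame:
        report = module_preservation(
            self.reference_, self.labels_, X_test, power=self.power,
            n_perm=self.n_permutations, seed=self.random_state)
        self.report_ = report
        return report
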