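"""Classification of gene expression into the 12 inheritance categories.

For one cross (WY or YW) at one laying stage, each gene's FPKM values in the
two purebreds (WW, YY) and the cross are compared with four tests:

* WW vs YY, F1 vs WW, F1 vs YY — Welch two-sample t-tests;
* F1 vs mid-parent — one-sample t-test of the F1 replicates against the
  estimated mid-parent constant (mu_WW + mu_YY) / 2.

Benjamini-Hochberg FDR is applied per comparison across genes within the
stage. The decision tree (fixed precedence so each gene gets one label):

1. overdominance — F1 significantly different from BOTH purebreds in the
   same direction; above/below parent (I / VII) when the purebreds do not
   differ, above high-parent (II, XII) / below low-parent (VI, VIII) when
   they do;
2. dominance — F1 significantly different from exactly one purebred and not
   from the other; high-parent (III, XI) when the matched parent is the
   higher one, low-parent (V, IX) otherwise;
3. additivity (IV, X) — purebreds significantly different and F1 not
   significantly different from the mid-parent;
4. otherwise none.

Within each mirrored pair the roman numeral follows the sign of
mu_YY - mu_WW (first numeral: YY higher), so swapping the parent labels
mirrors the numeral but never the supercategory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CROSSES, ExpressionMatrix
from .simulate import MIRROR, SUPERCATEGORY  # category tables shared with the generator

logger = logging.getLogger(__name__)

COMPARISONS = ("WW_vs_YY", "F1_vs_WW", "F1_vs_YY", "F1_vs_MPV")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are passed through; everything else must lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    if finite.sum():
        adjusted[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return adjusted


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, welch: bool):
    """Row-wise two-sample t-test with the degenerate-variance convention:
    both groups constant -> p = 1 when means agree, p = 0 when they differ."""
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        logger.warning("%d gene(s) with zero variance in both groups",
                       int(degenerate.sum()))
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(same, 0.0, np.inf), t)
    return t, p


def pairwise_gene_tests(x: ExpressionMatrix, cross: str, stage: int,
                        welch: bool = True,
                        midparent_mode: str = "one_sample") -> pd.DataFrame:
    """Per-gene test table for one cross at one stage, FDR per comparison.

    ``midparent_mode``: ``"one_sample"`` tests the F1 replicates against the
    estimated mid-parent constant; ``"pooled_parents"`` runs a two-sample
    Welch test of F1 against mean-centred parent pseudo-samples shifted to
    the mid-parent value.
    """
    if cross not in CROSSES:
        raise ValueError(f"cross must be one of {CROSSES}")
    meta = x.meta
    sel_stage = meta["stage"] == stage
    arrays = {}
    for group in ("WW", "YY", cross):
        cols = meta.index[sel_stage & (meta["group"] == group)]
        if len(cols) < 2:
            raise ValueError(f"need >= 2 replicates for {group} at stage {stage}")
        arrays[group] = x.values[cols].to_numpy(dtype=float)
    ww, yy, f1 = arrays["WW"], arrays["YY"], arrays[cross]
    mu_ww = ww.mean(axis=1)
    mu_yy = yy.mean(axis=1)
    mu_f1 = f1.mean(axis=1)
    mpv = (mu_ww + mu_yy) / 2.0

    out = pd.DataFrame(index=x.genes)
    out["mu_WW"], out["mu_YY"], out["mu_F1"], out["mpv"] = mu_ww, mu_yy, mu_f1, mpv

    t, p = _welch_or_pooled(ww, yy, welch)
    out["t_WW_vs_YY"], out["p_WW_vs_YY"] = t, p
    t, p = _welch_or_pooled(f1, ww, welch)
    out["t_F1_vs_WW"], out["p_F1_vs_WW"] = t, p
    t, p = _welch_or_pooled(f1, yy, welch)
    out["t_F1_vs_YY"], out["p_F1_vs_YY"] = t, p

    if midparent_mode == "one_sample":
        t, p = stats.ttest_1samp(f1, popmean=mpv[:, None], axis=1)
        sd = f1.std(axis=1, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            same = np.isclose(mu_f1, mpv)
            p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
            t = np.where(degenerate, np.where(same, 0.0, np.inf), t)
    elif midparent_mode == "pooled_parents":
        pseudo = np.concatenate([ww - mu_ww[:, None] + mpv[:, None],
                                 yy - mu_yy[:, None] + mpv[:, None]], axis=1)
        t, p = _welch_or_pooled(f1, pseudo, welch)
    else:
        raise ValueError(f"unknown midparent_mode {midparent_mode!r}")
    out["t_F1_vs_MPV"], out["p_F1_vs_MPV"] = t, p

    for comp in COMPARISONS:
        out[f"fdr_{comp}"] = bh_fdr(out[f"p_{comp}"].to_numpy())
    out["cross"] = cross
    out["stage"] = stage
    return out


def _category_for_row(mu_ww, mu_yy, mu_f1, sig_pp, sig_fw, sig_fy, sig_mid) -> str:
    yy_high = mu_yy > mu_ww
    ww_high = mu_ww > mu_yy
    # 1. overdominance: F1 significant vs both parents, same direction
    if sig_fw and sig_fy:
        above = mu_f1 > mu_ww and mu_f1 > mu_yy
        below = mu_f1 < mu_ww and mu_f1 < mu_yy
        if above:
            if not sig_pp:
                return "I"
            return "II" if yy_high else ("XII" if ww_high else "none")
        if below:
            if not sig_pp:
                return "VII"
            return "VI" if yy_high else ("VIII" if ww_high else "none")
        # F1 between the parents while significant against both: fall
        # through to the additivity check (conflicting-pattern rule)
    # 2. dominance: F1 significant vs exactly one parent
    elif sig_fw != sig_fy:
        matched_is_yy = sig_fw  # non-significant side is the matched parent
        if mu_ww == mu_yy:
            return "none"  # high vs low parent undefined
        matched_high = (mu_yy > mu_ww) if matched_is_yy else (mu_ww > mu_yy)
        if matched_high:
            return "III" if yy_high else "XI"
        return "V" if yy_high else "IX"
    # 3. additivity: parents differ, F1 consistent with the mid-parent
    if sig_pp and not sig_mid:
        return "IV" if yy_high else ("X" if ww_high else "none")
    return "none"


def classify_gene_action(tests: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Assign each gene of a test table one roman-numeral category (or none)
    and its supercategory."""
    sig = {comp: tests[f"fdr_{comp}"].to_numpy() < fdr for comp in COMPARISONS}
    categories = []
    for i, (_, row) in enumerate(tests.iterrows()):
        missing = any(not np.isfinite(tests[f"fdr_{c}"].iloc[i]) for c in COMPARISONS)
        if missing:
            categories.append("none")
            continue
        categories.append(_category_for_row(
            row["mu_WW"], row["mu_YY"], row["mu_F1"],
            sig["WW_vs_YY"][i], sig["F1_vs_WW"][i], sig["F1_vs_YY"][i],
            sig["F1_vs_MPV"][i]))
    out = tests.copy()
    out["category"] = categories
    out["supercategory"] = [SUPERCATEGORY[c] for c in categories]
    return out


def classify_expression(x: ExpressionMatrix, cross: str, fdr: float = 0.05,
                        welch: bool = True,
                        midparent_mode: str = "one_sample",
                        stages=None) -> pd.DataFrame:
    """Full gene x stage classification for one cross."""
    if stages is None:
        stages = sorted(x.meta["stage"].unique())
    frames = []
    for stage in stages:
        tests = pairwise_gene_tests(x, cross, stage, welch=welch,
                                    midparent_mode=midparent_mode)
        frames.append(classify_gene_action(tests, fdr=fdr).reset_index()
                      .rename(columns={"index": "gene"}))
    return pd.concat(frames, ignore_index=True)


def dominance_complementarity_summary(calls: pd.DataFrame, genes=None
                                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage category counts and stage-to-stage supercategory switches
    for a supplied gene list (e.g. hub genes of a pathway).

    Returns (counts per stage x category, transition table with one row per
    gene per consecutive stage pair).
    """
    if genes is not None:
        calls = calls[calls["gene"].isin(set(genes))]
    if calls.empty:
        return (pd.DataFrame(columns=["stage", "category", "count"]),
                pd.DataFrame(columns=["gene", "from_stage", "to_stage",
                                      "from", "to"]))
    counts = (calls.groupby(["stage", "category"]).size()
              .rename("count").reset_index())
    stages = sorted(calls["stage"].unique())
    wide = calls.pivot_table(index="gene", columns="stage",
                             values="supercategory", aggfunc="first")
    transitions = []
    for a, b in zip(stages[:-1], stages[1:]):
        if a not in wide.columns or b not in wide.columns:
            continue
        for gene, row in wide.iterrows():
            if pd.isna(row.get(a)) or pd.isna(row.get(b)):
                continue
            transitions.append({"gene": gene, "from_stage": a, "to_stage": b,
                                "from": row[a], "to": row[b]})
    return counts, pd.DataFrame(transitions)


class GeneActionClassifier(BaseEstimator):
    """Estimator wrapper over the gene-action decision tree.

    ``fit(X)`` with an ExpressionMatrix runs the tests and classification
    for the configured cross across all stages; results land in ``calls_``.
    """

    def __init__(self, cross="WY", fdr=0.05, welch=True,
                 midparent_mode="one_sample"):
        self.cross = cross
        self.fdr = fdr
        self.welch = welch
        self.midparent_mode = midparent_mode

    def fit(self, X, y=None):
        self.calls_ = classify_expression(
            X, self.cross, fdr=self.fdr, welch=self.welch,
            midparent_mode=self.midparent_mode)
        return self

    def predict(self, X=None) -> pd.Series:
        """Category per gene x stage from the fitted calls."""
        return self.calls_.set_index(["gene", "stage"])["category"]
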