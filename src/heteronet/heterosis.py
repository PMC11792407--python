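"""Heterosis index and its significance test.

Heterosis for a trait in a cross is measured against the mid-parent value
(MPV), the arithmetic mean of the two purebred line means:

    H = (F_bar - MPV) / MPV

and its significance comes from a transformed Student's t computed from the
cross phenotypes alone, with the parent means treated as fixed constants:

    t = H / ( 2 * s / ((P_bar_p + P_bar_m) * sqrt(n)) )

which is algebraically identical to t = (F_bar - MPV) * sqrt(n) / s, with
s the sample SD of the cross and df = n - 1. Both forms are computed and
asserted equal. The p-value is two-sided by default (the one-sided variant
is available by flag); p < 0.05 flags a window as significant downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CROSSES

logger = logging.getLogger(__name__)


def mid_parent_value(p_bar_p: float, p_bar_m: float) -> float:
    """Arithmetic mean of the two parental line means."""
    return (float(p_bar_p) + float(p_bar_m)) / 2.0


def heterosis_index(f_bar: float, mpv: float) -> float:
    """H = (F_bar - MPV) / MPV, as a fraction (0.10 == 10%)."""
    if mpv <= 0:
        raise ValueError("mid-parent value must be positive")
    return (float(f_bar) - mpv) / mpv


def heterosis_t_test(f: np.ndarray, p_bar_p: float, p_bar_m: float,
                     two_sided: bool = True) -> tuple[float, int, float]:
    """Transformed t-test of H against zero; returns (t, df, p).

    ``f`` holds the per-bird cross phenotypes; the parent means enter as
    fixed constants (no parent-variance term).
    """
    f = np.asarray(f, dtype=float)
    n = f.size
    if n < 2:
        raise ValueError("need at least 2 cross phenotypes")
    f_bar = f.mean()
    s = f.std(ddof=1)
    if s == 0:
        raise ValueError("zero SD among cross phenotypes: t undefined")
    mpv = mid_parent_value(p_bar_p, p_bar_m)
    h = heterosis_index(f_bar, mpv)
    t_printed = h / (2.0 * s / ((p_bar_p + p_bar_m) * np.sqrt(n)))
    t_direct = (f_bar - mpv) * np.sqrt(n) / s
    if not np.isclose(t_printed, t_direct, rtol=1e-9, atol=1e-12):
        raise AssertionError("the two algebraic forms of t disagree")
    df = n - 1
    if two_sided:
        p = 2.0 * stats.t.sf(abs(t_printed), df)
    else:
        p = stats.t.sf(t_printed, df)
    return float(t_printed), int(df), float(min(p, 1.0))


@dataclass
class HeterosisEstimate:
    """One window's heterosis estimate for one cross and trait."""

    cross: str
    window: int
    f_bar: float
    p_bar_p: float
    p_bar_m: float
    mpv: float
    h: float
    h_percent: float
    s: float
    n: int
    t: float
    df: int
    p: float
    significant: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def heterosis_by_window(phenotypes: pd.DataFrame, cross: str = "WY",
                        trait: str = "egg_number", alpha: float = 0.05,
                        two_sided: bool = True,
                        parents: tuple = ("WW", "YY")) -> pd.DataFrame:
    """One HeterosisEstimate row per 4-week window for one cross.

    Windows missing the cross or either parent group are skipped with a
    logged warning. Returns a DataFrame with all estimate fields.
    """
    if cross not in CROSSES:
        raise ValueError(f"cross must be one of {CROSSES}")
    required = {"group", "window", trait}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    rows = []
    for window, sub in phenotypes.groupby("window"):
        by_group = {g: sub.loc[sub["group"] == g, trait].to_numpy(dtype=float)
                    for g in (*parents, cross)}
        if any(len(v) == 0 for v in by_group.values()):
            logger.warning("window %s skipped: missing group data", window)
            continue
        p_bar_p = by_group[parents[0]].mean()
        p_bar_m = by_group[parents[1]].mean()
        f = by_group[cross]
        mpv = mid_parent_value(p_bar_p, p_bar_m)
        h = heterosis_index(f.mean(), mpv)
        t, df, p = heterosis_t_test(f, p_bar_p, p_bar_m, two_sided=two_sided)
        rows.append(HeterosisEstimate(
            cross=cross, window=int(window), f_bar=float(f.mean()),
            p_bar_p=float(p_bar_p), p_bar_m=float(p_bar_m), mpv=float(mpv),
            h=float(h), h_percent=float(100 * h), s=float(f.std(ddof=1)),
            n=int(f.size), t=t, df=df, p=p, significant=bool(p < alpha),
        ).as_dict())
    return pd.DataFrame(rows)


def stage_mean_heterosis(estimates: pd.DataFrame, stage_of_window: dict) -> pd.DataFrame:
    """Unweighted mean of window H within each laying stage.

    ``stage_of_window`` maps window index -> stage label (e.g. 's1'..'s5').
    """
    est = estimates.copy()
    est["stage"] = est["window"].map(stage_of_window)
    out = est.groupby("stage", dropna=True).agg(
        mean_h=("h", "mean"), mean_h_percent=("h_percent", "mean"),
        n_windows=("window", "size"))
    return out.reset_index()
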