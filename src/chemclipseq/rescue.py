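"""Treatment-rescue classification for expression and splicing.

A feature (gene abundance, or the percent-spliced-in of a splicing
event) is *dysregulated* when disease-vehicle differs from healthy-
vehicle (Welch's t-test, p < alpha); it is *shifted toward WT* when the
treated-group mean is closer to the healthy mean than the vehicle-group
mean is; and it is *rescued* when it was dysregulated, is shifted toward
WT, and is no longer significantly different from healthy after
treatment (p > alpha).

Expression is tested on log2(TPM + 1); percent-spliced-in values are
tested untransformed on [0, 1] (an arcsine-square-root transform is
available by flag). The per-feature test is a plain Welch t with raw
p-values by default — the classification rule this module implements is
a raw p < 0.05 rule. For transcriptome-scale *summaries* (the estimated
fraction of dysregulated features that treatment rescued), the
convenience estimator additionally applies a volcano-style effect-size
floor to the dysregulation calls (|group-mean difference| >= 1 log2
unit for expression, >= 0.1 for percent-spliced-in): at thousands of
null features a 5% per-feature error rate floods the dysregulated set
with false discoveries whose apparent "rescue" is a selection artifact,
biasing the estimated fraction regardless of the truth. (Benjamini-
Hochberg control is available instead, but at 2-3 replicates per group
the Welch test cannot produce p-values small enough to survive it, so
the fold-change floor is the default.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError

__all__ = [
    "RescueTable",
    "welch_pvalues",
    "classify_dysregulated",
    "classify_rescued",
    "estimate_rescue_fraction",
]

_P_FLOOR = 1e-300  # keeps p in (0, 1] when a zero-variance feature separates cleanly


def _transform(matrix: pd.DataFrame, mode: str, arcsine: bool = False) -> pd.DataFrame:
    if mode == "expression":
        if (matrix.values < 0).any():
            raise ConfigError("expression matrix contains negative values")
        return np.log2(matrix + 1.0)
    if mode == "psi":
        clipped = matrix.clip(0.0, 1.0)
        if arcsine:
            return np.arcsin(np.sqrt(clipped))
        return clipped
    raise ConfigError(f"unknown mode {mode!r} (expected 'expression' or 'psi')")


def welch_pvalues(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Row-wise Welch t-test p-values for two replicate matrices.

    Features that are constant across both groups get p = 1 (with a
    warning); a zero-variance feature whose group means differ is
    maximally significant and gets the p floor.
    """
    if not a.index.equals(b.index):
        raise ConfigError("feature indices of the two matrices differ")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ConfigError("need >= 2 replicates per group for the Welch test")
    av, bv = a.values.astype(float), b.values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(av, bv, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        means_equal = np.isclose(av.mean(axis=1), bv.mean(axis=1))
        n_const = int(degenerate.sum())
        warnings.warn(
            f"{n_const} feature(s) with degenerate (zero) variance; "
            "p set to 1 where group means agree",
            stacklevel=2,
        )
        p[degenerate & means_equal] = 1.0
        p[degenerate & ~means_equal] = _P_FLOOR
    return np.clip(p, _P_FLOOR, 1.0)


def classify_dysregulated(
    matrix_wt: pd.DataFrame,
    matrix_dm1: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "expression",
    correction: str = "none",
    min_effect: float = 0.0,
    arcsine: bool = False,
) -> pd.DataFrame:
    """Per-feature dysregulation calls: disease-vehicle vs healthy-vehicle.

    Returns a table with group means/sds (on the tested scale),
    p_vehicle, and the ``dysregulated`` flag: p < alpha (BH-adjusted
    when ``correction="bh"``) and, if ``min_effect`` > 0, an absolute
    group-mean difference of at least ``min_effect`` on the tested
    scale (a volcano-plot-style fold-change floor).
    """
    if correction not in ("none", "bh"):
        raise ConfigError(f"unknown correction {correction!r}")
    wt = _transform(matrix_wt, mode, arcsine)
    dm1 = _transform(matrix_dm1, mode, arcsine)
    p = welch_pvalues(wt, dm1)
    p_eff = multipletests(p, method="fdr_bh")[1] if correction == "bh" else p
    delta = dm1.mean(axis=1) - wt.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_wt": wt.mean(axis=1),
            "sd_wt": wt.std(axis=1, ddof=1),
            "mean_vehicle": dm1.mean(axis=1),
            "sd_vehicle": dm1.std(axis=1, ddof=1),
            "p_vehicle": p,
            "p_vehicle_adj": p_eff,
            "dysregulated": (p_eff < alpha) & (delta.abs() >= min_effect),
        },
        index=matrix_wt.index,
    )


@dataclass
class RescueTable:
    """Per-feature rescue classification plus summary counts/fractions."""

    table: pd.DataFrame
    summary: dict

    def __repr__(self) -> str:  # compact, summary-first
        s = self.summary
        return (
            f"RescueTable({s['n_features']} features, "
            f"{s['n_dysregulated']} dysregulated, {s['n_rescued']} rescued "
            f"[{100 * s['fraction_rescued']:.0f}%])"
        )


def classify_rescued(
    dysregulation: pd.DataFrame,
    matrix_wt: pd.DataFrame,
    matrix_treated: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "expression",
    arcsine: bool = False,
) -> RescueTable:
    """Extend dysregulation calls with the treated group and flag rescue.

    A feature is shifted toward WT when |mean_treated - mean_wt| <
    |mean_vehicle - mean_wt| (group means on the tested scale); it is
    rescued when it was dysregulated, is shifted, and its treated-vs-WT
    Welch p exceeds alpha (no longer statistically different). The
    summary reports the counts and the fractions among dysregulated
    features. ``matrix_wt`` must be the same healthy-vehicle matrix the
    dysregulation calls were made against (p_treated tests against its
    replicates).
    """
    if not dysregulation.index.equals(matrix_treated.index):
        raise ConfigError("treated matrix features do not match the dysregulation table")
    if not dysregulation.index.equals(matrix_wt.index):
        raise ConfigError("WT matrix features do not match the dysregulation table")
    treated = _transform(matrix_treated, mode, arcsine)
    p_treated = welch_pvalues(_transform(matrix_wt, mode, arcsine), treated)

    out = dysregulation.copy()
    out["mean_treated"] = treated.mean(axis=1)
    out["sd_treated"] = treated.std(axis=1, ddof=1)
    out["p_treated"] = p_treated
    out["shifted_toward_wt"] = (
        (out["mean_treated"] - out["mean_wt"]).abs()
        < (out["mean_vehicle"] - out["mean_wt"]).abs()
    )
    out["rescued"] = out["dysregulated"] & out["shifted_toward_wt"] & (p_treated > alpha)

    n_dys = int(out["dysregulated"].sum())
    n_shifted = int((out["dysregulated"] & out["shifted_toward_wt"]).sum())
    n_rescued = int(out["rescued"].sum())
    summary = {
        "n_features": int(len(out)),
        "n_dysregulated": n_dys,
        "n_shifted_toward_wt": n_shifted,
        "n_rescued": n_rescued,
        "fraction_shifted": n_shifted / n_dys if n_dys else float("nan"),
        "fraction_rescued": n_rescued / n_dys if n_dys else float("nan"),
        "alpha": alpha,
    }
    return RescueTable(table=out, summary=summary)


def estimate_rescue_fraction(
    matrix_wt: pd.DataFrame,
    matrix_vehicle: pd.DataFrame,
    matrix_treated: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "expression",
    correction: str = "none",
    min_effect: float | None = None,
    arcsine: bool = False,
) -> RescueTable:
    """End-to-end rescue estimate: dysregulate, classify, summarize.

    Applies an effect-size floor to the dysregulation calls by default
    (1 log2 unit for expression, 0.1 for percent-spliced-in; see the
    module docstring for why a raw per-feature alpha misbehaves at
    transcriptome scale); pass ``min_effect=0`` for the raw rule. The
    per-feature classification logic is otherwise unchanged.
    """
    if min_effect is None:
        min_effect = 1.0 if mode == "expression" else 0.1
    dys = classify_dysregulated(
        matrix_wt, matrix_vehicle, alpha=alpha, mode=mode,
        correction=correction, min_effect=min_effect, arcsine=arcsine,
    )
    return classify_rescued(
        dys, matrix_wt, matrix_treated, alpha=alpha, mode=mode, arcsine=arcsine
    )
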