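"""Per-variant summary-statistic sensitivity estimators.

IVW (through-origin weighted regression), MR-Egger (free intercept, the
intercept estimating average directional pleiotropy under InSIDE), the
weighted median (consistent when >= 50% of weight is from valid
instruments), and the minus-0.5 correction for the same-trait design.

These are one-sample sensitivity analyses: outputs carry a weak-instrument
warning when the mean per-variant F falls below 10, since the performance
of Egger/IVW deteriorates rapidly under weak-instrument bias and no simple
one-sample correction exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimators import Z95, IVEstimate
from .simulate import TrioCohort

__all__ = [
    "VariantSummary",
    "per_variant_summaries",
    "orient_summaries",
    "summaries_to_frame",
    "summaries_from_frame",
    "read_summaries",
    "write_summaries",
    "ivw",
    "mr_egger",
    "weighted_median",
    "minus_half_correction",
    "InsufficientInstrumentsError",
    "DegenerateRegressionError",
]

WEAK_INSTRUMENT_F = 10.0

SUMMARY_COLUMNS = ("variant", "beta_x", "se_x", "beta_y", "se_y")


class InsufficientInstrumentsError(ValueError):
    """Too few variant summaries for the requested estimator."""


class DegenerateRegressionError(ValueError):
    """No spread in the instrument-exposure coefficients."""


@dataclass(frozen=True)
class VariantSummary:
    """Per-variant exposure and outcome association coefficients.

    ``beta_x``/``beta_y`` are per-effect-allele effects (SD per allele);
    ``oriented`` records that the pair has been harmonized so beta_x >= 0.
    """

    variant_index: int
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    oriented: bool = False

    def __post_init__(self):
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("standard errors must be positive")

    @property
    def ratio(self) -> float:
        return self.beta_y / self.beta_x

    @property
    def f_statistic(self) -> float:
        return (self.beta_x / self.se_x) ** 2

    def orient(self) -> "VariantSummary":
        """Flip both coefficients jointly so the exposure effect is >= 0."""
        if self.beta_x < 0:
            return replace(
                self, beta_x=-self.beta_x, beta_y=-self.beta_y, oriented=True
            )
        return replace(self, oriented=True)


def orient_summaries(summaries: Sequence[VariantSummary]) -> list[VariantSummary]:
    return [s.orient() for s in summaries]


def _simple_slope(x: np.ndarray, y: np.ndarray):
    """OLS slope and homoskedastic SE of y on [1, x]."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ y) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    sigma2 = float(resid @ resid) / (n - 2)
    return slope, float(np.sqrt(sigma2 / sxx))


def per_variant_summaries(
    cohort: TrioCohort,
    adjust_offspring: bool = True,
    external_beta_x: Optional[pd.DataFrame] = None,
    orient: bool = True,
) -> list[VariantSummary]:
    """One exposure and one outcome regression per panel variant.

    The exposure coefficient regresses ``X_m`` on the maternal dosage; the
    outcome coefficient regresses ``Y_o`` on the maternal dosage,
    conditioning on the offspring dosage of the *same* variant when
    ``adjust_offspring`` (the recommended configuration: it restores InSIDE
    when maternal exposure and offspring outcome share genetics).

    ``external_beta_x`` (columns ``variant``, ``beta_x``, ``se_x``)
    substitutes externally estimated exposure coefficients; by default
    internal weights are used, with a warning that internal weights
    aggravate one-sample weak-instrument bias.

    Monomorphic variants are excluded with a warning.
    """
    mom = cohort.maternal_genotype.astype(float)
    kid = cohort.offspring_genotype.astype(float)
    x, y = cohort.X_m, cohort.Y_o
    n = cohort.n_trios

    external = None
    if external_beta_x is not None:
        external = external_beta_x.set_index("variant")
    else:
        warnings.warn(
            "using internal instrument-exposure weights; these exacerbate "
            "weak-instrument bias in one-sample analyses",
            stacklevel=2,
        )

    out = []
    for j in range(cohort.n_variants):
        g = mom[:, j]
        if np.ptp(g) == 0:
            warnings.warn(f"variant {j} is monomorphic; excluded", stacklevel=2)
            continue
        if external is not None and j in external.index:
            bx, sx = float(external.loc[j, "beta_x"]), float(external.loc[j, "se_x"])
        else:
            bx, sx = _simple_slope(g, x)
        if adjust_offspring:
            X = np.column_stack([np.ones(n), g, kid[:, j]])
            XtX_inv = np.linalg.inv(X.T @ X)
            coef = XtX_inv @ (X.T @ y)
            resid = y - X @ coef
            sigma2 = float(resid @ resid) / (n - 3)
            by, sy = float(coef[1]), float(np.sqrt(sigma2 * XtX_inv[1, 1]))
        else:
            by, sy = _simple_slope(g, y)
        out.append(VariantSummary(j, bx, sx, by, sy))
    if orient:
        out = orient_summaries(out)
    return out


def _check_weak(summaries: Sequence[VariantSummary], estimate: IVEstimate):
    mean_f = float(np.mean([s.f_statistic for s in summaries]))
    estimate.metadata["mean_variant_F"] = mean_f
    if mean_f < WEAK_INSTRUMENT_F:
        estimate.metadata["weak_instrument_warning"] = True
        warnings.warn(
            f"mean per-variant F = {mean_f:.1f} < {WEAK_INSTRUMENT_F:.0f}: "
            "one-sample IVW/Egger estimates may be severely biased",
            stacklevel=3,
        )
    return estimate


def ivw(summaries: Sequence[VariantSummary]) -> IVEstimate:
    """Inverse-variance-weighted estimate: through-origin weighted regression
    of outcome coefficients on (positively oriented) exposure coefficients,
    weights ``1 / se_y**2``; equivalently the weighted mean of per-variant
    ratio estimates."""
    if len(summaries) < 2:
        raise InsufficientInstrumentsError("IVW requires at least 2 variants")
    s = orient_summaries(summaries)
    bx = np.array([v.beta_x for v in s])
    by = np.array([v.beta_y for v in s])
    w = np.array([1.0 / v.se_y**2 for v in s])
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    est = IVEstimate.from_beta_se("ivw", beta, se, len(s), np.nan)
    return _check_weak(s, est)


def mr_egger(
    summaries: Sequence[VariantSummary],
) -> tuple[IVEstimate, IVEstimate]:
    """MR-Egger regression: weighted (``1/se_y**2``) linear regression of
    outcome on exposure coefficients with a free intercept.

    The intercept estimates the average directional pleiotropic effect; the
    slope estimates the causal effect under the InSIDE assumption.  Both
    standard errors carry a multiplicative overdispersion factor bounded
    below by 1.

    Returns ``(intercept, slope)`` estimates.
    """
    if len(summaries) < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 variants")
    s = orient_summaries(summaries)
    bx = np.array([v.beta_x for v in s])
    by = np.array([v.beta_y for v in s])
    if np.ptp(bx) == 0:
        raise DegenerateRegressionError(
            "no spread in instrument-exposure coefficients"
        )
    w = np.array([1.0 / v.se_y**2 for v in s])
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T @ (X * w[:, None])
    XtWX_inv = np.linalg.inv(XtWX)
    coef = XtWX_inv @ (X.T @ (w * by))
    resid = by - X @ coef
    # Overdispersion: weighted residual variance relative to its expectation,
    # floored at 1 (never deflate the nominal SEs).
    phi = max(1.0, float(np.sum(w * resid**2)) / (len(s) - 2))
    ses = np.sqrt(phi * np.diag(XtWX_inv))
    intercept = IVEstimate.from_beta_se(
        "egger_intercept", coef[0], ses[0], len(s), np.nan, overdispersion=phi
    )
    slope = IVEstimate.from_beta_se(
        "egger_slope", coef[1], ses[1], len(s), np.nan, overdispersion=phi
    )
    _check_weak(s, slope)
    return intercept, slope


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted empirical CDF with linear interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    # Midpoint cumulative weights, as in the standard weighted-median MR
    # implementation: cdf_i = cumsum(w)_i - w_i / 2.
    cdf = np.cumsum(w) - 0.5 * w
    if 0.5 <= cdf[0]:
        return float(r[0])
    if 0.5 >= cdf[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cdf, r))


def weighted_median(
    summaries: Sequence[VariantSummary],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> IVEstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-variant ratio estimates ``beta_y / beta_x`` are ordered and the
    estimate is the interpolated median of their inverse-variance weighted
    empirical distribution (weights ``(beta_x / se_y)**2``, the inverse
    first-order delta-method variance of the ratio).  Consistent when at
    least half of the total weight comes from valid instruments.
    """
    if len(summaries) < 3:
        raise InsufficientInstrumentsError(
            "weighted median requires at least 3 variants"
        )
    s = orient_summaries(summaries)
    kept = [v for v in s if v.beta_x != 0]
    if len(kept) < len(s):
        warnings.warn(
            f"excluded {len(s) - len(kept)} variant(s) with zero exposure "
            "coefficient after orientation",
            stacklevel=2,
        )
    if not kept:
        raise InsufficientInstrumentsError(
            "all variants have zero exposure coefficients"
        )
    bx = np.array([v.beta_x for v in kept])
    by = np.array([v.beta_y for v in kept])
    sx = np.array([v.se_x for v in kept])
    sy = np.array([v.se_y for v in kept])
    weights = (bx / sy) ** 2
    beta = _weighted_median(by / bx, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(bx.size)
        byb = by + sy * rng.standard_normal(by.size)
        flip = bxb < 0
        bxb, byb = np.abs(bxb), np.where(flip, -byb, byb)
        ok = bxb != 0
        boot[b] = _weighted_median(byb[ok] / bxb[ok], (bxb[ok] / sy[ok]) ** 2)
    se = float(np.std(boot, ddof=1))
    est = IVEstimate.from_beta_se(
        "weighted_median", beta, se, len(kept), np.nan, n_boot=n_boot
    )
    return _check_weak(kept, est)


def minus_half_correction(unadjusted: IVEstimate) -> IVEstimate:
    """Shift the unadjusted estimate and both CI bounds down by exactly 0.5.

    Applicable only in the same-trait design (identical maternal exposure
    and offspring outcome, additive linear model), where the unadjusted
    estimate absorbs half the offspring's shared genetic signal; the caller
    asserts applicability, which is recorded — not verified — in metadata.
    """
    return IVEstimate(
        method_label="unadjusted_minus_half",
        beta=unadjusted.beta - 0.5,
        se=unadjusted.se,
        ci_low=unadjusted.ci_low - 0.5,
        ci_high=unadjusted.ci_high - 0.5,
        n_used=unadjusted.n_used,
        first_stage_F=unadjusted.first_stage_F,
        metadata={
            **unadjusted.metadata,
            "correction": "minus_0.5",
            "applicability": "asserted by caller (same-trait additive linear design); not verified",
        },
    )


# -- delimited-text round trip ------------------------------------------


def summaries_to_frame(summaries: Sequence[VariantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": s.variant_index,
                "beta_x": s.beta_x,
                "se_x": s.se_x,
                "beta_y": s.beta_y,
                "se_y": s.se_y,
            }
            for s in summaries
        ],
        columns=list(SUMMARY_COLUMNS),
    )


def summaries_from_frame(frame: pd.DataFrame) -> list[VariantSummary]:
    missing = set(SUMMARY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    return [
        VariantSummary(
            int(row.variant),
            float(row.beta_x),
            float(row.se_x),
            float(row.beta_y),
            float(row.se_y),
        )
        for row in frame.itertuples()
    ]


def write_summaries(
    summaries: Sequence[VariantSummary], path: Union[str, Path]
) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)


def read_summaries(path: Union[str, Path]) -> list[VariantSummary]:
    return summaries_from_frame(pd.read_csv(path, sep="\t", comment="#"))
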