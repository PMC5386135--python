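"""Individual-level two-stage least-squares estimation strategies.

Implements the four estimation strategies compared in the simulation
study — unadjusted, offspring-genotype adjusted, offspring+paternal
adjusted, and the maternal non-transmitted-allele instrument — plus the
transmitted-score comparator and instrument diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import TrioCohort

__all__ = [
    "IVEstimate",
    "tsls",
    "estimate_all_strategies",
    "expected_unadjusted_estimate",
    "confounder_balance_check",
    "STRATEGIES",
    "SingularityError",
    "InsufficientDataError",
    "UndefinedInstrumentError",
]

Z95 = 1.96  # normal-approximation multiplier for 95% intervals

STRATEGIES = (
    "unadjusted",
    "offspring_adjusted",
    "offspring_paternal_adjusted",
    "nontransmitted",
    "transmitted",
)


class SingularityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested design."""


class UndefinedInstrumentError(ValueError):
    """The instrument has no first-stage association (q_x = 0)."""


@dataclass
class IVEstimate:
    """One causal-effect estimate (SD outcome per SD exposure)."""

    method_label: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n_used: int
    first_stage_F: float
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_beta_se(cls, method_label, beta, se, n_used, first_stage_F, **meta):
        return cls(
            method_label=method_label,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            n_used=int(n_used),
            first_stage_F=float(first_stage_F),
            metadata=meta,
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method_label,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_used,
            "first_stage_F": self.first_stage_F,
        }


def _ols(X: np.ndarray, y: np.ndarray):
    """Least-squares fit with an explicit rank check."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularityError(
            f"design matrix rank {rank} < {X.shape[1]} columns"
        )
    return coef


def tsls(
    exposure: np.ndarray,
    outcome: np.ndarray,
    instrument: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    robust: bool = False,
    method_label: str = "tsls",
) -> IVEstimate:
    """Just-identified two-stage least squares with a single instrument.

    The covariates (possibly none) enter both stages.  The standard error
    uses the homoskedastic IV formula with second-stage residuals formed
    from the *observed* exposure; set ``robust=True`` for an HC0 sandwich.
    The first-stage F is the partial F for the excluded instrument
    conditional on the covariates.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = np.asarray(instrument, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("exposure, outcome and instrument must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if covariates is None:
        W = np.empty((x.size, 0))
    else:
        W = np.atleast_2d(np.asarray(covariates, dtype=float))
        if W.shape[0] != x.size:
            W = W.T
        if W.shape[0] != x.size:
            raise ValueError("covariates must have one row per observation")
        keep &= np.isfinite(W).all(axis=1)
    x, y, z, W = x[keep], y[keep], z[keep], W[keep]
    n = x.size
    k_cov = W.shape[1]
    if n < k_cov + 3:
        raise InsufficientDataError(
            f"n={n} observations for {k_cov} covariates; need at least {k_cov + 3}"
        )
    if np.ptp(z) == 0:
        raise SingularityError("instrument is constant")

    ones = np.ones((n, 1))
    Wc = np.hstack([ones, W])
    Z = np.hstack([Wc, z[:, None]])

    # First stage: exposure on [1, covariates, instrument].
    fs_coef = _ols(Z, x)
    xhat = Z @ fs_coef
    fs_resid = x - xhat
    rss_full = float(fs_resid @ fs_resid)
    r_resid = x - Wc @ _ols(Wc, x)
    rss_restricted = float(r_resid @ r_resid)
    df = n - Z.shape[1]
    if rss_full <= 0 or df <= 0:
        first_stage_F = np.inf
    else:
        first_stage_F = max(0.0, (rss_restricted - rss_full) / (rss_full / df))

    # Second stage: outcome on [1, covariates, fitted exposure].
    D_hat = np.hstack([Wc, xhat[:, None]])
    coef = _ols(D_hat, y)
    beta = coef[-1]

    # IV residuals use the observed exposure.
    D = np.hstack([Wc, x[:, None]])
    u = y - D @ coef
    try:
        bread = np.linalg.inv(D_hat.T @ D_hat)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught above
        raise SingularityError(str(exc)) from exc
    if robust:
        meat = D_hat.T @ (D_hat * (u**2)[:, None])
        vcov = bread @ meat @ bread
    else:
        sigma2 = float(u @ u) / (n - D_hat.shape[1])
        vcov = sigma2 * bread
    se = float(np.sqrt(vcov[-1, -1]))
    return IVEstimate.from_beta_se(
        method_label, beta, se, n, first_stage_F, robust=robust
    )


def estimate_all_strategies(
    cohort: TrioCohort,
    strategies: Sequence[str] = STRATEGIES,
    robust: bool = False,
) -> list[IVEstimate]:
    """Apply the estimation strategies to one trio cohort.

    Strategies (1)-(3) instrument the maternal exposure by the maternal
    allele score, with no adjustment, offspring-score adjustment, and
    offspring+paternal-score adjustment respectively (covariates enter both
    stages).  Strategy (4) instruments by the maternal non-transmitted
    haplotype score with no covariates; the transmitted-score comparator is
    its mirror image.
    """
    specs = {
        "unadjusted": (cohort.G_m, None),
        "offspring_adjusted": (cohort.G_m, cohort.G_o[:, None]),
        "offspring_paternal_adjusted": (
            cohort.G_m,
            np.column_stack([cohort.G_o, cohort.G_p]),
        ),
        "nontransmitted": (cohort.G_nt, None),
        "transmitted": (cohort.G_t, None),
    }
    unknown = set(strategies) - set(specs)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    out = []
    for label in strategies:
        instrument, covariates = specs[label]
        out.append(
            tsls(
                cohort.X_m,
                cohort.Y_o,
                instrument,
                covariates,
                robust=robust,
                method_label=label,
            )
        )
    return out


def expected_unadjusted_estimate(gamma: float, q_x: float, v_o: float) -> float:
    """Probability limit of the unadjusted maternal-score IV estimate.

    Under the generative model without assortment or pleiotropy the
    unadjusted estimate converges to ``gamma + 0.5 * sqrt(v_o / q_x)``:
    the offspring's direct genetic path leaks into the instrument-outcome
    association through the 0.5 correlation between maternal and offspring
    scores.
    """
    if q_x == 0:
        raise UndefinedInstrumentError(
            "q_x = 0: the maternal score is not an instrument for the exposure"
        )
    if q_x < 0 or v_o < 0:
        raise ValueError("q_x and v_o must be non-negative")
    return float(gamma + 0.5 * np.sqrt(v_o / q_x))


def confounder_balance_check(
    cohort: TrioCohort,
    confounders: pd.DataFrame,
    adjust_offspring: bool = False,
) -> pd.DataFrame:
    """Instrument-confounder association diagnostics.

    Regresses each observed confounder column on the maternal score,
    optionally conditioning on the offspring score — the latter can turn a
    null association non-null via the collider path through offspring
    genotype, which is the point of running the check both ways.
    """
    if confounders.shape[1] < 1:
        raise ValueError("at least one confounder column is required")
    n = cohort.n_trios
    if len(confounders) != n:
        raise ValueError("confounder table must have one row per trio")
    cols = [np.ones(n), cohort.G_m]
    if adjust_offspring:
        cols.append(cohort.G_o)
    X = np.column_stack(cols)
    XtX_inv = np.linalg.inv(X.T @ X)
    rows = []
    for name in confounders.columns:
        y = confounders[name].to_numpy(dtype=float)
        coef = _ols(X, y)
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / (n - X.shape[1])
        se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
        rows.append(
            {
                "confounder": name,
                "coef_G_m": float(coef[1]),
                "se": se,
                "adjusted_for_offspring": adjust_offspring,
            }
        )
    return pd.DataFrame(rows)
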