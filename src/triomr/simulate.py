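"""Parent-offspring trio simulator with variance-component parameterization.

The generative model draws biallelic haplotypes for two parents, transmits
one haplotype per parent to the offspring, and builds standardized weighted
allele scores.  The maternal exposure ``X_m`` and offspring outcome ``Y_o``
both have unit model-implied variance; every genetic path coefficient is the
square root of the stated proportion of phenotypic variance explained:

    X_m = sqrt(q_x) * G_m + c_x * C + e_x
    Y_o = gamma * X_m + sqrt(v_o) * G_o + sqrt(v_p) * G_p + c_y * C
          + sum_j a_j * Z_mj + e_y

where ``C`` is a shared standard-normal confounder, ``Z_mj`` the
standardized maternal dosage at variant ``j`` (per-variant horizontal
pleiotropy ``a_j``), and the residual variances of ``e_x`` and ``e_y`` are
solved analytically so that ``var(X_m) = var(Y_o) = 1``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "TrioCohort",
    "ConfigurationError",
    "simulate_trio_cohort",
    "simulate_with_assortment",
    "model_implied_covariance",
]

SCORE_VARIABLES = ("G_m", "G_o", "G_p", "G_nt", "X_m", "Y_o")

DEFAULT_N_VARIANTS = 97


class ConfigurationError(ValueError):
    """A scenario configuration is internally inconsistent or infeasible."""


def _as_vector(value, n: int, name: str, default: float) -> np.ndarray:
    if value is None:
        return np.full(n, default, dtype=float)
    vec = np.asarray(value, dtype=float)
    if vec.shape != (n,):
        raise ConfigurationError(
            f"{name} must have length n_variants={n}, got shape {vec.shape}"
        )
    return vec


@dataclass
class ScenarioConfig:
    """All generative parameters of one simulation condition.

    Parameters
    ----------
    n_trios : int
        Trios per replicate (default 10000).
    n_replicates : int
        Number of Monte-Carlo replicates (default 1000).
    n_variants : int
        Number of independent biallelic variants in the instrument panel.
        When ``effect_allele_freqs`` is not given, a default panel of 97
        variants with frequencies drawn once (from ``seed``) uniformly in
        [0.1, 0.9] and equal weights is used.
    q_x : float
        Proportion of maternal-exposure variance explained by the maternal
        allele score, in [0, 1).
    gamma : float
        True causal effect of maternal exposure on offspring outcome
        (SD outcome per SD exposure).
    v_o, v_p : float
        Proportions of offspring-outcome variance explained by the direct
        paths from the offspring and paternal allele scores, in [0, 1).
    c_x, c_y : float
        Path coefficients of the shared standard-normal confounder on
        exposure and outcome.
    assortment_rho : float
        Target spousal correlation on the exposure-relevant phenotype,
        in (-1, 1); 0 disables assortative mating.
    pleiotropy : array-like, optional
        Per-variant direct maternal-genotype -> offspring-outcome path
        coefficients on the standardized maternal dosage (default all 0).
    seed : int
        Root random seed; replicate streams are derived deterministically
        from ``(seed, replicate_index)``.
    """

    n_trios: int = 10000
    n_replicates: int = 1000
    n_variants: Optional[int] = None
    effect_allele_freqs: Optional[Sequence[float]] = None
    variant_weights: Optional[Sequence[float]] = None
    q_x: float = 0.02
    gamma: float = 0.0
    v_o: float = 0.0
    v_p: float = 0.0
    c_x: float = 0.0
    c_y: float = 0.0
    assortment_rho: float = 0.0
    pleiotropy: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ConfigurationError("n_trios must be a positive integer")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be a positive integer")
        if self.n_variants is None:
            if self.effect_allele_freqs is not None:
                self.n_variants = len(np.atleast_1d(self.effect_allele_freqs))
            else:
                self.n_variants = DEFAULT_N_VARIANTS
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be a positive integer")

        if self.effect_allele_freqs is None:
            panel_rng = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(0,))
            )
            freqs = panel_rng.uniform(0.1, 0.9, self.n_variants)
        else:
            freqs = np.asarray(self.effect_allele_freqs, dtype=float)
            if freqs.shape != (self.n_variants,):
                raise ConfigurationError(
                    "effect_allele_freqs must have length n_variants"
                )
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ConfigurationError("effect_allele_freqs must lie in (0, 1)")
        self.effect_allele_freqs = freqs

        self.variant_weights = _as_vector(
            self.variant_weights, self.n_variants, "variant_weights", 1.0
        )
        if np.any(self.variant_weights < 0):
            raise ConfigurationError("variant_weights must be non-negative")
        if not np.any(self.variant_weights > 0):
            raise ConfigurationError("variant_weights must not be all zero")

        self.pleiotropy = _as_vector(
            self.pleiotropy, self.n_variants, "pleiotropy", 0.0
        )

        for name in ("q_x", "v_o", "v_p"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {val}")
        if not -1.0 < self.assortment_rho < 1.0:
            raise ConfigurationError(
                f"|assortment_rho| must be < 1, got {self.assortment_rho}"
            )

        # Solving the residual variances now both validates feasibility and
        # caches the coefficients used by every replicate.
        self.residual_variances()

    # -- analytic helpers ------------------------------------------------

    @property
    def _half_score_var(self) -> float:
        """Variance of a single (unstandardized) transmitted/non-transmitted
        haplotype score: sum w^2 p (1-p)."""
        p = self.effect_allele_freqs
        w = self.variant_weights
        return float(np.sum(w**2 * p * (1 - p)))

    @property
    def score_sd(self) -> float:
        """Analytic SD of a full (diploid) weighted allele score."""
        return float(np.sqrt(2.0 * self._half_score_var))

    @property
    def half_score_sd(self) -> float:
        """Analytic SD of a haplotype (transmitted-only) score."""
        return float(np.sqrt(self._half_score_var))

    @property
    def pleiotropy_score_cov(self) -> float:
        """cov(G_m, P) where P = sum_j a_j Z_mj (standardized dosages)."""
        p = self.effect_allele_freqs
        w = self.variant_weights
        a = self.pleiotropy
        return float(
            np.sum(a * w * np.sqrt(2.0 * p * (1 - p))) / self.score_sd
        )

    def residual_variances(self) -> tuple[float, float]:
        """Solve (var(e_x), var(e_y)) so both phenotypes have unit variance.

        Raises
        ------
        ConfigurationError
            If either residual variance is negative (infeasible budget).
        """
        var_ex = 1.0 - self.q_x - self.c_x**2
        if var_ex < 0:
            raise ConfigurationError(
                "exposure variance budget infeasible: "
                f"q_x + c_x^2 = {self.q_x + self.c_x ** 2:.4f} > 1"
            )
        g, qx = self.gamma, self.q_x
        vo, vp = self.v_o, self.v_p
        r = self.pleiotropy_score_cov
        var_p = float(np.sum(self.pleiotropy**2))
        sqx, svo, svp = np.sqrt(qx), np.sqrt(vo), np.sqrt(vp)
        systematic = (
            g**2
            + vo
            + vp
            + self.c_y**2
            + var_p
            + 2 * g * svo * 0.5 * sqx          # cov(X, G_o) = 0.5 sqrt(q_x)
            + 2 * g * self.c_y * self.c_x       # cov(X, C) = c_x
            + 2 * g * sqx * r                   # cov(X, P)
            + 2 * svo * 0.5 * r                 # cov(G_o, P)
            + 2 * svo * svp * 0.5               # cov(G_o, G_p) = 0.5
        )
        var_ey = 1.0 - systematic
        if var_ey < 0:
            raise ConfigurationError(
                "outcome variance budget infeasible: systematic paths "
                f"(gamma, v_o, v_p, c_y, pleiotropy) explain {systematic:.4f} > 1"
            )
        return var_ex, var_ey

    # -- serialization ---------------------------------------------------

    _VECTOR_FIELDS = ("effect_allele_freqs", "variant_weights", "pleiotropy")

    def to_text(self) -> str:
        """Serialize to flat ``key = value`` text (vectors comma-separated)."""
        lines = []
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name in self._VECTOR_FIELDS:
                val = ",".join(repr(float(v)) for v in np.asarray(val))
            lines.append(f"{f.name} = {val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScenarioConfig":
        kwargs = {}
        int_fields = {"n_trios", "n_replicates", "n_variants", "seed"}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"cannot parse config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in cls._VECTOR_FIELDS:
                kwargs[key] = [float(v) for v in val.split(",")] if val else None
            elif key in int_fields:
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ScenarioConfig":
        return cls.from_text(Path(path).read_text())

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class TrioCohort:
    """One simulated (or imported) cohort of parent-offspring trios.

    Haplotype arrays are ``(n_trios, n_variants)`` effect-allele counts in
    {0, 1}; scores are analytically standardized; phenotypes have unit
    model-implied variance.
    """

    maternal_transmitted: np.ndarray
    maternal_nontransmitted: np.ndarray
    paternal_transmitted: np.ndarray
    paternal_nontransmitted: np.ndarray
    G_m: np.ndarray
    G_o: np.ndarray
    G_p: np.ndarray
    G_t: np.ndarray
    G_nt: np.ndarray
    C: np.ndarray
    X_m: np.ndarray
    Y_o: np.ndarray
    config: Optional[ScenarioConfig] = field(default=None, repr=False)

    @property
    def n_trios(self) -> int:
        return self.maternal_transmitted.shape[0]

    @property
    def n_variants(self) -> int:
        return self.maternal_transmitted.shape[1]

    @property
    def offspring_genotype(self) -> np.ndarray:
        return self.maternal_transmitted + self.paternal_transmitted

    @property
    def maternal_genotype(self) -> np.ndarray:
        return self.maternal_transmitted + self.maternal_nontransmitted

    @property
    def paternal_genotype(self) -> np.ndarray:
        return self.paternal_transmitted + self.paternal_nontransmitted

    def to_dataframe(self, include_dosages: bool = True) -> pd.DataFrame:
        cols = {
            "G_m": self.G_m,
            "G_o": self.G_o,
            "G_p": self.G_p,
            "G_t": self.G_t,
            "G_nt": self.G_nt,
            "C": self.C,
            "X_m": self.X_m,
            "Y_o": self.Y_o,
        }
        df = pd.DataFrame(cols)
        if include_dosages:
            for name, mat in (
                ("mother", self.maternal_genotype),
                ("father", self.paternal_genotype),
                ("child", self.offspring_genotype),
            ):
                dos = pd.DataFrame(
                    mat,
                    columns=[f"{name}_v{j}" for j in range(self.n_variants)],
                )
                df = pd.concat([df, dos], axis=1)
        return df

    def to_csv(self, path: Union[str, Path], include_dosages: bool = True) -> None:
        """Export one row per trio as tab-delimited text.

        The first line is a comment naming the genotype convention
        (effect-allele dosage counts).
        """
        buf = io.StringIO()
        buf.write("# triomr cohort export; genotype columns are effect-allele dosage counts\n")
        self.to_dataframe(include_dosages).to_csv(buf, sep="\t", index=False)
        Path(path).write_text(buf.getvalue())


def _standardize_scores(config: ScenarioConfig, mt, mnt, pt, pnt):
    """Analytic standardization of full, transmitted and non-transmitted scores."""
    w = config.variant_weights
    p = config.effect_allele_freqs
    mean_full = float(np.sum(w * 2 * p))
    mean_half = float(np.sum(w * p))
    sd_full = config.score_sd
    sd_half = config.half_score_sd
    G_m = ((mt + mnt) @ w - mean_full) / sd_full
    G_p = ((pt + pnt) @ w - mean_full) / sd_full
    G_o = ((mt + pt) @ w - mean_full) / sd_full
    G_t = (mt @ w - mean_half) / sd_half
    G_nt = (mnt @ w - mean_half) / sd_half
    return G_m, G_o, G_p, G_t, G_nt


def _phenotypes(config: ScenarioConfig, rng, G_m, G_o, G_p, mt, mnt, C=None):
    var_ex, var_ey = config.residual_variances()
    n = G_m.shape[0]
    if C is None:
        C = rng.standard_normal(n)
    X_m = (
        np.sqrt(config.q_x) * G_m
        + config.c_x * C
        + np.sqrt(var_ex) * rng.standard_normal(n)
    )
    P = 0.0
    if np.any(config.pleiotropy != 0):
        p = config.effect_allele_freqs
        Z_m = (mt + mnt - 2 * p) / np.sqrt(2 * p * (1 - p))
        P = Z_m @ config.pleiotropy
    Y_o = (
        config.gamma * X_m
        + np.sqrt(config.v_o) * G_o
        + np.sqrt(config.v_p) * G_p
        + config.c_y * C
        + P
        + np.sqrt(var_ey) * rng.standard_normal(n)
    )
    return C, X_m, Y_o


def _replicate_rng(config: ScenarioConfig, replicate_index: int) -> np.random.Generator:
    if replicate_index < 0:
        raise ValueError("replicate_index must be >= 0")
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, replicate_index))
    )


def simulate_trio_cohort(
    config: ScenarioConfig, replicate_index: int = 0
) -> TrioCohort:
    """Simulate one replicate cohort under random (non-assortative) mating.

    Each parental haplotype allele is an independent Bernoulli draw at the
    panel frequency; the offspring genotype is the sum of the two labelled
    transmitted haplotypes, so Mendelian consistency holds by construction
    and ``corr(G_m, G_o) = 0.5`` in expectation.
    """
    rng = _replicate_rng(config, replicate_index)
    n, V = config.n_trios, config.n_variants
    p = config.effect_allele_freqs
    mt = (rng.random((n, V)) < p).astype(np.int8)
    mnt = (rng.random((n, V)) < p).astype(np.int8)
    pt = (rng.random((n, V)) < p).astype(np.int8)
    pnt = (rng.random((n, V)) < p).astype(np.int8)
    G_m, G_o, G_p, G_t, G_nt = _standardize_scores(config, mt, mnt, pt, pnt)
    C, X_m, Y_o = _phenotypes(config, rng, G_m, G_o, G_p, mt, mnt)
    return TrioCohort(
        mt, mnt, pt, pnt, G_m, G_o, G_p, G_t, G_nt, C, X_m, Y_o, config
    )


def simulate_with_assortment(
    config: ScenarioConfig, replicate_index: int = 0
) -> TrioCohort:
    """Simulate one replicate cohort with assortative mating on the exposure.

    Spouses are paired by rank-matching noisy copies of each parent's
    exposure-relevant phenotype (the father's phenotype is generated from
    the same path model as the mother's, with an independent confounder).
    The noise variance is chosen so the realized spousal phenotype
    correlation is approximately ``assortment_rho``; when ``q_x > 0`` this
    induces a positive spousal genotype-score correlation.  This
    rank-coupling is one of several possible assortment mechanisms.

    With ``assortment_rho == 0`` this is exactly ``simulate_trio_cohort``
    (same seed path).
    """
    rho = config.assortment_rho
    if rho == 0.0:
        return simulate_trio_cohort(config, replicate_index)

    rng = _replicate_rng(config, replicate_index)
    n, V = config.n_trios, config.n_variants
    p = config.effect_allele_freqs
    mt = (rng.random((n, V)) < p).astype(np.int8)
    mnt = (rng.random((n, V)) < p).astype(np.int8)
    pt = (rng.random((n, V)) < p).astype(np.int8)
    pnt = (rng.random((n, V)) < p).astype(np.int8)
    G_m, _, G_p, _, _ = _standardize_scores(config, mt, mnt, pt, pnt)

    var_ex, _ = config.residual_variances()
    C_m = rng.standard_normal(n)
    C_p = rng.standard_normal(n)
    X_m = (
        np.sqrt(config.q_x) * G_m + config.c_x * C_m
        + np.sqrt(var_ex) * rng.standard_normal(n)
    )
    X_p = (
        np.sqrt(config.q_x) * G_p + config.c_x * C_p
        + np.sqrt(var_ex) * rng.standard_normal(n)
    )

    # Perfect rank matching of U_m = X_m + s*eps against U_p makes
    # corr(X_m, X_p) ~= 1 / (1 + s^2); solve s^2 for the target |rho|.
    s2 = (1.0 - abs(rho)) / abs(rho)
    U_m = X_m + np.sqrt(s2) * rng.standard_normal(n)
    U_p = X_p + np.sqrt(s2) * rng.standard_normal(n)
    mother_order = np.argsort(U_m)
    father_order = np.argsort(U_p)
    if rho < 0:
        father_order = father_order[::-1]
    perm = np.empty(n, dtype=np.intp)
    perm[mother_order] = father_order  # father matched to each mother

    pt, pnt = pt[perm], pnt[perm]
    G_m, G_o, G_p, G_t, G_nt = _standardize_scores(config, mt, mnt, pt, pnt)
    P = 0.0
    if np.any(config.pleiotropy != 0):
        Z_m = (mt + mnt - 2 * p) / np.sqrt(2 * p * (1 - p))
        P = Z_m @ config.pleiotropy
    # Residual variances are solved under random mating; with assortment the
    # realized var(Y_o) deviates from 1 by O(rho * sqrt(q_x * v_p)).
    _, var_ey = config.residual_variances()
    Y_o = (
        config.gamma * X_m
        + np.sqrt(config.v_o) * G_o
        + np.sqrt(config.v_p) * G_p
        + config.c_y * C_m
        + P
        + np.sqrt(var_ey) * rng.standard_normal(n)
    )
    return TrioCohort(
        mt, mnt, pt, pnt, G_m, G_o, G_p, G_t, G_nt, C_m, X_m, Y_o, config
    )


def model_implied_covariance(config: ScenarioConfig) -> pd.DataFrame:
    """Closed-form covariance over (G_m, G_o, G_p, G_nt, X_m, Y_o).

    Valid only under random mating (``assortment_rho == 0``); serves both
    as the residual-variance solver's source of truth and as the analytic
    oracle for expected estimates (e.g. the probability limit of the
    unadjusted IV estimate is cov(G_m, Y_o) / cov(G_m, X_m)).
    """
    if config.assortment_rho != 0.0:
        raise ConfigurationError(
            "model_implied_covariance requires assortment_rho == 0"
        )
    g = config.gamma
    sqx = np.sqrt(config.q_x)
    svo = np.sqrt(config.v_o)
    svp = np.sqrt(config.v_p)
    cx, cy = config.c_x, config.c_y
    r = config.pleiotropy_score_cov
    inv_sqrt2 = 1.0 / np.sqrt(2.0)

    cov = pd.DataFrame(
        np.eye(6), index=SCORE_VARIABLES, columns=SCORE_VARIABLES
    )

    def put(a, b, val):
        cov.loc[a, b] = cov.loc[b, a] = val

    put("G_m", "G_o", 0.5)
    put("G_m", "G_p", 0.0)
    put("G_m", "G_nt", inv_sqrt2)
    put("G_o", "G_p", 0.5)
    put("G_o", "G_nt", 0.0)
    put("G_p", "G_nt", 0.0)
    put("G_m", "X_m", sqx)
    put("G_o", "X_m", 0.5 * sqx)
    put("G_p", "X_m", 0.0)
    put("G_nt", "X_m", sqx * inv_sqrt2)
    put("G_m", "Y_o", g * sqx + 0.5 * svo + r)
    put("G_o", "Y_o", g * 0.5 * sqx + svo + 0.5 * svp + 0.5 * r)
    put("G_p", "Y_o", 0.5 * svo + svp)
    put("G_nt", "Y_o", (g * sqx + r) * inv_sqrt2)
    put("X_m", "Y_o", g + 0.5 * svo * sqx + cx * cy + sqx * r)
    return cov
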