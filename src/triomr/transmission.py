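"""Resolve maternal transmitted/non-transmitted alleles from trio dosages.

For a biallelic variant, transmission is unambiguous whenever mother or
offspring is homozygous.  When both are heterozygous the maternal
transmitted allele is identifiable only if the father's dosage pins down
the paternal contribution (father homozygous); otherwise the cell is
ambiguous.  Ambiguous cells are excluded from haplotype scores rather than
imputed, since imputing at the expectation re-introduces the transmitted
component the non-transmitted instrument exists to remove.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "TransmissionStatus",
    "TransmissionCall",
    "resolve_transmission",
    "resolve_cohort",
    "build_nontransmitted_score",
    "scores_from_dosage_table",
    "EmptyInstrumentError",
    "MendelianErrorRateExceeded",
]


class EmptyInstrumentError(ValueError):
    """No resolved trio-variant cells: the instrument cannot be built."""


class MendelianErrorRateExceeded(ValueError):
    """Mendelian-inconsistency rate above the configured threshold."""


class TransmissionStatus(enum.Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    MENDELIAN_ERROR = "mendelian_error"


@dataclass(frozen=True)
class TransmissionCall:
    variant_index: int
    status: TransmissionStatus
    maternal_transmitted_allele: Optional[int] = None
    maternal_nontransmitted_allele: Optional[int] = None


_ALLELE_SETS = {0: (0,), 1: (0, 1), 2: (1,)}


def resolve_transmission(
    mother_dosage: int,
    offspring_dosage: int,
    father_dosage: Optional[int] = None,
    variant_index: int = 0,
) -> TransmissionCall:
    """Determine the maternal transmitted allele for one trio at one variant.

    Enumerates every (maternal, paternal) transmitted-allele pair compatible
    with the three effect-allele dosages; the call is resolved when exactly
    one maternal transmitted allele survives, ambiguous when both do, and a
    Mendelian error when none does.  A missing father is treated as
    compatible with either paternal allele.
    """
    for name, d in (("mother", mother_dosage), ("offspring", offspring_dosage)):
        if d not in (0, 1, 2):
            raise ValueError(f"{name} dosage must be in {{0, 1, 2}}, got {d}")
    if father_dosage is not None and father_dosage not in (0, 1, 2):
        raise ValueError(f"father dosage must be in {{0, 1, 2}}, got {father_dosage}")

    maternal = _ALLELE_SETS[mother_dosage]
    paternal = (0, 1) if father_dosage is None else _ALLELE_SETS[father_dosage]
    compatible = {
        tm for tm in maternal for tf in paternal if tm + tf == offspring_dosage
    }
    if not compatible:
        return TransmissionCall(variant_index, TransmissionStatus.MENDELIAN_ERROR)
    if len(compatible) > 1:
        return TransmissionCall(variant_index, TransmissionStatus.AMBIGUOUS)
    transmitted = compatible.pop()
    return TransmissionCall(
        variant_index,
        TransmissionStatus.RESOLVED,
        maternal_transmitted_allele=transmitted,
        maternal_nontransmitted_allele=mother_dosage - transmitted,
    )


def _build_lookup() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mother, offspring, father-or-3) -> (status code, t, nt); -1 = undefined."""
    status = np.empty((3, 3, 4), dtype=np.int8)
    trans = np.full((3, 3, 4), -1, dtype=np.int8)
    nontrans = np.full((3, 3, 4), -1, dtype=np.int8)
    codes = {
        TransmissionStatus.RESOLVED: 0,
        TransmissionStatus.AMBIGUOUS: 1,
        TransmissionStatus.MENDELIAN_ERROR: 2,
    }
    for m in range(3):
        for o in range(3):
            for f in (0, 1, 2, None):
                call = resolve_transmission(m, o, f)
                fi = 3 if f is None else f
                status[m, o, fi] = codes[call.status]
                if call.status is TransmissionStatus.RESOLVED:
                    trans[m, o, fi] = call.maternal_transmitted_allele
                    nontrans[m, o, fi] = call.maternal_nontransmitted_allele
    return status, trans, nontrans


_STATUS_LUT, _TRANS_LUT, _NONTRANS_LUT = _build_lookup()


def resolve_cohort(
    mother_dosages: np.ndarray,
    offspring_dosages: np.ndarray,
    father_dosages: Optional[np.ndarray] = None,
    max_mendelian_error_rate: float = 0.01,
):
    """Vectorized transmission resolution over an (n_trios, n_variants) table.

    Returns
    -------
    resolved : bool array, (n, V)
    transmitted, nontransmitted : int8 arrays, (n, V), -1 where unresolved
    mendelian_errors : bool array, (n, V)

    Raises
    ------
    MendelianErrorRateExceeded
        If the fraction of Mendelian-inconsistent cells exceeds
        ``max_mendelian_error_rate`` (default 1%).  Errors below the
        threshold are reported in the mask, never silently dropped.
    """
    m = np.asarray(mother_dosages, dtype=np.int8)
    o = np.asarray(offspring_dosages, dtype=np.int8)
    if m.shape != o.shape:
        raise ValueError("mother and offspring dosage tables must share shape")
    if father_dosages is None:
        f = np.full(m.shape, 3, dtype=np.int8)
    else:
        f = np.asarray(father_dosages, dtype=np.int8)
        if f.shape != m.shape:
            raise ValueError("father dosage table must share shape with mother's")
    status = _STATUS_LUT[m, o, f]
    resolved = status == 0
    errors = status == 2
    rate = float(errors.mean())
    if rate > max_mendelian_error_rate:
        raise MendelianErrorRateExceeded(
            f"Mendelian error rate {rate:.4f} exceeds threshold "
            f"{max_mendelian_error_rate:.4f}"
        )
    return resolved, _TRANS_LUT[m, o, f], _NONTRANS_LUT[m, o, f], errors


def build_nontransmitted_score(
    transmitted: np.ndarray,
    nontransmitted: np.ndarray,
    resolved: np.ndarray,
    weights: np.ndarray,
    freqs: np.ndarray,
    min_resolved_fraction: float = 0.5,
):
    """Standardized haplotype scores from resolved trio-variant cells only.

    Per-trio standardization uses the analytic haplotype variance of that
    trio's resolved variant subset, ``sum_j w_j^2 p_j (1 - p_j)``, so that
    fully and partially resolved trios are on the same scale.  Trios with a
    resolved fraction below ``min_resolved_fraction`` receive NaN scores and
    are flagged as dropped.

    Returns
    -------
    G_nt, G_t : float arrays, (n_trios,)
    report : DataFrame with per-variant resolved fractions, plus attrs
        ``n_trios_dropped`` and ``dropped`` (boolean mask).
    """
    resolved = np.asarray(resolved, dtype=bool)
    if not resolved.any():
        raise EmptyInstrumentError(
            "no resolved trio-variant cells: cannot build a haplotype instrument"
        )
    w = np.asarray(weights, dtype=float)
    p = np.asarray(freqs, dtype=float)
    n, V = resolved.shape

    t = np.where(resolved, transmitted, 0).astype(float)
    nt = np.where(resolved, nontransmitted, 0).astype(float)
    mean_contrib = resolved * (w * p)          # E[w_j * allele] per resolved cell
    var_contrib = resolved * (w**2 * p * (1 - p))
    denom = np.sqrt(var_contrib.sum(axis=1))
    ok = denom > 0
    G_t = np.full(n, np.nan)
    G_nt = np.full(n, np.nan)
    G_t[ok] = ((t @ w) - mean_contrib.sum(axis=1))[ok] / denom[ok]
    G_nt[ok] = ((nt @ w) - mean_contrib.sum(axis=1))[ok] / denom[ok]

    frac = resolved.mean(axis=0)
    trio_frac = resolved.mean(axis=1)
    dropped = (trio_frac < min_resolved_fraction) | ~ok
    G_t[dropped] = np.nan
    G_nt[dropped] = np.nan

    report = pd.DataFrame(
        {"variant": np.arange(V), "resolved_fraction": frac}
    )
    report.attrs["n_trios_dropped"] = int(dropped.sum())
    report.attrs["dropped"] = dropped
    return G_nt, G_t, report


def scores_from_dosage_table(
    table: Union[pd.DataFrame, str],
    weights: np.ndarray,
    freqs: np.ndarray,
    mother_prefix: str = "mother_v",
    father_prefix: str = "father_v",
    child_prefix: str = "child_v",
    min_resolved_fraction: float = 0.5,
    max_mendelian_error_rate: float = 0.01,
):
    """Resolve transmission and build haplotype scores from a dosage table.

    Accepts the simulator's cohort export format (or any delimited table
    with per-variant mother/father/child dosage columns).  Father columns
    are optional.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", comment="#")
    mom_cols = sorted(
        (c for c in table.columns if c.startswith(mother_prefix)),
        key=lambda c: int(c[len(mother_prefix):]),
    )
    kid_cols = [child_prefix + c[len(mother_prefix):] for c in mom_cols]
    dad_cols = [father_prefix + c[len(mother_prefix):] for c in mom_cols]
    if not mom_cols:
        raise ValueError(f"no columns with prefix {mother_prefix!r} found")
    missing = [c for c in kid_cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing offspring dosage columns: {missing[:3]}")
    mothers = table[mom_cols].to_numpy()
    children = table[kid_cols].to_numpy()
    fathers = (
        table[dad_cols].to_numpy()
        if all(c in table.columns for c in dad_cols)
        else None
    )
    resolved, t, nt, errors = resolve_cohort(
        mothers, children, fathers, max_mendelian_error_rate
    )
    G_nt, G_t, report = build_nontransmitted_score(
        t, nt, resolved, weights, freqs, min_resolved_fraction
    )
    report["mendelian_error_fraction"] = errors.mean(axis=0)
    return G_nt, G_t, report
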