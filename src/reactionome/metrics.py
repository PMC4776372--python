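"""Induction-temperature estimation and the inducibility/constitutive
tradeoff analysis.

**Induction temperature.**  For each transcript and species, predicted
log-expression is evaluated at the experimental temperatures and differenced
between consecutive levels; the pair with the greatest direction-appropriate
change is selected and its midpoint reported:

* ``upregulation-low`` — largest increase toward colder temperatures
  (used for Low transcripts and the cold end of Bimodal ones);
* ``upregulation-high`` — largest increase toward warmer temperatures
  (High transcripts and the warm end of Bimodal ones);
* ``downregulation-low-side`` / ``downregulation-high-side`` — largest
  decrease away from the middle, restricted to pairs whose midpoint lies
  below / above 20 °C (Intermediate transcripts).

Ties break toward the more extreme temperature of the mode's direction.

**Tradeoff (genetic-assimilation test).**  Constitutive expression is the
predicted value at the 25 °C rearing temperature; inducibility is
``(max TPM − min TPM) / min TPM × 100`` over the thermal range.  Per
transcript, between-species log ratios of the two quantities are regressed
(constitutive on inducibility, OLS); genetic assimilation — conversion of
inducible into constitutive expression — predicts a negative slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import ContractError, DegenerateDataError
from .fitting import PredictedCurve

__all__ = [
    "MODES",
    "InductionRecord",
    "TradeoffRecord",
    "TradeoffRegression",
    "induction_temperature",
    "inducibility",
    "constitutive_expression",
    "tradeoff_records",
    "tradeoff_regression",
]

MODES = ("upregulation-low", "upregulation-high",
         "downregulation-low-side", "downregulation-high-side")

_DOWNREGULATION_SPLIT = 20.0  # °C boundary between the two downregulation sides


@dataclass(frozen=True)
class InductionRecord:
    transcript_id: str
    species: str
    mode: str
    temperature: float    # midpoint of the selected consecutive pair, °C
    magnitude: float      # log-expression change across the pair, > 0


@dataclass(frozen=True)
class TradeoffRecord:
    transcript_id: str
    log_ratio_inducibility: float
    log_ratio_constitutive: float


@dataclass(frozen=True)
class TradeoffRegression:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def induction_temperature(curve: PredictedCurve,
                          experimental_temperatures: Sequence[float],
                          mode: str) -> InductionRecord:
    """Temperature of greatest direction-appropriate expression change.

    ``experimental_temperatures`` are the (retained) design temperatures at
    which the predicted curve is evaluated before consecutive differencing.
    """
    if mode not in MODES:
        raise ContractError(f"unknown mode {mode!r}; expected one of {MODES}")
    temps = np.asarray(sorted(experimental_temperatures), dtype=float)
    if len(temps) < 2:
        raise ContractError("need at least two experimental temperatures")
    values = np.array([curve.evaluate(t) for t in temps])
    diffs = np.diff(values)              # diffs[i] = y(T[i+1]) - y(T[i])
    mids = (temps[:-1] + temps[1:]) / 2.0

    if mode == "upregulation-low":
        change, keep, colder_first = -diffs, np.ones_like(mids, bool), True
    elif mode == "upregulation-high":
        change, keep, colder_first = diffs, np.ones_like(mids, bool), False
    elif mode == "downregulation-low-side":
        change, keep, colder_first = diffs, mids < _DOWNREGULATION_SPLIT, True
    else:  # downregulation-high-side
        change, keep, colder_first = -diffs, mids > _DOWNREGULATION_SPLIT, False

    if not keep.any():
        raise ContractError(
            f"no consecutive pair with midpoint on the required side of "
            f"{_DOWNREGULATION_SPLIT} °C"
        )
    change = np.where(keep, change, -np.inf)
    best = float(change.max())
    if best <= 0.0:
        raise ContractError(
            f"no positive {mode} change anywhere on the curve"
        )
    ties = np.flatnonzero(change >= best - 1e-12)
    pick = ties[0] if colder_first else ties[-1]  # toward the extreme
    return InductionRecord(
        transcript_id=curve.transcript_id, species=curve.species, mode=mode,
        temperature=float(mids[pick]), magnitude=float(change[pick]),
    )


def inducibility(curve: PredictedCurve) -> float | None:
    """Percent inducibility ``(max TPM − min TPM) / min TPM × 100``.

    TPM is recovered from the predicted log scale as ``exp(value) − 1``.
    Returns None (an exclusion signal, not an error) when the minimum TPM is
    not strictly positive, since the ratio is then undefined.
    """
    tpm = np.expm1(curve.values)
    tpm_min = float(tpm.min())
    if tpm_min <= 0.0:
        return None
    return float((tpm.max() - tpm_min) / tpm_min * 100.0)


def constitutive_expression(curve: PredictedCurve,
                            rearing_temperature: float = 25.0) -> float:
    """Predicted log(TPM + 1) at the rearing temperature (exact evaluation)."""
    return curve.evaluate(rearing_temperature)


def tradeoff_records(
    pairs: Iterable[tuple[PredictedCurve, PredictedCurve]],
    rearing_temperature: float = 25.0,
    flip_ratio: bool = False,
) -> tuple[list[TradeoffRecord], int]:
    """Between-species log ratios of inducibility and constitutive TPM.

    Ratios are first-species over second-species (natural log); pass
    ``flip_ratio`` for the opposite convention (the tradeoff slope's sign is
    invariant to it).  Transcripts with non-positive inducibility or
    constitutive TPM in either species are excluded; the second return value
    counts them.
    """
    records: list[TradeoffRecord] = []
    excluded = 0
    sign = -1.0 if flip_ratio else 1.0
    for curve_a, curve_b in pairs:
        ind_a, ind_b = inducibility(curve_a), inducibility(curve_b)
        con_a = np.expm1(constitutive_expression(curve_a, rearing_temperature))
        con_b = np.expm1(constitutive_expression(curve_b, rearing_temperature))
        if (ind_a is None or ind_b is None or ind_a <= 0 or ind_b <= 0
                or con_a <= 0 or con_b <= 0):
            excluded += 1
            continue
        records.append(TradeoffRecord(
            transcript_id=curve_a.transcript_id,
            log_ratio_inducibility=sign * float(np.log(ind_a / ind_b)),
            log_ratio_constitutive=sign * float(np.log(con_a / con_b)),
        ))
    return records, excluded


def tradeoff_regression(records: Sequence[TradeoffRecord]) -> TradeoffRegression:
    """OLS of constitutive log ratio on inducibility log ratio.

    A negative slope is the genetic-assimilation signature (transcripts more
    inducible in one species are more constitutively expressed in the other).
    """
    if len(records) < 3:
        raise ContractError(f"need at least 3 records, got {len(records)}")
    x = np.array([r.log_ratio_inducibility for r in records])
    y = np.array([r.log_ratio_constitutive for r in records])
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ContractError("records must carry finite log ratios")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("zero variance in the inducibility ratios")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return TradeoffRegression(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p=float(fit.pvalues[1]),
        n=len(records),
    )
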