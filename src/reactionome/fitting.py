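"""Per-transcript thermal reaction-norm regression.

Each transcript's log(TPM + 1) response is modelled by ordinary least squares
as a quadratic in exposure temperature with species-specific intercept, slope
and curvature::

    log(TPM + 1) = b0 + b1*species + b2*T + b3*T^2
                   + b4*species*T + b5*species*T^2 + error

where ``species`` is a 0/1 indicator (lexicographically first label is the
reference level) and ``T`` is temperature in °C, uncentred.  Significance is
the omnibus F-test of this full model against the intercept-only model, with
Benjamini–Hochberg adjustment across transcripts.  A final per-transcript
model is chosen by stepwise AIC search restricted to hierarchical (marginal)
polynomial term sets, and per-species predicted curves are evaluated from it
on a dense temperature grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FitError, ValidationError
from .expression_data import SampleTable, TemperatureGrid

__all__ = [
    "TERMS",
    "ReactionNormFit",
    "SelectedModel",
    "PredictedCurve",
    "build_design",
    "fit_transcript",
    "fit_many",
    "bh_adjust",
    "stepwise_aic",
    "predict_curves",
    "responsiveness_flags",
]

# Model terms beyond the intercept, in their canonical (deterministic) order.
TERMS: tuple[str, ...] = (
    "species", "temp", "temp2", "species:temp", "species:temp2",
)

# Direct parents under the marginality (hierarchy) rule: a term may be
# retained only while all its parents are retained.
_PARENTS: dict[str, tuple[str, ...]] = {
    "species": (),
    "temp": (),
    "temp2": ("temp",),
    "species:temp": ("species", "temp"),
    "species:temp2": ("species:temp", "temp2"),
}

_RSS_FLOOR = 1e-300  # keeps log() finite for exact fits; ties then break on 2k


@dataclass
class ReactionNormFit:
    """Full-model OLS fit for one transcript."""

    transcript_id: str
    beta: np.ndarray            # b0..b5
    residual_se: float
    overall_p: float
    aic_full: float
    n_obs: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (6,):
            raise ValidationError("beta must have 6 entries")
        if not 0.0 <= self.overall_p <= 1.0:
            raise ValidationError(f"overall_p out of [0,1]: {self.overall_p}")
        if self.residual_se < 0:
            raise ValidationError("residual_se must be non-negative")
        if self.n_obs <= 6:
            raise ValidationError("n_obs must exceed the 6 fitted parameters")


@dataclass
class SelectedModel:
    """AIC-selected term subset and its refit coefficients.

    ``coefficients`` maps ``"const"`` and each retained term to its estimate;
    absent terms contribute zero to predictions.
    """

    transcript_id: str
    retained_terms: tuple[str, ...]
    coefficients: dict[str, float]
    aic_selected: float
    residual_se: float = 0.0

    def __post_init__(self) -> None:
        retained = set(self.retained_terms)
        for term in retained:
            for parent in _PARENTS[term]:
                if parent not in retained:
                    raise ValidationError(
                        f"marginality violated: {term} retained without {parent}"
                    )

    def beta6(self) -> np.ndarray:
        """Coefficients expanded to the full (b0..b5) vector, absent = 0."""
        c = self.coefficients
        return np.array([
            c.get("const", 0.0), c.get("species", 0.0), c.get("temp", 0.0),
            c.get("temp2", 0.0), c.get("species:temp", 0.0),
            c.get("species:temp2", 0.0),
        ])


@dataclass
class PredictedCurve:
    """Predicted log(TPM + 1) for one species over a dense temperature grid."""

    transcript_id: str
    species: str
    temperatures: np.ndarray
    values: np.ndarray
    poly: tuple[float, float, float] | None = None  # (a0, a1, a2) exact form

    def evaluate(self, temperature: float) -> float:
        """Exact polynomial value when available, else linear interpolation."""
        lo, hi = self.temperatures[0], self.temperatures[-1]
        if not lo <= temperature <= hi:
            raise ValidationError(
                f"temperature {temperature} outside curve span [{lo}, {hi}]"
            )
        if self.poly is not None:
            a0, a1, a2 = self.poly
            return a0 + a1 * temperature + a2 * temperature * temperature
        return float(np.interp(temperature, self.temperatures, self.values))

    @property
    def value_range(self) -> float:
        return float(self.values.max() - self.values.min())


def build_design(samples: SampleTable) -> tuple[np.ndarray, pd.DataFrame]:
    """Design matrix [1, s, T, T², sT, sT²] over retained samples.

    Returns the matrix and the retained sample rows (in matrix row order).
    """
    rows = samples.retained_rows
    labels = samples.species_labels
    if len(labels) < 2:
        raise FitError(
            f"need both species in the design; found only {list(labels)}"
        )
    s = (rows["species"] == labels[1]).to_numpy(dtype=float)
    t = rows["temperature"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), s, t, t * t, s * t, s * t * t])
    _check_design(X, rows, labels)
    return X, rows


def _check_design(X: np.ndarray, rows: pd.DataFrame, labels) -> None:
    n = X.shape[0]
    if n <= X.shape[1]:
        raise FitError(f"{n} observations cannot identify {X.shape[1]} parameters")
    if n < 8:
        raise FitError(f"need at least 8 observations, got {n}")
    for lab in labels:
        k = rows.loc[rows["species"] == lab, "temperature"].nunique()
        if k < 4:
            raise FitError(
                f"species {lab!r} spans only {k} distinct temperatures (need 4)"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian OLS AIC up to an additive constant shared by all submodels."""
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2.0 * k


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_many(Y: np.ndarray, samples: SampleTable,
             transcript_ids: list[str] | None = None) -> pd.DataFrame:
    """Fit the full model to every row of ``Y`` at once.

    ``Y`` is transcripts × samples of log(TPM + 1), columns in the order of
    ``samples.data`` (non-retained columns are dropped here).  All transcripts
    share one design matrix, so the solve is a single pseudo-inverse product.

    Returns a frame with columns b0..b5, residual_se, overall_p, aic_full,
    n_obs, indexed by transcript id.
    """
    Y = np.asarray(Y, dtype=float)
    X, rows = build_design(samples)
    keep = samples.data["retained"].to_numpy()
    if Y.shape[1] == len(samples.data):
        Y = Y[:, keep]
    elif Y.shape[1] != X.shape[0]:
        raise FitError(
            f"{Y.shape[1]} expression columns vs {len(samples.data)} samples"
        )
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T                                  # (n_t, 6)
    resid = Y - B @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    ybar = Y.mean(axis=1, keepdims=True)
    tss = np.einsum("ij,ij->i", Y - ybar, Y - ybar)

    df_model, df_resid = p - 1, n - p
    mss = np.maximum(tss - rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (mss / df_model) / (rss / df_resid)
    pvals = stats.f.sf(F, df_model, df_resid)
    # Degenerate responses: no variance at all -> no evidence (p = 1);
    # perfect fit of a non-constant response -> p = 0.
    tiny = 1e-12 * np.maximum(tss, 1.0)
    pvals = np.where(tss <= tiny, 1.0, pvals)
    pvals = np.where((rss <= tiny) & (tss > tiny), 0.0, pvals)
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)

    aic = np.array([_aic(r, n, p) for r in rss])
    se = np.sqrt(np.maximum(rss, 0.0) / df_resid)
    if transcript_ids is None:
        transcript_ids = [f"t{i}" for i in range(Y.shape[0])]
    out = pd.DataFrame(
        B, columns=[f"b{i}" for i in range(6)],
        index=pd.Index(transcript_ids, name="transcript_id"),
    )
    out["residual_se"] = se
    out["overall_p"] = pvals
    out["aic_full"] = aic
    out["n_obs"] = n
    return out


def fit_transcript(y: np.ndarray, samples: SampleTable,
                   transcript_id: str = "transcript") -> ReactionNormFit:
    """Full-model OLS fit for a single transcript's log-expression vector.

    ``y`` must align with the retained samples (or all samples, in table
    order, in which case non-retained entries are dropped).
    """
    row = fit_many(np.asarray(y, dtype=float)[None, :], samples,
                   [transcript_id]).iloc[0]
    return ReactionNormFit(
        transcript_id=transcript_id,
        beta=row[[f"b{i}" for i in range(6)]].to_numpy(dtype=float),
        residual_se=float(row["residual_se"]),
        overall_p=float(row["overall_p"]),
        aic_full=float(row["aic_full"]),
        n_obs=int(row["n_obs"]),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stepwise_aic(fit: ReactionNormFit, y: np.ndarray, samples: SampleTable,
                 direction: str = "both",
                 species_removable: bool = False) -> SelectedModel:
    """Stepwise AIC search over hierarchical term subsets.

    Starts from the full model and repeatedly applies the single term
    removal or addition that most lowers AIC, subject to marginality (a
    parent term cannot leave while a child is retained, and a child cannot
    enter before its parents).  The species main effect is kept throughout
    unless ``species_removable``.  Ties and the candidate sweep follow the
    fixed ``TERMS`` order, so the search is deterministic.
    """
    if direction not in ("both", "backward"):
        raise ValidationError(f"unknown stepwise direction {direction!r}")
    y = np.asarray(y, dtype=float)
    X, _ = build_design(samples)
    keep = samples.data["retained"].to_numpy()
    if y.shape[0] == len(samples.data):
        y = y[keep]
    n = X.shape[0]
    col_of = {term: i + 1 for i, term in enumerate(TERMS)}

    cache: dict[frozenset, tuple[float, np.ndarray, float]] = {}

    def evaluate(terms: frozenset) -> tuple[float, np.ndarray, float]:
        if terms not in cache:
            cols = [0] + [col_of[t] for t in TERMS if t in terms]
            beta, rss = _ols(X[:, cols], y)
            cache[terms] = (_aic(rss, n, len(cols)), beta, rss)
        return cache[terms]

    current = frozenset(TERMS)
    current_aic = evaluate(current)[0]
    for _ in range(64):
        moves: list[tuple[float, int, frozenset]] = []
        order = 0
        for term in TERMS:            # removals first, canonical order
            if term not in current:
                continue
            if term == "species" and not species_removable:
                continue
            if any(term in _PARENTS[t] for t in current if t != term):
                continue
            cand = current - {term}
            moves.append((evaluate(cand)[0], order, cand))
            order += 1
        if direction == "both":
            for term in TERMS:        # then additions
                if term in current:
                    continue
                if not all(p in current for p in _PARENTS[term]):
                    continue
                cand = current | {term}
                moves.append((evaluate(cand)[0], order, cand))
                order += 1
        if not moves:
            break
        best_aic, _, best_set = min(moves, key=lambda m: (m[0], m[1]))
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_set, best_aic
        else:
            break

    aic_sel, beta, rss = evaluate(current)
    retained = tuple(t for t in TERMS if t in current)
    names = ["const"] + list(retained)
    df_resid = n - len(names)
    return SelectedModel(
        transcript_id=fit.transcript_id,
        retained_terms=retained,
        coefficients={nm: float(b) for nm, b in zip(names, beta)},
        aic_selected=aic_sel,
        residual_se=math.sqrt(max(rss, 0.0) / df_resid) if df_resid > 0 else 0.0,
    )


def predict_curves(model: SelectedModel, grid: TemperatureGrid,
                   species_labels: tuple[str, str] | None = None,
                   step: float = 0.1) -> tuple[PredictedCurve, PredictedCurve]:
    """Per-species predicted curves on a dense grid spanning the design range.

    Species A (reference) follows ``b0 + b2*T + b3*T²``; species B adds the
    species offset and interaction terms.  Terms dropped by model selection
    contribute zero.
    """
    if species_labels is None:
        species_labels = ("speciesA", "speciesB")
    b = model.beta6()
    lo, hi = grid.span
    temps = np.round(np.arange(lo, hi + step / 2, step), 10)
    curves = []
    for which, label in enumerate(species_labels):
        a0 = b[0] + which * b[1]
        a1 = b[2] + which * b[4]
        a2 = b[3] + which * b[5]
        curves.append(PredictedCurve(
            transcript_id=model.transcript_id, species=label,
            temperatures=temps, values=a0 + a1 * temps + a2 * temps * temps,
            poly=(float(a0), float(a1), float(a2)),
        ))
    return curves[0], curves[1]


def responsiveness_flags(curve_a: PredictedCurve, curve_b: PredictedCurve,
                         epsilon: float) -> tuple[bool, bool]:
    """A species is thermally responsive iff its predicted curve's range
    (max − min, log scale) strictly exceeds ``epsilon``."""
    return (curve_a.value_range > epsilon, curve_b.value_range > epsilon)
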