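"""Synthetic two-species reactionome generator with known ground truth.

Emulates the study design the pipeline targets: two species, one pooled
sample per species × temperature on the 0–38.5 °C grid (3.5 °C increments),
log-scale expression curves drawn from flat / linear / unimodal / bimodal
shape families, additive Gaussian noise on the log(TPM + 1) scale, and a
configurable fraction of thermally responsive transcripts whose shape may
diverge between species.

Unimodal and bimodal families are quadratics — the same class the analysis
model fits — so that noiseless coefficient recovery is exact; an optional
cubic family is provided for out-of-class misspecification stress tests.
Each cell of the emitted TPM matrix is ``max(exp(curve(T) + ε) − 1, 0)``
with ε i.i.d. N(0, noise_sd²).

The per-transcript ``SyntheticTruth`` records the generating shapes and the
intended category per species, where "intended" is defined as what the
shape classifier returns on the noiseless curve (using ``noise_sd`` as the
dispersion in the Bimodal margin rule) — so truth and classifier are
consistent by construction, and recovery tests measure only the effect of
noise and estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import ClassificationConfig, classify_pair
from .errors import ConfigError
from .expression_data import (
    ExpressionMatrix,
    SampleTable,
    TemperatureGrid,
    default_grid,
)
from .fitting import PredictedCurve

import pandas as pd

__all__ = [
    "ShapeSpec",
    "SyntheticTruth",
    "SimulationConfig",
    "noiseless_curve",
    "shape_curve",
    "generate",
    "generate_tradeoff_curves",
]

FAMILIES = ("flat", "linear", "unimodal", "bimodal", "cubic")


@dataclass(frozen=True)
class ShapeSpec:
    """One expression curve on the log(TPM + 1) scale.

    Families and their ``params`` keys:

    * ``flat`` — ``intercept``;
    * ``linear`` — ``intercept`` (value at 0 °C), ``slope`` (per °C);
    * ``unimodal`` — concave quadratic: ``peak_temperature`` (°C, interior),
      ``peak_height``, ``curvature`` (> 0);
    * ``bimodal`` — convex quadratic: ``trough_temperature`` (°C, interior),
      ``trough_level``, ``curvature`` (> 0);
    * ``cubic`` — out-of-class stress family: ``c0``..``c3``.
    """

    family: str
    params: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown shape family {self.family!r}")

    @classmethod
    def make(cls, family: str, **params: float) -> "ShapeSpec":
        return cls(family, tuple(sorted((k, float(v)) for k, v in params.items())))

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)


def noiseless_curve(spec: ShapeSpec, grid: TemperatureGrid) -> np.ndarray:
    """Closed-form curve values at each grid temperature."""
    return _evaluate(spec, np.asarray(grid.temperatures, dtype=float), grid)


def _evaluate(spec: ShapeSpec, temps: np.ndarray,
              grid: TemperatureGrid) -> np.ndarray:
    p = spec.p
    lo, hi = grid.span
    if spec.family == "flat":
        return np.full_like(temps, p["intercept"])
    if spec.family == "linear":
        return p["intercept"] + p["slope"] * temps
    if spec.family == "unimodal":
        tp = p["peak_temperature"]
        if not lo < tp < hi:
            raise ConfigError(f"unimodal peak {tp} outside grid span ({lo},{hi})")
        return p["peak_height"] - p["curvature"] * (temps - tp) ** 2
    if spec.family == "bimodal":
        tv = p["trough_temperature"]
        c = p["curvature"]
        if c * (lo - tv) ** 2 <= 0 or c * (hi - tv) ** 2 <= 0:
            raise ConfigError("bimodal amplitudes at grid extremes must be positive")
        return p["trough_level"] + c * (temps - tv) ** 2
    if spec.family == "cubic":
        return (p["c0"] + p["c1"] * temps + p["c2"] * temps ** 2
                + p["c3"] * temps ** 3)
    raise ConfigError(f"unknown family {spec.family!r}")  # pragma: no cover


def shape_curve(spec: ShapeSpec, grid: TemperatureGrid,
                transcript_id: str = "shape", species: str = "species",
                step: float = 0.1) -> PredictedCurve:
    """Dense noiseless curve as a :class:`PredictedCurve` (for classification)."""
    lo, hi = grid.span
    temps = np.round(np.arange(lo, hi + step / 2, step), 10)
    values = _evaluate(spec, temps, grid)
    poly = None
    p = spec.p
    if spec.family == "flat":
        poly = (p["intercept"], 0.0, 0.0)
    elif spec.family == "linear":
        poly = (p["intercept"], p["slope"], 0.0)
    elif spec.family == "unimodal":
        tp, c = p["peak_temperature"], p["curvature"]
        poly = (p["peak_height"] - c * tp * tp, 2 * c * tp, -c)
    elif spec.family == "bimodal":
        tv, c = p["trough_temperature"], p["curvature"]
        poly = (p["trough_level"] + c * tv * tv, -2 * c * tv, c)
    return PredictedCurve(transcript_id, species, temps, values, poly=poly)


@dataclass
class SyntheticTruth:
    """Generating shapes and intended categories for one transcript."""

    transcript_id: str
    shape_a: ShapeSpec
    shape_b: ShapeSpec
    responsive_a: bool
    responsive_b: bool
    category_a: str | None
    category_b: str | None
    noise_sd: float


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the emulated experiment: the 12-level grid with 7 °C
    excluded downstream, ~2.5 % of transcripts thermally responsive, and a
    majority of responsive transcripts diverging in shape between species.
    ``family_weights`` mixes the responsive families (flat shapes arise from
    the non-responsive fraction and from divergent draws with weight
    ``notresp_weight``).  Baseline log-expression is N(baseline_mean,
    baseline_sd²) clipped to keep TPM strictly positive.
    """

    n_transcripts: int = 2000
    fraction_responsive: float = 0.025
    family_weights: dict = field(default_factory=lambda: {
        "linear": 0.4, "unimodal": 0.4, "bimodal": 0.2,
    })
    noise_sd: float = 0.3
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    fraction_divergent: float = 0.6
    notresp_weight: float = 0.1
    species_offset_sd: float = 0.0
    seed: int = 0
    grid: TemperatureGrid = field(default_factory=default_grid)
    species_labels: tuple[str, str] = ("A_carolinensis", "A_picea")
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ConfigError("n_transcripts must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.fraction_responsive <= 1.0:
            raise ConfigError("fraction_responsive must lie in [0, 1]")
        if not 0.0 <= self.fraction_divergent <= 1.0:
            raise ConfigError("fraction_divergent must lie in [0, 1]")
        w = self.family_weights
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
            raise ConfigError("family_weights must be non-negative and sum to 1")
        unknown = set(w) - {"linear", "unimodal", "bimodal", "cubic"}
        if unknown:
            raise ConfigError(f"unknown responsive families: {sorted(unknown)}")


def _draw_baseline(rng, cfg) -> float:
    return float(np.clip(rng.normal(cfg.baseline_mean, cfg.baseline_sd),
                         0.5, 8.0))


def _draw_responsive_shape(rng, cfg) -> ShapeSpec:
    lo, hi = cfg.grid.span
    span = hi - lo
    names = sorted(cfg.family_weights)
    probs = np.array([cfg.family_weights[n] for n in names])
    family = names[int(rng.choice(len(names), p=probs))]
    b = _draw_baseline(rng, cfg)
    if family == "linear":
        slope = rng.uniform(0.02, 0.08) * (1 if rng.random() < 0.5 else -1)
        intercept = b + max(0.0, -slope) * span  # keep the curve ≥ b
        return ShapeSpec.make("linear", intercept=intercept, slope=slope)
    if family == "unimodal":
        tp = rng.uniform(lo + 2.0, hi - 2.0)
        c = rng.uniform(0.003, 0.01)
        dmax = max(tp - lo, hi - tp)
        return ShapeSpec.make("unimodal", peak_temperature=tp,
                              peak_height=b + c * dmax * dmax, curvature=c)
    if family == "bimodal":
        tv = rng.uniform(14.0, 26.0)
        c = rng.uniform(0.004, 0.012)
        return ShapeSpec.make("bimodal", trough_temperature=tv,
                              trough_level=b, curvature=c)
    # cubic: gentle out-of-class wiggle with guaranteed range
    c3 = rng.uniform(1e-4, 3e-4) * (1 if rng.random() < 0.5 else -1)
    c2 = -1.5 * c3 * (lo + hi) / 2
    c1 = rng.uniform(-0.02, 0.02)
    return ShapeSpec.make("cubic", c0=b + 2.0, c1=c1, c2=c2, c3=c3)


def _flat(rng, cfg, intercept=None) -> ShapeSpec:
    if intercept is None:
        intercept = _draw_baseline(rng, cfg)
    return ShapeSpec.make("flat", intercept=intercept)


def generate(config: SimulationConfig,
             ) -> tuple[ExpressionMatrix, SampleTable, list[SyntheticTruth]]:
    """Draw a full synthetic dataset: matrix, sample table, and truth.

    Identical seeds give bit-identical output.  One sample is produced per
    (species, grid temperature) including excluded levels, mirroring the
    real design where exclusion happens at analysis time.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    temps = np.asarray(cfg.grid.temperatures, dtype=float)
    sample_ids, species_col, temp_col = [], [], []
    for sp in cfg.species_labels:
        for t in temps:
            sample_ids.append(f"{sp}_T{t:04.1f}")
            species_col.append(sp)
            temp_col.append(t)
    samples = SampleTable(
        pd.DataFrame({"sample_id": sample_ids, "species": species_col,
                      "temperature": temp_col}),
        grid=cfg.grid,
    )

    n_s = len(sample_ids)
    tpm = np.empty((cfg.n_transcripts, n_s))
    truths: list[SyntheticTruth] = []
    for i in range(cfg.n_transcripts):
        tid = f"transcript{i:06d}"
        responsive = rng.random() < cfg.fraction_responsive
        if responsive:
            shape_a = _draw_responsive_shape(rng, cfg)
            if rng.random() < cfg.fraction_divergent:
                if rng.random() < cfg.notresp_weight:
                    shape_b = _flat(rng, cfg)
                else:
                    shape_b = _draw_responsive_shape(rng, cfg)
            else:
                shape_b = shape_a
        else:
            base = _draw_baseline(rng, cfg)
            offset = (rng.normal(0.0, cfg.species_offset_sd)
                      if cfg.species_offset_sd > 0 else 0.0)
            shape_a = _flat(rng, cfg, intercept=base)
            shape_b = _flat(rng, cfg, intercept=max(base + offset, 0.1))
        curve_a = shape_curve(shape_a, cfg.grid, tid, cfg.species_labels[0])
        curve_b = shape_curve(shape_b, cfg.grid, tid, cfg.species_labels[1])
        resp_a = curve_a.value_range > cfg.classification.flatness_epsilon
        resp_b = curve_b.value_range > cfg.classification.flatness_epsilon
        cat_a, cat_b = classify_pair(curve_a, curve_b, cfg.noise_sd,
                                     cfg.classification)
        log_a = _evaluate(shape_a, temps, cfg.grid)
        log_b = _evaluate(shape_b, temps, cfg.grid)
        noise = rng.normal(0.0, cfg.noise_sd, size=n_s)
        log_expr = np.concatenate([log_a, log_b]) + noise
        tpm[i] = np.maximum(np.expm1(log_expr), 0.0)
        truths.append(SyntheticTruth(
            transcript_id=tid, shape_a=shape_a, shape_b=shape_b,
            responsive_a=resp_a, responsive_b=resp_b,
            category_a=cat_a, category_b=cat_b, noise_sd=cfg.noise_sd,
        ))
    matrix = ExpressionMatrix(
        transcript_ids=[t.transcript_id for t in truths],
        sample_ids=sample_ids, tpm=tpm,
    )
    return matrix, samples, truths


def generate_tradeoff_curves(
    n_transcripts: int, slope: float, seed: int,
    noise_sd: float = 0.3, grid: TemperatureGrid | None = None,
) -> list[tuple[PredictedCurve, PredictedCurve]]:
    """Curve pairs with a built-in inducibility/constitutive-expression
    coupling of the given log-ratio slope.

    Species A receives a concave quadratic peaking at 34 °C (a High shape);
    species B's TPM curve is a power-law transform ``α · TPM_A(T)^γ`` whose
    exponent γ varies across transcripts.  γ sets the inducibility log-ratio
    x = log(I_A / I_B) exactly, and α is then solved so that the constitutive
    log-ratio equals ``slope·x`` plus N(0, noise_sd²) scatter — giving a
    dataset whose tradeoff regression has the requested true slope.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    lo, hi = grid.span
    temps = np.round(np.arange(lo, hi + 0.05, 0.1), 10)
    pairs = []
    for i in range(n_transcripts):
        tid = f"tradeoff{i:05d}"
        b = float(np.clip(rng.normal(3.0, 0.8), 1.5, 6.0))
        c = rng.uniform(0.002, 0.006)
        tp = 34.0
        peak = b + c * max(tp - lo, hi - tp) ** 2
        y_a = peak - c * (temps - tp) ** 2
        tpm_a = np.expm1(y_a)
        r = tpm_a.max() / tpm_a.min()
        gamma = float(np.exp(rng.normal(0.0, 0.3)))
        x = np.log((r - 1.0) / (r ** gamma - 1.0))
        y_target = slope * x + rng.normal(0.0, noise_sd)
        c_a = np.expm1(peak - c * (25.0 - tp) ** 2)
        log_alpha = (1.0 - gamma) * np.log(c_a) - y_target
        tpm_b = np.exp(log_alpha) * tpm_a ** gamma
        curve_a = PredictedCurve(tid, "A_picea", temps, y_a,
                                 poly=(peak - c * tp * tp, 2 * c * tp, -c))
        curve_b = PredictedCurve(tid, "A_carolinensis", temps,
                                 np.log1p(tpm_b), poly=None)
        pairs.append((curve_a, curve_b))
    return pairs
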