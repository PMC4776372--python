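"""End-to-end pipeline: fit → calibrate → classify → compare → metrics.

Each stage is a plain function over in-memory objects so it can be tested
and reused on its own; :func:`run_pipeline` sequences them, writes every
stage output under the configured directory, and emits a manifest with the
config echo, package version, seed trail and a SHA-256 checksum per output
file.  With identical inputs, config and root seed, the checksums are
identical across runs — wall-clock timings are recorded in a separate
manifest field that is not part of that determinism contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    CATEGORIES,
    ClassificationConfig,
    build_category_table,
    build_transition_table,
    classify,
)
from .comparative import (
    chi_square_independence,
    deviation_matrix,
    one_proportion_test,
    students_t_test,
    stuart_maxwell,
)
from .errors import ConfigError, ContractError, DegenerateDataError, ReactionomeError
from .expression_data import (
    ExpressionMatrix,
    SampleTable,
    TemperatureGrid,
    default_grid,
    load_expression_table,
    load_sample_metadata,
    log_transform,
)
from .fitting import (
    ReactionNormFit,
    fit_many,
    bh_adjust,
    predict_curves,
    stepwise_aic,
)
from .metrics import (
    induction_temperature,
    tradeoff_records,
    tradeoff_regression,
)
from .permutation import null_significant_counts, retain_true_positives

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_fit",
    "stage_calibrate",
    "stage_classify",
    "stage_compare",
    "stage_metrics",
]


@dataclass
class PipelineConfig:
    expression_path: str = ""
    metadata_path: str = ""
    output_dir: str = "."
    grid: TemperatureGrid = field(default_factory=default_grid)
    alpha: float = 0.05
    B: int = 100
    seed: int = 0
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)
    stepwise_direction: str = "both"
    species_removable: bool = False
    per_transcript_permutation: bool = False
    interaction_only_induction: bool = True
    run_calibration: bool = True
    run_comparative: bool = True
    run_metrics: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.B < 1:
            raise ConfigError(f"B must be at least 1, got {self.B}")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "grid" in raw:
            raw["grid"] = TemperatureGrid(
                tuple(raw["grid"].get("temperatures", ())),
                tuple(raw["grid"].get("excluded", ())),
            )
        if "classification" in raw:
            raw["classification"] = ClassificationConfig(**raw["classification"])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {"temperatures": list(self.grid.temperatures),
                     "excluded": list(self.grid.excluded)}
        return d


# ---------------------------------------------------------------------------
# stages

def stage_fit(Y: np.ndarray, samples: SampleTable,
              transcript_ids: list[str], alpha: float) -> pd.DataFrame:
    """Full-model fits for every transcript plus BH-adjusted q-values."""
    fits = fit_many(Y, samples, transcript_ids)
    fits["q"] = bh_adjust(fits["overall_p"].to_numpy())
    fits["significant"] = fits["q"] < alpha
    return fits


def stage_calibrate(Y: np.ndarray, samples: SampleTable, fits: pd.DataFrame,
                    alpha: float, B: int, seed: int,
                    per_transcript: bool = False):
    """Permutation null and the retained true-positive transcript list."""
    observed = int(fits["significant"].sum())
    null = null_significant_counts(
        Y, samples, B=B, alpha=alpha, seed=seed,
        transcript_ids=list(fits.index), per_transcript=per_transcript,
    )
    retained = retain_true_positives(fits, observed, null)
    return null, observed, retained


def stage_classify(Y: np.ndarray, samples: SampleTable, fits: pd.DataFrame,
                   retained_ids: list[str], grid: TemperatureGrid,
                   config: ClassificationConfig,
                   direction: str = "both", species_removable: bool = False):
    """Stepwise-select, predict per-species curves and categorise.

    Returns (per-transcript frame, category table, transition table, curves)
    where ``curves`` maps transcript id -> (curve_A, curve_B).
    """
    labels = samples.species_labels
    keep = samples.data["retained"].to_numpy()
    id_row = {t: i for i, t in enumerate(fits.index)}
    rows, curves, pairs = [], {}, {}
    cats_by_species: dict[str, list] = {labels[0]: [], labels[1]: []}
    for tid in retained_ids:
        i = id_row[tid]
        fit = ReactionNormFit(
            transcript_id=tid,
            beta=fits.iloc[i][[f"b{k}" for k in range(6)]].to_numpy(float),
            residual_se=float(fits.iloc[i]["residual_se"]),
            overall_p=float(fits.iloc[i]["overall_p"]),
            aic_full=float(fits.iloc[i]["aic_full"]),
            n_obs=int(fits.iloc[i]["n_obs"]),
        )
        y = Y[i, keep] if Y.shape[1] == len(keep) else Y[i]
        model = stepwise_aic(fit, y, samples, direction=direction,
                             species_removable=species_removable)
        curve_a, curve_b = predict_curves(model, grid, species_labels=labels)
        resp_a = curve_a.value_range > config.flatness_epsilon
        resp_b = curve_b.value_range > config.flatness_epsilon
        cat_a = classify(curve_a, resp_a, resp_b, fit.residual_se, config)
        cat_b = classify(curve_b, resp_b, resp_a, fit.residual_se, config)
        curves[tid] = (curve_a, curve_b)
        cats_by_species[labels[0]].append(cat_a)
        cats_by_species[labels[1]].append(cat_b)
        if cat_a is not None and cat_b is not None:
            pairs[tid] = (cat_a, cat_b)
        at25 = config.rearing_temperature
        rows.append({
            "transcript_id": tid,
            "retained_terms": ";".join(model.retained_terms),
            f"responsive_{labels[0]}": resp_a,
            f"responsive_{labels[1]}": resp_b,
            f"category_{labels[0]}": cat_a,
            f"category_{labels[1]}": cat_b,
            f"argmax_temp_{labels[0]}":
                float(curve_a.temperatures[int(np.argmax(curve_a.values))]),
            f"argmax_temp_{labels[1]}":
                float(curve_b.temperatures[int(np.argmax(curve_b.values))]),
            f"bimodal_margin_low_{labels[0]}":
                float(curve_a.values[0] - curve_a.evaluate(at25)),
            f"bimodal_margin_high_{labels[0]}":
                float(curve_a.values[-1] - curve_a.evaluate(at25)),
            f"bimodal_margin_low_{labels[1]}":
                float(curve_b.values[0] - curve_b.evaluate(at25)),
            f"bimodal_margin_high_{labels[1]}":
                float(curve_b.values[-1] - curve_b.evaluate(at25)),
        })
    per_transcript = pd.DataFrame(rows)
    category_table = build_category_table(cats_by_species)
    transition_table = build_transition_table(pairs)
    return per_transcript, category_table, transition_table, curves


def _result_dict(fn, *args, **kwargs) -> dict:
    """Run one comparative test, capturing degenerate inputs as a record."""
    try:
        r = fn(*args, **kwargs)
        return {"statistic": r.statistic, "df": r.df, "p": r.p,
                "method": r.method, "correction": r.correction}
    except (DegenerateDataError, ContractError) as exc:
        return {"error": str(exc)}


def stage_compare(category_table: pd.DataFrame,
                  transition_table: pd.DataFrame) -> dict:
    """The between-species statistical battery on the two count tables."""
    results: dict = {}
    results["categories_2x5"] = _result_dict(
        chi_square_independence, category_table.to_numpy(), yates=False)
    totals = category_table.sum(axis=1)
    for cat in CATEGORIES[:4]:  # each responsive category vs the rest
        counts = category_table[cat]
        table = np.array([
            [counts.iloc[0], totals.iloc[0] - counts.iloc[0]],
            [counts.iloc[1], totals.iloc[1] - counts.iloc[1]],
        ])
        results[f"{cat.lower()}_2x2_yates"] = _result_dict(
            chi_square_independence, table, yates=True)
    responsive = (totals - category_table["NotResp"]).astype(int)
    n_responsive = int(responsive.sum())
    if n_responsive > 0:
        results["total_responsive_proportion"] = _result_dict(
            one_proportion_test, int(responsive.iloc[0]), n_responsive, 0.5,
            correction=True)
    results["stuart_maxwell"] = _result_dict(
        stuart_maxwell, transition_table.to_numpy())
    try:
        results["deviation_matrix"] = deviation_matrix(
            transition_table).to_dict()
    except DegenerateDataError as exc:
        results["deviation_matrix"] = {"error": str(exc)}
    return results


def stage_metrics(per_transcript: pd.DataFrame, curves: dict,
                  samples: SampleTable, grid: TemperatureGrid,
                  config: ClassificationConfig,
                  interaction_only: bool = True) -> dict:
    """Induction temperatures, species t-tests, and tradeoff regressions."""
    labels = samples.species_labels
    exp_temps = grid.retained
    mode_of = {"Low": ("upregulation-low",), "High": ("upregulation-high",),
               "Bimodal": ("upregulation-low", "upregulation-high"),
               "Intermediate": ("downregulation-low-side",
                                "downregulation-high-side")}
    induction_rows, skipped = [], 0
    for row in per_transcript.itertuples(index=False):
        d = row._asdict()
        if interaction_only and not any(
                t in d["retained_terms"].split(";")
                for t in ("species:temp", "species:temp2")):
            continue
        pair = curves[d["transcript_id"]]
        for which, label in enumerate(labels):
            cat = d[f"category_{label}"]
            for mode in mode_of.get(cat, ()):
                try:
                    rec = induction_temperature(pair[which], exp_temps, mode)
                except ContractError:
                    skipped += 1
                    continue
                induction_rows.append({
                    "transcript_id": rec.transcript_id, "species": label,
                    "mode": rec.mode, "temperature": rec.temperature,
                    "magnitude": rec.magnitude,
                })
    induction = pd.DataFrame(
        induction_rows, columns=["transcript_id", "species", "mode",
                                 "temperature", "magnitude"])
    ttests = {}
    for mode in sorted(induction["mode"].unique()) if len(induction) else []:
        sub = induction[induction["mode"] == mode]
        x = sub.loc[sub["species"] == labels[0], "temperature"].to_numpy()
        y = sub.loc[sub["species"] == labels[1], "temperature"].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            ttests[mode] = _result_dict(students_t_test, x, y)

    tradeoffs = {}
    panels = {
        # upregulated at the extreme each species meets less often
        "high_in_second_species":
            per_transcript[f"category_{labels[1]}"].isin(["High"]),
        "low_in_first_species":
            per_transcript[f"category_{labels[0]}"].isin(["Low"]),
    } if len(per_transcript) else {}
    for name, mask in panels.items():
        ids = per_transcript.loc[mask, "transcript_id"]
        recs, excluded = tradeoff_records(
            [curves[t] for t in ids], config.rearing_temperature)
        try:
            reg = tradeoff_regression(recs)
            tradeoffs[name] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "r_squared": reg.r_squared, "p": reg.p, "n": reg.n,
                "excluded": excluded,
            }
        except (ContractError, DegenerateDataError) as exc:
            tradeoffs[name] = {"error": str(exc), "excluded": excluded}
    return {"induction": induction, "induction_skipped": skipped,
            "ttests": ttests, "tradeoffs": tradeoffs}


# ---------------------------------------------------------------------------
# orchestration

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig,
                 matrix: ExpressionMatrix | None = None,
                 samples: SampleTable | None = None) -> dict:
    """Run every enabled stage, write outputs, and return the manifest."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731
    timings: dict[str, float] = {}
    outputs: list[str] = []

    def timed(name):
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 4)

    try:
        stage = timed("load")
        if matrix is None:
            matrix = load_expression_table(config.expression_path)
        if samples is None:
            samples = load_sample_metadata(config.metadata_path, matrix,
                                           config.grid)
        Y = log_transform(matrix).to_numpy()
        done(stage)

        stage = timed("fit")
        fits = stage_fit(Y, samples, matrix.transcript_ids, config.alpha)
        fits.to_csv(out("fits.tsv"), sep="\t", float_format="%.10g")
        outputs.append("fits.tsv")
        done(stage)

        stage = timed("calibrate")
        if config.run_calibration:
            null, observed, retained = stage_calibrate(
                Y, samples, fits, config.alpha, config.B, config.seed,
                config.per_transcript_permutation)
            _write_json({
                "counts": null.counts.tolist(), "q95": null.q95,
                "n_replicates": null.n_replicates, "seed": null.seed,
                "observed_significant": observed,
                "retained_count": len(retained),
            }, out("calibration.json"))
            pd.Series(retained, name="transcript_id").to_csv(
                out("retained.tsv"), sep="\t", index=False)
            outputs += ["calibration.json", "retained.tsv"]
        else:
            retained = list(fits.index[fits["significant"]])
        done(stage)

        stage = timed("classify")
        per_transcript, category_table, transition_table, curves = (
            stage_classify(Y, samples, fits, retained, config.grid,
                           config.classification, config.stepwise_direction,
                           config.species_removable))
        per_transcript.to_csv(out("classification.tsv"), sep="\t",
                              index=False, float_format="%.10g")
        category_table.to_csv(out("category_table.tsv"), sep="\t")
        transition_table.to_csv(out("transition_table.tsv"), sep="\t")
        outputs += ["classification.tsv", "category_table.tsv",
                    "transition_table.tsv"]
        done(stage)

        if config.run_comparative:
            stage = timed("compare")
            comparative = stage_compare(category_table, transition_table)
            _write_json(comparative, out("comparative.json"))
            outputs.append("comparative.json")
            done(stage)

        if config.run_metrics:
            stage = timed("metrics")
            m = stage_metrics(per_transcript, curves, samples, config.grid,
                              config.classification,
                              config.interaction_only_induction)
            m["induction"].to_csv(out("induction.tsv"), sep="\t", index=False,
                                  float_format="%.10g")
            _write_json({"ttests": m["ttests"], "tradeoffs": m["tradeoffs"],
                         "induction_skipped": m["induction_skipped"]},
                        out("metrics.json"))
            outputs += ["induction.tsv", "metrics.json"]
            done(stage)
    except ReactionomeError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": config.echo(),
        "outputs": {name: _sha256(out(name)) for name in outputs},
        "seed_trail": {
            "root": config.seed,
            "calibration_subseeds":
                [config.seed + b for b in range(config.B)]
                if config.run_calibration else [],
        },
        "timings_s": timings,
    }
    _write_json(manifest, out("manifest.json"))
    return manifest
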