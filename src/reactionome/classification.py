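"""Expression-shape classification and category/transition tables.

Each thermally responsive (transcript, species) pair is assigned one of five
categories from its predicted log-expression curve:

* **Bimodal** — predicted expression at both thermal extremes exceeds the
  value at the 25 °C rearing temperature by at least one residual standard
  error (multiplier configurable);
* otherwise, by the temperature of maximal predicted expression:
  **Low** (< 10 °C), **High** (> 31 °C), **Intermediate** ([10, 31] °C);
* **NotResp** — not responsive in this species while responsive in the other.

Transcripts responsive in neither species receive no category and are
excluded.  The 2 species × 5 category count table and the paired 5 × 5
between-species transition table feed the comparative statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .fitting import PredictedCurve

__all__ = [
    "CATEGORIES",
    "ClassificationConfig",
    "classify",
    "classify_pair",
    "build_category_table",
    "build_transition_table",
]

CATEGORIES: tuple[str, ...] = ("Low", "Intermediate", "High", "Bimodal", "NotResp")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for the five-way shape taxonomy.

    ``low_cutoff`` / ``high_cutoff`` bound the Intermediate band of maximal
    expression; ``bimodal_sd_multiplier`` scales the residual-SE margin that
    both extremes must clear over expression at ``rearing_temperature``;
    ``flatness_epsilon`` is the minimal log-scale curve range for a species
    to count as thermally responsive at all.
    """

    low_cutoff: float = 10.0
    high_cutoff: float = 31.0
    rearing_temperature: float = 25.0
    bimodal_sd_multiplier: float = 1.0
    flatness_epsilon: float = 0.5

    def __post_init__(self) -> None:
        if not self.low_cutoff < self.rearing_temperature < self.high_cutoff:
            raise ValidationError(
                "require low_cutoff < rearing_temperature < high_cutoff"
            )
        if self.bimodal_sd_multiplier < 0 or self.flatness_epsilon < 0:
            raise ValidationError("multipliers must be non-negative")


def classify(curve: PredictedCurve, responsive: bool, other_responsive: bool,
             residual_se: float,
             config: ClassificationConfig | None = None) -> str | None:
    """Assign a category to one (transcript, species), or None if excluded.

    ``residual_se`` is the dispersion used by the Bimodal one-SD rule
    (by default the transcript's full-model residual standard error).
    """
    if config is None:
        config = ClassificationConfig()
    lo, hi = curve.temperatures[0], curve.temperatures[-1]
    if not lo <= config.rearing_temperature <= hi:
        raise ContractError(
            f"curve [{lo}, {hi}] does not span the rearing temperature "
            f"{config.rearing_temperature}"
        )
    if not responsive:
        return "NotResp" if other_responsive else None
    at_rearing = curve.evaluate(config.rearing_temperature)
    margin = config.bimodal_sd_multiplier * residual_se
    if (curve.values[0] - at_rearing >= margin
            and curve.values[-1] - at_rearing >= margin):
        return "Bimodal"
    # argmax convention: first (coldest) maximiser on the dense grid
    t_max = float(curve.temperatures[int(np.argmax(curve.values))])
    if t_max < config.low_cutoff:
        return "Low"
    if t_max > config.high_cutoff:
        return "High"
    return "Intermediate"


def classify_pair(curve_a: PredictedCurve, curve_b: PredictedCurve,
                  residual_se: float,
                  config: ClassificationConfig | None = None,
                  ) -> tuple[str | None, str | None]:
    """Classify both species of one transcript with shared responsiveness."""
    if config is None:
        config = ClassificationConfig()
    resp_a = curve_a.value_range > config.flatness_epsilon
    resp_b = curve_b.value_range > config.flatness_epsilon
    return (
        classify(curve_a, resp_a, resp_b, residual_se, config),
        classify(curve_b, resp_b, resp_a, residual_se, config),
    )


def build_category_table(
    categories: Mapping[str, Sequence[str | None]],
) -> pd.DataFrame:
    """Count categories per species: one row per species, columns CATEGORIES.

    Input maps species label -> per-transcript categories (None = excluded,
    which is only valid when the transcript is excluded, not merely
    unclassified — callers must pass every retained transcript).
    """
    rows = {}
    for species, cats in categories.items():
        counts = dict.fromkeys(CATEGORIES, 0)
        for i, c in enumerate(cats):
            if c is None:
                continue
            if c not in counts:
                raise ContractError(
                    f"unknown category {c!r} for species {species!r} (entry {i})"
                )
            counts[c] += 1
        rows[species] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")[list(CATEGORIES)]
    table.index.name = "species"
    return table.astype(int)


def build_transition_table(
    pairs: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Paired 5 × 5 table: rows species-A category, columns species-B.

    ``pairs`` maps transcript id -> (category_A, category_B), or is a plain
    sequence of such pairs.  Every pair must carry two valid categories; an
    unpaired or unclassified entry is a contract violation.
    """
    if isinstance(pairs, Mapping):
        items = [(k, v) for k, v in pairs.items()]
    else:
        items = [(f"entry{i}", v) for i, v in enumerate(pairs)]
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for key, pair in items:
        if pair is None or len(pair) != 2 or any(c is None for c in pair):
            raise ContractError(f"transcript {key!r} lacks a category pair")
        a, b = pair
        if a not in CATEGORIES or b not in CATEGORIES:
            raise ContractError(f"transcript {key!r} has unknown category {pair}")
        table.loc[a, b] += 1
    table.index.name = "species_a"
    table.columns.name = "species_b"
    return table
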