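"""Permutation-null calibration of the significant-transcript count.

Temperature labels are shuffled within each species block, every transcript
is refit, and the number of transcripts passing the BH-FDR threshold is
recorded.  Repeating this B times (default 100) yields a null distribution
of "false significant" counts; its 95th percentile (nearest-rank) is the
null expectation.  The retained "true positive" set is the top
``observed − q95`` transcripts by ascending adjusted p-value — empty when
the observed count does not exceed the null expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression_data import SampleTable
from .fitting import bh_adjust, fit_many

__all__ = [
    "NullDistribution",
    "permute_temperatures",
    "null_significant_counts",
    "retain_true_positives",
]


@dataclass
class NullDistribution:
    """Counts of FDR-significant transcripts across permutation replicates."""

    counts: np.ndarray
    q95: int
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n_replicates,):
            raise ConfigError("counts length must equal n_replicates")


def _nearest_rank_q95(counts: np.ndarray) -> int:
    """Nearest-rank 95th percentile: the ceil(0.95·B)-th order statistic."""
    ordered = np.sort(np.asarray(counts, dtype=int))
    rank = math.ceil(0.95 * len(ordered))
    return int(ordered[rank - 1])


def permute_temperatures(samples: SampleTable, seed: int) -> SampleTable:
    """Shuffle temperature labels uniformly within each species block.

    Species labels and the per-species multiset of temperatures are
    untouched; the permutation is deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    df = samples.data.copy()
    new_temp = df["temperature"].to_numpy(dtype=float).copy()
    for species in samples.species_labels:
        idx = np.flatnonzero((df["species"] == species).to_numpy())
        new_temp[idx] = new_temp[idx][rng.permutation(len(idx))]
    before = {
        sp: sorted(df.loc[df["species"] == sp, "temperature"])
        for sp in samples.species_labels
    }
    df["temperature"] = new_temp
    df["retained"] = ~df["temperature"].isin(samples.grid.excluded)
    out = SampleTable(df.drop(columns=["retained"]), grid=samples.grid)
    for sp in samples.species_labels:  # multiset preservation, asserted always
        after = sorted(out.data.loc[out.data["species"] == sp, "temperature"])
        assert after == before[sp], "permutation altered a temperature multiset"
    return out


def null_significant_counts(Y: np.ndarray, samples: SampleTable, B: int,
                            alpha: float, seed: int,
                            transcript_ids: list[str] | None = None,
                            per_transcript: bool = False) -> NullDistribution:
    """Null distribution of the FDR-significant count over B permutations.

    ``Y`` is the transcripts × samples log(TPM + 1) matrix in the column
    order of ``samples.data``.  Replicate b uses sub-seed ``seed + b``.  By
    default one permutation per replicate is applied to all transcripts
    (preserving between-transcript correlation); ``per_transcript`` instead
    shuffles each transcript independently within species blocks.
    """
    if B < 1:
        raise ConfigError(f"need at least one replicate, got B={B}")
    if not 0.0 < alpha < 1.0:
        if alpha == 1.0:  # degenerate but well-defined: everything significant
            n_t = np.asarray(Y).shape[0]
            counts = np.full(B, n_t, dtype=int)
            return NullDistribution(counts, _nearest_rank_q95(counts), B, seed)
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    Y = np.asarray(Y, dtype=float)
    counts = np.empty(B, dtype=int)
    for b in range(B):
        sub_seed = seed + b
        if per_transcript:
            fits = _fit_per_transcript_permuted(Y, samples, sub_seed,
                                                transcript_ids)
        else:
            permuted = permute_temperatures(samples, sub_seed)
            fits = fit_many(Y, permuted, transcript_ids)
        q = bh_adjust(fits["overall_p"].to_numpy())
        counts[b] = int(np.sum(q < alpha))
    return NullDistribution(counts, _nearest_rank_q95(counts), B, seed)


def _fit_per_transcript_permuted(Y, samples, seed, transcript_ids):
    """Independently permute each transcript's values within species blocks.

    Equivalent to per-transcript temperature re-assignment: shuffling the
    response within a species block is the same exchange of (value, T)
    pairings, and keeps the shared design matrix usable.
    """
    rng = np.random.default_rng(seed)
    rows = samples.data
    Yp = Y.copy()
    for species in samples.species_labels:
        idx = np.flatnonzero((rows["species"] == species).to_numpy())
        for i in range(Y.shape[0]):
            Yp[i, idx] = Yp[i, idx][rng.permutation(len(idx))]
    return fit_many(Yp, samples, transcript_ids)


def retain_true_positives(fits: pd.DataFrame, observed_significant: int,
                          null: NullDistribution) -> list[str]:
    """Transcripts kept after discounting the permutation-null expectation.

    ``fits`` must carry columns ``overall_p`` and ``q`` (BH-adjusted) indexed
    by transcript id.  The top ``max(0, observed − q95)`` transcripts are
    retained by ascending adjusted p, ties broken by ascending raw p then
    transcript id.  Returns the retained ids in that rank order.
    """
    if observed_significant < 0:
        raise ConfigError("observed_significant must be non-negative")
    n_keep = max(0, observed_significant - null.q95)
    if n_keep == 0:
        return []
    ranked = fits.reset_index().sort_values(
        ["q", "overall_p", "transcript_id"], kind="mergesort"
    )
    return ranked["transcript_id"].head(n_keep).tolist()
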