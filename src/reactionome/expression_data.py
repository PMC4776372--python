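"""Data model and I/O for expression matrices and sample metadata.

The pipeline's primary input is a transcripts × samples table of TPM
(transcripts per million) values together with a metadata table mapping each
sample to a species label and an exposure temperature in °C.  The experimental
design is one pooled sample per species × temperature cell on a fixed
temperature grid.

All downstream regression operates on log(TPM + 1) — natural log — which
stabilises the heavy right skew of TPM values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InputError,
    ReconciliationError,
    ValidationError,
)

__all__ = [
    "TemperatureGrid",
    "ExpressionMatrix",
    "SampleTable",
    "default_grid",
    "load_expression_table",
    "write_expression_table",
    "load_sample_metadata",
    "log_transform",
]


@dataclass(frozen=True)
class TemperatureGrid:
    """Ordered experimental temperature levels, with optional exclusions.

    Parameters
    ----------
    temperatures
        Strictly increasing exposure temperatures in °C.
    excluded
        Subset of ``temperatures`` dropped from analysis (samples at these
        levels are flagged and removed from design matrices).
    """

    temperatures: tuple[float, ...]
    excluded: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        excl = tuple(sorted(float(t) for t in self.excluded))
        if len(temps) < 2:
            raise ValidationError("temperature grid needs at least 2 levels")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValidationError("grid temperatures must be strictly increasing")
        if not set(excl) <= set(temps):
            bad = sorted(set(excl) - set(temps))
            raise ValidationError(f"excluded temperatures not on grid: {bad}")
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "excluded", excl)

    @property
    def retained(self) -> tuple[float, ...]:
        """Grid temperatures that enter the analysis."""
        return tuple(t for t in self.temperatures if t not in set(self.excluded))

    @property
    def span(self) -> tuple[float, float]:
        return self.temperatures[0], self.temperatures[-1]


def default_grid() -> TemperatureGrid:
    """The 12-level design grid: 0 to 38.5 °C in 3.5 °C increments.

    The 7 °C level is excluded by default (suspect labelling in the original
    experiment); override by constructing a :class:`TemperatureGrid` directly.
    """
    return TemperatureGrid(tuple(np.arange(12) * 3.5), excluded=(7.0,))


@dataclass
class ExpressionMatrix:
    """Transcripts × samples table of non-negative TPM values."""

    transcript_ids: list[str]
    sample_ids: list[str]
    tpm: np.ndarray

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        n_t, n_s = len(self.transcript_ids), len(self.sample_ids)
        if self.tpm.shape != (n_t, n_s):
            raise ValidationError(
                f"TPM shape {self.tpm.shape} does not match "
                f"{n_t} transcripts × {n_s} samples"
            )
        for name, ids in (("transcript", self.transcript_ids),
                          ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise FormatError(f"duplicate {name} id(s): {dupes}")
        if not np.all(np.isfinite(self.tpm)):
            raise ValidationError("TPM matrix contains non-finite values")
        if np.any(self.tpm < 0):
            r, c = map(int, np.argwhere(self.tpm < 0)[0])
            raise ValidationError(
                f"negative TPM at transcript {self.transcript_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.tpm, index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            transcript_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            tpm=frame.to_numpy(dtype=float),
        )

    def subset(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset preserving the requested order."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.transcript_ids, list(sample_ids),
                                self.tpm[:, cols])


@dataclass
class SampleTable:
    """Per-sample design information validated against a matrix and grid.

    ``data`` has one row per sample with columns ``sample_id``, ``species``,
    ``temperature`` and a boolean ``retained`` (False for samples at excluded
    grid temperatures).  Downstream design matrices use only retained rows.
    """

    data: pd.DataFrame
    grid: TemperatureGrid = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "temperature"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"sample table missing column(s): {sorted(missing)}")
        df = self.data.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["species"] = df["species"].astype(str)
        df["temperature"] = df["temperature"].astype(float)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample id(s): {dupes}")
        species = sorted(df["species"].unique())
        if len(species) > 2:
            raise ValidationError(
                f"expected at most two species labels, got {species}"
            )
        on_grid = df["temperature"].isin(self.grid.temperatures)
        if not on_grid.all():
            bad = df.loc[~on_grid, ["sample_id", "temperature"]]
            raise ValidationError(
                "off-grid temperature(s): "
                + ", ".join(f"{r.sample_id}={r.temperature}"
                            for r in bad.itertuples())
            )
        dup_cell = df.duplicated(subset=["species", "temperature"])
        if dup_cell.any():
            bad = df.loc[dup_cell, ["species", "temperature"]]
            raise ValidationError(
                "more than one sample per (species, temperature) cell: "
                + ", ".join(f"({r.species}, {r.temperature})"
                            for r in bad.itertuples())
            )
        if "retained" not in df.columns:
            df["retained"] = ~df["temperature"].isin(self.grid.excluded)
        self.data = df.reset_index(drop=True)

    @property
    def species_labels(self) -> tuple[str, ...]:
        """Species labels in lexicographic order (first = reference level)."""
        return tuple(sorted(self.data["species"].unique()))

    @property
    def retained_rows(self) -> pd.DataFrame:
        return self.data[self.data["retained"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def load_expression_table(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a TSV expression table: first column transcript id, rest samples."""
    if not os.path.exists(path):
        raise InputError(f"expression table not found: {path}")
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise FormatError(f"duplicate sample id(s) in header: {dupes}")
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate transcript id(s): {dupes}")
    values = np.empty(frame.shape, dtype=float)
    # cell-by-cell float(): correctly rounded (pandas' fast parser is not),
    # and failures can name their coordinates
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                v = float("nan")
            if not np.isfinite(v) or v < 0:
                raise FormatError(
                    f"non-numeric or negative cell at transcript "
                    f"{frame.index[i]!r}, sample {col!r}: {raw!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(
        transcript_ids=[str(i) for i in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        tpm=values,
    )


def write_expression_table(matrix: ExpressionMatrix,
                           path: str | os.PathLike) -> None:
    """Write a matrix as TSV at full float precision (round-trip safe).

    Values are written with Python's shortest round-trip repr, so a
    write-then-read cycle reproduces the matrix bit for bit.
    """
    matrix.to_frame().to_csv(path, sep="\t")


def load_sample_metadata(path: str | os.PathLike, matrix: ExpressionMatrix,
                         grid: TemperatureGrid | None = None) -> SampleTable:
    """Read and validate sample metadata against a matrix and grid.

    Samples at excluded grid temperatures are kept in the table but flagged
    ``retained=False`` so they drop out of downstream design matrices.
    """
    if grid is None:
        grid = default_grid()
    if not os.path.exists(path):
        raise InputError(f"sample metadata not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = SampleTable(
        pd.DataFrame({
            "sample_id": df["sample_id"].astype(str)
            if "sample_id" in df.columns else _missing(path, "sample_id"),
            "species": df["species"].astype(str)
            if "species" in df.columns else _missing(path, "species"),
            "temperature": pd.to_numeric(df["temperature"])
            if "temperature" in df.columns else _missing(path, "temperature"),
        }),
        grid=grid,
    )
    meta_ids = set(table.data["sample_id"])
    matrix_ids = set(matrix.sample_ids)
    if meta_ids != matrix_ids:
        only_meta = sorted(meta_ids - matrix_ids)
        only_matrix = sorted(matrix_ids - meta_ids)
        raise ReconciliationError(
            f"sample mismatch — in metadata only: {only_meta}; "
            f"in matrix only: {only_matrix}"
        )
    return table


def _missing(path, column):
    raise FormatError(f"sample metadata {path} missing column {column!r}")


def log_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Return log(TPM + 1), natural log, as a transcripts × samples frame."""
    return pd.DataFrame(
        np.log1p(matrix.tpm),
        index=pd.Index(matrix.transcript_ids, name="transcript_id"),
        columns=matrix.sample_ids,
    )
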