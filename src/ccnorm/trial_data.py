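"""Repeated-trial spike data: containers, binning, PSTH, and file I/O.

The raw object of study is a trial matrix: ``N`` repeated presentations of
the same stimulus, each binned into ``T`` time bins of spike counts. The
peri-stimulus time histogram (PSTH) — the per-bin mean count across trials
— is the target signal every prediction is scored against. With finite
``N`` the PSTH is only a noisy estimate of the neuron's underlying firing
rate, which is exactly why the downstream metrics correct for
trial-to-trial variability.

Conventions
-----------
* Bins are half-open ``[start, end)`` with 0-based indices; a spike landing
  exactly on a boundary belongs to the later bin.
* The PSTH is kept in mean counts per bin. Conversion to spikes/s is a
  display concern (divide by the bin width); the performance metrics are
  invariant to a common rescaling of data and prediction.
* Default bin width is 5 ms.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.005  # seconds

PathLike = Union[str, Path]


class DataFormatError(ValueError):
    """Raised when an input file or array violates the expected format."""


@dataclass(frozen=True)
class TrialMatrix:
    """N repeated trials × T time bins of non-negative spike counts."""

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise DataFormatError(
                f"trial matrix must be 2-D (trials × bins), got shape {counts.shape}"
            )
        if counts.shape[0] < 1:
            raise DataFormatError("trial matrix needs at least one trial")
        if counts.shape[1] < 2:
            raise DataFormatError(
                f"trial matrix needs at least 2 time bins, got {counts.shape[1]}"
            )
        if not np.all(np.isfinite(counts)):
            raise DataFormatError("trial matrix contains non-finite values")
        if np.any(counts < 0):
            raise DataFormatError("spike counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise DataFormatError("spike counts must be integral")
        if self.bin_width <= 0:
            raise DataFormatError(f"bin width must be positive, got {self.bin_width}")
        object.__setattr__(self, "counts", np.round(counts).astype(np.int64))

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin-center times in seconds."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class RateSeries:
    """A length-T real-valued series on the trial matrix's time grid.

    Used both for the PSTH ``y`` (mean counts per bin) and for a model
    prediction ``ŷ``. ``values / bin_width`` gives spikes/s.
    """

    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size < 2:
            raise DataFormatError(f"rate series needs at least 2 bins, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise DataFormatError("rate series contains non-finite values")
        if self.bin_width <= 0:
            raise DataFormatError(f"bin width must be positive, got {self.bin_width}")
        object.__setattr__(self, "values", values)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def as_hz(self) -> np.ndarray:
        return self.values / self.bin_width

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpikeTable:
    """Spike times tagged by 1-based trial id, before binning."""

    trial_ids: np.ndarray
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.trial_ids, dtype=np.int64).ravel()
        times = np.asarray(self.spike_times, dtype=float).ravel()
        if ids.size != times.size:
            raise DataFormatError("trial ids and spike times differ in length")
        if ids.size and ids.min() < 1:
            raise DataFormatError("trial ids must be ≥ 1")
        if times.size and times.min() < 0:
            raise DataFormatError("spike times must be non-negative")
        object.__setattr__(self, "trial_ids", ids)
        object.__setattr__(self, "spike_times", times)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SpikeTable":
        recs = list(records)
        if recs:
            ids, times = zip(*recs)
        else:
            ids, times = (), ()
        return cls(np.array(ids, dtype=np.int64), np.array(times, dtype=float))

    def __len__(self) -> int:
        return self.trial_ids.size


def compute_psth(trials: TrialMatrix) -> RateSeries:
    """Average the trial matrix over trials: the PSTH, in counts per bin."""
    return RateSeries(trials.counts.mean(axis=0), trials.bin_width)


def bin_spikes(
    spikes: SpikeTable,
    n_trials: int,
    duration: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> TrialMatrix:
    """Bin a spike-time table into an N×T count matrix.

    Bins are half-open ``[t0, t0 + bin_width)``; a spike exactly on a
    boundary is counted in the later bin. A final partial bin (when
    ``duration`` is not an integer multiple of ``bin_width``) is dropped
    with a logged warning, as is any spike at or beyond the last full bin.
    """
    if n_trials < 1:
        raise DataFormatError("n_trials must be ≥ 1")
    if duration <= 0 or bin_width <= 0:
        raise DataFormatError("duration and bin_width must be positive")
    n_bins = int(math.floor(duration / bin_width + 1e-9))
    if n_bins < 2:
        raise DataFormatError(
            f"duration {duration}s at bin width {bin_width}s yields {n_bins} bins; need ≥ 2"
        )
    if abs(duration - n_bins * bin_width) > 1e-9 * max(1.0, duration):
        logger.warning(
            "duration %.6gs is not a multiple of bin width %.6gs; "
            "dropping the final partial bin",
            duration,
            bin_width,
        )
    ids = spikes.trial_ids
    if ids.size and (ids.min() < 1 or ids.max() > n_trials):
        bad = ids[(ids < 1) | (ids > n_trials)][0]
        raise DataFormatError(f"trial id {bad} outside 1..{n_trials}")
    counts = np.zeros((n_trials, n_bins), dtype=np.int64)
    if ids.size:
        bin_idx = np.floor(spikes.spike_times / bin_width + 1e-9).astype(np.int64)
        in_range = bin_idx < n_bins
        n_out = int((~in_range).sum())
        if n_out:
            logger.warning("%d spike(s) at/after %.6gs dropped", n_out, n_bins * bin_width)
        np.add.at(counts, (ids[in_range] - 1, bin_idx[in_range]), 1)
    return TrialMatrix(counts, bin_width)


# ---------------------------------------------------------------------------
# File I/O. Trial matrices and rate series are plain CSV/TSV; the delimiter
# is sniffed and an optional header row is detected by a non-numeric first
# row. Parse errors name the offending row/column (1-based, header included).
# ---------------------------------------------------------------------------


def _sniff_rows(path: PathLike) -> list[list[str]]:
    text = Path(path).read_text()
    if not text.strip():
        raise DataFormatError(f"{path}: file is empty")
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        delim = dialect.delimiter
    except csv.Error:
        delim = ","
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delim) if row]
    return [[cell.strip() for cell in row] for row in rows]


def _is_numeric_row(row: Sequence[str]) -> bool:
    for cell in row:
        try:
            float(cell)
        except ValueError:
            return False
    return True


def _parse_numeric(rows: list[list[str]], path: PathLike) -> tuple[np.ndarray, int]:
    """Parse rows to a float matrix, skipping one header row if present.

    Returns the matrix and the 1-based file row number of the first data row.
    """
    start = 0 if _is_numeric_row(rows[0]) else 1
    data_rows = rows[start:]
    if not data_rows:
        raise DataFormatError(f"{path}: no data rows below the header")
    width = len(data_rows[0])
    out = np.empty((len(data_rows), width), dtype=float)
    for i, row in enumerate(data_rows):
        file_row = start + i + 1
        if len(row) != width:
            raise DataFormatError(
                f"{path}: row {file_row} has {len(row)} fields, expected {width} (ragged rows)"
            )
        for j, cell in enumerate(row):
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-numeric value {cell!r} at row {file_row}, column {j + 1}"
                ) from None
    return out, start + 1


def read_trial_matrix(path: PathLike, bin_width: float = DEFAULT_BIN_WIDTH) -> TrialMatrix:
    """Read an N×T count matrix from CSV/TSV (rows = trials, columns = bins)."""
    rows = _sniff_rows(path)
    matrix, first_row = _parse_numeric(rows, path)
    neg = np.argwhere(matrix < 0)
    if neg.size:
        i, j = neg[0]
        raise DataFormatError(
            f"{path}: negative count at row {first_row + int(i)}, column {int(j) + 1}"
        )
    nonint = np.argwhere(~np.isclose(matrix, np.round(matrix)))
    if nonint.size:
        i, j = nonint[0]
        raise DataFormatError(
            f"{path}: non-integral count at row {first_row + int(i)}, column {int(j) + 1}"
        )
    return TrialMatrix(matrix, bin_width)


def write_trial_matrix(trials: TrialMatrix, path: PathLike) -> None:
    """Write a trial matrix as CSV (no header); lossless round trip."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(trials.counts).to_csv(path, sep=sep, header=False, index=False)


def read_rate_series(path: PathLike, bin_width: float = DEFAULT_BIN_WIDTH) -> RateSeries:
    """Read a rate series from a single-row or single-column CSV/TSV."""
    rows = _sniff_rows(path)
    matrix, _ = _parse_numeric(rows, path)
    if 1 not in matrix.shape:
        raise DataFormatError(
            f"{path}: rate series must be a single row or column, got shape {matrix.shape}"
        )
    return RateSeries(matrix.ravel(), bin_width)


def write_rate_series(series: RateSeries, path: PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame([series.values]).to_csv(path, sep=sep, header=False, index=False)


def read_spike_table(path: PathLike) -> SpikeTable:
    """Read a spike table from CSV with columns ``trial`` and ``time_s``."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "trial" not in cols or "time_s" not in cols:
        raise DataFormatError(
            f"{path}: spike table needs columns 'trial' and 'time_s', got {list(df.columns)}"
        )
    return SpikeTable(df[cols["trial"]].to_numpy(), df[cols["time_s"]].to_numpy())
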