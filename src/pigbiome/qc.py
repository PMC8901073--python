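"""Quality filtering of joined 16S amplicon reads.

Three rules, applied in order, decide a read's fate:

1. a run of more than ``max_bad_run`` consecutive low-quality base calls
   (Phred <= ``threshold``) truncates the read immediately before the run
   starts;
2. the retained length must be at least ``min_fraction`` of the original
   read length;
3. the retained portion must contain no uncalled ('N') bases.

Low quality means Phred <= 19 under the default threshold: the convention
of the amplicon toolchains this mirrors, which treat the threshold value
itself as low. An alternative "longest stretch" semantics — no truncation,
the fraction being the longest run of high-quality calls over read length —
is available via ``mode="longest_run"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

FAILURE_RULES = ("long_low_run", "low_fraction", "contains_N")


@dataclass
class ReadRecord:
    """A single read: id, bases and per-base Phred scores."""

    id: str
    sequence: str
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int64)
        if len(self.sequence) != self.quality.size:
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {self.quality.size}"
            )
        if self.quality.size and (
            self.quality.min() < 0 or self.quality.max() > 60
        ):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcStats:
    """Partition of the input reads into kept and per-rule failures."""

    n_input: int = 0
    n_kept: int = 0
    n_failed: dict = field(
        default_factory=lambda: {r: 0 for r in FAILURE_RULES}
    )

    @property
    def retention_rate(self) -> float:
        return self.n_kept / self.n_input if self.n_input else float("nan")


def max_consecutive_low_quality(
    quality: Sequence[int], threshold: int
) -> int:
    """Length of the longest run of scores <= ``threshold``."""
    q = np.asarray(quality)
    if q.size == 0:
        raise ValueError("empty quality vector")
    low = q <= threshold
    if not low.any():
        return 0
    # run lengths via boundaries of the low-quality indicator
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def _first_disqualifying_run(quality: np.ndarray, threshold: int,
                             max_bad_run: int) -> int | None:
    """Start index of the first low-quality run longer than max_bad_run."""
    low = np.asarray(quality) <= threshold
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    long_enough = (ends - starts) > max_bad_run
    if not long_enough.any():
        return None
    return int(starts[long_enough][0])


def truncate_and_fraction(
    read: ReadRecord, threshold: int = 19, max_bad_run: int = 3
) -> tuple[ReadRecord, float]:
    """Truncate at the first over-long low-quality run; report the fraction.

    The read is cut immediately before the start of the first run of more
    than ``max_bad_run`` consecutive calls with Phred <= ``threshold``; the
    returned fraction is truncated length over original length (1.0 when no
    such run exists).
    """
    n = len(read)
    if n == 0:
        return read, 1.0
    cut = _first_disqualifying_run(read.quality, threshold, max_bad_run)
    if cut is None:
        return read, 1.0
    truncated = ReadRecord(read.id, read.sequence[:cut], read.quality[:cut])
    return truncated, cut / n


def longest_high_quality_fraction(
    read: ReadRecord, threshold: int = 19
) -> float:
    """Longest stretch of Phred > threshold over read length (no truncation)."""
    n = len(read)
    if n == 0:
        return 1.0
    high = read.quality > threshold
    if not high.any():
        return 0.0
    padded = np.concatenate(([False], high, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return float((edges[1::2] - edges[::2]).max() / n)


def filter_reads(
    reads: Iterable[ReadRecord],
    threshold: int = 19,
    max_bad_run: int = 3,
    min_fraction: float = 0.75,
    mode: str = "truncate",
) -> tuple[list[ReadRecord], QcStats]:
    """Apply the three QC rules to a read stream.

    Returns the kept (possibly truncated) reads and a :class:`QcStats`
    partitioning every failure under its first failing rule. Under the
    default truncation semantics an over-long low-quality run only ever
    fails a read through the retained-length fraction, so such reads count
    under ``low_fraction``; under ``mode="longest_run"`` (no truncation)
    the run rule is applied on its own first (``long_low_run``), then the
    fraction rule. Reads passing both with an 'N' in the retained portion
    count under ``contains_N``.
    """
    if mode not in ("truncate", "longest_run"):
        raise ValueError(f"unknown QC mode {mode!r}")
    kept: list[ReadRecord] = []
    stats = QcStats()
    for read in reads:
        stats.n_input += 1
        if mode == "truncate":
            retained, fraction = truncate_and_fraction(
                read, threshold, max_bad_run
            )
        else:
            retained = read
            fraction = longest_high_quality_fraction(read, threshold)
            if (len(read) > 0 and
                    max_consecutive_low_quality(read.quality, threshold)
                    > max_bad_run):
                stats.n_failed["long_low_run"] += 1
                continue
        if fraction < min_fraction:
            stats.n_failed["low_fraction"] += 1
            continue
        if "N" in retained.sequence:
            stats.n_failed["contains_N"] += 1
            continue
        stats.n_kept += 1
        kept.append(retained)
    return kept, stats
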