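"""cfDNA fragment input and per-bin short/long tallies.

Fragments arrive as BED3+ intervals (0-based, half-open; one deduplicated
sequenced molecule per row).  Each fragment is assigned to the unique
100-kb bin containing its midpoint and classified by length: short =
100-150 bp, long = 151-220 bp (inclusive).  Lengths of all bin-assigned
fragments within [50, 400] bp are additionally retained (as an integer
histogram) for fragment-length mixture modelling.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import ParseError
from .tiling import AUTOSOMES, ReferenceTiling

logger = logging.getLogger(__name__)

SHORT_RANGE = (100, 150)  # bp, inclusive
LONG_RANGE = (151, 220)  # bp, inclusive
LENGTH_RANGE = (50, 400)  # bp, inclusive window retained for mixture fitting

LENGTH_GRID = np.arange(LENGTH_RANGE[0], LENGTH_RANGE[1] + 1)


class Fragment(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ParseStats:
    """Counters accumulated while reading a fragment BED."""

    n_read: int = 0
    n_non_autosomal: int = 0


@dataclass
class BinnedCounts:
    """Per-bin short/long fragment counts plus the retained length histogram.

    ``length_hist[i]`` counts assigned fragments of length ``LENGTH_GRID[i]``.
    """

    sample_id: str
    short: np.ndarray
    long: np.ndarray
    length_hist: np.ndarray
    total_fragments: int = 0

    def __post_init__(self) -> None:
        self.short = np.asarray(self.short)
        self.long = np.asarray(self.long)
        self.length_hist = np.asarray(self.length_hist)
        if self.short.shape != self.long.shape:
            raise ValueError("short/long count arrays must have equal length")
        if (self.short < 0).any() or (self.long < 0).any() or (self.length_hist < 0).any():
            raise ValueError("negative counts")
        if self.length_hist.shape != LENGTH_GRID.shape:
            raise ValueError(f"length_hist must have {LENGTH_GRID.size} entries")

    @property
    def n_lengths(self) -> int:
        return int(self.length_hist.sum())


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fragments(source, stats: ParseStats | None = None) -> Iterator[Fragment]:
    """Yield autosomal fragments from a BED3+ path or text stream, in file order.

    Non-autosomal records are dropped (counted in ``stats`` and logged);
    malformed coordinates or inverted intervals raise ``ParseError`` with the
    offending line number.  Columns beyond the third are ignored.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with _open_maybe_gzip(source) as fh:
            yield from read_fragments(fh, stats=stats)
        return
    stats = stats if stats is not None else ParseStats()
    autosomes = set(AUTOSOMES)
    for lineno, line in enumerate(source, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected >=3 columns, got {len(parts)}")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ParseError(f"line {lineno}: start ({start}) must be < end ({end})")
        stats.n_read += 1
        if chrom not in autosomes:
            stats.n_non_autosomal += 1
            continue
        yield Fragment(chrom, start, end)
    if stats.n_non_autosomal:
        logger.info("dropped %d non-autosomal fragment(s)", stats.n_non_autosomal)


def bin_fragments(
    fragments: Iterable[Fragment], tiling: ReferenceTiling, sample_id: str = "sample"
) -> BinnedCounts:
    """Tally short/long fragments per 100-kb bin by fragment midpoint.

    A fragment contributes to the unique bin containing its midpoint
    ``floor((start + end) / 2)``; fragments whose midpoint lies in no bin are
    dropped.  Length classification: short if in [100, 150], long if in
    [151, 220]; all assigned fragments with length in [50, 400] enter the
    retained length histogram.
    """
    frags = list(fragments) if not isinstance(fragments, pd.DataFrame) else None
    if frags is not None:
        if len(frags) == 0:
            n = tiling.n_bins
            return BinnedCounts(sample_id, np.zeros(n, np.int64), np.zeros(n, np.int64),
                                np.zeros(LENGTH_GRID.size, np.int64), 0)
        df = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    else:
        df = fragments[["chrom", "start", "end"]]

    n_bins = tiling.n_bins
    short = np.zeros(n_bins, np.int64)
    long_ = np.zeros(n_bins, np.int64)
    length_hist = np.zeros(LENGTH_GRID.size, np.int64)
    total = len(df)

    mid = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2
    length = df["end"].to_numpy(np.int64) - df["start"].to_numpy(np.int64)
    chroms = df["chrom"].to_numpy()

    bins = tiling.bins
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        cbins = bins[bins["chrom"] == chrom]
        if len(cbins) == 0:
            continue
        starts = cbins["start"].to_numpy()
        ends = cbins["end"].to_numpy()
        ids = cbins.index.to_numpy()
        m = mid[cmask]
        ln = length[cmask]
        pos = np.searchsorted(starts, m, side="right") - 1
        inside = (pos >= 0) & (m < ends[np.clip(pos, 0, None)])
        if not inside.any():
            continue
        bin_idx = ids[pos[inside]]
        ln_in = ln[inside]
        s_mask = (ln_in >= SHORT_RANGE[0]) & (ln_in <= SHORT_RANGE[1])
        l_mask = (ln_in >= LONG_RANGE[0]) & (ln_in <= LONG_RANGE[1])
        np.add.at(short, bin_idx[s_mask], 1)
        np.add.at(long_, bin_idx[l_mask], 1)
        keep = (ln_in >= LENGTH_RANGE[0]) & (ln_in <= LENGTH_RANGE[1])
        if keep.any():
            length_hist += np.bincount(
                ln_in[keep] - LENGTH_RANGE[0], minlength=LENGTH_GRID.size
            )
    return BinnedCounts(sample_id, short, long_, length_hist, total)


# ---------------------------------------------------------------------------
# Counts / lengths file I/O
# ---------------------------------------------------------------------------

def write_counts(counts: BinnedCounts, path, header_comment: str | None = None) -> None:
    """Write per-bin counts as TSV ``bin_id short long``."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("bin_id\tshort\tlong\n")
        for i, (s, l) in enumerate(zip(counts.short, counts.long)):
            fh.write(f"{i}\t{s}\t{l}\n")


def write_lengths(counts: BinnedCounts, path, header_comment: str | None = None) -> None:
    """Write the retained length histogram as TSV ``length count`` (zeros omitted)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("length\tcount\n")
        for ln, c in zip(LENGTH_GRID, counts.length_hist):
            if c:
                fh.write(f"{ln}\t{c}\n")


def read_counts(counts_path, lengths_path=None, sample_id: str | None = None) -> BinnedCounts:
    """Read counts (and optionally a length histogram) written by the writers above."""
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    for col in ("bin_id", "short", "long"):
        if col not in df.columns:
            raise ParseError(f"counts file missing column {col!r}")
    df = df.sort_values("bin_id")
    if not (df["bin_id"].to_numpy() == np.arange(len(df))).all():
        raise ParseError("counts file bin_ids are not 0..n-1")
    hist = np.zeros(LENGTH_GRID.size, np.int64)
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", comment="#")
        lens = ldf["length"].to_numpy(np.int64)
        if ((lens < LENGTH_RANGE[0]) | (lens > LENGTH_RANGE[1])).any():
            raise ParseError("length histogram outside the retained [50, 400] bp window")
        hist[lens - LENGTH_RANGE[0]] = ldf["count"].to_numpy(np.int64)
    sid = sample_id or str(counts_path)
    total = int(df["short"].sum() + df["long"].sum())
    return BinnedCounts(sid, df["short"].to_numpy(np.int64), df["long"].to_numpy(np.int64),
                        hist, total)
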