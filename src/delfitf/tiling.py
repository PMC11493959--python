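"""Genomic coordinate system for fragmentation profiling.

The method scores cfDNA fragmentation over a fixed tiling of the hg19
autosomes: adjacent, non-overlapping 100-kb bins that avoid excluded
(gap/low-mappability) regions, annotated with chromosome arm and GC
fraction, and aggregated into 5-Mb groups of 50 contiguous bins for
profile construction.  The canonical hg19 tiling has exactly 26,236
100-kb bins, 504 5-Mb groups and 39 scoreable arms (the five acrocentric
short arms 13p/14p/15p/21p/22p are never tiled).

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, TilingError

BIN_SIZE = 100_000
GROUP_SIZE = 50  # 100-kb bins per 5-Mb group

#: hg19 autosome lengths (UCSC chromInfo).
HG19_AUTOSOME_SIZES: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}

#: hg19 centromere gaps (UCSC gap table), half-open intervals.
HG19_CENTROMERES: dict[str, tuple[int, int]] = {
    "chr1": (121_535_434, 124_535_434), "chr2": (92_326_171, 95_326_171),
    "chr3": (90_504_854, 93_504_854), "chr4": (49_660_117, 52_660_117),
    "chr5": (46_405_641, 49_405_641), "chr6": (58_830_166, 61_830_166),
    "chr7": (58_054_331, 61_054_331), "chr8": (43_838_887, 46_838_887),
    "chr9": (47_367_679, 50_367_679), "chr10": (39_254_935, 42_254_935),
    "chr11": (51_644_205, 54_644_205), "chr12": (34_856_694, 37_856_694),
    "chr13": (16_000_000, 19_000_000), "chr14": (16_000_000, 19_000_000),
    "chr15": (17_000_000, 20_000_000), "chr16": (35_335_801, 38_335_801),
    "chr17": (22_263_006, 25_263_006), "chr18": (15_460_898, 18_460_898),
    "chr19": (24_681_782, 27_681_782), "chr20": (26_369_569, 29_369_569),
    "chr21": (11_288_129, 14_288_129), "chr22": (13_000_000, 16_000_000),
}

#: Acrocentric chromosomes: the p arm is heterochromatic rDNA and never scored.
ACROCENTRIC = ("chr13", "chr14", "chr15", "chr21", "chr22")

TELOMERE_PAD = 10_000  # hg19 telomere gap at each chromosome end

AUTOSOMES = tuple(HG19_AUTOSOME_SIZES)

# canonical hg19 contract
HG19_N_BINS = 26_236
HG19_N_GROUPS = 504
HG19_N_ARMS = 39

_BIN_COLUMNS = ["bin_id", "chrom", "start", "end", "gc", "arm", "group5mb"]
_GC_NOISE_SEED = 20_240_521  # fixed seed of the synthetic GC track


def _chrom_rank(chrom: str) -> int:
    try:
        return AUTOSOMES.index(chrom)
    except ValueError:
        return len(AUTOSOMES)  # non-canonical names sort after, by insertion


@dataclass
class ReferenceTiling:
    """Validated 100-kb tiling with arm labels, GC track and 5-Mb groups.

    ``bins`` columns: ``bin_id chrom start end gc arm group5mb``;
    ``group5mb`` uses ``-1`` for bins that belong to no complete 5-Mb group.
    """

    bins: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.bins["chrom"].unique(), key=_chrom_rank)

    @property
    def arms(self) -> list[str]:
        """Arm labels in chromosome order, p before q."""
        seen = self.bins["arm"].unique().tolist()
        return sorted(seen, key=lambda a: (_chrom_rank("chr" + a[:-1]), a[-1]))

    @property
    def n_groups(self) -> int:
        g = self.bins["group5mb"]
        return int((g >= 0).sum()) // GROUP_SIZE

    @property
    def group_ids(self) -> np.ndarray:
        g = np.unique(self.bins["group5mb"].to_numpy())
        return g[g >= 0]

    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(float)

    def content_hash(self) -> str:
        """Stable hash of the bin table, used for model/tiling compatibility."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.bins.to_csv(sep="\t", index=False).encode())
        return h.hexdigest()[:12]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        b = self.bins
        if len(b) == 0:
            raise TilingError("no bins")
        if list(b.columns) != _BIN_COLUMNS:
            raise TilingError(f"bin table columns must be {_BIN_COLUMNS}")
        if b["bin_id"].duplicated().any():
            raise TilingError("duplicate bin_ids")
        if not (b["end"] - b["start"] == BIN_SIZE).all():
            bad = b.loc[b["end"] - b["start"] != BIN_SIZE].iloc[0]
            raise TilingError(
                f"bin {bad.bin_id} has width {bad.end - bad.start}, expected {BIN_SIZE}"
            )
        order = b.sort_values(
            ["chrom", "start"], key=lambda s: s.map(_chrom_rank) if s.name == "chrom" else s
        ).index
        if not (order.to_numpy() == np.arange(len(b))).all():
            raise TilingError("bins not sorted by (chrom, start)")
        for chrom, grp in b.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise TilingError(f"overlapping bins on {chrom}")
        if ((b["gc"] < 0) | (b["gc"] > 1)).any():
            raise TilingError("gc_fraction outside [0, 1]")
        self._validate_groups()
        self._validate_exclusions()

    def _validate_groups(self) -> None:
        b = self.bins
        grouped = b[b["group5mb"] >= 0]
        for gid, grp in grouped.groupby("group5mb"):
            if len(grp) != GROUP_SIZE:
                raise TilingError(f"5-Mb group {gid} has {len(grp)} bins, expected {GROUP_SIZE}")
            if grp["arm"].nunique() != 1:
                raise TilingError(f"5-Mb group {gid} spans multiple arms")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (starts[1:] == ends[:-1]).all():
                raise TilingError(f"5-Mb group {gid} is not contiguous")

    def _validate_exclusions(self) -> None:
        if len(self.exclusions) == 0:
            return
        excl = self.exclusions
        for chrom, grp in self.bins.groupby("chrom", sort=False):
            e = excl[excl["chrom"] == chrom]
            if len(e) == 0:
                continue
            es = e["start"].to_numpy()
            ee = e["end"].to_numpy()
            idx = np.searchsorted(es, grp["start"].to_numpy(), side="right") - 1
            prev_overlaps = (idx >= 0) & (ee[np.clip(idx, 0, None)] > grp["start"].to_numpy())
            nxt = idx + 1
            next_overlaps = (nxt < len(es)) & (es[np.clip(nxt, None, len(es) - 1)] < grp["end"].to_numpy())
            if (prev_overlaps | next_overlaps).any():
                raise TilingError(f"bin intersects an exclusion interval on {chrom}")

    # -- serialization -----------------------------------------------------
    def write(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out = self.bins.copy()
            out["gc"] = out["gc"].map(lambda v: format(v, ".17g"))
            out.to_csv(fh, sep="\t", index=False)

    def write_exclusions(self, path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False, header=False)


def _merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(
        ["chrom", "start"], key=lambda s: s.map(_chrom_rank) if s.name == "chrom" else s
    ).reset_index(drop=True)


def _check_exclusions(exclusions: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    if len(exclusions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    excl = exclusions[["chrom", "start", "end"]].copy()
    for chrom in excl["chrom"].unique():
        if chrom not in chrom_sizes:
            raise TilingError(f"exclusion chromosome {chrom!r} absent from chrom sizes")
    for chrom, grp in excl.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if (np.diff(s) < 0).any():
            raise TilingError(f"exclusions not sorted on {chrom}")
        if (s[1:] < e[:-1]).any():
            raise TilingError(f"overlapping exclusions on {chrom}")
        if (s >= e).any():
            raise TilingError(f"empty/inverted exclusion interval on {chrom}")
    return excl.reset_index(drop=True)


def synthetic_gc(bins: pd.DataFrame) -> np.ndarray:
    """Deterministic synthetic GC track.

    Real per-bin GC is a genome property the package does not ship at full
    resolution; this stand-in combines a smooth positional wave (isochore-like
    structure) with fixed-seed bin-level noise, clipped to a realistic range.
    It is synthetic data: it makes the GC-correction machinery exercisable,
    not biologically faithful.
    """
    chrom_idx = bins["chrom"].map(_chrom_rank).to_numpy()
    pos = bins["start"].to_numpy(float)
    wave = 0.055 * np.sin(2 * np.pi * pos / 3.7e7 + 0.9 * chrom_idx)
    noise = 0.025 * np.random.default_rng(_GC_NOISE_SEED).standard_normal(len(bins))
    return np.clip(0.41 + wave + noise, 0.30, 0.62)


def build_tiling(
    chrom_sizes: dict[str, int],
    exclusions: pd.DataFrame | None = None,
    gc_source=None,
    centromeres: dict[str, tuple[int, int]] | None = None,
) -> ReferenceTiling:
    """Tile chromosomes into 100-kb bins avoiding excluded regions.

    Within every maximal non-excluded run, adjacent 100-kb bins are laid
    down from the run start; a sub-100-kb remainder is left untiled.  Bins
    are labelled with the arm containing them (p/q split at the centromere
    interval; a chromosome without a centromere entry is treated as a single
    q arm).  Consecutive runs of 50 bins on one arm form 5-Mb groups;
    leftover bins that cannot complete a group carry ``group5mb = -1``.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    exclusions
        DataFrame ``chrom start end`` of sorted, merged intervals no bin may
        intersect.  Overlapping or unsorted intervals raise ``TilingError``.
    gc_source
        ``None`` (synthetic track), an array of per-bin GC fractions, or a
        callable ``bins_df -> array``.
    centromeres
        Mapping chromosome -> (start, end) of the centromere gap.
    """
    excl = _check_exclusions(
        exclusions if exclusions is not None else pd.DataFrame(columns=["chrom", "start", "end"]),
        chrom_sizes,
    )
    centromeres = centromeres or {}
    records: list[tuple] = []
    group_id = 0
    for chrom in sorted(chrom_sizes, key=_chrom_rank):
        size = chrom_sizes[chrom]
        cen = centromeres.get(chrom, (0, 0))
        e = excl[excl["chrom"] == chrom]
        # non-excluded runs over [0, size)
        edges = [0]
        for s, ee in zip(e["start"], e["end"]):
            edges.extend((int(s), int(min(ee, size))))
        edges.append(size)
        runs = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2) if edges[i] < edges[i + 1]]
        for run_start, run_end in runs:
            # split the run at the centromere so no bin straddles arms
            pieces = []
            if cen[1] > cen[0] and run_start < cen[1] and run_end > cen[0]:
                if run_start < cen[0]:
                    pieces.append((run_start, cen[0]))
                if run_end > cen[1]:
                    pieces.append((cen[1], run_end))
            else:
                pieces.append((run_start, run_end))
            for ps, pe in pieces:
                arm_letter = "p" if (cen[1] > cen[0] and pe <= cen[0]) else "q"
                arm = chrom.removeprefix("chr") + arm_letter
                n = (pe - ps) // BIN_SIZE
                run_bins = [(chrom, ps + i * BIN_SIZE, ps + (i + 1) * BIN_SIZE, arm) for i in range(n)]
                n_groups_here = n // GROUP_SIZE
                for i, rec in enumerate(run_bins):
                    gid = group_id + i // GROUP_SIZE if i // GROUP_SIZE < n_groups_here else -1
                    records.append((*rec, gid))
                group_id += n_groups_here
    if not records:
        raise TilingError("no bins")
    bins = pd.DataFrame(records, columns=["chrom", "start", "end", "arm", "group5mb"])
    bins.insert(0, "bin_id", np.arange(len(bins)))
    if gc_source is None:
        gc = synthetic_gc(bins)
    elif callable(gc_source):
        gc = np.asarray(gc_source(bins), float)
    else:
        gc = np.asarray(gc_source, float)
    if len(gc) != len(bins):
        raise TilingError(f"gc_source length {len(gc)} != number of bins {len(bins)}")
    bins.insert(4, "gc", gc)
    return ReferenceTiling(bins=bins[_BIN_COLUMNS], exclusions=excl)


# ---------------------------------------------------------------------------
# Canonical hg19 tiling
# ---------------------------------------------------------------------------

def _hg19_arm_spans() -> list[tuple[str, str, int, int]]:
    """(arm, chrom, start, end) scoreable spans, p before q, chromosome order."""
    spans = []
    for chrom in AUTOSOMES:
        size = HG19_AUTOSOME_SIZES[chrom]
        cs, ce = HG19_CENTROMERES[chrom]
        stem = chrom.removeprefix("chr")
        if chrom not in ACROCENTRIC:
            spans.append((stem + "p", chrom, TELOMERE_PAD, cs))
        spans.append((stem + "q", chrom, ce, size - TELOMERE_PAD))
    return spans


def _hg19_allocation() -> dict[str, int]:
    """Bins per arm such that totals hit the 26,236 / 504 / 39-arm contract.

    Remainder bins (26,236 - 504*50 = 1,036 = 17*26 + 22*27) are spread as
    26 per arm plus one extra on the 22 highest-capacity arms; 5-Mb groups
    are allocated across arms by largest-remainder apportionment of each
    arm's bin capacity, capped so every arm can still hold its remainder.
    """
    spans = _hg19_arm_spans()
    arms = [a for a, *_ in spans]
    cap = {a: (e - s) // BIN_SIZE for a, _, s, e in spans}
    total_cap = sum(cap.values())

    extra = sorted(arms, key=lambda a: (-cap[a], arms.index(a)))[:22]
    rem = {a: 27 if a in extra else 26 for a in arms}

    gcap = {a: (cap[a] - rem[a]) // GROUP_SIZE for a in arms}
    ideal = {a: HG19_N_GROUPS * cap[a] / total_cap for a in arms}
    groups = {a: min(int(ideal[a]), gcap[a]) for a in arms}
    deficit = HG19_N_GROUPS - sum(groups.values())
    while deficit > 0:
        cands = [a for a in arms if groups[a] < gcap[a]]
        cands.sort(key=lambda a: (-(ideal[a] - groups[a]), arms.index(a)))
        for a in cands[:deficit]:
            groups[a] += 1
        deficit = HG19_N_GROUPS - sum(groups.values())
    return {a: GROUP_SIZE * groups[a] + rem[a] for a in arms}


def hg19_exclusions() -> pd.DataFrame:
    """Canonical exclusion set: complement of the tiled hg19 bins.

    Assembled from the hg19 gap annotations (telomeres, centromeres,
    acrocentric short arms) plus deterministic arm-end padding chosen so the
    tiled bins meet the published bin/group/arm counts exactly.
    """
    alloc = _hg19_allocation()
    rows = []
    for arm, chrom, s, _e in _hg19_arm_spans():
        rows.append((chrom, s, s + alloc[arm] * BIN_SIZE))
    tiled = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    excl_rows = []
    for chrom in AUTOSOMES:
        size = HG19_AUTOSOME_SIZES[chrom]
        t = tiled[tiled["chrom"] == chrom].sort_values("start")
        prev = 0
        for s, e in zip(t["start"], t["end"]):
            if s > prev:
                excl_rows.append((chrom, prev, s))
            prev = e
        if prev < size:
            excl_rows.append((chrom, prev, size))
    return _merge_intervals(pd.DataFrame(excl_rows, columns=["chrom", "start", "end"]))


def hg19_tiling(gc_source=None) -> ReferenceTiling:
    """The canonical hg19 autosome tiling (26,236 bins, 504 groups, 39 arms)."""
    return build_tiling(
        HG19_AUTOSOME_SIZES, hg19_exclusions(), gc_source=gc_source,
        centromeres=HG19_CENTROMERES,
    )


# ---------------------------------------------------------------------------
# Miniature synthetic tiling for fast tests
# ---------------------------------------------------------------------------

def mini_tiling(n_chroms: int = 2) -> ReferenceTiling:
    """Small synthetic tiling: 500 bins / 10 groups per chromosome.

    Each chromosome carries a 200-bin p arm (4 groups) and a 300-bin q arm
    (6 groups); the default two chromosomes give 1,000 bins in 20 groups.
    Use ``n_chroms >= 5`` when a plasma-aneuploidy score is needed.
    """
    if not 1 <= n_chroms <= 22:
        raise TilingError("n_chroms must be in [1, 22]")
    p_bins, q_bins = 200, 300
    cen_start = TELOMERE_PAD + p_bins * BIN_SIZE
    cen_end = cen_start + 1_000_000
    size = cen_end + q_bins * BIN_SIZE + TELOMERE_PAD
    sizes = {f"chr{i + 1}": size for i in range(n_chroms)}
    cens = {c: (cen_start, cen_end) for c in sizes}
    excl_rows = []
    for c in sizes:
        excl_rows += [
            (c, 0, TELOMERE_PAD),
            (c, cen_start, cen_end),
            (c, size - TELOMERE_PAD, size),
        ]
    excl = _merge_intervals(pd.DataFrame(excl_rows, columns=["chrom", "start", "end"]))
    return build_tiling(sizes, excl, centromeres=cens)


# ---------------------------------------------------------------------------
# Tiling file I/O
# ---------------------------------------------------------------------------

def load_tiling(path, exclusions_path=None) -> ReferenceTiling:
    """Load and validate a tiling TSV (``bin_id chrom start end gc arm group5mb``)."""
    try:
        bins = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "arm": str})
    except pd.errors.EmptyDataError:
        raise TilingError("no bins") from None
    missing = [c for c in _BIN_COLUMNS if c not in bins.columns]
    if missing:
        raise ParseError(f"tiling file missing columns: {missing}")
    if len(bins) == 0:
        raise TilingError("no bins")
    for col in ("bin_id", "start", "end", "group5mb"):
        if not np.issubdtype(bins[col].dtype, np.integer):
            try:
                bins[col] = bins[col].astype(np.int64)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-integer values in column {col!r}") from exc
    bins["gc"] = bins["gc"].astype(float)
    exclusions = None
    if exclusions_path is not None:
        exclusions = read_bed3(exclusions_path)
    return ReferenceTiling(
        bins=bins[_BIN_COLUMNS],
        exclusions=exclusions if exclusions is not None else pd.DataFrame(columns=["chrom", "start", "end"]),
    )


def read_bed3(path_or_buf) -> pd.DataFrame:
    """Read a 3+-column BED of intervals into ``chrom start end``."""
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf) as fh:
            return read_bed3(fh)
    rows = []
    for lineno, line in enumerate(path_or_buf, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"line {lineno}: expected >=3 columns")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column ``chrom<TAB>size`` TSV."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected 2 columns")
            try:
                out[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer size") from exc
    return out
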