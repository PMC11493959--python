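"""maxMAF from targeted-panel variant reports.

For validation cohorts profiled with a deep targeted panel instead of
ddPCR, circulating tumor burden is summarised as the maximum MAF over
somatic hotspot variants.  A variant is a hotspot when its exact
nucleotide change recurs in at least 20 catalogued cancer cases;
non-hotspots with MAF above 40% are treated as putative germline.  Both
non-hotspots and putative germline calls are filtered before taking the
maximum.  Hotspots with MAF above 40% are retained (the germline rule is
defined only for non-hotspots) but flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParseError

HOTSPOT_MIN_RECURRENCE = 20
GERMLINE_MAF_THRESHOLD = 40.0  # percent, exclusive


@dataclass(frozen=True)
class VariantCall:
    gene: str
    variant: str
    maf: float  # percent
    recurrence: int  # identical alterations in the cancer-mutation catalogue

    def __post_init__(self) -> None:
        if not 0 <= self.maf <= 100:
            raise ValueError(f"MAF must be in [0, 100], got {self.maf}")
        if self.recurrence < 0:
            raise ValueError(f"recurrence must be >= 0, got {self.recurrence}")


def classify_variant(v: VariantCall) -> str:
    """Return ``'hotspot'``, ``'putative_germline'`` or ``'non_hotspot'``."""
    if v.recurrence >= HOTSPOT_MIN_RECURRENCE:
        return "hotspot"
    if v.maf > GERMLINE_MAF_THRESHOLD:
        return "putative_germline"
    return "non_hotspot"


@dataclass
class MaxMafResult:
    max_maf: float | None  # None when no hotspot survives filtering
    n_hotspots: int
    flags: list[str]

    @property
    def defined(self) -> bool:
        return self.max_maf is not None


def max_maf(variants: list[VariantCall]) -> MaxMafResult:
    """Maximum MAF over hotspot variants; undefined when none survive.

    Order-independent; adding non-hotspot or putative-germline variants
    never changes the result.  High-MAF hotspots (> 40%) are retained and
    flagged.
    """
    hotspots = [v for v in variants if classify_variant(v) == "hotspot"]
    flags = [
        f"high_maf_hotspot:{v.gene}:{v.variant}"
        for v in hotspots
        if v.maf > GERMLINE_MAF_THRESHOLD
    ]
    if not hotspots:
        reason = "no_variants" if not variants else "no_hotspots_after_filtering"
        return MaxMafResult(None, 0, [reason])
    return MaxMafResult(max(v.maf for v in hotspots), len(hotspots), flags)


def read_variants(path) -> list[VariantCall]:
    """Read a TSV ``gene variant maf recurrence`` into variant calls."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("gene", "variant", "maf", "recurrence") if c not in df.columns]
    if missing:
        raise ParseError(f"variant table missing columns: {missing}")
    return [
        VariantCall(str(r.gene), str(r.variant), float(r.maf), int(r.recurrence))
        for r in df.itertuples()
    ]
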