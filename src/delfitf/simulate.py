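"""Synthetic longitudinal cfDNA cohorts with known tumor fractions.

Real cohorts for this method are controlled-access; the simulator makes
every stage of the pipeline verifiable by generating bin-level fragment
counts and fragment-length histograms from an explicit two-archetype
generative model:

* a healthy archetype with a smooth per-group short/long baseline and
  length mixture 0.80 N(167,10) + 0.15 N(320,30) + 0.05 N(480,40);
* a tumor archetype with its own smooth ratio curve, per-patient
  arm-level copy events (multiplicative 2^+-u, u ~ U(0.2, 1.0)) and
  length mixture 0.40 N(145,12) + 0.45 N(167,10) + 0.15 N(320,30).

A sample at tumor fraction theta draws per-bin short and long counts from
Poisson means mixing the archetypes (1-theta)/theta and fragment lengths
from the theta-mixed length model.  Per-patient trajectories decay
exponentially from baseline after treatment start and regrow after a
nadir; ddPCR-style labels are binomial mutant-droplet counts at
probability theta*s (clonality s ~ Beta(50, 2.5)), zeroed below the
droplet limit of detection.  A healthy panel is a set of theta = 0
samples.

Count simulation happens at bin level (the method consumes bin counts and
lengths only); optional BED emission supports end-to-end I/O tests.  All
randomness flows from a single seed via spawned generator sub-streams.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import DelfiTFError
from .fragments import (
    LENGTH_GRID,
    LONG_RANGE,
    SHORT_RANGE,
    BinnedCounts,
    write_counts,
    write_lengths,
)
from .tiling import ReferenceTiling

HEALTHY_LENGTH_MIX = ((0.80, 167.0, 10.0), (0.15, 320.0, 30.0), (0.05, 480.0, 40.0))
TUMOR_LENGTH_MIX = ((0.40, 145.0, 12.0), (0.45, 167.0, 10.0), (0.15, 320.0, 30.0))
ARM_EFFECT_RANGE = (0.2, 1.0)  # |log2| copy effect per altered arm
CLONALITY_BETA = (50.0, 2.5)  # clonality s ~ Beta(a, b), mean ~0.95

_EPOCH = dt.date(2020, 1, 6)  # registration date of the first simulated patient


@dataclass
class SimulationConfig:
    """Cohort-level knobs; the defaults are the package's study conditions.

    ``coverage`` is the expected number of fragments per sample,
    ``tf_range`` the baseline tumor-fraction range, ``response_decay`` /
    ``regrowth`` the per-day exponential rates of the on-treatment
    trajectory, and ``droplet_count`` / ``lod_droplets`` the ddPCR label
    process.  ``seed`` is mandatory: every random draw descends from it.
    """

    seed: int
    n_patients: int = 60
    draws_per_patient: int = 4
    coverage: int = 8_000_000
    tf_range: tuple[float, float] = (0.005, 0.45)
    n_altered_arms: int = 8
    response_decay: float = 0.06  # per day
    regrowth: float = 0.02  # per day
    droplet_count: int = 10_000
    lod_droplets: int = 10
    n_panel: int = 30
    draw_interval_days: int = 56
    never_progressor_frac: float = 0.15
    bio_arm_sd: float = 0.01  # per-sample arm-level lognormal jitter
    bio_profile_sd: float = 0.01  # per-sample 5-Mb-group lognormal jitter
    length_shift_sd: float = 1.5  # bp, per-sample shift of the length modes

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DelfiTFError("simulation seed is mandatory")
        lo, hi = self.tf_range
        if not 0 <= lo <= hi <= 0.5:
            raise DelfiTFError(f"tf_range must satisfy 0 <= lo <= hi <= 0.5, got {self.tf_range}")
        if self.coverage < 10_000:
            raise DelfiTFError("coverage must be >= 10,000 fragments per sample")
        if self.n_patients < 1 or self.draws_per_patient < 1:
            raise DelfiTFError("need at least one patient and one draw")
        if self.lod_droplets < 1 or self.droplet_count < self.lod_droplets:
            raise DelfiTFError("droplet_count must be >= lod_droplets >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        obj.update(overrides)
        if "tf_range" in obj:
            obj["tf_range"] = tuple(obj["tf_range"])
        return cls(**obj)

    def to_yaml(self, path) -> None:
        obj = asdict(self)
        obj["tf_range"] = list(obj["tf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=True)


@dataclass
class SimulatedSample:
    counts: BinnedCounts
    patient_id: str
    date: dt.date
    day: int
    maf_label: float  # percent; 0 when undetected
    detectable: bool
    truth_tf: float
    truth_arms: tuple[str, ...]

    @property
    def sample_id(self) -> str:
        return self.counts.sample_id


@dataclass
class SimulatedCohort:
    samples: list[SimulatedSample]
    panel_counts: list[BinnedCounts]
    clinical: pd.DataFrame  # patient_id, treatment_start, progression_date
    config: SimulationConfig
    tiling_hash: str = ""

    def metadata(self, include_truth: bool = True) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "date": s.date.isoformat(),
                "maf_label": s.maf_label,
                "detectable": s.detectable,
            }
            if include_truth:
                row["truth_tf"] = s.truth_tf
                row["truth_arms"] = ",".join(s.truth_arms)
            rows.append(row)
        return pd.DataFrame(rows)

    def feature_inputs(self):
        """(counts, metadata) pairs for featurisation -- truth columns excluded."""
        for s in self.samples:
            yield s.counts, {
                "patient_id": s.patient_id,
                "date": s.date.isoformat(),
                "maf_label": s.maf_label,
                "detectable": s.detectable,
            }


def _mixture_density(mix, shift: float = 0.0) -> np.ndarray:
    """Length density over the retained grid, renormalised after truncation."""
    x = LENGTH_GRID.astype(float)
    d = np.zeros_like(x)
    for w, mu, sd in mix:
        d += w * sps.norm.pdf(x, mu + shift, sd)
    return d / d.sum()


def _window_prob(density: np.ndarray, lo: int, hi: int) -> float:
    g0 = LENGTH_GRID[0]
    return float(density[lo - g0: hi - g0 + 1].sum())


class CohortSimulator:
    """Precomputes archetype rates for one tiling and emits samples/cohorts."""

    def __init__(self, config: SimulationConfig, tiling: ReferenceTiling):
        self.config = config
        self.tiling = tiling
        self.arms = list(tiling.arms)
        if config.n_altered_arms > len(self.arms):
            raise DelfiTFError(
                f"n_altered_arms={config.n_altered_arms} exceeds the tiling's {len(self.arms)} arms"
            )
        bins = tiling.bins
        self._arm_idx = bins["arm"].map({a: i for i, a in enumerate(self.arms)}).to_numpy()
        gid = bins["group5mb"].to_numpy()
        self._gid = np.where(gid >= 0, gid, tiling.n_groups)  # ungrouped -> extra slot
        n_slots = tiling.n_groups + 1

        self._f_h = _mixture_density(HEALTHY_LENGTH_MIX)
        self._f_t = _mixture_density(TUMOR_LENGTH_MIX)
        sh = _window_prob(self._f_h, *SHORT_RANGE)
        lh = _window_prob(self._f_h, *LONG_RANGE)
        st = _window_prob(self._f_t, *SHORT_RANGE)
        lt = _window_prob(self._f_t, *LONG_RANGE)

        lam = config.coverage / tiling.n_bins
        g = np.arange(n_slots) / max(tiling.n_groups, 1)
        # fixed smooth modulation curves; tumor phase-shifted so profiles differ
        mod_h = 1.0 + 0.12 * np.sin(2 * np.pi * 3 * g) + 0.08 * np.cos(2 * np.pi * 5 * g)
        dem_h = 1.0 - 0.06 * np.sin(2 * np.pi * 3 * g)
        mod_t = 1.0 + 0.15 * np.sin(2 * np.pi * 4 * g + 1.3) + 0.10 * np.cos(2 * np.pi * 7 * g + 0.4)
        dem_t = 1.0 - 0.08 * np.sin(2 * np.pi * 4 * g + 1.3)
        self._short_h = lam * sh * mod_h[self._gid]
        self._long_h = lam * lh * dem_h[self._gid]
        self._short_t = lam * st * mod_t[self._gid]
        self._long_t = lam * lt * dem_t[self._gid]

    # -- single sample -----------------------------------------------------
    def sample_counts(
        self,
        theta: float,
        rng: np.random.Generator,
        arm_log2: np.ndarray | None = None,
        sample_id: str = "sample",
    ) -> BinnedCounts:
        """Draw one sample's binned counts and length histogram at ``theta``."""
        cfg = self.config
        if arm_log2 is None:
            arm_log2 = np.zeros(len(self.arms))
        arm_mult = np.exp2(arm_log2)[self._arm_idx]
        arm_jit = np.exp(rng.normal(0.0, cfg.bio_arm_sd, len(self.arms)))[self._arm_idx]
        grp_jit = np.exp(
            rng.normal(0.0, cfg.bio_profile_sd, self.tiling.n_groups + 1)
        )[self._gid]
        jitter = arm_jit * grp_jit
        short_mean = ((1 - theta) * self._short_h + theta * self._short_t * arm_mult) * jitter
        long_mean = ((1 - theta) * self._long_h + theta * self._long_t * arm_mult) * jitter
        short = rng.poisson(short_mean)
        long_ = rng.poisson(long_mean)

        shift = rng.normal(0.0, cfg.length_shift_sd)
        density = (1 - theta) * _mixture_density(HEALTHY_LENGTH_MIX, shift) \
            + theta * _mixture_density(TUMOR_LENGTH_MIX, shift)
        density = density / density.sum()
        n_len = rng.poisson(cfg.coverage)
        hist = rng.multinomial(n_len, density)
        return BinnedCounts(sample_id, short, long_, hist, int(n_len))

    # -- cohort ------------------------------------------------------------
    def _trajectory(self, theta0, decay, regrow, t_nadir, day):
        theta = theta0 * np.exp(-decay * min(day, t_nadir))
        if day > t_nadir:
            theta *= np.exp(regrow * (day - t_nadir))
        return float(min(theta, 0.5))

    def simulate(self) -> SimulatedCohort:
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        panel_ss, patients_ss = root.spawn(2)

        panel_counts = [
            self.sample_counts(0.0, np.random.default_rng(ss), sample_id=f"panel_{i:03d}")
            for i, ss in enumerate(panel_ss.spawn(cfg.n_panel))
        ]

        samples: list[SimulatedSample] = []
        clinical_rows = []
        for p, ss in enumerate(patients_ss.spawn(cfg.n_patients)):
            rng = np.random.default_rng(ss)
            pid = f"P{p:03d}"
            reg = _EPOCH + dt.timedelta(days=3 * p)
            theta0 = rng.uniform(*cfg.tf_range)
            decay = cfg.response_decay * rng.uniform(0.5, 1.5)
            regrow = cfg.regrowth * rng.uniform(0.5, 1.5)
            t_nadir = rng.uniform(40, 110)
            clonality = rng.beta(*CLONALITY_BETA)
            progresses = rng.uniform() >= cfg.never_progressor_frac
            prog_day = int(rng.uniform(150, 215)) if progresses else None
            altered = rng.choice(len(self.arms), cfg.n_altered_arms, replace=False)
            arm_log2 = np.zeros(len(self.arms))
            arm_log2[altered] = rng.choice([-1.0, 1.0], cfg.n_altered_arms) \
                * rng.uniform(*ARM_EFFECT_RANGE, cfg.n_altered_arms)
            truth_arms = tuple(self.arms[i] for i in sorted(altered))

            for d in range(cfg.draws_per_patient):
                day = d * cfg.draw_interval_days
                theta = self._trajectory(theta0, decay, regrow, t_nadir, day) if day else theta0
                counts = self.sample_counts(
                    theta, rng, arm_log2, sample_id=f"{pid}_T{d}"
                )
                droplets = rng.binomial(cfg.droplet_count, min(theta * clonality, 1.0))
                detectable = droplets >= cfg.lod_droplets
                maf = 100.0 * droplets / cfg.droplet_count if detectable else 0.0
                samples.append(
                    SimulatedSample(
                        counts=counts,
                        patient_id=pid,
                        date=reg + dt.timedelta(days=day),
                        day=day,
                        maf_label=maf,
                        detectable=bool(detectable),
                        truth_tf=theta,
                        truth_arms=truth_arms,
                    )
                )
            clinical_rows.append(
                {
                    "patient_id": pid,
                    "treatment_start": reg.isoformat(),
                    "progression_date": (reg + dt.timedelta(days=prog_day)).isoformat()
                    if prog_day is not None else "",
                }
            )
        return SimulatedCohort(
            samples=samples,
            panel_counts=panel_counts,
            clinical=pd.DataFrame(clinical_rows),
            config=cfg,
            tiling_hash=self.tiling.content_hash(),
        )


def simulate_cohort(config: SimulationConfig, tiling: ReferenceTiling) -> SimulatedCohort:
    """Generate a longitudinal cohort plus healthy-panel samples."""
    return CohortSimulator(config, tiling).simulate()


def simulate_healthy(
    config: SimulationConfig, tiling: ReferenceTiling, n: int, seed_offset: int = 1
) -> list[BinnedCounts]:
    """Extra tumor-fraction-0 samples independent of the cohort streams."""
    sim = CohortSimulator(config, tiling)
    root = np.random.SeedSequence((config.seed, seed_offset))
    return [
        sim.sample_counts(0.0, np.random.default_rng(ss), sample_id=f"healthy_{i:03d}")
        for i, ss in enumerate(root.spawn(n))
    ]


def simulate_spike_ins(
    config: SimulationConfig,
    tiling: ReferenceTiling,
    thetas: list[float],
    seed_offset: int = 2,
) -> list[BinnedCounts]:
    """One synthetic patient sampled at several tumor fractions.

    The arm-level copy events are drawn once and shared across all
    fractions, emulating serial draws from a single tumor.
    """
    sim = CohortSimulator(config, tiling)
    root = np.random.SeedSequence((config.seed, seed_offset))
    rng = np.random.default_rng(root)
    arms = list(tiling.arms)
    altered = rng.choice(len(arms), config.n_altered_arms, replace=False)
    arm_log2 = np.zeros(len(arms))
    arm_log2[altered] = rng.choice([-1.0, 1.0], config.n_altered_arms) \
        * rng.uniform(*ARM_EFFECT_RANGE, config.n_altered_arms)
    return [
        sim.sample_counts(th, np.random.default_rng(ss), arm_log2,
                          sample_id=f"spike_{th:g}")
        for th, ss in zip(thetas, root.spawn(len(thetas)))
    ]


# ---------------------------------------------------------------------------
# Cohort output
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: SimulatedCohort,
    directory,
    tiling: ReferenceTiling | None = None,
    write_bed: bool = False,
    header: str | None = None,
) -> None:
    """Write per-sample counts and length files plus cohort metadata.

    Metadata truth columns are prefixed ``truth_`` and are excluded from the
    feature-matrix path.  With ``write_bed=True`` (requires ``tiling``) each
    sample additionally gets a fragment BED whose per-bin short/long tallies
    reproduce the sample's counts exactly; within-class lengths are
    resampled uniformly, so BED emission is meant for I/O tests at small
    coverage, not for re-deriving length histograms.
    """
    import os

    if write_bed and tiling is None:
        raise DelfiTFError("write_bed=True requires the tiling")
    os.makedirs(directory, exist_ok=True)
    all_counts = [s.counts for s in cohort.samples] + cohort.panel_counts
    for i, counts in enumerate(all_counts):
        base = os.path.join(directory, counts.sample_id)
        write_counts(counts, base + ".counts.tsv", header_comment=header)
        write_lengths(counts, base + ".lengths.tsv", header_comment=header)
        if write_bed:
            emit_bed(counts, tiling, base + ".bed", seed=cohort.config.seed + i)
    cohort.metadata(include_truth=True).to_csv(
        os.path.join(directory, "cohort_metadata.tsv"), sep="\t", index=False
    )
    cohort.clinical.to_csv(
        os.path.join(directory, "clinical.tsv"), sep="\t", index=False
    )


def emit_bed(
    counts: BinnedCounts, tiling: ReferenceTiling, path, seed: int = 0
) -> None:
    """Emit a fragment BED reproducing the sample's per-bin short/long counts.

    Fragment midpoints are placed away from bin edges so midpoint binning
    assigns every emitted fragment to its source bin.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBED)))
    bins = tiling.bins
    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    with open(path, "w") as fh:
        for i in range(tiling.n_bins):
            for n, (lo, hi) in ((counts.short[i], SHORT_RANGE), (counts.long[i], LONG_RANGE)):
                if n == 0:
                    continue
                lens = rng.integers(lo, hi + 1, int(n))
                mids = rng.integers(starts[i] + 300, starts[i] + 99_700, int(n))
                fs = mids - lens // 2
                for s, ln in zip(fs, lens):
                    fh.write(f"{chroms[i]}\t{s}\t{s + ln}\n")
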