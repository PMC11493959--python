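"""Fragmentation features: GC-corrected short/long profiles, arm-level
aneuploidy z-scores, the plasma-aneuploidy (PA) score, and fragment-length
mixture summaries.

Feature set per sample (before the two principal components added at model
time): 11 length-mixture weights, the PA-score, and the two largest
absolute arm z-scores -- 14 values, extended to 16 by profile PCs.

All reference statistics (per-arm mean/sd of arm count fractions, the
median short/long ratio profile, and the shared mixture components) come
from a panel of non-cancer samples and are held fixed when scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DelfiTFError, PanelError, SampleQCError
from .fragments import LENGTH_GRID, LENGTH_RANGE, BinnedCounts
from .tiling import ReferenceTiling, _chrom_rank

LOESS_SPAN = 0.75
LOESS_ROBUST_ITER = 2
PA_DF = 3  # degrees of freedom of the t distribution mapping |z| to p
PA_TOP_CHROMS = 5
PA_P_FLOOR = 1e-300
N_MIXTURE_COMPONENTS = 12
N_WEIGHT_FEATURES = 11  # first 11 of the 12 mean-sorted component weights
MAX_MISSING_GROUP_FRAC = 0.05

BASE_FEATURE_NAMES = (
    [f"w{i}" for i in range(1, N_WEIGHT_FEATURES + 1)] + ["pa", "z_top1", "z_top2"]
)


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def gc_correct(counts: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Remove the GC dependence of per-bin counts by loess residualisation.

    Fits a locally weighted regression of counts on GC fraction (span 0.75,
    two robustness iterations) and returns
    ``counts - fitted + median(counts)``, floored at zero.  Applied
    separately to short and long counts.  A constant GC vector degenerates
    to subtracting the mean (nothing to fit); all-zero counts are returned
    unchanged.
    """
    counts = np.asarray(counts, float)
    gc = np.asarray(gc, float)
    if counts.shape != gc.shape:
        raise ValueError("counts and gc must be aligned to the same tiling")
    if not np.any(counts):
        return counts.copy()
    span = float(np.ptp(gc))
    if span == 0.0:
        fitted = np.full_like(counts, counts.mean())
    else:
        fitted = lowess(
            counts, gc, frac=LOESS_SPAN, it=LOESS_ROBUST_ITER,
            delta=0.01 * span, return_sorted=False,
        )
    corrected = counts - fitted + np.median(counts)
    return np.maximum(corrected, 0.0)


# ---------------------------------------------------------------------------
# Short/long ratio profiles
# ---------------------------------------------------------------------------

def short_long_profile(
    short_corrected: np.ndarray,
    long_corrected: np.ndarray,
    tiling: ReferenceTiling,
    max_missing_frac: float = MAX_MISSING_GROUP_FRAC,
) -> np.ndarray:
    """Per-5-Mb-group ratio of summed corrected short to long counts.

    Groups whose corrected long count sums to zero yield ``NaN``; a sample
    with more than ``max_missing_frac`` missing groups is rejected with
    ``SampleQCError``.
    """
    gids = tiling.bins["group5mb"].to_numpy()
    grouped = gids >= 0
    n_groups = tiling.n_groups
    s = np.bincount(gids[grouped], weights=np.asarray(short_corrected, float)[grouped],
                    minlength=n_groups)
    l = np.bincount(gids[grouped], weights=np.asarray(long_corrected, float)[grouped],
                    minlength=n_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(l > 0, s / np.where(l > 0, l, 1.0), np.nan)
    n_missing = int(np.isnan(ratios).sum())
    if n_missing > max_missing_frac * n_groups:
        raise SampleQCError(
            f"{n_missing}/{n_groups} 5-Mb groups have zero corrected long counts"
        )
    return ratios


def profile_correlation(ratios: np.ndarray, median_profile: np.ndarray) -> float:
    """Pearson correlation of a sample's ratio profile with the panel median.

    Missing ratios are imputed from the panel median.  A zero-variance
    profile has no defined correlation: returns ``NaN`` with a warning.
    """
    ratios = np.asarray(ratios, float).copy()
    median_profile = np.asarray(median_profile, float)
    if ratios.shape != median_profile.shape:
        raise ValueError("profile and panel median have different lengths")
    nan = np.isnan(ratios)
    ratios[nan] = median_profile[nan]
    if np.ptp(ratios) == 0 or np.ptp(median_profile) == 0:
        warnings.warn("zero-variance profile: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(ratios, median_profile)[0, 1])


# ---------------------------------------------------------------------------
# Arm-level aneuploidy
# ---------------------------------------------------------------------------

@dataclass
class ArmStats:
    """Arm z-scores plus the two largest absolute values.

    Ties in |z| are broken by arm label order (chromosome order, p before q).
    """

    arms: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        if len(self.arms) != self.z.size:
            raise ValueError("arm labels and z-scores differ in length")
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite arm z-scores")

    def _top_order(self) -> np.ndarray:
        return np.argsort(-np.abs(self.z), kind="stable")

    @property
    def top1_abs(self) -> float:
        return float(np.abs(self.z[self._top_order()[0]]))

    @property
    def top2_abs(self) -> float:
        if self.z.size < 2:
            raise DelfiTFError("need at least two arms for top-2 |z|")
        return float(np.abs(self.z[self._top_order()[1]]))


def arm_fractions(
    short_corrected: np.ndarray, long_corrected: np.ndarray, tiling: ReferenceTiling
) -> np.ndarray:
    """Fraction of total corrected (short+long) counts falling on each arm."""
    total = np.asarray(short_corrected, float) + np.asarray(long_corrected, float)
    arms = tiling.arms
    arm_of_bin = tiling.bins["arm"].to_numpy()
    sums = np.array([total[arm_of_bin == a].sum() for a in arms])
    denom = sums.sum()
    if denom <= 0:
        raise SampleQCError("sample has zero corrected counts on all arms")
    return sums / denom


def arm_zscores(
    short_corrected: np.ndarray,
    long_corrected: np.ndarray,
    tiling: ReferenceTiling,
    panel: "HealthyPanel",
) -> ArmStats:
    """Standardise per-arm count fractions against the healthy panel."""
    if (panel.arm_sd <= 0).any():
        raise PanelError("panel arm sd must be positive for every arm")
    f = arm_fractions(short_corrected, long_corrected, tiling)
    if list(tiling.arms) != list(panel.arms):
        raise PanelError("panel arms do not match tiling arms")
    z = (f - panel.arm_mean) / panel.arm_sd
    return ArmStats(arms=list(tiling.arms), z=z)


def pa_score(arm_stats: ArmStats, df: int = PA_DF, n_chroms: int = PA_TOP_CHROMS) -> float:
    """Plasma-aneuploidy score.

    For each chromosome take its maximum-|z| arm; rank chromosomes by that
    value and keep the top five; convert each to a two-sided p-value under a
    t distribution with three degrees of freedom (floored at 1e-300); the
    score is the negative sum of the natural logs of those p-values.  Zero
    when every z is zero; strictly monotone in every selected |z|.
    """
    chrom_of = ["chr" + a[:-1] for a in arm_stats.arms]
    best: dict[str, float] = {}
    for c, zv in zip(chrom_of, np.abs(arm_stats.z)):
        if c not in best or zv > best[c]:
            best[c] = float(zv)
    if len(best) < n_chroms:
        raise DelfiTFError(
            f"PA-score needs z-scores on >= {n_chroms} chromosomes, got {len(best)}"
        )
    ranked = sorted(best, key=lambda c: (-best[c], _chrom_rank(c)))[:n_chroms]
    absz = np.array([best[c] for c in ranked])
    p = np.maximum(2.0 * sps.t.sf(absz, df), PA_P_FLOOR)
    return float(-np.log(p).sum()) + 0.0  # normalise -0.0


# ---------------------------------------------------------------------------
# Fragment-length mixture model
# ---------------------------------------------------------------------------

@dataclass
class LengthMixture:
    """A k-component normal mixture over fragment length (bp).

    With k components the free-parameter count is ``2k + (k - 1)`` (means,
    standard deviations, and weights constrained to the simplex): 35 for the
    default 12 components.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        self.weights = np.asarray(self.weights, float)
        k = self.means.size
        if self.sds.size != k or self.weights.size != k:
            raise ValueError("means, sds, weights must have equal length")
        if (self.sds <= 0).any():
            raise ValueError("component sds must be positive")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        if not (np.diff(self.means) > 0).all():
            raise ValueError("component means must be strictly increasing")

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def n_free_parameters(self) -> int:
        return 2 * self.k + (self.k - 1)

    def component_pdf(self, x: np.ndarray) -> np.ndarray:
        """(k, len(x)) matrix of component densities."""
        x = np.asarray(x, float)
        return sps.norm.pdf(x[None, :], self.means[:, None], self.sds[:, None])


SD_FLOOR = 0.5  # bp; collapsed components are floored, not removed


def _as_length_hist(lengths=None, hist=None) -> np.ndarray:
    if (lengths is None) == (hist is None):
        raise ValueError("provide exactly one of lengths or hist")
    if hist is not None:
        hist = np.asarray(hist, float)
        if hist.shape != LENGTH_GRID.shape:
            raise ValueError(f"hist must align to the {LENGTH_GRID.size}-point length grid")
        return hist
    lengths = np.rint(np.asarray(lengths, float)).astype(np.int64)
    keep = (lengths >= LENGTH_RANGE[0]) & (lengths <= LENGTH_RANGE[1])
    return np.bincount(lengths[keep] - LENGTH_RANGE[0], minlength=LENGTH_GRID.size).astype(float)


def _em_run(c, x, means, sds, weights, max_iter, tol):
    """One EM run on a weighted histogram; returns (means, sds, weights, ll, ok)."""
    n = c.sum()
    prev_ll = -np.inf
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        pdf = sps.norm.pdf(x[None, :], means[:, None], sds[:, None])  # (k, m)
        wp = weights[:, None] * pdf
        total = wp.sum(axis=0)
        total = np.where(total > 0, total, np.finfo(float).tiny)
        ll = float((c * np.log(total)).sum())
        resp = wp / total  # (k, m)
        nk = resp @ c  # effective counts per component
        safe = nk > 1e-12
        new_means = np.where(safe, (resp * x[None, :]) @ c / np.where(safe, nk, 1.0), means)
        var = ((resp * (x[None, :] - new_means[:, None]) ** 2) @ c) / np.where(safe, nk, 1.0)
        new_sds = np.where(safe, np.sqrt(np.maximum(var, SD_FLOOR**2)), sds)
        means, sds = new_means, np.maximum(new_sds, SD_FLOOR)
        weights = np.maximum(nk / n, 0.0)
        weights = weights / weights.sum()
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
    return means, sds, weights, ll, converged


def _split_duplicates(c, x, means, sds, weights):
    """Relocate components that collapsed onto one another.

    Duplicated components (means within 0.5 bp) are merged into the first of
    each cluster; the freed components restart at the grid points where the
    data most exceed the current model, with fresh sd and near-zero weight.
    Returns None when there was nothing to do.
    """
    order = np.argsort(means, kind="stable")
    means, sds, weights = means[order].copy(), sds[order].copy(), weights[order].copy()
    dup = np.zeros(means.size, bool)
    for i in range(1, means.size):
        if means[i] - means[i - 1] < 0.5:
            dup[i] = True
            weights[i - 1] += weights[i]
            weights[i] = 0.0
    if not dup.any():
        return None
    model = (weights[:, None] * sps.norm.pdf(x[None, :], means[:, None], sds[:, None])).sum(0)
    deficit = c / c.sum() - model
    # never restart on top of a surviving component
    kept = means[~dup]
    blocked = (np.abs(x[:, None] - kept[None, :]) < 5.0).any(axis=1)
    deficit = np.where(blocked, -np.inf, deficit)
    targets = np.argsort(deficit)[::-1][: int(dup.sum())]
    for slot, j in zip(np.flatnonzero(dup), targets):
        means[slot] = x[j]
        sds[slot] = 15.0
        weights[slot] = 1e-4
    return means, sds, weights / weights.sum()


def fit_base_components(
    lengths=None,
    *,
    hist=None,
    k: int = N_MIXTURE_COMPONENTS,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> LengthMixture:
    """Fit the shared k-component normal mixture to pooled panel lengths by EM.

    Operates on the integer-bp histogram over [50, 400] (lengths are integer
    bp, so the computation is exact and fast).  Two deterministic
    initialisations are tried -- means evenly spaced over the window, and
    means at evenly spaced data quantiles -- each with sds at 15 bp and
    uniform weights; after a run, components that collapsed onto one another
    are merged and the freed components restarted where the data most exceed
    the model.  The best-likelihood fit wins.  Convergence when the relative
    log-likelihood change drops below ``tol`` or after ``max_iter``
    iterations (the best iterate is returned with ``converged=False``).
    Component sds are floored at 0.5 bp.  The procedure is deterministic
    given the data; ``seed`` is accepted for interface uniformity.
    """
    c = _as_length_hist(lengths, hist)
    n = c.sum()
    if n < 10_000:
        raise PanelError(f"mixture fitting needs >= 10,000 lengths, got {int(n)}")
    x = LENGTH_GRID.astype(float)
    lo, hi = LENGTH_RANGE
    even = lo + (np.arange(k) + 0.5) * (hi - lo) / k
    cdf = np.cumsum(c) / n
    quantile = np.interp((np.arange(k) + 0.5) / k, cdf, x)

    best = None
    for init_means in (even, quantile):
        means, sds, weights = init_means.copy(), np.full(k, 15.0), np.full(k, 1.0 / k)
        means, sds, weights, ll, ok = _em_run(c, x, means, sds, weights, max_iter, tol)
        for _ in range(3):  # rescue collapsed components, then refine
            repaired = _split_duplicates(c, x, means, sds, weights)
            if repaired is None:
                break
            means, sds, weights, ll, ok = _em_run(c, x, *repaired, max_iter, tol)
        if best is None or ll > best[3]:
            best = (means, sds, weights, ll, ok)
    means, sds, weights, _, converged = best
    if not converged:
        warnings.warn("length-mixture EM did not converge; returning best iterate",
                      stacklevel=2)
    order = np.argsort(means, kind="stable")
    means, sds, weights = means[order], sds[order], weights[order]
    # enforce strict ordering if residual near-duplicates remain
    for i in range(1, k):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + 1e-6
    return LengthMixture(means, sds, weights, converged=converged)


def sample_length_weights(
    lengths=None,
    base: LengthMixture | None = None,
    *,
    hist=None,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Re-estimate mixture weights for one sample with components frozen.

    With means and sds fixed this EM is a convex maximum-likelihood problem
    in the weights; iterates until the weight vector moves less than
    ``tol`` in max norm.  Weights sum to 1.  Samples with fewer than 500
    retained lengths trigger a warning (the estimate is kept).
    """
    if base is None:
        raise ValueError("base mixture is required")
    c = _as_length_hist(lengths, hist)
    n = c.sum()
    if n == 0:
        raise DelfiTFError("cannot estimate mixture weights from zero lengths")
    if n < 500:
        warnings.warn(f"only {int(n)} lengths; mixture weights are unstable", stacklevel=2)
    pdf = base.component_pdf(LENGTH_GRID)  # (k, m), fixed
    w = np.full(base.k, 1.0 / base.k)
    for _ in range(max_iter):
        wp = w[:, None] * pdf
        total = wp.sum(axis=0)
        total = np.where(total > 0, total, np.finfo(float).tiny)
        w_new = ((wp / total) @ c) / n
        w_new = np.maximum(w_new, 0.0)
        w_new = w_new / w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return w


# ---------------------------------------------------------------------------
# Healthy reference panel
# ---------------------------------------------------------------------------

@dataclass
class HealthyPanel:
    """Reference statistics from non-cancer samples.

    Holds per-arm mean/sd of arm count fractions, the per-group median
    short/long ratio profile, and the shared length-mixture components.
    GC correction is per-sample and needs no panel state.
    """

    arms: list[str]
    arm_mean: np.ndarray
    arm_sd: np.ndarray
    median_profile: np.ndarray
    base: LengthMixture
    n_samples: int
    tiling_hash: str = ""

    def __post_init__(self) -> None:
        self.arm_mean = np.asarray(self.arm_mean, float)
        self.arm_sd = np.asarray(self.arm_sd, float)
        self.median_profile = np.asarray(self.median_profile, float)
        if not (len(self.arms) == self.arm_mean.size == self.arm_sd.size):
            raise PanelError("arm statistics misaligned")
        if (self.arm_sd <= 0).any():
            raise PanelError("panel arm sd must be positive for every arm")

    def to_json(self, path) -> None:
        obj = {
            "arms": self.arms,
            "arm_mean": self.arm_mean.tolist(),
            "arm_sd": self.arm_sd.tolist(),
            "median_profile": self.median_profile.tolist(),
            "base": {
                "means": self.base.means.tolist(),
                "sds": self.base.sds.tolist(),
                "weights": self.base.weights.tolist(),
                "converged": self.base.converged,
            },
            "n_samples": self.n_samples,
            "tiling_hash": self.tiling_hash,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HealthyPanel":
        with open(path) as fh:
            obj = json.load(fh)
        base = LengthMixture(
            np.array(obj["base"]["means"]), np.array(obj["base"]["sds"]),
            np.array(obj["base"]["weights"]), obj["base"].get("converged", True),
        )
        return cls(obj["arms"], np.array(obj["arm_mean"]), np.array(obj["arm_sd"]),
                   np.array(obj["median_profile"]), base, obj["n_samples"],
                   obj.get("tiling_hash", ""))


def build_healthy_panel(
    panel_counts: list[BinnedCounts],
    tiling: ReferenceTiling,
    k: int = N_MIXTURE_COMPONENTS,
    seed: int | None = None,
    min_samples: int = 20,
) -> HealthyPanel:
    """Derive panel statistics from non-cancer samples on one tiling."""
    if len(panel_counts) < min_samples:
        raise PanelError(
            f"healthy panel needs >= {min_samples} samples, got {len(panel_counts)}"
        )
    gc = tiling.gc()
    fracs, profiles = [], []
    pooled_hist = np.zeros(LENGTH_GRID.size, float)
    for counts in panel_counts:
        s = gc_correct(counts.short, gc)
        l = gc_correct(counts.long, gc)
        fracs.append(arm_fractions(s, l, tiling))
        profiles.append(short_long_profile(s, l, tiling))
        pooled_hist += counts.length_hist
    fracs = np.array(fracs)
    profiles = np.array(profiles)
    arm_sd = fracs.std(axis=0, ddof=1)
    if (arm_sd <= 0).any():
        raise PanelError("degenerate panel: an arm fraction has zero variance")
    base = fit_base_components(hist=pooled_hist, k=k, seed=seed)
    return HealthyPanel(
        arms=list(tiling.arms),
        arm_mean=fracs.mean(axis=0),
        arm_sd=arm_sd,
        median_profile=np.nanmedian(profiles, axis=0),
        base=base,
        n_samples=len(panel_counts),
        tiling_hash=tiling.content_hash(),
    )


# ---------------------------------------------------------------------------
# Per-sample featurisation
# ---------------------------------------------------------------------------

def featurize_sample(
    counts: BinnedCounts, tiling: ReferenceTiling, panel: HealthyPanel
) -> tuple[dict, np.ndarray]:
    """Compute one sample's base features and its (imputed) ratio profile.

    Returns ``(features, ratios)`` where features holds ``w1..w11``, ``pa``,
    ``z_top1``, ``z_top2`` and the profile-vs-panel correlation
    ``corr_healthy``; missing ratio groups are imputed from the panel median
    so the profile can enter PCA directly.
    """
    gc = tiling.gc()
    s = gc_correct(counts.short, gc)
    l = gc_correct(counts.long, gc)
    ratios = short_long_profile(s, l, tiling)
    corr = profile_correlation(ratios, panel.median_profile)
    nan = np.isnan(ratios)
    ratios[nan] = panel.median_profile[nan]
    arms = arm_zscores(s, l, tiling, panel)
    w = sample_length_weights(hist=counts.length_hist, base=panel.base)
    feats = {f"w{i + 1}": float(w[i]) for i in range(N_WEIGHT_FEATURES)}
    feats["pa"] = pa_score(arms)
    feats["z_top1"] = arms.top1_abs
    feats["z_top2"] = arms.top2_abs
    feats["corr_healthy"] = corr
    return feats, ratios


def featurize_cohort(
    samples, tiling: ReferenceTiling, panel: HealthyPanel
) -> tuple[pd.DataFrame, np.ndarray]:
    """Featurise an iterable of ``(BinnedCounts, metadata dict)`` pairs.

    Metadata keys (``patient_id``, ``date``, ``maf_label``, ...) are carried
    through to the returned feature table; the profile matrix rows align
    with the table rows.
    """
    rows, profiles = [], []
    for item in samples:
        counts, meta = item if isinstance(item, tuple) else (item, {})
        feats, ratios = featurize_sample(counts, tiling, panel)
        rows.append({"sample_id": counts.sample_id, **meta, **feats})
        profiles.append(ratios)
    return pd.DataFrame(rows), np.array(profiles)
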