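"""Random-forest regression from fragmentation features to tumor fraction.

The model maps a 16-feature vector -- 11 length-mixture weights, the
PA-score, the two largest absolute arm z-scores, and the top two principal
components of the 5-Mb short/long ratio profile -- to a predicted mutant
allele frequency (percent).  Training labels are ddPCR MAFs of a
tumor-specific driver variant; samples with undetectable ddPCR enter with
label 0 by default.

The cross-validated score (the method's output, "DELFI-TF") comes from
leave-one-patient-out cross-validation: every patient's samples are
predicted by a model fitted, including its profile PCA, without any of
that patient's samples.  Panel statistics and the shared length-mixture
components derive from non-cancer samples outside the labeled cohort and
are never refit per fold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ModelError
from .features import BASE_FEATURE_NAMES, HealthyPanel, LengthMixture

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: forest defaults: 1000 trees, a third of features per split, leaves >= 2
DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 1000,
    "max_features": 1.0 / 3.0,
    "min_samples_leaf": 2,
}

FEATURE_NAMES = BASE_FEATURE_NAMES + ["pc1", "pc2"]

FEATURE_GROUPS = {
    "chromosomal": ["pa", "z_top1", "z_top2"],
    "mixture": [f"w{i}" for i in range(1, 12)],
    "sl": ["pc1", "pc2"],
}


# ---------------------------------------------------------------------------
# Profile PCA
# ---------------------------------------------------------------------------

def fit_pca(profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center profiles and return (center, top-2 loadings).

    Column-centered, unscaled; loadings are the top two right singular
    vectors with sign fixed so each loading's largest-magnitude entry is
    positive.  Requires >= 3 samples and rank >= 2.
    """
    P = np.asarray(profiles, float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ModelError("PCA needs a 2-D profile matrix with >= 3 samples")
    center = P.mean(axis=0)
    X = P - center
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s.size < 2 or s[1] <= max(X.shape) * np.finfo(float).eps * s[0]:
        raise ModelError("profile matrix has rank < 2; cannot extract two components")
    loadings = vt[:2].copy()
    for i in range(2):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return center, loadings


def project_profiles(profiles: np.ndarray, center: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Project profiles onto stored principal components -> (n, 2)."""
    return (np.asarray(profiles, float) - center) @ loadings.T


# ---------------------------------------------------------------------------
# Trained model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    forest: RandomForestRegressor
    pca_center: np.ndarray
    pca_loadings: np.ndarray
    base: LengthMixture
    panel: HealthyPanel
    label_range: tuple[float, float]
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    tiling_hash: str = ""
    format_version: int = MODEL_FORMAT_VERSION

    def config_hash(self) -> str:
        payload = json.dumps(
            {"hyper": self.hyperparameters, "seed": self.seed, "tiling": self.tiling_hash},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ModelError(f"{path} is not a saved model archive")
        if obj.format_version != MODEL_FORMAT_VERSION:
            raise ModelError(
                f"model format {obj.format_version} != supported {MODEL_FORMAT_VERSION}"
            )
        return obj


def _feature_matrix(features: pd.DataFrame, pcs: np.ndarray) -> np.ndarray:
    missing = [c for c in BASE_FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ModelError(f"feature table missing columns: {missing}")
    X = np.column_stack([features[BASE_FEATURE_NAMES].to_numpy(float), pcs])
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        sid = features["sample_id"].iloc[int(np.flatnonzero(bad)[0])]
        raise ModelError(f"non-finite feature value in sample {sid!r}")
    return X


def _make_forest(hyperparameters: dict | None, seed: int) -> RandomForestRegressor:
    hyper = {**DEFAULT_HYPERPARAMETERS, **(hyperparameters or {})}
    return RandomForestRegressor(random_state=seed, n_jobs=1, **hyper)


def _check_labels(features: pd.DataFrame) -> np.ndarray:
    y = features["maf_label"].to_numpy(float)
    if not np.isfinite(y).all():
        sid = features["sample_id"].iloc[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise ModelError(f"non-finite label for sample {sid!r}")
    return y


def train(
    features: pd.DataFrame,
    profiles: np.ndarray,
    panel: HealthyPanel,
    seed: int,
    hyperparameters: dict | None = None,
    include_undetectable: bool = True,
) -> TrainedModel:
    """Fit the profile PCA and regression forest on labeled samples.

    ``features`` must contain ``sample_id``, ``patient_id``, ``maf_label``
    (percent) and the 14 base feature columns; ``profiles`` aligns row-wise.
    Undetectable-ddPCR samples (``detectable == False``) train with label 0
    unless ``include_undetectable=False`` drops them.  Deterministic given
    identical inputs and seed.
    """
    features = features.reset_index(drop=True)
    profiles = np.asarray(profiles, float)
    if len(features) != len(profiles):
        raise ModelError("feature table and profile matrix are misaligned")
    if not include_undetectable and "detectable" in features.columns:
        keep = features["detectable"].astype(bool).to_numpy()
        features = features.loc[keep].reset_index(drop=True)
        profiles = profiles[keep]
    if features["patient_id"].nunique() < 2:
        raise ModelError("training needs samples from >= 2 patients")
    # canonical row order: the fit depends only on fold membership, not on
    # the order samples arrive in (bootstrap draws are positional)
    order = np.argsort(features["sample_id"].to_numpy(), kind="stable")
    features = features.iloc[order].reset_index(drop=True)
    profiles = profiles[order]
    y = _check_labels(features)
    center, loadings = fit_pca(profiles)
    X = _feature_matrix(features, project_profiles(profiles, center, loadings))
    forest = _make_forest(hyperparameters, seed).fit(X, y)
    return TrainedModel(
        forest=forest,
        pca_center=center,
        pca_loadings=loadings,
        base=panel.base,
        panel=panel,
        label_range=(float(y.min()), float(y.max())),
        seed=seed,
        hyperparameters={**DEFAULT_HYPERPARAMETERS, **(hyperparameters or {})},
        tiling_hash=panel.tiling_hash,
    )


def score(
    model: TrainedModel,
    features: pd.DataFrame,
    profiles: np.ndarray,
    tiling_hash: str | None = None,
) -> pd.DataFrame:
    """Apply a locked model: deterministic predictions clipped to [0, 100].

    No component is refit; profiles are projected with the stored PCA.  A
    tiling hash, when supplied, must match the one the model was trained
    against.
    """
    if tiling_hash is not None and model.tiling_hash and tiling_hash != model.tiling_hash:
        raise ModelError(
            f"tiling mismatch: model trained on {model.tiling_hash}, input is {tiling_hash}"
        )
    profiles = np.asarray(profiles, float)
    if profiles.shape[1] != model.pca_center.size:
        raise ModelError(
            f"profile length {profiles.shape[1]} != model's {model.pca_center.size}"
        )
    X = _feature_matrix(features.reset_index(drop=True),
                        project_profiles(profiles, model.pca_center, model.pca_loadings))
    pred = np.clip(model.forest.predict(X), 0.0, 100.0)
    out = features[["sample_id"]].copy().reset_index(drop=True)
    if "patient_id" in features.columns:
        out["patient_id"] = features["patient_id"].to_numpy()
    out["delfi_tf"] = pred
    return out


def lopo_cv(
    features: pd.DataFrame,
    profiles: np.ndarray,
    panel: HealthyPanel,
    seed: int,
    hyperparameters: dict | None = None,
    include_undetectable: bool = True,
) -> pd.DataFrame:
    """Leave-one-patient-out cross-validated scores.

    For each patient, the PCA and forest are fitted on every other
    patient's samples and the held-out patient's samples are predicted;
    the out-of-fold prediction is the sample's score.  Returns a table
    ``sample_id patient_id fold delfi_tf`` in input order.
    """
    features = features.reset_index(drop=True)
    profiles = np.asarray(profiles, float)
    if len(features) != len(profiles):
        raise ModelError("feature table and profile matrix are misaligned")
    patients = features["patient_id"].unique().tolist()
    if len(patients) < 3:
        raise ModelError("leave-one-patient-out CV needs >= 3 patients")
    pred = np.full(len(features), np.nan)
    fold = np.empty(len(features), dtype=object)
    for p in patients:
        hold = (features["patient_id"] == p).to_numpy()
        if not hold.any():
            logger.warning("patient %s has no samples; skipped", p)
            continue
        fit_model = train(
            features.loc[~hold], profiles[~hold], panel, seed,
            hyperparameters=hyperparameters, include_undetectable=include_undetectable,
        )
        scored = score(fit_model, features.loc[hold], profiles[hold])
        pred[hold] = scored["delfi_tf"].to_numpy()
        fold[hold] = p
    out = features[["sample_id", "patient_id"]].copy()
    out["fold"] = fold
    out["delfi_tf"] = pred
    return out


def grouped_importance(model: TrainedModel) -> dict[str, float]:
    """Impurity-based feature importances aggregated into the three
    feature groups (chromosomal, mixture, short/long PCs); fractions sum to 1."""
    imp = model.forest.feature_importances_
    by_name = dict(zip(FEATURE_NAMES, imp))
    total = float(imp.sum())
    if total <= 0:
        raise ModelError("forest has zero total importance")
    return {
        g: float(sum(by_name[f] for f in names)) / total
        for g, names in FEATURE_GROUPS.items()
    }
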