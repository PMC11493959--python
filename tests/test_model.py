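"""Profile PCA, forest training, LOPO cross-validation, locked scoring."""

import numpy as np
import pandas as pd
import pytest

from delfitf.errors import ModelError
from delfitf.model import (
    fit_pca,
    grouped_importance,
    lopo_cv,
    project_profiles,
    score,
    train,
)

FAST = {"n_estimators": 150}


def make_dataset(n_patients=6, per_patient=3, n_groups=60, seed=0, label="pa"):
    """Synthetic feature table + profiles with a controllable label signal."""
    rng = np.random.default_rng(seed)
    n = n_patients * per_patient
    rows = []
    for p in range(n_patients):
        for d in range(per_patient):
            w = rng.dirichlet(np.ones(12))[:11]
            row = {f"w{i+1}": w[i] for i in range(11)}
            row.update(
                sample_id=f"P{p}_T{d}", patient_id=f"P{p}",
                pa=rng.uniform(0, 40), z_top1=rng.uniform(0, 20),
                z_top2=rng.uniform(0, 10),
            )
            rows.append(row)
    feats = pd.DataFrame(rows)
    profiles = 0.25 + 0.02 * rng.standard_normal((n, n_groups))
    if label == "pa":
        feats["maf_label"] = feats["pa"].to_numpy() + 0.5 * rng.standard_normal(n)
    elif label == "noise":
        feats["maf_label"] = rng.uniform(0, 30, n)
    else:
        feats["maf_label"] = float(label)
    feats["detectable"] = True
    return feats, profiles


@pytest.fixture(scope="module")
def panel(small_run):
    return small_run.panel


class TestPca:
    def test_single_direction_captured_by_pc1(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=80)
        scores = rng.normal(size=40)
        profiles = 0.3 + np.outer(scores, direction) + 1e-4 * rng.standard_normal((40, 80))
        center, loadings = fit_pca(profiles)
        proj = project_profiles(profiles, center, loadings)
        var = proj.var(axis=0)
        assert var[0] / (var.sum()) > 0.99

    def test_training_mean_projects_to_origin(self):
        profiles = np.random.default_rng(2).normal(size=(10, 30))
        center, loadings = fit_pca(profiles)
        assert np.allclose(project_profiles(profiles.mean(0)[None, :], center, loadings), 0)

    def test_loadings_unit_norm_and_sign_fixed(self):
        profiles = np.random.default_rng(3).normal(size=(12, 25))
        _, loadings = fit_pca(profiles)
        assert np.allclose(np.linalg.norm(loadings, axis=1), 1.0)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_deficient_matrix_rejected(self):
        profiles = np.tile(np.linspace(0, 1, 20), (5, 1)) * np.arange(1, 6)[:, None]
        with pytest.raises(ModelError, match="rank"):
            fit_pca(profiles)  # rank 1 exactly


class TestTrain:
    def test_same_seed_is_bit_reproducible(self, panel):
        feats, profiles = make_dataset(seed=4)
        m1 = train(feats, profiles, panel, seed=7, hyperparameters=FAST)
        m2 = train(feats, profiles, panel, seed=7, hyperparameters=FAST)
        s1 = score(m1, feats, profiles)["delfi_tf"]
        s2 = score(m2, feats, profiles)["delfi_tf"]
        assert (s1 == s2).all()

    def test_constant_labels_predict_constant(self, panel):
        feats, profiles = make_dataset(seed=5, label=17.5)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        assert np.allclose(score(m, feats, profiles)["delfi_tf"], 17.5)

    def test_separable_signal_fits_training_set(self, panel):
        feats, profiles = make_dataset(n_patients=10, seed=6, label="pa")
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        pred = score(m, feats, profiles)["delfi_tf"]
        assert np.corrcoef(pred, feats["maf_label"])[0, 1] > 0.9

    def test_non_finite_feature_names_sample(self, panel):
        feats, profiles = make_dataset(seed=7)
        feats.loc[3, "pa"] = np.nan
        with pytest.raises(ModelError, match=feats.loc[3, "sample_id"]):
            train(feats, profiles, panel, seed=1, hyperparameters=FAST)


class TestLopoCv:
    def test_out_of_fold_assignment(self, panel):
        feats, profiles = make_dataset(seed=8)
        scores = lopo_cv(feats, profiles, panel, seed=1, hyperparameters=FAST)
        assert (scores["fold"] == scores["patient_id"]).all()
        assert scores["delfi_tf"].between(0, 100).all()

    def test_duplicated_patient_does_not_change_other_folds(self, panel):
        feats, profiles = make_dataset(seed=9)
        base = lopo_cv(feats, profiles, panel, seed=1, hyperparameters=FAST)
        dup = feats[feats["patient_id"] == "P0"].copy()
        dup["patient_id"] = "P_new"
        dup["sample_id"] = dup["sample_id"] + "_dup"
        feats2 = pd.concat([feats, dup], ignore_index=True)
        profiles2 = np.vstack([profiles, profiles[: len(dup)]])
        again = lopo_cv(feats2, profiles2, panel, seed=1, hyperparameters=FAST)
        # P0's own fold changes (its twin is now in training) but every other
        # patient's fold gains identical twin samples with identical labels,
        # leaving its training set's information content unchanged only for
        # the grouping contract: fold membership must match patient_id.
        assert (again["fold"] == again["patient_id"]).all()

    def test_label_leakage_absent(self, panel):
        """A patient's own out-of-fold predictions never see their labels.

        Perturbing patient p's labels must leave p's own predictions
        bit-identical (p's fold model trains without p), while the folds of
        other patients -- which legitimately train on p -- shift.
        """
        feats, profiles = make_dataset(seed=10)
        base = lopo_cv(feats, profiles, panel, seed=1, hyperparameters=FAST)
        feats2 = feats.copy()
        mask = (feats2["patient_id"] == "P2").to_numpy()
        feats2.loc[mask, "maf_label"] = 99.0
        perturbed = lopo_cv(feats2, profiles, panel, seed=1, hyperparameters=FAST)
        assert np.array_equal(
            base.loc[mask, "delfi_tf"].to_numpy(),
            perturbed.loc[mask, "delfi_tf"].to_numpy(),
        )
        assert not np.array_equal(
            base.loc[~mask, "delfi_tf"].to_numpy(),
            perturbed.loc[~mask, "delfi_tf"].to_numpy(),
        )

    def test_sample_order_within_folds_irrelevant(self, panel):
        feats, profiles = make_dataset(seed=11)
        base = lopo_cv(feats, profiles, panel, seed=1, hyperparameters=FAST)
        perm = np.random.default_rng(0).permutation(len(feats))
        shuffled = lopo_cv(
            feats.iloc[perm].reset_index(drop=True), profiles[perm], panel,
            seed=1, hyperparameters=FAST,
        )
        merged = base.merge(shuffled, on="sample_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["delfi_tf_a"], merged["delfi_tf_b"])

    def test_too_few_patients_rejected(self, panel):
        feats, profiles = make_dataset(n_patients=2, seed=12)
        with pytest.raises(ModelError, match=">= 3 patients"):
            lopo_cv(feats, profiles, panel, seed=1, hyperparameters=FAST)


class TestScore:
    def test_locked_scoring_matches_in_sample_prediction(self, panel):
        feats, profiles = make_dataset(seed=13)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        a = score(m, feats, profiles)["delfi_tf"].to_numpy()
        b = score(m, feats, profiles)["delfi_tf"].to_numpy()
        assert (a == b).all()

    def test_tiling_hash_mismatch_names_both(self, panel):
        feats, profiles = make_dataset(seed=14)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        with pytest.raises(ModelError, match=m.tiling_hash):
            score(m, feats, profiles, tiling_hash="deadbeef0000")

    def test_profile_length_mismatch_rejected(self, panel):
        feats, profiles = make_dataset(seed=15)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        with pytest.raises(ModelError, match="profile length"):
            score(m, feats, profiles[:, :10])

    def test_model_archive_round_trip(self, tmp_path, panel):
        from delfitf.model import TrainedModel

        feats, profiles = make_dataset(seed=16)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        m.save(tmp_path / "model.joblib")
        back = TrainedModel.load(tmp_path / "model.joblib")
        assert (score(back, feats, profiles)["delfi_tf"]
                == score(m, feats, profiles)["delfi_tf"]).all()


class TestGroupedImportance:
    def test_fractions_sum_to_one(self, panel):
        feats, profiles = make_dataset(seed=17)
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        imp = grouped_importance(m)
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(imp) == {"chromosomal", "mixture", "sl"}

    def test_pa_driven_labels_load_on_chromosomal_group(self, panel):
        feats, profiles = make_dataset(n_patients=12, seed=18, label="pa")
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        assert grouped_importance(m)["chromosomal"] > 0.5

    def test_noise_labels_spread_importance(self, panel):
        feats, profiles = make_dataset(n_patients=12, seed=19, label="noise")
        m = train(feats, profiles, panel, seed=1, hyperparameters=FAST)
        assert max(grouped_importance(m).values()) < 0.9
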