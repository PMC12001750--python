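"""Fragmentation classifier: filtering, factorization, selection, scoring."""

import numpy as np
import pandas as pd
import pytest

from fragsignal import simulate
from fragsignal.io import AmpliconPanel, CountMatrix
from fragsignal.signal import (
    SignalModel,
    choose_dimension,
    exposures,
    extract_signatures,
    filter_amplicons,
    fit_signal_pipeline,
    normalize_by_arm,
    score_signal,
    select_fragmentation_features,
    signature_length_centroids,
)


def make_panel(arms, n_per_arm, rng, insert_range=(80, 160)):
    rows = []
    for arm in arms:
        for j in range(n_per_arm):
            rows.append(
                {
                    "amplicon_id": f"{arm}_a{j}",
                    "chrom": arm[:-1],
                    "arm": arm,
                    "start": 1000 * (j + 1),
                    "expected_insert_length": int(rng.integers(*insert_range)),
                }
            )
    return AmpliconPanel(pd.DataFrame(rows))


class TestFilterAmplicons:
    def make_counts(self, rng, n_per_batch=10, n_amp=200):
        base = rng.lognormal(3, 0.3, n_amp)
        counts = rng.poisson(base, size=(2 * n_per_batch, n_amp))
        idx = [f"s{i}" for i in range(2 * n_per_batch)]
        batch = pd.Series(["b1"] * n_per_batch + ["b2"] * n_per_batch, index=idx)
        return pd.DataFrame(counts, index=idx, columns=[f"a{j}" for j in range(n_amp)]), batch

    def test_constructed_batch_effect_detected(self, rng):
        counts, batch = self.make_counts(rng)
        counts.loc[batch == "b2", "a0"] *= 3
        report = filter_amplicons(CountMatrix(counts, batch))
        assert "a0" in report.dropped
        assert "batch_effect" in report.stats.set_index("amplicon_id").loc["a0", "reason"]

    def test_null_drop_fraction_bounded_by_fdr(self, rng):
        counts, batch = self.make_counts(rng, n_per_batch=15, n_amp=1000)
        report = filter_amplicons(CountMatrix(counts, batch), q_max=0.05)
        batch_drops = (report.stats["q_value"] < 0.05).sum()
        # BH under the global null rejects rarely; allow binomial slack
        assert batch_drops / 1000 <= 0.05 + 0.02

    def test_all_zero_amplicon_dropped_by_floor(self, rng):
        counts, batch = self.make_counts(rng)
        counts["a0"] = 0
        report = filter_amplicons(CountMatrix(counts, batch))
        assert "a0" in report.dropped
        assert "low_count" in report.stats.set_index("amplicon_id").loc["a0", "reason"]

    def test_single_batch_instructs_skip(self, rng):
        counts, batch = self.make_counts(rng)
        batch[:] = "b1"
        with pytest.raises(ValueError, match="skip filtering"):
            filter_amplicons(CountMatrix(counts, batch))

    def test_kept_and_dropped_partition_input(self, rng):
        counts, batch = self.make_counts(rng)
        report = filter_amplicons(CountMatrix(counts, batch))
        assert set(report.kept) | set(report.dropped) == set(counts.columns)
        assert not set(report.kept) & set(report.dropped)


class TestNormalizeByArm:
    def test_single_arm_fractions(self, rng):
        panel = make_panel(["1p"], 3, rng)
        counts = pd.DataFrame([[2, 3, 5]], index=["s"], columns=panel.amplicon_ids)
        out = normalize_by_arm(counts, panel)
        assert np.allclose(out["1p"].to_numpy(), [[0.2, 0.3, 0.5]])

    def test_arms_normalized_independently(self, rng):
        panel = make_panel(["1p", "1q"], 2, rng)
        counts = pd.DataFrame([[1, 1, 3, 1]], index=["s"], columns=panel.amplicon_ids)
        out = normalize_by_arm(counts, panel)
        assert np.allclose(out["1p"].to_numpy(), [[0.5, 0.5]])
        assert np.allclose(out["1q"].to_numpy(), [[0.75, 0.25]])

    def test_depth_scale_invariance(self, rng):
        panel = make_panel(["1p", "1q"], 5, rng)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(3, 10)), index=list("abc"), columns=panel.amplicon_ids
        )
        out1 = normalize_by_arm(counts, panel)
        out2 = normalize_by_arm(counts * 10, panel)
        for arm in out1:
            pd.testing.assert_frame_equal(out1[arm], out2[arm])

    def test_zero_arm_total_names_sample_and_arm(self, rng):
        panel = make_panel(["1p", "1q"], 2, rng)
        counts = pd.DataFrame([[1, 1, 0, 0]], index=["bad"], columns=panel.amplicon_ids)
        with pytest.raises(ValueError, match="bad.*1q"):
            normalize_by_arm(counts, panel)


class TestExtractSignatures:
    def test_rank_one_matrix_recovered_exactly(self, rng):
        e = rng.uniform(0.5, 2.0, 12)
        w = rng.dirichlet(np.ones(8))
        v = pd.DataFrame(
            np.outer(e, w), index=[f"s{i}" for i in range(12)], columns=[f"a{j}" for j in range(8)]
        )
        model = extract_signatures({"1p": v}, k=1, seed=0)
        expo = exposures(model, {"1p": v})
        recon = expo.to_numpy() @ model.w["1p"].to_numpy().T
        assert np.abs(recon - v.to_numpy()).max() < 1e-6

    def test_disjoint_support_mixture_recovered(self, rng):
        w1 = np.concatenate([rng.dirichlet(np.ones(4)), np.zeros(4)])
        w2 = np.concatenate([np.zeros(4), rng.dirichlet(np.ones(4))])
        # separable mixture: include pure samples of each profile so the
        # factorization is identifiable
        coef = np.vstack([rng.uniform(0.0, 1.0, size=(26, 2)), [[1, 0]], [[0, 1]], [[2, 0]], [[0, 2]]])
        v = pd.DataFrame(coef @ np.vstack([w1, w2]), columns=[f"a{j}" for j in range(8)])
        model = extract_signatures({"1p": v}, k=2, seed=0)
        w = model.w["1p"].to_numpy()
        support = w > 1e-6
        # after column matching, supports are the two disjoint halves
        first_half = support[:4].any(axis=0)
        cols = {tuple(support[:, j]) for j in range(2)}
        assert len(cols) == 2
        assert (w[:4, :].sum(axis=0) > 0.99).sum() == 1
        assert (w[4:, :].sum(axis=0) > 0.99).sum() == 1

    def test_columns_are_distributions(self, small_cohort):
        mats = normalize_by_arm(small_cohort.counts, small_cohort.panel)
        model = extract_signatures(mats, k=2, seed=0)
        for arm, w in model.w.items():
            arr = w.to_numpy()
            assert (arr >= 0).all()
            assert np.allclose(arr.sum(axis=0), 1.0, atol=1e-9)

    def test_k_too_large_rejected(self, rng):
        v = pd.DataFrame(rng.uniform(size=(3, 5)))
        with pytest.raises(ValueError, match="exceeds"):
            extract_signatures({"1p": v}, k=4, seed=0)


class TestExposures:
    def test_exact_signature_gives_indicator(self, rng):
        panel = make_panel(["1p"], 6, rng)
        mats = {
            "1p": pd.DataFrame(
                rng.dirichlet(np.ones(6), size=20), columns=panel.amplicon_ids
            )
        }
        model = extract_signatures(mats, k=2, seed=0)
        w = model.w["1p"]
        sample = pd.DataFrame([w["s1"].to_numpy()], index=["x"], columns=w.index)
        expo = exposures(model, {"1p": sample})
        assert expo.loc["x", "1p:s1"] == pytest.approx(1.0, abs=1e-8)
        assert expo.loc["x", "1p:s0"] == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_sample_rejected(self, rng):
        panel = make_panel(["1p"], 4, rng)
        mats = {"1p": pd.DataFrame(rng.dirichlet(np.ones(4), size=10), columns=panel.amplicon_ids)}
        model = extract_signatures(mats, k=1, seed=0)
        zero = pd.DataFrame([[0.0] * 4], index=["z"], columns=panel.amplicon_ids)
        with pytest.raises(ValueError, match="all-zero"):
            exposures(model, {"1p": zero})

    def test_panel_mismatch_rejected(self, rng):
        panel = make_panel(["1p"], 4, rng)
        mats = {"1p": pd.DataFrame(rng.dirichlet(np.ones(4), size=10), columns=panel.amplicon_ids)}
        model = extract_signatures(mats, k=1, seed=0)
        other = pd.DataFrame([[0.5, 0.5]], index=["x"], columns=["b1", "b2"])
        with pytest.raises(ValueError, match="panel mismatch|missing"):
            exposures(model, {"1p": other})


class TestFeatureSelection:
    def test_fragmentation_tilt_selects_short_signature(self, small_cohort):
        res = small_cohort
        mats = normalize_by_arm(res.counts, res.panel)
        model = extract_signatures(mats, k=2, seed=0)
        expo = exposures(model, mats)
        sel = select_fragmentation_features(model, res.panel, expo, res.labels)
        assert len(sel) > 0
        centroids = signature_length_centroids(model, res.panel)
        lengths = res.panel.insert_lengths()
        median_len = lengths.median()
        # at least one selected signature is short-centroid and cancer-up
        short_up = False
        for i in sel:
            name = expo.columns[i]
            if centroids[name] < median_len:
                up = expo[name][res.labels].mean() > expo[name][~res.labels].mean()
                short_up = short_up or up
        assert short_up

    def test_label_permutation_selects_little(self, small_cohort):
        res = small_cohort
        mats = normalize_by_arm(res.counts, res.panel)
        model = extract_signatures(mats, k=2, seed=0)
        expo = exposures(model, mats)
        rng = np.random.default_rng(5)
        perm = rng.permutation(res.labels)
        sel = select_fragmentation_features(model, res.panel, expo, perm)
        assert len(sel) <= max(2, int(0.2 * expo.shape[1]))

    def test_no_class_difference_returns_empty(self, rng):
        panel = make_panel(["1p"], 4, rng)
        mats = {"1p": pd.DataFrame(rng.dirichlet(np.ones(4), size=40), columns=panel.amplicon_ids)}
        model = extract_signatures(mats, k=1, seed=0)
        expo = exposures(model, mats)
        labels = np.array([True, False] * 20)
        sel = select_fragmentation_features(model, panel, expo, labels)
        assert sel == []


class TestPipeline:
    def test_scores_bounded_and_separating(self, small_cohort):
        res = small_cohort
        model = fit_signal_pipeline(res.counts, res.panel, res.labels, k=2, seed=0)
        scores = score_signal(model, res.counts, res.panel)
        assert scores.between(0, 1).all()
        assert scores[res.labels].mean() > scores[~res.labels].mean()

    def test_deterministic_given_seed(self, small_cohort):
        res = small_cohort
        m1 = fit_signal_pipeline(res.counts, res.panel, res.labels, k=2, seed=3)
        m2 = fit_signal_pipeline(res.counts, res.panel, res.labels, k=2, seed=3)
        s1 = score_signal(m1, res.counts, res.panel)
        s2 = score_signal(m2, res.counts, res.panel)
        assert np.abs(s1.to_numpy() - s2.to_numpy()).max() < 1e-12
        assert m1.threshold == m2.threshold

    def test_json_roundtrip_preserves_scores(self, small_cohort):
        res = small_cohort
        model = fit_signal_pipeline(res.counts, res.panel, res.labels, k=2, seed=0)
        restored = SignalModel.from_jsonable(model.to_jsonable())
        s1 = score_signal(model, res.counts, res.panel)
        s2 = score_signal(restored, res.counts, res.panel)
        assert np.abs(s1.to_numpy() - s2.to_numpy()).max() < 1e-12

    def test_single_class_rejected(self, small_cohort):
        res = small_cohort
        with pytest.raises(ValueError):
            fit_signal_pipeline(
                res.counts, res.panel, np.zeros(len(res.counts.sample_ids), bool), k=2, seed=0
            )


class TestChooseDimension:
    def test_grid_of_one_returns_it(self, small_cohort):
        res = small_cohort
        assert choose_dimension(res.counts, res.panel, res.labels, [2]) == 2

    def test_low_rank_signal_plateaus_early(self, rng):
        # two tumor components with different short-insert tilts: the
        # class signal spans ~2 signature directions per arm
        cfg = simulate.SimConfig(
            n_arms=3, amplicons_per_arm=40, n_controls=60, n_cancers=60, depth_mean=100.0
        )
        res = simulate.gen_cohort(cfg, seed=9)
        panel, counts = res.panel, res.counts.counts.copy()
        inserts = panel.table["expected_insert_length"].to_numpy(float)
        arm_of = panel.table["arm"].to_numpy()
        gen = np.random.default_rng(9)
        labels = res.labels.copy()
        for i, (sid, is_cancer) in enumerate(zip(res.counts.sample_ids, labels)):
            if is_cancer:
                beta = 0.15 if i % 2 else 0.05
                tilt = np.exp(-beta * (inserts - inserts.min()))
                mean = counts.loc[sid].to_numpy() * (0.7 + 0.3 * tilt / tilt.mean())
                counts.loc[sid] = gen.poisson(np.maximum(mean, 0.1))
        cm = CountMatrix(counts, res.counts.batch)
        k = choose_dimension(
            cm, panel, labels, [1, 2, 3, 4], folds=3, specificity=0.9, eps=0.05, seed=0
        )
        assert 1 <= k <= 3

    def test_permuted_labels_return_smallest_k(self, small_cohort):
        res = small_cohort
        rng = np.random.default_rng(11)
        perm = rng.permutation(res.labels)
        k = choose_dimension(
            res.counts, res.panel, perm, [1, 2, 3], folds=3, specificity=0.9, eps=0.1, seed=0
        )
        assert k == 1
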