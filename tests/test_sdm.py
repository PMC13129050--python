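"""Occurrence preparation, model evaluation, and the ensemble machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist
from scipy.stats import chisquare

from frugicast import sdm
from frugicast.grids import GridSpec


class TestThinning:
    def test_far_apart_points_untouched(self):
        pts = np.array([[0, 0], [5, 0], [0, 5]], dtype=float)
        out = sdm.thin_occurrences(pts, min_distance=1.0, seed=0)
        assert len(out) == 3

    def test_coincident_pair_keeps_one(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = sdm.thin_occurrences(pts, min_distance=0.5, seed=0)
        assert len(out) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_maximal_valid_subset(self, seed):
        """The greedy result is a valid set whose size equals the best
        subset found by exhaustive search."""
        rng = np.random.default_rng(seed)
        pts = rng.random((8, 2)) * 3
        d = 1.0
        out = sdm.thin_occurrences(pts, d, seed=seed)
        dist = cdist(out, out)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= d
        best = 0
        for r in range(len(pts), 0, -1):
            for idx in itertools.combinations(range(len(pts)), r):
                sub = pts[list(idx)]
                dd = cdist(sub, sub)
                np.fill_diagonal(dd, np.inf)
                if dd.min() >= d:
                    best = r
                    break
            if best:
                break
        assert len(out) == best


class TestVifPrune:
    def _stack(self, layers):
        n = next(iter(layers.values())).shape
        return sdm.PredictorStack(GridSpec(*n), layers)

    def test_identical_layers_keep_one(self, rng):
        a = rng.random((6, 6))
        kept = sdm.vif_prune(self._stack({"a": a, "b": a.copy()}))
        assert len(kept) == 1

    def test_orthogonal_layers_all_kept(self):
        n = 16
        t = np.arange(n * n).reshape(n, n) * (2 * np.pi / (n * n))
        layers = {"s": np.sin(t), "c": np.cos(t)}
        kept = sdm.vif_prune(self._stack(layers))
        assert sorted(kept) == ["c", "s"]

    def test_noisy_sum_dropped_by_manual_iteration(self, rng):
        """Layer c = a + b + small noise: the procedure drops exactly the
        layer a hand run of pairwise-r + VIF comparison drops."""
        a = rng.random((10, 10))
        b = rng.random((10, 10))
        c = a + b + rng.normal(0, 0.05, (10, 10))
        stack = self._stack({"a": a, "b": b, "c": c})
        kept = sdm.vif_prune(stack, r_threshold=0.6)
        # manual oracle: find the most-correlated pair, drop higher VIF, repeat
        X = stack.design_matrix()
        names = ["a", "b", "c"]

        def vif(j, idx):
            others = [k for k in idx if k != j]
            A = np.column_stack([X[:, others], np.ones(len(X))])
            coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            r = X[:, j] - A @ coef
            r2 = 1 - r.var() / X[:, j].var()
            return 1 / (1 - r2)

        idx = [0, 1, 2]
        while len(idx) > 1:
            corr = np.corrcoef(X[:, idx], rowvar=False)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            if abs(corr[i, j]) <= 0.6:
                break
            pair = (idx[i], idx[j])
            idx.remove(max(pair, key=lambda k: vif(k, idx)))
        assert sorted(kept) == sorted(names[k] for k in idx)

    def test_retained_pairs_below_threshold(self, rng):
        layers = {f"l{i}": rng.random((8, 8)) for i in range(4)}
        layers["dup"] = layers["l0"] * 2 + 0.01 * rng.random((8, 8))
        kept = sdm.vif_prune(self._stack(layers), r_threshold=0.6)
        X = np.column_stack(
            [layers[k].ravel() for k in kept]
        )
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        assert np.abs(corr).max() <= 0.6

    def test_constant_layer_dropped_with_warning(self, rng):
        layers = {"flat": np.ones((5, 5)), "a": rng.random((5, 5)), "b": rng.random((5, 5))}
        with pytest.warns(UserWarning, match="constant"):
            kept = sdm.vif_prune(self._stack(layers))
        assert "flat" not in kept


class TestBackgroundAndPseudoAbsences:
    def test_single_point_square(self):
        ext = sdm.make_background(np.array([[3.0, 4.0]]), pad=10.0)
        assert ext == (-7.0, -6.0, 13.0, 14.0)

    def test_zero_pad_is_bounding_box(self):
        pts = np.array([[0.0, 1.0], [2.0, 5.0]])
        assert sdm.make_background(pts, pad=0.0) == (0.0, 1.0, 2.0, 5.0)

    def test_two_point_corners(self):
        pts = np.array([[1.0, 2.0], [4.0, 3.0]])
        assert sdm.make_background(pts, pad=2.0) == (-1.0, 0.0, 6.0, 5.0)

    def test_zero_presences_gives_empty_sample(self):
        grid = GridSpec(10, 10)
        out = sdm.sample_pseudo_absences((0, 0, 10, 10), 0, grid)
        assert out.shape == (0, 2)

    def test_determinism_under_seed(self):
        grid = GridSpec(10, 10)
        a = sdm.sample_pseudo_absences((0, 0, 10, 10), 20, grid, seed=7)
        b = sdm.sample_pseudo_absences((0, 0, 10, 10), 20, grid, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_presence_cells_excluded(self):
        grid = GridSpec(3, 3)
        cells = np.array([[r, c] for r in range(3) for c in range(3) if (r, c) != (1, 1)])
        pts = sdm.sample_pseudo_absences((0, 0, 3, 3), 50, grid, cells, seed=0)
        assert np.all(pts == np.array([1.5, 1.5]))

    def test_frequencies_uniform_over_eligible_cells(self):
        grid = GridSpec(4, 4)
        pts = sdm.sample_pseudo_absences((0, 0, 4, 4), 10_000, grid, seed=11)
        row, col = grid.cell_of(pts[:, 0], pts[:, 1])
        counts = np.bincount(row * 4 + col, minlength=16)
        assert chisquare(counts).pvalue > 0.01


class TestEvaluation:
    def test_tss_perfect(self):
        assert sdm.tss(5, 0, 5, 0) == pytest.approx(1.0)

    def test_tss_random(self):
        assert sdm.tss(5, 5, 5, 5) == pytest.approx(0.0)

    def test_tss_worked(self):
        assert sdm.tss(8, 4, 6, 2) == pytest.approx(0.4)

    def test_tss_empty_class_rejected(self):
        with pytest.raises(ValueError):
            sdm.tss(0, 0, 5, 0)

    def test_auc_separated(self):
        assert sdm.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_auc_identical_scores(self):
        assert sdm.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = rng.random(n).round(1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert sdm.auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_threshold_separated_takes_smallest_qualifying(self):
        thr = sdm.select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == 0.8

    @given(st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_threshold_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = rng.random(n).round(2)
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        thr = sdm.select_threshold(scores, labels)
        cands = np.unique(np.concatenate([scores, [0.0, 1.0]]))
        best = max(cands, key=lambda c: (round(sdm._tss_at(scores, labels, c), 12), -c))
        assert sdm._tss_at(scores, labels, thr) == pytest.approx(
            sdm._tss_at(scores, labels, best)
        )
        assert thr <= best + 1e-12

    def test_threshold_invariant_to_duplication(self):
        scores = np.array([0.2, 0.4, 0.6, 0.7])
        labels = np.array([0, 0, 1, 1])
        a = sdm.select_threshold(scores, labels)
        b = sdm.select_threshold(np.tile(scores, 2), np.tile(labels, 2))
        assert a == b


class TestLearnerAndEnsemble:
    def _toy(self, rng, n=300, signal=True):
        grid = GridSpec(20, 20)
        layer = np.linspace(0, 1, 400).reshape(20, 20)
        stack = sdm.PredictorStack(grid, {"env": layer, "noise": rng.random((20, 20))})
        pts = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 20, n)])
        env = stack.values_at(pts)[:, 0]
        if signal:
            labels = (rng.random(n) < env).astype(int)
        else:
            labels = rng.integers(0, 2, n)
        return sdm.OccurrenceSet(pts, labels), stack

    def test_no_signal_gives_near_half_scores(self, rng):
        data, stack = self._toy(rng, signal=False)
        model = sdm.fit_learner(data, stack)
        scores = model.predict_suitability(stack.values_at(data.points))
        assert abs(scores.mean() - 0.5) < 0.1

    def test_monotone_signal_gives_monotone_scores(self, rng):
        data, stack = self._toy(rng)
        model = sdm.fit_learner(data, stack)
        X = np.column_stack([np.linspace(0.1, 0.9, 9), np.full(9, 0.5)])
        s = model.predict_suitability(X)
        assert np.all(np.diff(s) > 0)

    def test_training_auc_beats_chance_on_separable_data(self, rng):
        data, stack = self._toy(rng)
        model = sdm.fit_learner(data, stack)
        scores = model.predict_suitability(stack.values_at(data.points))
        assert sdm.auc(scores, data.labels) >= 0.5

    def test_degenerate_predictors_rejected(self):
        learner = sdm.BaselineLogisticLearner()
        with pytest.raises(ValueError):
            learner.fit(np.ones((10, 2)), np.array([0, 1] * 5))

    def test_replicates_count_and_holdout_contract(self, rng):
        data, stack = self._toy(rng)
        members = sdm.run_replicates(
            data, stack, n_replicates=15, algorithms=["logistic"] * 3, seed=3
        )
        assert len(members) == 45  # 3 algorithms x 15 replicates
        assert all(-1 <= m.evaluation.tss <= 1 for m in members)

    def test_single_replicate_reproducible(self, rng):
        data, stack = self._toy(rng)
        a = sdm.run_replicates(data, stack, n_replicates=1, seed=5)[0]
        b = sdm.run_replicates(data, stack, n_replicates=1, seed=5)[0]
        np.testing.assert_array_equal(a.prediction, b.prediction)
        assert a.evaluation == b.evaluation

    def test_ensemble_single_member_identity(self, rng):
        data, stack = self._toy(rng)
        members = sdm.run_replicates(data, stack, n_replicates=1, seed=5)
        ens = sdm.ensemble(members, stack.grid)
        np.testing.assert_allclose(ens.suitability, members[0].prediction)

    def test_ensemble_hand_weights(self):
        grid = GridSpec(2, 2)
        m1 = sdm.MemberModel(np.full((2, 2), 0.2), sdm.ModelEvaluation(0.2, 0.6, 0.5), "a", 0)
        m2 = sdm.MemberModel(np.full((2, 2), 0.6), sdm.ModelEvaluation(0.6, 0.8, 0.5), "a", 1)
        ens = sdm.ensemble([m1, m2], grid)
        np.testing.assert_allclose(ens.member_weights, [0.25, 0.75])
        np.testing.assert_allclose(ens.suitability, 0.25 * 0.2 + 0.75 * 0.6)

    def test_ensemble_within_member_bounds(self, rng):
        data, stack = self._toy(rng)
        members = sdm.run_replicates(data, stack, n_replicates=4, seed=5)
        ens = sdm.ensemble(members, stack.grid)
        stackp = np.stack([m.prediction for m in members])
        assert np.all(ens.suitability >= stackp.min(axis=0) - 1e-12)
        assert np.all(ens.suitability <= stackp.max(axis=0) + 1e-12)

    def test_negative_tss_members_zero_weighted(self):
        grid = GridSpec(2, 2)
        good = sdm.MemberModel(np.full((2, 2), 0.9), sdm.ModelEvaluation(0.5, 0.9, 0.5), "a", 0)
        bad = sdm.MemberModel(np.full((2, 2), 0.1), sdm.ModelEvaluation(-0.2, 0.4, 0.5), "a", 1)
        ens = sdm.ensemble([good, bad], grid)
        np.testing.assert_allclose(ens.member_weights, [1.0, 0.0])
        with pytest.raises(ValueError):
            sdm.ensemble([bad], grid)

    def test_binarize_worked_grid(self):
        grid = GridSpec(3, 3)
        surf = np.array([[0.1, 0.5, 0.9], [0.4, 0.6, 0.2], [0.7, 0.3, 0.55]])
        m = sdm.binarize(surf, 0.5, "sp", "current", grid)
        np.testing.assert_array_equal(
            m.presence, [[0, 1, 1], [0, 1, 0], [1, 0, 1]]
        )

    def test_binarize_extremes(self):
        grid = GridSpec(2, 2)
        surf = np.array([[0.2, 0.4], [0.6, 0.8]])
        assert sdm.binarize(surf, 0.0, "s", "current", grid).n_cells == 4
        assert sdm.binarize(surf, 0.9, "s", "current", grid).n_cells == 0


class TestParameterRecovery:
    def test_gaussian_niche_species_recovered(self):
        """Fitting the ensemble on points sampled from a Gaussian-niche
        virtual species recovers the true range (Jaccard > 0.6 against the
        truth binarized at the ensemble's own threshold)."""
        from frugicast.simulate import (
            DEFAULT_GRADIENTS, make_landscape, sample_occurrences, true_suitability,
        )
        from frugicast.simulate import VirtualSpecies

        rng = np.random.default_rng(2)
        land = make_landscape(60, 60, DEFAULT_GRADIENTS, seed=rng)
        sp = VirtualSpecies(
            "v", "frugivore", niche={"temperature": (17.0, 3.0), "precipitation": (1000.0, 300.0)}
        )
        suit = true_suitability(sp, land)
        pts = sample_occurrences(suit, 250, land.grid, seed=rng)
        stack = sdm.PredictorStack(land.grid, land.layers)
        ext = sdm.make_background(pts, pad=10, clip_to=land.grid.extent)
        row, col = land.grid.cell_of(pts[:, 0], pts[:, 1])
        pa = sdm.sample_pseudo_absences(ext, len(pts), land.grid, np.column_stack([row, col]), seed=rng)
        data = sdm.OccurrenceSet(
            np.vstack([pts, pa]),
            np.concatenate([np.ones(len(pts), int), np.zeros(len(pa), int)]),
        )
        members = sdm.run_replicates(data, stack, n_replicates=5, seed=9)
        ens = sdm.ensemble(members, land.grid)
        r, c = land.grid.cell_of(data.points[:, 0], data.points[:, 1])
        thr = sdm.select_threshold(ens.suitability[r, c], data.labels)
        est = ens.suitability >= thr
        truth = suit >= thr
        jaccard = (est & truth).sum() / (est | truth).sum()
        assert jaccard > 0.6
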