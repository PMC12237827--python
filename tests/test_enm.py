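"""Ensemble model building blocks: metrics, pseudo-absences, members,
weighting, prediction and binarisation."""

import numpy as np
import pandas as pd
import pytest

from nicheshift.enm import (
    EnsembleSDM,
    EnvelopeModel,
    UndefinedMetricError,
    auc,
    binarize,
    fit_member,
    gate_and_weight,
    generate_pseudo_absences,
    kfold_split,
    mss_threshold,
)
from nicheshift.grids import Grid, SuitabilityMap
from nicheshift.occurrences import OccurrenceSet
from nicheshift.pipeline import simulate_species
from nicheshift.synthetic import suitability_map


# --- independent oracles ------------------------------------------------------


def auc_brute_force(scores, labels):
    """All presence-absence pairs; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > a) + 0.5 * (p == a) for p in pos for a in neg)
    return wins / (len(pos) * len(neg))


def mss_brute_force(scores, labels):
    """Exhaustive scan of all midpoint/extreme thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    d = np.unique(scores)
    cands = np.concatenate([[d[0] - 1e-9], (d[:-1] + d[1:]) / 2, [d[-1] + 1e-9]])
    best = (-np.inf, None)
    for t in cands:
        pred = scores >= t
        ss = pred[labels].mean() + (~pred)[~labels].mean()
        if ss > best[0] + 1e-12:
            best = (ss, t)
    return best[1], best[0] - 1.0


class TestAuc:
    def test_matches_brute_force_oracle(self, rng):
        for n in (6, 20, 80, 200):
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                labels[:2] = [True, False]
            assert np.isclose(auc(scores, labels), auc_brute_force(scores, labels))

    def test_known_values(self):
        assert auc([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.9], [1, 1])


class TestMssThreshold:
    def test_matches_exhaustive_oracle(self, rng):
        for n in (8, 40, 150):
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                labels[:2] = [True, False]
            t, ev = mss_threshold(scores, labels)
            t_o, tss_o = mss_brute_force(scores, labels)
            assert np.isclose(t, t_o)
            assert np.isclose(ev.tss, tss_o)

    def test_midpoint_rule_example(self):
        t, ev = mss_threshold([0.9, 0.6, 0.55, 0.1], [1, 1, 0, 0])
        assert np.isclose(t, 0.575)
        assert ev.tss == 1.0 and ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_separable_gives_tss_one(self, rng):
        scores = np.sort(rng.uniform(size=30))
        labels = np.arange(30) >= 15
        _, ev = mss_threshold(scores, labels)
        assert np.isclose(ev.tss, 1.0)

    def test_tss_never_negative_at_mss(self, rng):
        # extreme thresholds give sens+spec = 1, so the maximum is >= 0
        scores = rng.uniform(size=50)
        labels = scores < rng.uniform(size=50)  # anti-correlated
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        _, ev = mss_threshold(scores, labels)
        assert ev.tss >= 0

    def test_eval_identity(self, rng):
        scores = rng.uniform(size=60)
        labels = rng.uniform(size=60) < 0.5
        labels[:2] = [True, False]
        _, ev = mss_threshold(scores, labels)
        assert np.isclose(ev.tss, ev.sensitivity + ev.specificity - 1.0)


def _occ_at_cells(stack, cells, status="native"):
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    lon, lat = stack.grid.cell_center(rows, cols)
    return OccurrenceSet(pd.DataFrame({
        "species": "ant", "longitude": lon, "latitude": lat,
        "status": status, "uncertainty_km": np.nan,
    }))


class TestPseudoAbsences:
    def test_counts_follow_presence_rule(self, landscape2):
        many = _occ_at_cells(
            landscape2, [(i // 40, i % 40) for i in range(1500)]
        )
        few = _occ_at_cells(landscape2, [(i, i) for i in range(20)])
        pas = generate_pseudo_absences(many, landscape2, n_reps=2, seed=0)
        assert all(len(p) == 1500 for p in pas)
        pas = generate_pseudo_absences(few, landscape2, n_reps=2, seed=0)
        assert all(len(p) == 1000 for p in pas)

    def test_presence_cells_excluded(self, landscape2):
        cells = [(i, j) for i in range(5) for j in range(5)]
        occ = _occ_at_cells(landscape2, cells)
        presence_env = {tuple(np.round(landscape2.values[:, r, c], 9)) for r, c in cells}
        pas = generate_pseudo_absences(occ, landscape2, n_reps=3, seed=1)
        for pa in pas:
            for row in pa:
                assert tuple(np.round(row, 9)) not in presence_env

    def test_deterministic_per_replicate(self, landscape2):
        occ = _occ_at_cells(landscape2, [(i, i) for i in range(30)])
        a = generate_pseudo_absences(occ, landscape2, n_reps=2, seed=5)
        b = generate_pseudo_absences(occ, landscape2, n_reps=2, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert not np.array_equal(a[0], a[1])


class TestKfold:
    def test_sizes_and_partition(self):
        labels = np.array([1] * 5 + [0] * 5)
        folds = kfold_split(labels, k=5, seed=0)
        assert sorted(np.bincount(folds)) == [2] * 5
        assert set(folds) == set(range(5))

    def test_stratification(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = kfold_split(labels, k=5, seed=1)
        for f in range(5):
            sel = folds == f
            assert labels[sel].sum() == 10 and (~labels[sel].astype(bool)).sum() == 10

    def test_small_class_falls_back(self):
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        folds = kfold_split(labels, k=5, seed=0)
        assert len(folds) == 10 and set(folds) <= set(range(5))


class TestMembers:
    def test_logistic_separates_toy_data(self):
        x = np.vstack([np.full((20, 2), 2.0), np.full((20, 2), -2.0)])
        x += np.random.default_rng(0).normal(0, 0.1, x.shape)
        y = np.array([1] * 20 + [0] * 20)
        m = fit_member(x, y, "glm", seed=0)
        assert auc(m.predict_score(x), y) == 1.0

    def test_envelope_scores_median_one(self, rng):
        pres = rng.standard_normal((200, 3))
        m = EnvelopeModel().fit(pres, np.ones(200))
        assert m.predict_score(np.median(pres, axis=0)[None, :])[0] == 1.0
        # declines outside the envelope
        far = np.full((1, 3), 10.0)
        assert m.predict_score(far)[0] < 0.1

    def test_member_determinism(self, rng):
        x = rng.standard_normal((100, 2))
        y = (x[:, 0] > 0).astype(int)
        a = fit_member(x, y, "random_forest", seed=4)
        b = fit_member(x, y, "random_forest", seed=4)
        assert np.array_equal(a.predict_score(x), b.predict_score(x))

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            fit_member(np.zeros((4, 2)), [0, 1, 0, 1], "maxent")


class TestGateAndWeight:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["algorithm", "replicate", "auc", "tss"])

    def test_tss_proportional_weights(self):
        t = gate_and_weight(self._table([("a", 0, 0.9, 0.8), ("b", 0, 0.9, 0.6)]))
        assert np.allclose(sorted(t["weight"]), [3 / 7, 4 / 7])

    def test_high_auc_low_tss_excluded(self):
        t = gate_and_weight(self._table([("a", 0, 0.95, 0.5), ("b", 0, 0.85, 0.7)]))
        assert t.loc[t.algorithm == "a", "weight"].iloc[0] == 0.0
        assert not t.loc[t.algorithm == "a", "retained"].iloc[0]

    def test_single_retained_gets_weight_one(self):
        t = gate_and_weight(self._table([("a", 0, 0.9, 0.7), ("b", 0, 0.5, 0.1)]))
        assert t["weight"].max() == 1.0

    def test_all_excluded_raises(self):
        from nicheshift.enm import NoValidModelError

        with pytest.raises(NoValidModelError):
            gate_and_weight(self._table([("a", 0, 0.5, 0.1)]))


class TestPredictAndBinarize:
    def test_two_member_average_and_bounds(self, landscape2, rng):
        occ, *_ = _make_species(landscape2, rng)
        res = EnsembleSDM(
            occ, landscape2, algorithms=("glm", "glm_quadratic"), n_pa_reps=1
        ).fit(seed=2)
        smap = res.predict()
        rows, cols = landscape2.valid_cells()
        member_scores = np.column_stack([
            res.fitted[key].predict_score(landscape2.env_table())
            for key in res.fitted
        ])
        ens = smap.values[rows, cols]
        assert (ens <= member_scores.max(axis=1) + 1e-9).all()
        assert (ens >= member_scores.min(axis=1) - 1e-9).all()

    def test_binarize_thresholds(self, landscape2):
        vals = np.clip(landscape2.values[0] * 0.1 + 0.5, 0, 1)
        smap = SuitabilityMap(landscape2.grid, vals, landscape2.nodata_mask)
        assert binarize(smap, 0.0).values.all()
        top = binarize(smap, 1.0)
        assert top.n_cells == (vals >= 1.0).sum()

    def test_equator_cell_area(self):
        # one 10 x 10 km cell centred on the equator
        cell = 10.0 / 111.19492664455873
        grid = Grid(1, 1, cell, origin_lon=0.0, origin_lat=-cell / 2)
        smap = SuitabilityMap(grid, np.ones((1, 1)), np.zeros((1, 1), bool))
        mask = binarize(smap, 0.5)
        assert abs(mask.area_km2 - 100.0) / 100.0 < 0.01


def _make_species(stack, rng, n=400):
    return simulate_species(stack, "v", n, n, 0.0, 1.0, seed=17)


class TestRangeRecovery:
    def test_native_range_recovers_truth_region(self, landscape2):
        # well-specified member (quadratic logistic = the Gaussian-niche
        # family): the MSS range must contain the half-peak truth core and
        # stay within a modest area inflation (the MSS contour sits near the
        # presence/background density crossing, below the half-peak level)
        occ, niche_native, _ = simulate_species(
            landscape2, "v", 1000, 1000, 0.0, 1.0, seed=21
        )
        from nicheshift.occurrences import spatial_rarefy, split_by_status

        native, _ = split_by_status(spatial_rarefy(occ, 5.0, seed=21))
        res = EnsembleSDM(
            native, landscape2, algorithms=("glm_quadratic",), n_pa_reps=5
        ).fit(seed=3)
        truth = suitability_map(niche_native, landscape2) >= 0.5
        pred = res.range_mask().values
        recall = (truth & pred).sum() / truth.sum()
        assert recall >= 0.9
        assert pred.sum() <= 4 * truth.sum()
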