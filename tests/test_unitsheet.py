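"""Unit-sheet selectivity, top-k profiles, overlap scores, permutation tests."""

import numpy as np
import pytest
from scipy import stats as sps

from otctopo import (
    UnitSheet,
    UnitSheetConfig,
    build_section_grid,
    generate_unit_sheet,
    overlap_contrast,
    permutation_test,
    section_overlap_score,
    top_k_profile,
    unit_selectivity,
)
from otctopo.synthgen import CATEGORIES, N_STIMULI_PER_CATEGORY
from otctopo.unitsheet import SectionGrid, UninformativeMapError


def _labels():
    return tuple(c for c in CATEGORIES for _ in range(N_STIMULI_PER_CATEGORY))


def _sheet(responses, positions=None, extent=(50.0, 50.0)):
    n = responses.shape[0]
    if positions is None:
        positions = np.random.default_rng(0).uniform(0, extent[0], size=(n, 2))
    return UnitSheet(
        positions=positions,
        responses=responses,
        stimulus_categories=_labels(),
        extent_mm=extent,
    )


class TestUnitSelectivity:
    def test_zero_variance_unit_flagged_undefined(self):
        resp = np.zeros((3, 72))
        resp[0, :12] = 1.0  # responds 1.0 to all faces, 0.0 elsewhere, no noise
        resp[1] = np.random.default_rng(1).normal(size=72)
        resp[2] = np.random.default_rng(2).normal(size=72)
        selmap = unit_selectivity(_sheet(resp))
        # the faces contrast has zero variance on both sides -> undefined;
        # the unit is selective for nothing
        assert selmap.undefined[0, 0]
        assert not selmap.selective[0].any()

    def test_tiny_noise_makes_clean_unit_selective_for_its_category_only(self):
        rng = np.random.default_rng(3)
        resp = rng.normal(0, 0.01, size=(5, 72))
        resp[0, :12] += 1.0
        selmap = unit_selectivity(_sheet(resp))
        assert selmap.selective[0, 0]
        assert not selmap.selective[0, 1:].any()
        assert selmap.df == 70

    def test_null_selectivity_rate_matches_t70_tail(self):
        rng = np.random.default_rng(4)
        resp = rng.normal(size=(30_000, 72))
        selmap = unit_selectivity(_sheet(resp, positions=rng.uniform(0, 50, (30_000, 2))))
        rate = selmap.selective.mean()
        assert rate == pytest.approx(sps.t.sf(3.5, 70), rel=0.4)

    def test_invariant_to_per_unit_constant_shift(self):
        rng = np.random.default_rng(5)
        resp = rng.normal(size=(50, 72))
        pos = rng.uniform(0, 50, (50, 2))
        a = unit_selectivity(_sheet(resp, pos))
        b = unit_selectivity(_sheet(resp + rng.normal(size=(50, 1)), pos))
        np.testing.assert_allclose(a.t, b.t, atol=1e-9)


class TestTopKProfile:
    def test_k_equals_one_returns_dominant_unit_means(self):
        rng = np.random.default_rng(6)
        resp = rng.normal(0, 0.01, size=(4, 72))
        resp[2, 36:48] += 5.0  # huge tools unit
        sheet = _sheet(resp)
        selmap = unit_selectivity(sheet)
        prof = top_k_profile(selmap, sheet, "tools", k=1)
        ind = sheet.category_indicator()
        expected = (resp[2] @ ind) / ind.sum(axis=0)
        np.testing.assert_allclose(prof.to_numpy(), expected)

    def test_k_all_units_equals_grand_category_means(self):
        rng = np.random.default_rng(7)
        resp = rng.normal(size=(20, 72))
        sheet = _sheet(resp)
        selmap = unit_selectivity(sheet)
        prof = top_k_profile(selmap, sheet, "hands", k=20)
        ind = sheet.category_indicator()
        expected = (resp.mean(axis=0) @ ind) / ind.sum(axis=0)
        np.testing.assert_allclose(prof.to_numpy(), expected)

    def test_planted_clusters_win_their_own_category(self):
        cfg = UnitSheetConfig(
            n_units=1500,
            mode="clustered",
            cluster_assignments={
                c: ((10.0 + 6 * i, 10.0 + 5 * i), 6.0) for i, c in enumerate(CATEGORIES)
            },
        )
        sheet = generate_unit_sheet(cfg, seed=1)
        selmap = unit_selectivity(sheet)
        for cat in CATEGORIES:
            prof = top_k_profile(selmap, sheet, cat, k=20)
            assert prof.idxmax() == cat

    def test_insufficient_rankable_units_rejected(self):
        resp = np.zeros((3, 72))  # all undefined
        sheet = _sheet(resp)
        selmap = unit_selectivity(sheet)
        with pytest.raises(ValueError, match="rankable"):
            top_k_profile(selmap, sheet, "tools", k=2)


class TestSectionOverlap:
    def _grid_from_fractions(self, fa, fb):
        n = len(fa)
        fr = np.zeros((n, 6))
        fr[:, 3] = fa
        fr[:, 4] = fb
        return SectionGrid(
            categories=CATEGORIES,
            fractions=fr,
            counts=np.ones(n, int),
            section_mm=1.0,
            section_ids=np.zeros((n, 2), int),
        )

    def test_identical_maps_score_one(self):
        f = np.array([0.1, 0.5, 0.9, 0.3])
        grid = self._grid_from_fractions(f, f)
        assert section_overlap_score(grid, "tools", "manipulable") == pytest.approx(1.0)

    def test_complementary_maps_score_zero(self):
        f = np.array([0.1, 0.5, 0.9, 0.3])
        grid = self._grid_from_fractions(f, 1.0 - f)
        assert section_overlap_score(grid, "tools", "manipulable") == pytest.approx(0.0)

    def test_zero_variance_raises_uninformative(self):
        grid = self._grid_from_fractions(np.full(4, 0.5), np.array([0.1, 0.2, 0.3, 0.4]))
        with pytest.raises(UninformativeMapError, match="uninformative"):
            section_overlap_score(grid, "tools", "manipulable")

    def test_symmetry_and_section_order_invariance(self):
        rng = np.random.default_rng(8)
        fa, fb = rng.random(30), rng.random(30)
        g1 = self._grid_from_fractions(fa, fb)
        perm = rng.permutation(30)
        g2 = self._grid_from_fractions(fa[perm], fb[perm])
        s1 = section_overlap_score(g1, "tools", "manipulable")
        assert s1 == pytest.approx(section_overlap_score(g1, "manipulable", "tools"))
        assert s1 == pytest.approx(section_overlap_score(g2, "tools", "manipulable"))

    def test_every_unit_in_exactly_one_section(self):
        cfg = UnitSheetConfig(n_units=800)
        sheet = generate_unit_sheet(cfg, seed=2)
        grid = build_section_grid(sheet, unit_selectivity(sheet))
        assert grid.counts.sum() == sheet.n_units
        assert ((grid.fractions >= 0) & (grid.fractions <= 1)).all()

    def test_coincident_planted_clusters_score_near_one(self):
        """Two categories tuned on the same disc have identical selectivity maps."""
        scores = []
        for seed in range(10):
            cfg = UnitSheetConfig(
                n_units=2000,
                mode="clustered",
                response_sd=0.3,
                cluster_assignments={
                    "hands": ((25.0, 25.0), 10.0),
                    "tools": ((25.0, 25.0), 10.0),
                },
                tuning_prob=0.0,
            )
            sheet = generate_unit_sheet(cfg, seed=seed)
            grid = build_section_grid(sheet, unit_selectivity(sheet))
            scores.append(section_overlap_score(grid, "hands", "tools"))
        assert np.mean(scores) > 0.95

    def test_identical_selectivity_maps_score_exactly_one(self):
        cfg = UnitSheetConfig(
            n_units=1000,
            mode="clustered",
            response_sd=0.0,  # noiseless: selectivity maps coincide exactly
            cluster_assignments={
                "hands": ((25.0, 25.0), 12.0),
                "tools": ((25.0, 25.0), 12.0),
            },
            tuning_prob=0.0,
        )
        sheet = generate_unit_sheet(cfg, seed=0)
        selmap = unit_selectivity(sheet)
        # noiseless tuned units are undefined only if variance collapses;
        # tuned units here have exact two-level responses -> defined t
        grid = build_section_grid(sheet, selmap)
        assert section_overlap_score(grid, "hands", "tools") == pytest.approx(1.0)


class TestPermutationTest:
    @staticmethod
    def _mean_diff(labels):
        labels = np.asarray(labels)
        x = np.arange(72, dtype=float)
        return x[labels == "tools"].mean() - x[labels != "tools"].mean()

    def test_observed_below_every_permutation_gives_one(self):
        def stat(labels):
            labels = np.asarray(labels)
            return -np.inf if (labels == _labels()).all() else 1.0

        res = permutation_test(lambda l: 0.0, _labels(), n_perm=50, seed=0)
        # constant statistic: every permutation ties the observed -> p = 1
        assert res.p == 1.0

    def test_minimum_resolvable_p_is_inverse_n_perm(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=72)
        x[36:48] += 50.0  # overwhelming tools effect

        def stat(labels):
            labels = np.asarray(labels)
            return x[labels == "tools"].mean()

        res = permutation_test(stat, _labels(), n_perm=10_000, seed=1)
        assert res.p == pytest.approx(1.0 / 10_000)

    def test_null_rejection_rate_calibrated(self):
        """Type-I error at alpha=0.05 over 2,000 null replicates."""
        rng = np.random.default_rng(10)
        labels = _labels()
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=72)

            def stat(lab, x=x):
                lab = np.asarray(lab)
                return x[lab == "tools"].mean()

            res = permutation_test(stat, labels, n_perm=199, seed=rng)
            rejections += res.p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_undefined_statistic_fraction_aborts(self):
        calls = {"n": 0}

        def stat(labels):
            calls["n"] += 1
            return 1.0 if calls["n"] == 1 else np.nan

        with pytest.raises(ValueError, match="undefined"):
            permutation_test(stat, _labels(), n_perm=20, seed=0)


class TestOverlapContrast:
    def test_identical_pairs_give_p_one(self):
        sheets = [generate_unit_sheet(UnitSheetConfig(n_units=600), seed=s) for s in (1, 2)]
        res = overlap_contrast(
            sheets, ("hands", "tools"), ("hands", "tools"), n_perm=200, seed=0
        )
        assert res.observed == 0.0
        assert res.p == 1.0

    @staticmethod
    def _spatially_coclustered_sheet(seed):
        """Distinct hand- and tool-selective unit populations sharing one
        territory (spatial co-occurrence without unit-level co-tuning);
        manipulable units live elsewhere."""
        rng = np.random.default_rng(seed)
        n = 1800
        pos = rng.uniform(0, 50, size=(n, 2))
        resp = rng.normal(0, 1.0, size=(n, 72))
        near_a = np.linalg.norm(pos - [15, 15], axis=1) <= 11
        near_b = np.linalg.norm(pos - [38, 38], axis=1) <= 11
        ids_a = np.flatnonzero(near_a)
        rng.shuffle(ids_a)
        half = len(ids_a) // 2
        resp[np.ix_(ids_a[:half], np.arange(24, 36))] += 3.0  # hands units
        resp[np.ix_(ids_a[half:], np.arange(36, 48))] += 3.0  # tools units
        resp[np.ix_(np.flatnonzero(near_b), np.arange(48, 60))] += 3.0  # manipulable
        return _sheet(resp, positions=pos)

    def test_planted_coclustering_reaches_min_p(self):
        """pair_1 spatially co-clustered, pair_2 not: p hits the permutation floor."""
        sheets = [self._spatially_coclustered_sheet(s) for s in range(3)]
        res = overlap_contrast(
            sheets, ("hands", "tools"), ("hands", "manipulable"), n_perm=2000, seed=0
        )
        assert res.observed > 0.0
        assert res.p == pytest.approx(1.0 / 2000)

    def test_null_sheets_calibrated(self):
        """Type-I of the score contrast stays near alpha on null sheets."""
        rng = np.random.default_rng(11)
        rejections, reps = 0, 120
        for rep in range(reps):
            sheets = [
                generate_unit_sheet(UnitSheetConfig(n_units=900), seed=1000 * rep + s)
                for s in range(2)
            ]
            res = overlap_contrast(
                sheets, ("hands", "tools"), ("hands", "manipulable"), n_perm=99, seed=rng
            )
            rejections += res.p <= 0.05
        assert rejections / reps <= 0.10

    def test_needs_two_instances(self):
        sheet = generate_unit_sheet(UnitSheetConfig(n_units=500), seed=0)
        with pytest.raises(ValueError, match="2 instances"):
            overlap_contrast([sheet], ("hands", "tools"), ("hands", "manipulable"))

    def test_label_scheme_aborts_on_strongly_tuned_sheets(self):
        sheets = [generate_unit_sheet(UnitSheetConfig(n_units=800), seed=s) for s in (5, 6)]
        with pytest.raises((ValueError, UninformativeMapError)):
            overlap_contrast(
                sheets,
                ("hands", "tools"),
                ("hands", "manipulable"),
                n_perm=50,
                seed=0,
                scheme="labels",
            )


def test_end_to_end_animacy_but_no_action_organization():
    """Planted animate/inanimate territories, no hand-tool co-clustering:
    within-domain scores beat between-domain scores and the hand-tool
    contrast stays null — the network-layer result pattern."""
    ext = 50.0
    assignments = {
        "faces": ((14.0, 12.0), 8.0),
        "bodies": ((10.0, 21.0), 8.0),
        "hands": ((19.0, 20.0), 8.0),
        "tools": ((34.0, 33.0), 9.0),
        "manipulable": ((38.0, 28.0), 9.0),
        "nonmanipulable": ((32.0, 38.0), 9.0),
    }
    cfg = UnitSheetConfig(
        sheet_extent_mm=(ext, ext),
        n_units=2000,
        mode="clustered",
        cluster_assignments=assignments,
        tuning_prob=0.05,
    )
    sheets = [generate_unit_sheet(cfg, seed=s) for s in range(3)]
    within, between = [], []
    animate = {"faces", "bodies", "hands"}
    for sheet in sheets:
        grid = build_section_grid(sheet, unit_selectivity(sheet))
        for i, a in enumerate(CATEGORIES):
            for b in CATEGORIES[i + 1 :]:
                s = section_overlap_score(grid, a, b)
                same = (a in animate) == (b in animate)
                (within if same else between).append(s)
    assert np.mean(within) > np.mean(between)
    res = overlap_contrast(
        sheets, ("hands", "tools"), ("hands", "manipulable"), n_perm=500, seed=3
    )
    assert res.p > 0.05
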