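"""RDM construction, aspect ratio, model fits, noise ceiling, and MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otctopo import (
    RDM,
    aspect_ratio,
    generate_ratings,
    generate_stimulus_masks,
    mds_embed,
    model_fit_profile,
    model_profile_correlation,
    model_rdm_correlations,
    model_rdm_from_ratings,
    model_rdm_from_shape,
    neural_rdm,
    noise_ceiling_lower,
    rsa_correlate,
)
from otctopo.rsa import ZeroVariancePatternError
from otctopo.synthgen import CATEGORIES, ShapeSpec


def _random_dissimilarity(rng, labels=CATEGORIES) -> RDM:
    n = len(labels)
    d = rng.uniform(0.1, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return RDM(labels=labels, values=d, kind="dissimilarity")


class TestNeuralRdm:
    def test_identical_patterns_correlate_perfectly(self, rng):
        p = rng.normal(size=12)
        r = neural_rdm(np.tile(p, (6, 1)))
        assert np.allclose(r.values, 1.0)

    def test_reversed_pattern_gives_minus_one(self):
        r = neural_rdm(np.array([[1.0, 2, 3], [3, 2, 1]]), labels=("a", "b"))
        assert r.values[0, 1] == pytest.approx(-1.0)

    def test_orthogonal_random_patterns_near_zero(self, rng):
        pats = rng.normal(size=(6, 10_000))
        r = neural_rdm(pats)
        off = r.lower_triangle()
        assert np.abs(off.mean()) < 0.02

    def test_zero_variance_pattern_named_in_error(self):
        pats = np.random.default_rng(0).normal(size=(6, 10))
        pats[3] = 5.0
        with pytest.raises(ZeroVariancePatternError, match="tools"):
            neural_rdm(pats, labels=CATEGORIES)

    def test_rdm_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            RDM(labels=("a", "b"), values=np.array([[0, 1.0], [2.0, 0]]), kind="dissimilarity")
        with pytest.raises(ValueError, match="diagonal"):
            RDM(labels=("a", "b"), values=np.array([[1.0, 0.5], [0.5, 1.0]]), kind="dissimilarity")


class TestAspectRatio:
    """Closed-form shapes: circle 1.0, square 4/pi, 4:1 rectangle 6.25/pi."""

    @pytest.mark.parametrize(
        "spec, expected, rel",
        [
            (ShapeSpec("ellipse", (100, 100), name="m"), 1.0, 0.02),
            (ShapeSpec("rectangle", (200, 200), name="m"), 4 / np.pi, 0.02),
            (ShapeSpec("rectangle", (200, 50), name="m"), 6.25 / np.pi, 0.03),
        ],
    )
    def test_closed_forms(self, spec, expected, rel):
        mask = generate_stimulus_masks([spec], canvas_px=400)["m"]
        assert aspect_ratio(mask) == pytest.approx(expected, rel=rel)

    def test_rotation_invariance(self):
        masks = generate_stimulus_masks(
            [ShapeSpec("rectangle", (200, 50), orientation_deg=35, name="m")]
        )
        assert aspect_ratio(masks["m"]) == pytest.approx(6.25 / np.pi, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aspect_ratio(np.zeros((50, 50), bool))

    def test_multiple_components_error_or_sum(self):
        m = np.zeros((60, 60), bool)
        m[5:15, 5:15] = True
        m[40:50, 40:50] = True
        with pytest.raises(ValueError, match="components"):
            aspect_ratio(m)
        v = aspect_ratio(m, multiple="sum")  # P and A totalled first
        single = np.zeros((60, 60), bool)
        single[5:15, 5:15] = True
        assert v == pytest.approx(2 * aspect_ratio(single), rel=0.05)


class TestModelRdms:
    def test_hands_tools_entry_is_mean_difference(self):
        ratings = generate_ratings(sd=0.0, seed=0)
        rdm = model_rdm_from_ratings(ratings, level="category")
        i, j = CATEGORIES.index("hands"), CATEGORIES.index("tools")
        assert rdm.values[i, j] == pytest.approx(0.6)

    def test_action_rank_order_from_default_means(self):
        """Dissimilarity to hands: tools (0.6) < bodies (1.8) < manipulable (3.0)."""
        rdm = model_rdm_from_ratings(generate_ratings(sd=0.0, seed=0))
        h = CATEGORIES.index("hands")
        d = {c: rdm.values[h, CATEGORIES.index(c)] for c in ("tools", "bodies", "manipulable")}
        assert d["tools"] == pytest.approx(0.6)
        assert d["bodies"] == pytest.approx(1.8)
        assert d["manipulable"] == pytest.approx(3.0)
        assert d["tools"] < d["bodies"] < d["manipulable"]

    def test_equal_ratings_give_zero_matrix(self):
        ratings = generate_ratings(means={c: 4.0 for c in CATEGORIES}, sd=0.0)
        rdm = model_rdm_from_ratings(ratings)
        assert np.allclose(rdm.values, 0.0)

    def test_stimulus_level_collapses_to_category_level_when_noiseless(self):
        ratings = generate_ratings(sd=0.0, seed=0)
        stim = model_rdm_from_ratings(ratings, level="stimulus")
        cat = model_rdm_from_ratings(ratings, level="category")
        # mean over cross-category stimulus pairs == category entry
        ids = list(stim.labels)
        for a in ("hands", "tools"):
            for b in ("faces", "manipulable"):
                ia = [k for k, s in enumerate(ids) if s.startswith(a)]
                ib = [k for k, s in enumerate(ids) if s.startswith(b)]
                block = stim.values[np.ix_(ia, ib)].mean()
                assert block == pytest.approx(
                    cat.values[cat.labels.index(a), cat.labels.index(b)]
                )

    def test_shape_rdm_circle_vs_elongated_rectangle(self):
        specs = [
            ShapeSpec("ellipse", (100, 100), name="faces_00"),
            ShapeSpec("rectangle", (200, 50), name="tools_00"),
        ]
        masks = generate_stimulus_masks(specs)
        rdm, table = model_rdm_from_shape(
            masks, {"faces_00": "faces", "tools_00": "tools"}, categories=("faces", "tools")
        )
        assert rdm.values[0, 1] == pytest.approx(6.25 / np.pi - 1.0, rel=0.06)
        assert set(table["category"]) == {"faces", "tools"}

    def test_same_shapes_everywhere_give_zero_matrix(self):
        specs = [
            ShapeSpec("ellipse", (50, 50), name=f"{c}_00") for c in ("faces", "tools")
        ]
        masks = generate_stimulus_masks(specs)
        rdm, _ = model_rdm_from_shape(
            masks, {f"{c}_00": c for c in ("faces", "tools")}, categories=("faces", "tools")
        )
        assert np.allclose(rdm.values, 0.0)

    def test_single_category_gives_1x1_zero(self):
        masks = generate_stimulus_masks([ShapeSpec("ellipse", (40, 40), name="tools_00")])
        rdm, _ = model_rdm_from_shape(masks, {"tools_00": "tools"}, categories=("tools",))
        assert rdm.values.shape == (1, 1)
        assert rdm.values[0, 0] == 0.0


class TestRsaCorrelate:
    def test_model_equal_to_neural_dissimilarity_gives_one(self, rng):
        model = _random_dissimilarity(rng)
        neural = RDM(labels=CATEGORIES, values=1 - model.values + np.diag(np.ones(6) * 0), kind="similarity")
        # neural similarity = 1 - model distance, so 1 - r recovers the model
        vals = 1 - model.values
        np.fill_diagonal(vals, 1.0)
        neural = RDM(labels=CATEGORIES, values=vals, kind="similarity")
        assert rsa_correlate(neural, model) == pytest.approx(1.0)

    def test_negated_model_gives_minus_one(self, rng):
        model = _random_dissimilarity(rng)
        neg = model.values.max() - model.values
        np.fill_diagonal(neg, 0.0)
        neg_rdm = RDM(labels=CATEGORIES, values=neg, kind="dissimilarity")
        vals = 1 - model.values
        np.fill_diagonal(vals, 1.0)
        neural = RDM(labels=CATEGORIES, values=vals, kind="similarity")
        assert rsa_correlate(neural, neg_rdm) == pytest.approx(-1.0)

    def test_planted_model_recovered_under_noise(self, rng):
        """Neural = model + weak noise recovers r > 0.9 on average."""
        model = _random_dissimilarity(rng)
        sd = model.lower_triangle().std()
        fits = []
        for _ in range(200):
            noise = rng.normal(0, 0.1 * sd, size=(6, 6))
            noise = (noise + noise.T) / 2
            v = model.values + noise
            np.fill_diagonal(v, 0.0)
            neural = RDM(labels=CATEGORIES, values=np.abs(v), kind="dissimilarity")
            fits.append(rsa_correlate(neural, model))
        assert np.mean(fits) > 0.9

    def test_zero_variance_model_rejected(self, rng):
        model = RDM(labels=CATEGORIES, values=np.ones((6, 6)) - np.eye(6), kind="dissimilarity")
        neural = _random_dissimilarity(rng)
        with pytest.raises(ValueError, match="zero variance"):
            rsa_correlate(neural, model)

    def test_invariant_to_common_relabeling(self, rng):
        neural = _random_dissimilarity(rng)
        model = _random_dissimilarity(rng)
        r1 = rsa_correlate(neural, model)
        perm = rng.permutation(6)
        relab = tuple(CATEGORIES[k] for k in perm)
        n2 = RDM(labels=relab, values=neural.values[np.ix_(perm, perm)], kind="dissimilarity")
        m2 = RDM(labels=relab, values=model.values[np.ix_(perm, perm)], kind="dissimilarity")
        assert rsa_correlate(n2, m2) == pytest.approx(r1)


class TestNoiseCeiling:
    def test_identical_subjects_hit_one(self, rng):
        r = _random_dissimilarity(rng)
        assert noise_ceiling_lower([r] * 5) == pytest.approx(1.0)

    def test_independent_subjects_center_on_zero(self, rng):
        means = []
        for _ in range(200):
            rdms = [_random_dissimilarity(rng) for _ in range(18)]
            means.append(noise_ceiling_lower(rdms))
        assert abs(np.mean(means)) < 0.05

    def test_ceiling_rises_monotonically_as_noise_vanishes(self, rng):
        shared = _random_dissimilarity(rng)
        ceilings = []
        for noise_sd in (1.0, 0.3, 0.05):
            vals = []
            for _ in range(50):
                rdms = []
                for _ in range(10):
                    e = rng.normal(0, noise_sd, (6, 6))
                    e = (e + e.T) / 2
                    v = np.abs(shared.values + e)
                    np.fill_diagonal(v, 0.0)
                    rdms.append(RDM(labels=CATEGORIES, values=v, kind="dissimilarity"))
                vals.append(noise_ceiling_lower(rdms))
            ceilings.append(np.mean(vals))
        assert ceilings[0] < ceilings[1] < ceilings[2]
        assert ceilings[2] > 0.95

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling_lower([_random_dissimilarity(rng)] * 2)


class TestProfilesAndOrthogonality:
    def test_identical_profiles_correlate_at_one(self, rng):
        n_sub, n_sph = 6, 20
        rdms = [[_random_dissimilarity(rng) for _ in range(n_sph)] for _ in range(n_sub)]
        models = {"m1": _random_dissimilarity(rng)}
        models["m2"] = models["m1"]
        fits = model_fit_profile(rdms, models)
        st_ = model_profile_correlation(fits, "m1", "m2")
        np.testing.assert_allclose(st_.per_subject_r, 1.0)

    def test_too_few_shared_spheres_rejected(self, rng):
        fits = model_fit_profile(
            [[_random_dissimilarity(rng) if k < 2 else None for k in range(5)] for _ in range(4)],
            {"m1": _random_dissimilarity(rng), "m2": _random_dissimilarity(rng)},
        )
        with pytest.raises(ValueError, match="at least 3"):
            model_profile_correlation(fits, "m1", "m2")

    def test_orthogonality_report_matches_brute_force(self, rng):
        """Pairwise model-RDM correlations agree with a naive oracle."""
        models = {f"m{k}": _random_dissimilarity(rng) for k in range(3)}
        report = model_rdm_correlations(models)
        for _, row in report.iterrows():
            a = models[row["model_a"]].values
            b = models[row["model_b"]].values
            tri = np.tril_indices(6, -1)
            oracle = np.corrcoef(a[tri], b[tri])[0, 1]
            assert row["r"] == pytest.approx(oracle, abs=1e-12)


class TestMds:
    def test_round_trip_from_known_2d_points(self, rng):
        pts = rng.normal(size=(6, 2)) * 3
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        rdm = RDM(labels=CATEGORIES, values=d, kind="dissimilarity")
        coords = mds_embed(rdm, dims=2)
        # Procrustes: optimal orthogonal alignment residual ~ 0
        a = pts - pts.mean(0)
        b = coords - coords.mean(0)
        u, _, vt = np.linalg.svd(b.T @ a)
        resid = np.linalg.norm(b @ (u @ vt) - a)
        assert resid < 1e-6

    def test_zero_matrix_maps_to_origin(self):
        rdm = RDM(labels=CATEGORIES, values=np.zeros((6, 6)), kind="dissimilarity")
        assert np.allclose(mds_embed(rdm), 0.0)

    def test_two_labels_distance_preserved(self):
        rdm = RDM(labels=("a", "b"), values=np.array([[0, 3.0], [3.0, 0]]), kind="dissimilarity")
        coords = mds_embed(rdm, dims=1)
        assert abs(coords[0, 0] - coords[1, 0]) == pytest.approx(3.0)

    def test_non_euclidean_warns(self):
        v = np.ones((6, 6)) - np.eye(6)
        v[0, 1] = v[1, 0] = 50.0  # violates the triangle inequality badly
        rdm = RDM(labels=CATEGORIES, values=v, kind="dissimilarity")
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            mds_embed(rdm)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_rdm_operations_preserve_symmetry_and_diagonal(seed):
    """Property: every RDM construction yields symmetric, correct-diagonal output."""
    rng = np.random.default_rng(seed)
    pats = rng.normal(size=(6, 8))
    r = neural_rdm(pats)
    assert np.allclose(r.values, r.values.T)
    assert np.allclose(np.diag(r.values), 1.0)
    d = r.to_dissimilarity()
    assert np.allclose(np.diag(d.values), 0.0)
    assert (d.values >= -1e-10).all()
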