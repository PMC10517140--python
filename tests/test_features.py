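"""Feature axes, squared-cosine similarity, greedy selection and inversion."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexmap import features, space
from cortexmap.exceptions import ArgumentError, DegenerateDataError, SingularMatrixError


class TestSCA:
    def test_identical_and_orthogonal(self, rng):
        v = rng.normal(size=25)
        assert features.sca(v, v) == pytest.approx(1.0)
        w = np.zeros(25)
        w[0] = 1.0
        u = np.zeros(25)
        u[1] = 1.0
        assert features.sca(w, u) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_complete_orthonormal_basis_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=8)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        total = sum(features.sca(v, Q[:, i]) for i in range(8))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(ArgumentError):
            features.sca(np.zeros(5), np.ones(5))


class TestGOF:
    @pytest.mark.parametrize("scale,expected", [(1.0, 1.0), (0.0, 0.0), (-1.0, -3.0)])
    def test_closed_forms(self, scale, expected):
        f2 = np.zeros(25)
        f2[0] = 1.0
        assert features.gof(scale * f2, f2) == pytest.approx(expected)


class TestLabelAxis:
    def _selections(self, k=5):
        sels = []
        for a in range(k):
            axis = np.zeros(k)
            axis[a] = 1.0
            sels.append(
                space.ImageSelection(
                    a, axis,
                    np.array([f"p{a}_{i}" for i in range(3)]),
                    np.array([f"n{a}_{i}" for i in range(3)]),
                    np.zeros(3), np.zeros(3),
                )
            )
        return sels

    def test_delta_design_returns_basis_vector(self):
        sels = self._selections()
        vals = {i: 0.0 for s in sels for i in np.concatenate([s.positive_ids, s.negative_ids])}
        for i in sels[2].positive_ids:
            vals[i] = 1.0
        ax = features.label_axis(vals, sels)
        expect = np.zeros(5)
        expect[2] = 1.0
        np.testing.assert_allclose(ax.vector, expect, atol=1e-12)

    def test_shift_invariance(self, rng):
        sels = self._selections()
        ids = [i for s in sels for i in np.concatenate([s.positive_ids, s.negative_ids])]
        vals = {i: rng.normal() for i in ids}
        shifted = {i: v + 13.7 for i, v in vals.items()}
        a = features.label_axis(vals, sels)
        b = features.label_axis(shifted, sels)
        np.testing.assert_allclose(a.vector, b.vector, atol=1e-9)

    def test_coordinate_projection_fidelity(self, rng):
        """Values along a planted direction project back to that direction."""
        coords = space.ImageCoords(rng.normal(size=(2000, 25)), np.arange(2000))
        u = rng.normal(size=25)
        u /= np.linalg.norm(u)
        sels = [
            space.select_representatives(coords, np.eye(25)[a], n_per_pole=40, axis_id=a)
            for a in range(25)
        ]
        vals = {i: coords.coords[i] @ u for i in range(2000)}
        ax = features.label_axis(vals, sels)
        assert abs(ax.vector @ u) > 0.9

    def test_constant_values_rejected(self):
        sels = self._selections()
        vals = {i: 1.0 for s in sels for i in np.concatenate([s.positive_ids, s.negative_ids])}
        with pytest.raises(DegenerateDataError):
            features.label_axis(vals, sels)


class TestImageStatistics:
    def test_grating_energy_in_matching_band(self):
        deg_per_px = 11.0 / 227.0
        n = 227
        xx = np.arange(n) * deg_per_px
        img = np.sin(2 * np.pi * 2.0 * xx)[None, :].repeat(n, axis=0)  # 2 cyc/degree
        bands = features.image_band_energy(img, deg_per_px=deg_per_px)[0]
        # the fifth band spans 1.45-2.91 cyc/degree under the octave defaults
        edges = features.default_band_edges()
        assert edges[4] == pytest.approx(1.455)
        assert edges[5] == pytest.approx(2.91)
        assert bands[4] / bands.sum() > 0.9

    def test_constant_image_all_zero(self):
        bands = features.image_band_energy(np.full((64, 64), 5.0), deg_per_px=0.05)
        np.testing.assert_allclose(bands, 0.0, atol=1e-9)

    def test_white_noise_flat_spectrum(self, rng):
        """Flat expected |F|: per-annulus mean magnitudes are comparable."""
        img = rng.normal(size=(256, 256))
        bands = features.image_band_energy(img, deg_per_px=0.05)[0]
        assert bands.max() / bands.min() < 1.5

    def test_colorfulness_closed_forms(self):
        gray = np.tile(np.arange(12.0).reshape(2, 2, 3, 1).mean(axis=2)[..., None], (1, 1, 3))
        assert features.colorfulness(gray)[0] == pytest.approx(0.0)
        red = np.zeros((4, 4, 3))
        red[..., 0] = 255.0
        assert features.colorfulness(red)[0] == pytest.approx(np.std([255, 0, 0]), abs=1e-9)
        assert features.colorfulness(2 * red)[0] == pytest.approx(2 * np.std([255, 0, 0]))

    def test_non_rgb_rejected(self):
        with pytest.raises(ArgumentError):
            features.colorfulness(np.zeros((4, 4, 2)))


class TestContrastAxis:
    def test_antipodal_groups_and_swap(self, rng):
        u = rng.normal(size=25)
        u /= np.linalg.norm(u)
        a = features.contrast_axis(u[None, :], -u[None, :])
        np.testing.assert_allclose(a.vector, u, atol=1e-12)
        b = features.contrast_axis(-u[None, :], u[None, :])
        np.testing.assert_allclose(b.vector, -u, atol=1e-12)

    def test_planted_cluster_separation(self, rng):
        u = rng.normal(size=25)
        u /= np.linalg.norm(u)
        A = 2 * u + 0.3 * rng.normal(size=(200, 25))
        B = -2 * u + 0.3 * rng.normal(size=(200, 25))
        ax = features.contrast_axis(A, B)
        assert abs(ax.vector @ u) > 0.95


class TestWordnetScreen:
    def test_boundaries_and_bruteforce(self, rng):
        table = {
            "rare": np.zeros(2500, bool),
            "boundary_low": np.arange(2500) < 100,
            "just_under": np.arange(2500) < 99,
            "boundary_high": np.arange(2500) < 2000,
            "too_common": np.arange(2500) < 2001,
        }
        kept = features.wordnet_label_screen(table)
        assert set(kept) == {"boundary_low", "boundary_high"}
        brute = [k for k, v in table.items() if 100 <= v.sum() <= 2000]
        assert set(kept) == set(brute)


class TestGreedySelect:
    def _planted(self, rng, noise=0.25, n_cells=150):
        e = np.eye(25)
        w = rng.uniform(-1, 1, size=(n_cells, 2))
        truth = w @ np.vstack([e[0], e[1]])

        def halves(rg):
            def mk():
                M = truth + noise * rg.normal(size=truth.shape)
                return M / np.linalg.norm(M, axis=1, keepdims=True)

            return mk(), mk()

        full = truth / np.linalg.norm(truth, axis=1, keepdims=True)
        cands = [features.FeatureAxis("ax0", e[0]), features.FeatureAxis("ax1", e[1])] + [
            features.FeatureAxis(f"rand{i}", rng.normal(size=25)) for i in range(6)
        ]
        return full, cands, halves

    def test_planted_axes_selected_first_with_optimal_k2(self, rng):
        full, cands, halves = self._planted(rng)
        res = features.greedy_select(full, cands, max_k=5, halves=halves, n_splits=30, seed=0)
        assert {f.name for f in res.ordered_features[:2]} == {"ax0", "ax1"}
        assert res.optimal_k == 2

    def test_duplicate_candidate_never_admitted(self, rng):
        full, cands, _ = self._planted(rng)
        cands = cands + [features.FeatureAxis("dup", cands[0].vector)]
        res = features.greedy_select(full, cands, max_k=6)
        names = [f.name for f in res.ordered_features]
        assert not ("ax0" in names and "dup" in names)

    def test_identical_halves_match_projection_gof(self, rng):
        full, cands, _ = self._planted(rng, noise=0.0)
        res = features.greedy_select(full, cands, max_k=3)
        basis = features.orthonormalize([f.vector for f in res.ordered_features[:2]])
        proj = full @ basis.T @ basis
        expect = np.mean(1 - np.sum((full - proj) ** 2, axis=1))
        assert res.gof_curve[1] == pytest.approx(expect, abs=1e-12)


class TestNoiseCeiling:
    def test_identical_halves_ceiling_one(self, rng):
        F = rng.normal(size=(100, 25))
        F /= np.linalg.norm(F, axis=1, keepdims=True)
        naive, corrected = features.noise_ceiling(F, F, seed=0)
        assert naive == pytest.approx(1.0)
        assert corrected == pytest.approx(1.0, abs=1e-6)

    def test_correction_tracks_true_gof(self, rng):
        g = rng.normal(size=(400, 25))
        g /= np.linalg.norm(g, axis=1, keepdims=True)

        def noisy(s, r):
            M = g + s * r.normal(size=g.shape)
            return M / np.linalg.norm(M, axis=1, keepdims=True)

        for s in (0.3, 0.6):
            h1, h2 = noisy(s, rng), noisy(s, rng)
            true_gof = float(np.mean(1 - np.sum((h2 - g) ** 2, axis=1)))
            _, corrected = features.noise_ceiling(h1, h2, seed=3)
            assert abs(corrected - true_gof) < 0.05

    def test_pure_noise_naive_nonpositive(self, rng):
        def unit(M):
            return M / np.linalg.norm(M, axis=1, keepdims=True)

        naive, _ = features.noise_ceiling(
            unit(rng.normal(size=(500, 25))), unit(rng.normal(size=(500, 25))), seed=0
        )
        assert naive <= 0.0


class TestResidualFeatures:
    def test_map_inside_span_yields_empty(self, rng):
        e = np.eye(25)
        cells = rng.normal(size=(80, 2)) @ np.vstack([e[0], e[1]])
        sel = [features.FeatureAxis("a", e[0]), features.FeatureAxis("b", e[1])]
        with pytest.warns(UserWarning, match="numerically zero"):
            assert features.residual_features(cells, sel) == []

    def test_planted_orthogonal_residual_recovered(self, rng):
        e = np.eye(25)
        cells = (
            rng.normal(size=(200, 2)) @ np.vstack([e[0], e[1]])
            + rng.normal(size=(200, 1)) @ e[2][None, :]
        )
        sel = [features.FeatureAxis("a", e[0]), features.FeatureAxis("b", e[1])]
        res = features.residual_features(cells, sel, n_residual=1)
        assert abs(res[0].vector @ e[2]) > 0.95

    def test_residuals_orthogonal_to_selected(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(25, 3)))
        sel = [features.FeatureAxis(f"s{i}", Q[:, i]) for i in range(3)]
        cells = rng.normal(size=(150, 25))
        res = features.residual_features(cells, sel, n_residual=4)
        for r in res:
            for s in sel:
                assert abs(r.vector @ s.vector) < 1e-8


class TestInvertRegionAxis:
    def test_identity_matrix(self, rng):
        R = rng.normal(size=25)
        inv = features.invert_region_axis(np.eye(25), R)
        np.testing.assert_allclose(inv.weights, R)
        assert inv.condition_number == pytest.approx(1.0)

    def test_forward_backward_round_trip(self, rng):
        A = rng.normal(size=(25, 25)) + 3 * np.eye(25)
        w0 = rng.normal(size=25)
        inv = features.invert_region_axis(A, A @ w0)
        np.testing.assert_allclose(inv.weights, w0, atol=1e-8)

    def test_rank_deficient_raises(self, rng):
        A = np.outer(rng.normal(size=25), rng.normal(size=25))
        with pytest.raises(SingularMatrixError):
            features.invert_region_axis(A, rng.normal(size=25))

    def test_ill_conditioned_warns(self):
        A = np.diag(np.concatenate([[1e8], np.ones(24)]))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            features.invert_region_axis(A, np.ones(25))
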