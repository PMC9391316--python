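"""KDE fingerprints: plug-in bandwidth, pdf, HDR levels, mode, curation."""

import numpy as np
import pytest

from particleprint import (EmbeddingSet, Fingerprint, fit_fingerprint,
                           global_mode, hdr_levels, hdr_mass, kde_pdf,
                           nearest_to_point, plugin_bandwidth)


def rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


class TestPluginBandwidth:
    def test_scale_equivariance_exact(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((400, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        H = plugin_bandwidth(x)
        np.testing.assert_allclose(plugin_bandwidth(2.5 * x), 2.5**2 * H,
                                   atol=1e-8)

    def test_rotation_equivariance_exact(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((400, 2)) * np.array([1.0, 0.5])
        H = plugin_bandwidth(x)
        R = rot(0.9)
        np.testing.assert_allclose(plugin_bandwidth(x @ R.T), R @ H @ R.T,
                                   atol=1e-8)

    def test_gaussian_20k_matches_amise_oracle(self, gaussian_20k_bandwidth):
        _, H = gaussian_20k_bandwidth
        target = 20000 ** (-1.0 / 3.0)
        assert abs(H[0, 0] - target) / target < 0.20
        assert abs(H[1, 1] - target) / target < 0.20

    def test_bandwidth_shrinks_with_sample_size(self, gaussian_20k_bandwidth):
        x20k, H20k = gaussian_20k_bandwidth
        diags = []
        for n in (200, 2000):
            diags.append(np.diag(plugin_bandwidth(x20k[:n])))
        diags.append(np.diag(H20k))
        assert np.all(np.diff([d.mean() for d in diags]) < 0)

    def test_degenerate_clouds_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            plugin_bandwidth(np.random.default_rng(0).standard_normal((5, 2)))
        line = np.linspace(0, 1, 50)[:, None] * np.array([[1.0, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            plugin_bandwidth(line)


class TestFingerprintPdf:
    def test_single_component_peak_closed_form(self):
        fp = Fingerprint(points=np.zeros((1, 2)), H=np.eye(2))
        assert kde_pdf(fp, np.zeros((1, 2)))[0] == pytest.approx(1 / (2 * np.pi))

    def test_unit_mass_by_quadrature(self, bimodal_fingerprint):
        fp = bimodal_fingerprint
        sd = np.sqrt(np.diag(fp.H)).max() + np.ptp(fp.points, axis=0).max()
        lo = fp.points.min(axis=0) - 8 * np.sqrt(np.diag(fp.H).max())
        hi = fp.points.max(axis=0) + 8 * np.sqrt(np.diag(fp.H).max())
        gx = np.linspace(lo[0], hi[0], 400)
        gy = np.linspace(lo[1], hi[1], 400)
        xx, yy = np.meshgrid(gx, gy)
        z = fp.pdf(np.column_stack([xx.ravel(), yy.ravel()]))
        mass = z.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert z.min() >= 0
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_two_point_symmetry(self):
        fp = Fingerprint(points=np.array([[-1.0, 0.0], [1.0, 0.0]]),
                         H=0.5 * np.eye(2))
        q = np.array([[0.3, 0.7], [-0.3, 0.7]])
        vals = fp.pdf(q)
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)

    def test_fit_fingerprint_contracts(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((60, 2))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        emb = EmbeddingSet(coords, labels)
        with pytest.raises(ValueError, match="no points"):
            fit_fingerprint(emb, subset="zzz")
        small = EmbeddingSet(coords[:3], labels[:3])
        with pytest.raises(ValueError, match="at least"):
            fit_fingerprint(small)
        # a union is fit with the union's own bandwidth, not an average
        fp_union = fit_fingerprint(emb, subset=["a", "b"])
        fp_a = fit_fingerprint(emb, subset="a")
        fp_b = fit_fingerprint(emb, subset="b")
        assert fp_union.n == 60
        assert not np.allclose(fp_union.H, (fp_a.H + fp_b.H) / 2)

    def test_serialization_roundtrip_preserves_pdf(self, bimodal_fingerprint,
                                                   tmp_path):
        fp = bimodal_fingerprint
        fp.to_json(tmp_path / "fp.json")
        back = Fingerprint.from_json(tmp_path / "fp.json")
        rng = np.random.default_rng(4)
        probes = rng.standard_normal((100, 2)) * 2
        np.testing.assert_allclose(back.pdf(probes), fp.pdf(probes), atol=1e-12)


class TestHdrLevels:
    def test_single_normal_component_closed_form(self):
        # for f = N(0, I), the level enclosing mass p is (1-p)/(2*pi)
        fp = Fingerprint(points=np.zeros((1, 2)), H=np.eye(2))
        samples = fp.sample(10000, np.random.default_rng(3))
        masses = np.array([0.2, 0.4, 0.6, 0.8])
        lv = hdr_levels(fp, masses, points=samples)
        exact = (1 - masses) / (2 * np.pi)
        np.testing.assert_allclose(lv.levels, exact, rtol=0.05)

    def test_levels_strictly_decrease_in_mass(self, bimodal_fingerprint):
        lv = hdr_levels(bimodal_fingerprint, [0.2, 0.4, 0.6, 0.8])
        assert np.all(np.diff(lv.levels) < 0)

    def test_small_mass_limit_approaches_density_maximum(self, bimodal_fingerprint):
        fp = bimodal_fingerprint
        lv = hdr_levels(fp, [1e-9])
        assert lv.levels[0] == pytest.approx(fp.pdf(fp.points).max(), rel=1e-6)

    def test_monte_carlo_mass_matches_nominal(self, bimodal_fingerprint):
        fp = bimodal_fingerprint
        # calibrated variant: quantiles over a fresh sample of the mixture
        smp = fp.sample(20000, np.random.default_rng(9))
        lv = hdr_levels(fp, [0.5], points=smp)
        mass = hdr_mass(fp, lv.levels[0], 20000, np.random.default_rng(8))
        assert mass == pytest.approx(0.5, abs=0.04)
        # the support-point default carries a small upward smoothing bias
        lv0 = hdr_levels(fp, [0.5])
        mass0 = hdr_mass(fp, lv0.levels[0], 20000, np.random.default_rng(8))
        assert mass0 == pytest.approx(0.5, abs=0.10)

    def test_mass_outside_unit_interval_rejected(self, bimodal_fingerprint):
        with pytest.raises(ValueError):
            hdr_levels(bimodal_fingerprint, [0.0, 0.5])


class TestGlobalMode:
    def test_single_component_mode_is_the_point(self):
        fp = Fingerprint(points=np.array([[1.3, -2.1]]), H=0.2 * np.eye(2))
        m = global_mode(fp)
        np.testing.assert_allclose(m.point, [1.3, -2.1], atol=1e-6)
        assert not m.tie

    def test_exact_tie_is_flagged_first_maximizer_returned(self):
        fp = Fingerprint(points=np.array([[-3.0, 0.0], [3.0, 0.0]]),
                         H=0.1 * np.eye(2))
        m = global_mode(fp)
        assert m.tie
        assert m.point[0] == pytest.approx(-3.0, abs=1e-6)

    def test_beats_brute_force_grid(self, bimodal_fingerprint):
        fp = bimodal_fingerprint
        m = global_mode(fp)
        lo = fp.points.min(axis=0) - 1
        hi = fp.points.max(axis=0) + 1
        gx = np.linspace(lo[0], hi[0], 512)
        gy = np.linspace(lo[1], hi[1], 512)
        xx, yy = np.meshgrid(gx, gy)
        grid_max = fp.pdf(np.column_stack([xx.ravel(), yy.ravel()])).max()
        assert m.density >= grid_max

    def test_translation_moves_mode_by_same_vector(self, bimodal_fingerprint):
        fp = bimodal_fingerprint
        shift = np.array([2.5, -1.5])
        moved = Fingerprint(points=fp.points + shift, H=fp.H)
        m0 = global_mode(fp)
        m1 = global_mode(moved)
        np.testing.assert_allclose(m1.point, m0.point + shift, atol=1e-6)


class TestNearestToPoint:
    def test_k_equals_n_returns_distance_sorted_order(self):
        rng = np.random.default_rng(5)
        emb = EmbeddingSet(rng.standard_normal((30, 2)), np.zeros(30))
        point = np.array([0.2, -0.1])
        idx = nearest_to_point(emb, point, k=30)
        d = np.linalg.norm(emb.coords - point, axis=1)
        assert np.all(np.diff(d[idx]) >= 0)

    def test_query_on_an_embedding_returns_it_first(self):
        rng = np.random.default_rng(6)
        emb = EmbeddingSet(rng.standard_normal((40, 2)), np.zeros(40))
        idx = nearest_to_point(emb, emb.coords[17], k=5)
        assert idx[0] == 17

    def test_matches_full_sort_brute_force_with_tie_rule(self):
        rng = np.random.default_rng(7)
        coords = np.round(rng.standard_normal((1000, 2)), 1)  # force ties
        emb = EmbeddingSet(coords, np.zeros(1000))
        point = np.array([0.0, 0.0])
        idx = nearest_to_point(emb, point, k=50)
        d = np.linalg.norm(coords - point, axis=1)
        brute = sorted(range(1000), key=lambda i: (d[i], i))[:50]
        assert idx.tolist() == brute

    def test_k_too_large_rejected(self):
        emb = EmbeddingSet(np.zeros((4, 2)), np.zeros(4))
        with pytest.raises(ValueError):
            nearest_to_point(emb, np.zeros(2), k=5)
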