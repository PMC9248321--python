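import numpy as np
import pytest

from lgrbsn.bijectivity import (
    BijectivityConfig,
    MaskBundle,
    bijectivity_step,
    demons_velocity,
    demons_velocity_sum,
    enforce_bijectivity,
    residual,
)
from lgrbsn.fields import (
    DisplacementField,
    Grid,
    LabelImage,
    count_nonpositive_jacobian,
)
from lgrbsn.idw import IDWConfig, compose_global, compute_cores, idw_weights


def const_field(grid, vec, direction="forward"):
    dom = "subject" if direction == "forward" else "template"
    vals = np.broadcast_to(np.asarray(vec, float), grid.shape + (grid.ndim,)).copy()
    return DisplacementField(grid, vals, domain=dom, direction=direction)


@pytest.fixture
def folded_pair():
    """An IDW-composed field pair that genuinely folds between two regions."""
    g = Grid((40, 20))
    lab = np.zeros((40, 20), int)
    lab[4:14, 4:16] = 1
    lab[16:26, 4:16] = 2
    img = LabelImage(g, lab)
    part = compute_cores(img, 2)
    w = idw_weights(part, IDWConfig())
    c = 3.0
    u_sm = compose_global(
        [const_field(g, (c, 0)), const_field(g, (-c, 0))], w, "forward"
    )
    u_ms = compose_global(
        [const_field(g, (-c, 0), "reverse"), const_field(g, (c, 0), "reverse")],
        w,
        "reverse",
    )
    bundle = MaskBundle(img.mask(), img.mask(), [lab == 1, lab == 2], [lab == 1, lab == 2])
    return u_sm, u_ms, bundle


class TestConfig:
    def test_weights_normalized_on_construction(self):
        cfg = BijectivityConfig(w1=2.0, w2=1.0, w3=1.0)
        assert cfg.w1 + cfg.w2 + cfg.w3 == pytest.approx(1.0)
        assert cfg.w1 == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "kw", [{"w1": -1.0}, {"w1": 0, "w2": 0, "w3": 0}, {"beta": 0.0}, {"sigma_cc": 0.0}]
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            BijectivityConfig(**kw)


class TestResidual:
    def test_zero_fields(self):
        g = Grid((6, 6))
        r = residual(
            DisplacementField.zeros(g),
            DisplacementField.zeros(g, domain="template", direction="reverse"),
        )
        assert np.allclose(r.values, 0.0)

    def test_exact_inverse_translations_vanish(self):
        g = Grid((8, 8))
        r = residual(const_field(g, (1.5, -2.0)), const_field(g, (-1.5, 2.0), "reverse"))
        assert np.abs(r.values).max() < 1e-12

    def test_one_sided_translation(self):
        g = Grid((8, 8))
        r = residual(const_field(g, (1.0, 0.0)), const_field(g, (0.0, 0.0), "reverse"))
        assert np.allclose(r.values, [1.0, 0.0])

    def test_same_direction_rejected(self):
        g = Grid((6, 6))
        with pytest.raises(ValueError, match="opposite"):
            residual(DisplacementField.zeros(g), DisplacementField.zeros(g))


class TestDemons:
    def test_matched_masks_give_zero_velocity(self):
        g = Grid((10, 10))
        m = np.zeros((10, 10))
        m[3:7, 3:7] = 1.0
        from scipy.ndimage import gaussian_filter

        sm = gaussian_filter(m, 1.0)
        from lgrbsn.fields import DeformationMap

        v = demons_velocity(sm, sm, DeformationMap.identity(g), alpha=1.0)
        assert np.abs(v.values).max() < 1e-12

    def test_constant_image_guarded_to_zero(self):
        g = Grid((6, 6))
        from lgrbsn.fields import DeformationMap

        F = np.full((6, 6), 0.7)
        M = np.zeros((6, 6))
        v = demons_velocity(F, M, DeformationMap.identity(g), alpha=1.0)
        assert np.allclose(v.values, 0.0)

    def test_step_edge_against_hand_evaluation(self):
        # 1D step edges (constant along the second axis): fixed edge at
        # index 5, moving edge at 6, alpha = 1.  The demons formula is
        # re-evaluated here from scratch with explicit finite differences.
        g = Grid((11, 4))
        F = np.zeros((11, 4))
        F[5:, :] = 1.0
        M = np.zeros((11, 4))
        M[6:, :] = 1.0
        from lgrbsn.fields import DeformationMap

        v = demons_velocity(F, M, DeformationMap.identity(g), alpha=1.0)
        gx = np.gradient(F, axis=0)
        gy = np.gradient(F, axis=1)
        diff = F - M
        denom = gx**2 + gy**2 + 1.0 * diff**2
        expected_x = np.where(denom < 1e-12, 0.0, diff * gx / np.where(denom == 0, 1, denom))
        assert np.allclose(v.values[..., 0], expected_x, atol=1e-12)
        assert np.allclose(v.values[..., 1], 0.0, atol=1e-12)
        # at the fixed edge voxel the velocity pushes toward the moving edge
        assert v.values[5, 2, 0] != 0.0

    def test_sum_linearity(self, rng):
        g = Grid((12, 12))
        from lgrbsn.fields import DeformationMap
        from scipy.ndimage import gaussian_filter

        U = DeformationMap.identity(g)
        empty = demons_velocity_sum([], [], U, alpha=1.0)
        assert np.allclose(empty.values, 0.0)
        f1 = gaussian_filter((rng.random((12, 12)) > 0.6).astype(float), 1.0)
        m1 = gaussian_filter((rng.random((12, 12)) > 0.6).astype(float), 1.0)
        f2 = np.zeros((12, 12))
        f2[8:11, 1:4] = 1.0
        m2 = np.roll(f2, 1, axis=0)
        single = demons_velocity(f1, m1, U, 1.0)
        assert np.allclose(demons_velocity_sum([f1], [m1], U, 1.0).values, single.values)
        total = demons_velocity_sum([f1, f2], [m1, m2], U, 1.0)
        expected = single.values + demons_velocity(f2, m2, U, 1.0).values
        assert np.allclose(total.values, expected, atol=1e-12)
        with pytest.raises(ValueError):
            demons_velocity_sum([f1], [], U, 1.0)


class TestStep:
    def _matched_bundle(self, g):
        lab = np.zeros(g.shape, int)
        lab[2:-2, 2:-2] = 1
        img = LabelImage(g, lab)
        return MaskBundle(img.mask(), img.mask())

    def test_fixed_point_on_exact_inverses(self):
        g = Grid((12, 12))
        bundle = self._matched_bundle(g)
        u_sm = const_field(g, (0.0, 0.0))
        u_ms = const_field(g, (0.0, 0.0), "reverse")
        new_sm, new_ms, _, _ = bijectivity_step(u_sm, u_ms, bundle, BijectivityConfig())
        assert np.abs(new_sm.values - u_sm.values).max() < 1e-14
        assert np.abs(new_ms.values - u_ms.values).max() < 1e-14

    @pytest.mark.parametrize("beta", [0.25, 0.5])
    def test_contraction_factor_on_constant_translations(self, beta):
        # with w = (1, 0, 0) the inverse-consistency error of constant
        # translation fields contracts by |1 - 2 beta w1| per step
        g = Grid((10, 10))
        bundle = self._matched_bundle(g)
        cfg = BijectivityConfig(w1=1.0, w2=0.0, w3=0.0, beta=beta)
        u_sm = const_field(g, (1.0, 0.0))
        u_ms = const_field(g, (0.0, 0.0), "reverse")
        r0 = np.abs(residual(u_sm, u_ms).values).max()
        new_sm, new_ms, _, _ = bijectivity_step(u_sm, u_ms, bundle, cfg)
        r1 = np.abs(residual(new_sm, new_ms).values).max()
        assert r1 == pytest.approx(abs(1 - 2 * beta * 1.0) * r0, abs=1e-12)

    def test_w1_zero_reduces_to_demons_only(self):
        g = Grid((12, 12))
        lab = np.zeros((12, 12), int)
        lab[3:8, 3:8] = 1
        img_s = LabelImage(g, lab)
        img_t = LabelImage(g, np.roll(lab, 1, axis=0))
        bundle = MaskBundle(img_s.mask(), img_t.mask())
        cfg = BijectivityConfig(w1=0.0, w2=1.0, w3=0.0)
        u_sm = const_field(g, (0.4, 0.0))
        u_ms = const_field(g, (0.0, 0.0), "reverse")
        new_sm, _, _, _ = bijectivity_step(u_sm, u_ms, bundle, cfg)
        delta = new_sm.values - u_sm.values
        # the update is exactly the smoothed cortex demons term
        from scipy.ndimage import gaussian_filter

        from lgrbsn.bijectivity import _smooth_field

        cc_s, cc_t, _, _ = bundle.smoothed(g, g, cfg.mask_presmooth)
        v = demons_velocity(cc_s, cc_t, u_sm.as_map(), cfg.alpha)
        expected = -cfg.w2 * _smooth_field(v.values, cfg.sigma_cc, g)
        assert np.allclose(delta, expected, atol=1e-12)


class TestEnforce:
    def test_bijective_input_returned_at_iteration_zero(self):
        g = Grid((10, 10))
        lab = np.zeros((10, 10), int)
        lab[2:8, 2:8] = 1
        img = LabelImage(g, lab)
        bundle = MaskBundle(img.mask(), img.mask())
        u_sm = const_field(g, (0.5, 0.0))
        u_ms = const_field(g, (-0.5, 0.0), "reverse")
        out_sm, out_ms, history = enforce_bijectivity(u_sm, u_ms, bundle)
        assert len(history) == 1 and history[0]["iteration"] == 0
        assert out_sm is u_sm and out_ms is u_ms

    def test_folded_composition_is_repaired(self, folded_pair):
        u_sm, u_ms, bundle = folded_pair
        assert count_nonpositive_jacobian(u_sm.as_map()) > 0
        out_sm, out_ms, history = enforce_bijectivity(u_sm, u_ms, bundle)
        assert history[-1]["nonpositive_fwd"] == 0
        assert history[-1]["nonpositive_rev"] == 0
        counts = [h["nonpositive_fwd"] for h in history]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert count_nonpositive_jacobian(out_sm.as_map()) == 0

    def test_symmetry_of_roles(self, folded_pair):
        u_sm, u_ms, bundle = folded_pair
        cfg = BijectivityConfig(max_iter=3, target_nonpositive=-1)  # fixed 3 steps
        a_sm, a_ms, _ = enforce_bijectivity(u_sm, u_ms, bundle, cfg)
        swapped_sm = DisplacementField(u_ms.grid, u_ms.values, "subject", "forward")
        swapped_ms = DisplacementField(u_sm.grid, u_sm.values, "template", "reverse")
        swapped_bundle = MaskBundle(
            bundle.cc_template,
            bundle.cc_subject,
            bundle.subcortical_template,
            bundle.subcortical_subject,
        )
        b_sm, b_ms, _ = enforce_bijectivity(swapped_sm, swapped_ms, swapped_bundle, cfg)
        assert np.allclose(a_sm.values, b_ms.values)
        assert np.allclose(a_ms.values, b_sm.values)
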