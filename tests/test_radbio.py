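"""EQD2 conversion, gEUD, and the LKB / logistic-V50 NTCP models."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from esontcp import (
    DVH,
    EQD2Params,
    FractionationScheme,
    LKBParams,
    LogisticV50Params,
    ModelConfigError,
    VoxelDoseMap,
    dvh_from_voxels,
    eqd2_per_voxel,
    eqd2_transform,
    geud,
    kwint_ntcp,
    lkb_ntcp,
    predict_toxicity,
    published_registry,
)

WIJSMAN = LKBParams(n=1.04, m=0.65, td50_gy=32.84)
CHEN = LKBParams(n=0.03, m=0.03, td50_gy=76.1)


def uniform_dvh(dose, volume=10.0, width=0.001, kind="physical"):
    return dvh_from_voxels(
        VoxelDoseMap("p", "SIB", "s", [volume], [dose]), width, dose_kind=kind
    )


class TestEQD2:
    @pytest.mark.parametrize(
        "dose,n_fx,ab,expected",
        [
            (50.4, 28, 10.0, 50.4 * (1.8 + 10) / 12),   # 49.56
            (50.4, 28, 3.0, 50.4 * (1.8 + 3) / 5),      # 48.384
            (64.8, 28, 10.0, 64.8 * (64.8 / 28 + 10) / 12),  # 66.497
            (56.0, 28, 10.0, 56.0),  # exactly 2 Gy/fraction: identity
        ],
    )
    def test_hand_values(self, dose, n_fx, ab, expected):
        assert eqd2_per_voxel(dose, n_fx, ab) == pytest.approx(expected)

    @given(
        d1=st.floats(0.1, 80), d2=st.floats(0.1, 80), ab=st.floats(0.5, 20),
        n_fx=st.integers(1, 40),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_increasing(self, d1, d2, ab, n_fx):
        if abs(d1 - d2) < 1e-9:
            return
        lo, hi = sorted((d1, d2))
        assert eqd2_per_voxel(lo, n_fx, ab) < eqd2_per_voxel(hi, n_fx, ab)

    def test_convex_in_dose(self):
        d = np.linspace(0, 80, 200)
        e = eqd2_per_voxel(d, 28, 10.0)
        assert np.all(np.diff(e, 2) >= -1e-9)

    def test_transform_identity_at_2gy_per_fraction(self):
        dmap = VoxelDoseMap("p", "SD", "s", np.ones(5), np.full(5, 56.0))
        out = eqd2_transform(dmap, FractionationScheme(56.0, 28), EQD2Params(10.0))
        np.testing.assert_allclose(out.dose_gy, dmap.dose_gy)

    def test_transform_dvh_tags_and_preserves_volume(self):
        dvh = uniform_dvh(50.4, width=0.1)
        out = eqd2_transform(dvh, FractionationScheme(50.4, 28), EQD2Params(10.0))
        assert out.dose_kind == "EQD2"
        assert out.total_volume_cc == pytest.approx(dvh.total_volume_cc)

    def test_double_conversion_refused(self):
        dvh = uniform_dvh(50.4, kind="EQD2")
        with pytest.raises(ValueError, match="already"):
            eqd2_transform(dvh, FractionationScheme(50.4, 28), EQD2Params(10.0))

    def test_fractionation_scheme_per_fraction_dose(self):
        assert FractionationScheme(64.8, 28).dose_per_fraction_gy == pytest.approx(
            2.3142857142857145
        )
        assert FractionationScheme(50.4, 28).dose_per_fraction_gy == pytest.approx(1.8)


class TestGEUD:
    @pytest.mark.parametrize("n", [0.03, 0.5, 1.0, 1.04, 3.0])
    def test_uniform_dose_identity(self, n):
        dvh = uniform_dvh(40.0)
        assert geud(dvh, n) == pytest.approx(40.0, abs=1e-3)

    def test_closed_form_half_and_half(self):
        dvh = dvh_from_voxels(
            VoxelDoseMap("p", "SIB", "s", [0.5, 0.5], [0.0, 60.0]), 0.001
        )
        assert geud(dvh, 0.5) == pytest.approx(math.sqrt(0.5 * 60**2), abs=0.05)

    @pytest.mark.parametrize("seed", range(30))
    def test_n_equals_one_is_mean_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        dvh = dvh_from_voxels(
            VoxelDoseMap("p", "SIB", "s", rng.uniform(0.1, 2, 15),
                         rng.uniform(1, 70, 15)),
            0.01,
        )
        mid = dvh.bin_midpoints_gy
        w = dvh.diff_volume_cc / dvh.total_volume_cc
        mean = float(np.dot(w, mid))
        assert geud(dvh, 1.0) == pytest.approx(mean, rel=1e-10)
        occupied = mid[dvh.diff_volume_cc > 0]
        for n in (0.03, 0.3, 1.0, 2.0):
            val = geud(dvh, n)
            assert occupied.min() - 1e-9 <= val <= occupied.max() + 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_serial_limit_approaches_dmax(self, seed):
        """As n -> 0+ the gEUD rises monotonically toward the maximum dose."""
        rng = np.random.default_rng(seed)
        dvh = dvh_from_voxels(
            VoxelDoseMap("p", "SIB", "s", rng.uniform(0.1, 2, 10),
                         rng.uniform(5, 70, 10)),
            0.01,
        )
        g_003, g_0001 = geud(dvh, 0.03), geud(dvh, 0.001)
        dmax = dvh.bin_midpoints_gy[dvh.diff_volume_cc > 0].max()
        assert g_003 <= g_0001 <= dmax + 1e-9
        assert dmax - g_0001 < dmax - g_003 + 1e-9

    @pytest.mark.parametrize("seed", range(30))
    def test_log_domain_matches_direct_power_sum(self, seed):
        """Brute-force oracle: direct power sum where it does not overflow."""
        rng = np.random.default_rng(seed)
        dvh = dvh_from_voxels(
            VoxelDoseMap("p", "SIB", "s", rng.uniform(0.1, 2, 12),
                         rng.uniform(1, 70, 12)),
            0.05,
        )
        for n in (0.2, 0.5, 1.0, 2.0):
            mid = dvh.bin_midpoints_gy
            w = dvh.diff_volume_cc / dvh.total_volume_cc
            pos = (w > 0) & (mid > 0)
            direct = float(np.sum(w[pos] * mid[pos] ** (1 / n)) ** n)
            assert geud(dvh, n) == pytest.approx(direct, rel=1e-10)

    def test_all_zero_dose_map_collapses_to_zero(self):
        # an unirradiated structure: gEUD is 0 up to the midpoint convention
        empty_dose = dvh_from_voxels(
            VoxelDoseMap("p", "SIB", "s", [1.0], [0.0]), 0.001
        )
        for n in (0.5, 1.0):
            assert geud(empty_dose, n) <= 0.001


class TestLKB:
    def test_half_probability_at_td50(self):
        assert lkb_ntcp(32.84, WIJSMAN) == pytest.approx(0.5)
        assert lkb_ntcp(76.1, CHEN) == pytest.approx(0.5)

    def test_one_slope_above(self):
        assert lkb_ntcp(32.84 * 1.65, WIJSMAN) == pytest.approx(0.8413447, abs=1e-6)

    def test_far_tail_against_high_precision_oracle(self):
        """Chen at a 52.5 Gy uniform dose sits ~10 sigma below TD50."""
        t = (52.5 - 76.1) / (0.03 * 76.1)
        oracle = float(sympy.erfc(-sympy.Float(t) / sympy.sqrt(2)) / 2)
        value = lkb_ntcp(52.5, CHEN)
        assert value == pytest.approx(oracle, rel=1e-10)
        assert 1e-25 < value < 1e-24

    @given(e1=st.floats(0, 120), e2=st.floats(0, 120))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_monotone_and_bounded(self, e1, e2):
        p1, p2 = lkb_ntcp(e1, WIJSMAN), lkb_ntcp(e2, WIJSMAN)
        assert 0.0 <= p1 <= 1.0
        if e2 - e1 > 1e-6:  # resolvable in double precision
            assert p1 < p2


class TestLogisticV50:
    def test_midpoint_and_hand_values(self):
        params = LogisticV50Params(intercept=-2.0, slope=0.05)
        assert kwint_ntcp(40.0, params) == pytest.approx(0.5)
        assert kwint_ntcp(80.0, params) == pytest.approx(1 / (1 + math.exp(-2)))
        assert kwint_ntcp(0.0, params) == pytest.approx(1 / (1 + math.exp(2)))

    def test_zero_slope_constant(self):
        params = LogisticV50Params(intercept=1.0, slope=0.0)
        vals = {kwint_ntcp(v, params) for v in (0.0, 25.0, 100.0)}
        assert len(vals) == 1

    def test_missing_coefficients_error(self):
        with pytest.raises(ModelConfigError, match="coefficients required"):
            kwint_ntcp(40.0, None)


class TestPredictToxicity:
    def test_uniform_at_d50_gives_half(self, registry):
        # physical dose whose EQD2 equals 32.84: solve D(D/28+10)/12 = 32.84
        d = np.roots([1 / 28, 10, -12 * 32.84]).max()
        dvh = uniform_dvh(float(d))
        p = predict_toxicity(dvh, FractionationScheme(50.4, 28), registry["wijsman_g2"])
        assert p == pytest.approx(0.5, abs=1e-3)

    def test_uniform_56gy_wijsman(self, registry):
        dvh = uniform_dvh(56.0)
        p = predict_toxicity(dvh, FractionationScheme(56.0, 28), registry["wijsman_g2"])
        assert p == pytest.approx(0.8610, abs=2e-3)

    def test_v50_zero_logistic_baseline(self, registry):
        dvh = uniform_dvh(20.0)  # far below 50 Gy -> V50 = 0
        p = predict_toxicity(dvh, FractionationScheme(50.4, 28), registry["kwint_g2"])
        assert p == pytest.approx(1 / (1 + math.exp(2)), abs=1e-9)

    def test_requires_physical_dvh(self, registry):
        dvh = uniform_dvh(56.0, kind="EQD2")
        with pytest.raises(ValueError, match="physical"):
            predict_toxicity(dvh, FractionationScheme(56.0, 28), registry["wijsman_g2"])

    @pytest.mark.parametrize("model", ["kwint_g2", "kwint_g3", "wijsman_g2", "chen_let"])
    def test_dominance_propagates(self, registry, model, default_config):
        """A voxelwise-dominating plan never predicts lower toxicity."""
        from esontcp import dvh_from_voxels, simulate_patient

        rec = simulate_patient(default_config, 0)
        sib = dvh_from_voxels(rec.dose_sib, 0.1)
        sd = dvh_from_voxels(rec.dose_sd, 0.1)
        scheme_sib = FractionationScheme(64.8, 28)
        scheme_sd = FractionationScheme(50.4, 28)
        spec = registry[model]
        assert predict_toxicity(sib, scheme_sib, spec) >= predict_toxicity(
            sd, scheme_sd, spec
        )


class TestRegistry:
    def test_published_parameters(self, registry):
        w = registry["wijsman_g2"]
        assert (w.lkb.n, w.lkb.m, w.lkb.td50_gy) == (1.04, 0.65, 32.84)
        assert w.eqd2.alpha_beta_gy == 10.0
        c = registry["chen_let"]
        assert (c.lkb.n, c.lkb.m, c.lkb.td50_gy) == (0.03, 0.03, 76.1)
        assert c.eqd2.alpha_beta_gy == 3.0

    def test_unparameterized_kwint_by_default(self):
        bare = published_registry()
        assert bare["kwint_g2"].logistic is None
        assert bare["kwint_g3"].logistic is None

    def test_yaml_round_trip(self, registry, tmp_path):
        from esontcp import registry_from_yaml, registry_to_yaml

        path = tmp_path / "models.yaml"
        registry_to_yaml(registry, path)
        back = registry_from_yaml(path)
        assert set(back) == set(registry)
        for name in registry:
            assert back[name] == registry[name]
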