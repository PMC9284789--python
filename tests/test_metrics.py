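import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtplan.bev import StructureVolume
from dtplan.errors import DoseError, EmptyStructureError
from dtplan.metrics import (
    DoseGrid,
    ci_paddick,
    dvh,
    endpoint_D_cc,
    endpoint_Dx,
    endpoint_Vx,
    hi95,
    mean_dose,
    normalize,
    resample_dose,
)


def _structure(mask, spacing=2.0):
    return StructureVolume(
        name="s", role="oar", mask=mask, spacing_mm=(spacing,) * 3, origin_mm=(0, 0, 0)
    )


def _dose(arr, rx=50.0, spacing=2.0):
    return DoseGrid(dose=arr, spacing_mm=np.full(3, spacing), origin_mm=np.zeros(3), prescription_gy=rx)


def _case(dose_values, shape=None):
    """Structure covering given voxel doses inside a larger zero grid."""
    vals = np.asarray(dose_values, float)
    n = len(vals)
    shape = shape or (n, 1, 1)
    arr = np.zeros(shape)
    mask = np.zeros(shape, bool)
    arr.flat[:n] = vals
    mask.flat[:n] = True
    return _dose(arr), _structure(mask)


def oracle_dx(values, x_percent):
    """Independent hand-rolled linear-interpolated order statistic."""
    v = sorted(values)
    n = len(v)
    pos = (100.0 - x_percent) / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class TestDvh:
    def test_uniform_dose_step_function(self):
        dose, s = _case([50.0] * 8)
        c = dvh(dose, s)
        assert c.volume_fraction[0] == 1.0
        assert np.interp(49.9, c.dose_gy, c.volume_fraction) > 0.99
        assert endpoint_Vx(c, 50.0) == 1.0
        assert endpoint_Vx(c, 50.1) == 0.0

    def test_two_voxel_order_statistics(self):
        dose, s = _case([40.0, 60.0])
        c = dvh(dose, s)
        assert endpoint_Vx(c, 50.0) == 0.5
        assert endpoint_Vx(c, 40.0) == 1.0
        assert endpoint_Vx(c, 60.5) == 0.0

    def test_monotone_nonincreasing(self, rng):
        dose, s = _case(rng.random(100) * 70)
        c = dvh(dose, s)
        assert c.volume_fraction[0] == 1.0
        assert np.all(np.diff(c.volume_fraction) <= 1e-12)

    def test_empty_structure_rejected(self):
        dose = _dose(np.zeros((3, 3, 3)))
        with pytest.raises(EmptyStructureError, match="empty structure"):
            dvh(dose, _structure(np.zeros((3, 3, 3), bool)))

    def test_grid_mismatch_rejected(self):
        dose = _dose(np.zeros((3, 3, 3)))
        with pytest.raises(DoseError):
            dvh(dose, _structure(np.ones((4, 4, 4), bool)))


class TestEndpoints:
    def test_uniform_dose_endpoints(self):
        dose, s = _case([50.0] * 27)
        c = dvh(dose, s)
        assert endpoint_Dx(c, 95) == 50.0
        assert endpoint_Vx(c, 50.0) == 1.0
        assert mean_dose(dose, s) == 50.0
        assert endpoint_D_cc(dose, s, 0.03) == 50.0

    def test_d50_of_1_to_10_matches_oracle(self):
        vals = list(range(1, 11))
        dose, s = _case(vals)
        assert endpoint_Dx(dvh(dose, s), 50) == pytest.approx(oracle_dx(vals, 50))

    def test_dx_matches_oracle_random(self, rng):
        for _ in range(100):
            vals = rng.random(rng.integers(2, 60)) * 80
            x = float(rng.uniform(1, 99))
            dose, s = _case(vals)
            assert endpoint_Dx(dvh(dose, s), x) == pytest.approx(oracle_dx(vals, x), abs=1e-9)

    def test_d_cc_interpolates_within_hottest_voxel(self):
        # voxel volume = 8 mm3 = 0.008 cc; two voxels at 10 and 2 Gy
        dose, s = _case([10.0, 2.0])
        assert endpoint_D_cc(dose, s, 0.008) == pytest.approx(10.0)
        assert endpoint_D_cc(dose, s, 0.016) == pytest.approx(2.0)
        assert endpoint_D_cc(dose, s, 0.012) == pytest.approx(6.0)  # midpoint

    def test_cc_exceeding_structure_rejected(self):
        dose, s = _case([5.0, 5.0])
        with pytest.raises(DoseError, match="volume exceeds structure"):
            endpoint_D_cc(dose, s, 1.0)


class TestNormalize:
    def test_uniform_45_to_prescription_50(self):
        dose, s = _case([45.0] * 10)
        out = normalize(dose, s, "D95->100%")
        assert np.all(out.dose[s.mask] == pytest.approx(50.0))

    def test_idempotent(self, rng):
        dose, s = _case(45 + rng.random(30) * 10)
        once = normalize(dose, s, "D95->100%")
        twice = normalize(once, s, "D95->100%")
        np.testing.assert_allclose(once.dose, twice.dose)

    def test_d97_rule_on_uniform(self):
        dose, s = _case([50.0] * 10)
        out = normalize(dose, s, "D97->99%")
        assert np.all(out.dose[s.mask] == pytest.approx(0.99 * 50.0))

    def test_degenerate_dose_rejected(self):
        dose, s = _case([0.0] * 10)
        with pytest.raises(DoseError, match="degenerate dose"):
            normalize(dose, s, "D95->100%")


class TestCiPaddick:
    def test_perfect_conformity(self):
        arr = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        arr[mask] = 50.0
        assert ci_paddick(_dose(arr), _structure(mask, spacing=2.0)) == 1.0

    def test_piv_double_tv_gives_half(self):
        # TV 100 voxels fully inside a 200-voxel PIV -> 100^2/(100*200) = 0.5
        arr = np.zeros((200, 1, 1))
        arr[:200] = 50.0
        mask = np.zeros((200, 1, 1), bool)
        mask[:100] = True
        assert ci_paddick(_dose(arr), _structure(mask)) == pytest.approx(0.5)

    def test_disjoint_piv_is_zero(self):
        arr = np.zeros((10, 1, 1))
        arr[5:] = 60.0
        mask = np.zeros((10, 1, 1), bool)
        mask[:5] = True
        assert ci_paddick(_dose(arr), _structure(mask)) == 0.0

    def test_no_piv_is_zero(self):
        arr = np.full((4, 4, 4), 10.0)
        mask = np.ones((4, 4, 4), bool)
        assert ci_paddick(_dose(arr), _structure(mask)) == 0.0

    def test_invariant_under_joint_rescaling(self, rng):
        arr = rng.random((8, 8, 8)) * 60
        mask = rng.random((8, 8, 8)) < 0.3
        a = ci_paddick(_dose(arr, rx=50), _structure(mask))
        b = ci_paddick(_dose(arr * 2, rx=100), _structure(mask))
        assert a == pytest.approx(b)


class TestHi95:
    def test_uniform_prescription_dose_is_100(self):
        dose, s = _case([50.0] * 20)
        assert hi95(dose, s) == 100.0

    def test_half_96_half_106_gives_50(self):
        dose, s = _case([48.0] * 10 + [53.0] * 10)  # 96% and 106% of 50
        assert hi95(dose, s) == pytest.approx(50.0)

    def test_all_below_95_is_zero(self):
        dose, s = _case([40.0] * 20)
        assert hi95(dose, s) == 0.0

    def test_invariant_under_joint_rescaling(self, rng):
        vals = 40 + rng.random(50) * 20
        d1, s = _case(vals)
        d2, _ = _case(vals * 3)
        assert hi95(d1, s, 50.0) == pytest.approx(hi95(d2, s, 150.0))


class TestResample:
    def test_identity_resample(self, rng):
        arr = rng.random((6, 6, 6))
        dose = _dose(arr)
        like = _structure(np.ones((6, 6, 6), bool))
        out = resample_dose(dose, like)
        np.testing.assert_allclose(out.dose, arr, atol=1e-12)

    def test_coarse_to_fine_linear_field_exact(self):
        # linear field is reproduced exactly by trilinear interpolation
        x = np.arange(10) * 2.5
        arr = np.broadcast_to(x[:, None, None], (10, 4, 4)).copy()
        dose = DoseGrid(arr, np.array([2.5, 2.5, 2.5]), np.zeros(3), 50.0)
        fine = StructureVolume(
            name="f", role="oar", mask=np.ones((11, 4, 4), bool),
            spacing_mm=(2.0, 2.5, 2.5), origin_mm=(0, 0, 0),
        )
        out = resample_dose(dose, fine)
        np.testing.assert_allclose(out.dose[:, 0, 0], np.arange(11) * 2.0, atol=1e-9)
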