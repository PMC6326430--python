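"""Degradation model vs the brute-force double-sum oracle, and the
half-saturation transform's closed-form identities."""

import numpy as np
import pytest

from prairieq import (
    GridSpec,
    HabitatRaster,
    LandCoverGrid,
    QualityParams,
    SensitivityTable,
    ThreatLayer,
    ThreatSpec,
    decay_factor,
    degradation,
    degradation_bruteforce,
    quality,
    threat_kernel,
)
from conftest import grid_from_names, uniform_grid

FULL_SENS = SensitivityTable({("native prairie", "t"): 1.0})


def one_threat(presence, weight=1.0, d_max=90.0, name="t"):
    return ThreatLayer(ThreatSpec(name, weight, d_max), np.asarray(presence))


class TestDecayFactor:
    @pytest.mark.parametrize(
        "d,d_max,expected",
        [(0.0, 100.0, 1.0), (100.0, 100.0, 0.0), (45.0, 90.0, 0.5), (500.0, 100.0, 0.0)],
    )
    def test_linear_decay(self, d, d_max, expected):
        assert decay_factor(d, ThreatSpec("t", 1.0, d_max)) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_factor(-1.0, ThreatSpec("t", 1.0, 100.0))

    def test_kernel_taps_equal_decay_at_offsets(self):
        spec = ThreatSpec("t", 1.0, 95.0)
        k = threat_kernel(spec, 30.0)
        c = k.shape[0] // 2
        assert k[c, c] == 1.0
        assert k[c, c + 1] == pytest.approx(decay_factor(30.0, spec))
        assert k[c + 2, c + 2] == pytest.approx(decay_factor(30.0 * np.hypot(2, 2), spec))
        assert k[c, c + 4] == 0.0  # beyond d_max


class TestDegradation:
    def test_no_threat_pixels_gives_zero(self):
        grid = uniform_grid("native prairie", 5, 5)
        layer = one_threat(np.zeros((5, 5), dtype=int))
        assert degradation(grid, [layer], FULL_SENS).values.max() == 0.0

    def test_empty_threat_list_warns_and_returns_zero(self, caplog):
        grid = uniform_grid("native prairie", 3, 3)
        with caplog.at_level("WARNING"):
            d = degradation(grid, [], FULL_SENS)
        assert d.values.max() == 0.0
        assert any("no threat" in rec.message for rec in caplog.records)

    def test_single_pair_matches_hand_computation(self):
        # threat pixel one 30 m step from the focal pixel, w=1, d_max=90, S=1
        grid = uniform_grid("native prairie", 1, 2)
        presence = np.array([[1, 0]])
        d = degradation(grid, [one_threat(presence)], FULL_SENS)
        assert d.values[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert d.values[0, 0] == pytest.approx(1.0, abs=1e-12)  # self-degradation

    def test_single_threat_invariant_to_weight_rescaling(self):
        grid = uniform_grid("native prairie", 7, 7)
        presence = np.zeros((7, 7), dtype=int)
        presence[3, 3] = 1
        d1 = degradation(grid, [one_threat(presence, weight=1.0)], FULL_SENS)
        d2 = degradation(grid, [one_threat(presence, weight=0.25)], FULL_SENS)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_adding_threat_pixel_never_decreases_d(self, params):
        grid = uniform_grid("native prairie", 9, 9)
        base = np.zeros((9, 9), dtype=int)
        base[2, 2] = 1
        more = base.copy()
        more[6, 6] = 1
        d0 = degradation(grid, [one_threat(base)], FULL_SENS)
        d1 = degradation(grid, [one_threat(more)], FULL_SENS)
        assert np.all(d1.values >= d0.values - 1e-12)
        q0 = quality(HabitatRaster(grid.spec, np.ones((9, 9))), d0)
        q1 = quality(HabitatRaster(grid.spec, np.ones((9, 9))), d1)
        assert np.all(q1.values <= q0.values + 1e-12)

    def test_locality_beyond_dmax(self):
        grid = uniform_grid("native prairie", 9, 9)
        presence = np.zeros((9, 9), dtype=int)
        presence[0, 0] = 1
        layer = one_threat(presence, d_max=60.0)
        d = degradation(grid, [layer], FULL_SENS)
        X, Y = grid.spec.cell_centers()
        dist = np.hypot(X - X[0, 0], Y - Y[0, 0])
        assert np.all(d.values[dist >= 60.0] == 0.0)
        h = HabitatRaster(grid.spec, np.full((9, 9), 0.8))
        q = quality(h, d)
        np.testing.assert_array_equal(q.values[dist >= 60.0], 0.8)

    def test_mixed_threats_match_bruteforce(self, rng):
        # 9x9 grid, two threats (weights 0.8 / 0.4), scattered pixels, mixed S
        names = [
            [
                ["native prairie", "small grains", "row crop"][rng.integers(3)]
                for _ in range(9)
            ]
            for _ in range(9)
        ]
        grid = grid_from_names(names)
        sens = SensitivityTable(
            {
                ("native prairie", "a"): 1.0,
                ("native prairie", "b"): 0.5,
                ("small grains", "a"): 0.5,
                ("small grains", "b"): 0.0,
            }
        )
        layers = []
        for name, w, dmax in (("a", 0.8, 120.0), ("b", 0.4, 75.0)):
            presence = np.zeros((9, 9), dtype=int)
            idx = rng.choice(81, size=3, replace=False)
            presence.flat[idx] = 1
            layers.append(ThreatLayer(ThreatSpec(name, w, dmax), presence))
        fast = degradation(grid, layers, sens)
        slow = degradation_bruteforce(grid, layers, sens)
        assert np.abs(fast.values - slow.values).max() < 1e-9

    def test_zero_weight_sum_rejected(self):
        grid = uniform_grid("native prairie", 3, 3)
        layer = one_threat(np.ones((3, 3), dtype=int), weight=0.0)
        with pytest.raises(ValueError):
            degradation(grid, [layer], FULL_SENS)

    def test_bruteforce_guard_refuses_large_grids(self):
        grid = uniform_grid("native prairie", 130, 2)
        layer = one_threat(np.zeros((130, 2), dtype=int))
        with pytest.raises(ValueError, match="128"):
            degradation_bruteforce(grid, [layer], FULL_SENS)


class TestQualityTransform:
    def setup_method(self):
        self.spec = GridSpec(3, 3)
        self.h = HabitatRaster(self.spec, np.full((3, 3), 0.8))

    def test_zero_degradation_preserves_habitat(self):
        from prairieq.quality import DegradationRaster

        q = quality(self.h, DegradationRaster(self.spec, np.zeros((3, 3))))
        np.testing.assert_array_equal(q.values, self.h.values)

    @pytest.mark.parametrize("z", [0.5, 1.0, 2.5, 4.0])
    def test_half_saturation_halves_quality_for_any_exponent(self, z):
        from prairieq.quality import DegradationRaster

        params = QualityParams(half_saturation=0.2, exponent=z)
        d = DegradationRaster(self.spec, np.full((3, 3), 0.2))
        q = quality(self.h, d, params)
        np.testing.assert_allclose(q.values, self.h.values / 2, atol=1e-12)

    def test_zero_habitat_stays_zero(self):
        from prairieq.quality import DegradationRaster

        h0 = HabitatRaster(self.spec, np.zeros((3, 3)))
        d = DegradationRaster(self.spec, np.full((3, 3), 5.0))
        assert quality(h0, d).values.max() == 0.0

    def test_quality_monotone_decreasing_in_degradation(self):
        from prairieq.quality import DegradationRaster

        ds = np.linspace(0, 3, 50)
        q = [
            quality(
                HabitatRaster(GridSpec(1, 1), np.array([[1.0]])),
                DegradationRaster(GridSpec(1, 1), np.array([[d]])),
            ).values[0, 0]
            for d in ds
        ]
        assert np.all(np.diff(q) < 0)


def test_invalid_threat_parameters_rejected():
    with pytest.raises(ValueError):
        ThreatSpec("t", 1.2, 100.0)
    with pytest.raises(ValueError):
        ThreatSpec("t", 0.5, 0.0)
    with pytest.raises(ValueError):
        ThreatSpec("t", 0.5, 100.0, decay="exponential")
    with pytest.raises(ValueError):
        ThreatLayer(ThreatSpec("t", 0.5, 100.0), np.array([[0, 2]]))
    with pytest.raises(ValueError):
        SensitivityTable({("a", "t"): 1.5})
    with pytest.raises(ValueError):
        QualityParams(half_saturation=0.0)
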