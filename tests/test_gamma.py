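"""Gamma-index analysis: oracle equivalence and limiting behaviour."""

import numpy as np
import pytest

from thermoplan.gamma import (
    GammaConfig,
    accuracy_bias,
    gamma_map,
    passing_rate,
)


def brute_force_gamma(ref, ev, spacing, dd_abs, dta, radius):
    """Independent exhaustive minimisation over in-bounds voxel offsets."""
    out = np.zeros(ref.shape)
    shape = ref.shape
    offs = []
    for di in range(-shape[0] + 1, shape[0]):
        for dj in range(-shape[1] + 1, shape[1]):
            for dk in range(-shape[2] + 1, shape[2]):
                d2 = (di * spacing[0]) ** 2 + (dj * spacing[1]) ** 2 + (dk * spacing[2]) ** 2
                if d2 <= radius**2 + 1e-12:
                    offs.append((di, dj, dk, d2))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                best = np.inf
                for di, dj, dk, d2 in offs:
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]:
                        g2 = (ref[i, j, k] - ev[ii, jj, kk]) ** 2 / dd_abs**2 + d2 / dta**2
                        best = min(best, g2)
                out[i, j, k] = np.sqrt(best)
    return out


def test_identical_volumes_give_zero_gamma_and_full_passing():
    rng = np.random.default_rng(7)
    vol = rng.random((8, 8, 8))
    cfg = GammaConfig(dd_percent=1.0, dta_mm=0.5)
    g = gamma_map(vol, vol.copy(), (0.5, 0.5, 0.5), cfg)
    assert np.allclose(g, 0.0)
    assert passing_rate(g) == 100.0


def test_uniform_dose_offset_of_exactly_dd_gives_gamma_one():
    # binary-exact values so gamma is exactly 1: DD_abs = 25% of 8 = 2
    ref = np.full((6, 6, 6), 8.0)
    cfg = GammaConfig(dd_percent=25.0, dta_mm=1.0, normalization=8.0)
    ev = ref + 2.0  # exactly DD_abs above the reference everywhere
    g = gamma_map(ref, ev, (1.0, 1.0, 1.0), cfg)
    assert np.allclose(g, 1.0)
    # passing convention: gamma <= 1 passes, gamma < 1 does not
    assert passing_rate(g, pass_leq=True) == 100.0
    assert passing_rate(g, pass_leq=False) == 0.0


def test_matches_brute_force_oracle_on_random_volumes():
    rng = np.random.default_rng(42)
    ref = rng.random((9, 9, 9))
    ev = ref + rng.normal(0, 0.02, ref.shape)
    spacing = (0.5, 0.5, 0.5)
    cfg = GammaConfig(dd_percent=1.0, dta_mm=0.5, normalization=1.0)
    g = gamma_map(ref, ev, spacing, cfg, interpolate=False)
    expected = brute_force_gamma(ref, ev, spacing, 0.01, 0.5, cfg.search_radius)
    assert np.allclose(g, expected, atol=1e-12)


def test_spatial_shift_within_dta_passes():
    # a feature shifted by one voxel passes when DTA covers the shift
    ref = np.zeros((12, 5, 5))
    ref[6, 2, 2] = 1.0
    ev = np.zeros_like(ref)
    ev[7, 2, 2] = 1.0
    spacing = (1.0, 1.0, 1.0)
    strict = gamma_map(ref, ev, spacing, GammaConfig(1.0, 0.5, normalization=1.0),
                       interpolate=False)
    lenient = gamma_map(ref, ev, spacing, GammaConfig(1.0, 2.0, normalization=1.0),
                        interpolate=False)
    assert strict[6, 2, 2] > 1.0
    assert lenient[6, 2, 2] <= 1.0


def test_enlarging_criteria_never_decreases_passing_rate():
    rng = np.random.default_rng(3)
    ref = rng.random((7, 7, 7))
    ev = ref + rng.normal(0, 0.05, ref.shape)
    spacing = (1.0, 1.0, 1.0)
    # sampling held fixed so only the criteria change
    fixed = dict(normalization=1.0, search_radius=6.0, interp_step=0.25)
    base = gamma_map(ref, ev, spacing, GammaConfig(1.0, 0.5, **fixed))
    for dd, dta in [(2.0, 0.5), (1.0, 1.0), (3.0, 2.0)]:
        g = gamma_map(ref, ev, spacing, GammaConfig(dd, dta, **fixed))
        assert np.all(g <= base + 1e-9)
        assert passing_rate(g) >= passing_rate(base)


def test_interpolation_finds_subvoxel_agreement():
    # linear ramp shifted by half a voxel: brute force fails at DTA < spacing,
    # sub-voxel interpolation recovers agreement
    x = np.arange(10.0)
    ref = np.broadcast_to(x[:, None, None], (10, 4, 4)).copy()
    ev = ref + 0.5  # equals ref shifted by half a voxel along x
    cfg = GammaConfig(dd_percent=1.0, dta_mm=0.6, normalization=10.0, interp_step=0.25)
    g_interp = gamma_map(ref, ev, (1.0, 1.0, 1.0), cfg)
    inner = g_interp[1:-1]
    assert np.all(inner <= 1.0)


def test_passing_rate_counts():
    g = np.concatenate([np.full(50, 0.5), np.full(50, 1.5)]).reshape(10, 10, 1)
    assert passing_rate(g, np.ones(g.shape, bool)) == 50.0
    assert passing_rate(np.full((3, 3, 3), 2.0), np.ones((3, 3, 3), bool)) == 0.0


def test_accuracy_and_bias_examples():
    rng = np.random.default_rng(11)
    ref = rng.random((6, 6, 6)) * 8.0
    acc, bias = accuracy_bias(ref, ref)
    assert acc == 0.0 and bias == 0.0
    ev = ref + 0.01 * ref.max()
    acc, bias = accuracy_bias(ref, ev)
    assert acc == pytest.approx(1.0)
    assert bias == pytest.approx(1.0)
    # alternating +-1% of max cancels in the mean but not in the magnitude
    signs = np.indices(ref.shape).sum(axis=0) % 2 * 2 - 1
    ev = ref + signs * 0.01 * ref.max()
    acc, bias = accuracy_bias(ref, ev)
    assert acc == pytest.approx(1.0)
    assert abs(bias) < 0.01
    assert abs(bias) <= acc


def test_invalid_inputs_rejected():
    vol = np.ones((4, 4, 4))
    cfg = GammaConfig(1.0, 0.5)
    with pytest.raises(ValueError):
        gamma_map(vol, vol, (1, 1, 1), cfg, voi=np.zeros(vol.shape, bool))
    with pytest.raises(ValueError):
        gamma_map(np.zeros((4, 4, 4)), vol, (1, 1, 1), cfg)  # zero normalisation
    with pytest.raises(ValueError):
        GammaConfig(dd_percent=0.0, dta_mm=1.0)
    with pytest.raises(ValueError):
        GammaConfig(dd_percent=1.0, dta_mm=1.0, search_radius=0.5)
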