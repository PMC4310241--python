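"""Neutrosophic transform and α-means, checked against a literal
triple-loop transliteration of the defining formulas."""

import numpy as np
import pytest

from coroseg import (AlphaParams, alpha_means, dwt3, idwt3, local_mean,
                     to_neutrosophic, true_volume)


# ---------------------------------------------------------------------------
# independent oracle: direct loops over the defining sums, no shared code
# ---------------------------------------------------------------------------

def oracle_local_mean(band, w, mode, use_abs):
    src = np.abs(band) if use_abs else band
    n = band.shape
    out = np.zeros_like(src, dtype=float)
    half = w // 2
    upper = (w + 1) // 2  # literal forward bound round(i + w/2) - i, half-up
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                acc = 0.0
                if mode == "centered":
                    rng_i = range(i - half, i + half + 1)
                    rng_j = range(j - half, j + half + 1)
                    rng_k = range(k - half, k + half + 1)
                else:
                    rng_i = range(i, i + upper + 1)
                    rng_j = range(j, j + upper + 1)
                    rng_k = range(k, k + upper + 1)
                for l in rng_i:
                    for m in rng_j:
                        for o in rng_k:
                            acc += src[min(max(l, 0), n[0] - 1),
                                       min(max(m, 0), n[1] - 1),
                                       min(max(o, 0), n[2] - 1)]
                out[i, j, k] = acc / w**3
    return out


def oracle_memberships(band, w, mode):
    hbar = oracle_local_mean(band, w, mode, use_abs=True)
    T = (hbar - hbar.min()) / (hbar.max() - hbar.min()) \
        if hbar.max() > hbar.min() else np.zeros_like(hbar)
    delta = np.abs(band - hbar)
    U = (delta - delta.min()) / (delta.max() - delta.min()) \
        if delta.max() > delta.min() else np.zeros_like(delta)
    return T, 1.0 - T, U


def oracle_alpha_means(T, U, alpha, w, mode):
    t_bar = oracle_local_mean(T, w, mode, use_abs=False)
    T_new = np.where(U >= alpha, t_bar, T)
    t_bar_bar = oracle_local_mean(t_bar, w, mode, use_abs=False)
    d = np.abs(t_bar - t_bar_bar)
    U_new = (d - d.min()) / (d.max() - d.min()) \
        if d.max() > d.min() else np.zeros_like(d)
    return T_new, 1.0 - T_new, U_new


# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode", ["centered", "literal"])
@pytest.mark.parametrize("use_abs", [True, False])
def test_local_mean_matches_loop_oracle(rng, mode, use_abs):
    band = rng.normal(size=(6, 6, 6))
    params = AlphaParams(window=3, window_mode=mode,
                         magnitude_mode="abs" if use_abs else "raw")
    np.testing.assert_allclose(local_mean(band, params),
                               oracle_local_mean(band, 3, mode, use_abs),
                               atol=1e-12)


def test_local_mean_closed_forms():
    const = np.full((5, 5, 5), -3.0)
    assert np.all(local_mean(const, AlphaParams()) == 3.0)          # abs mode
    assert np.all(local_mean(const, AlphaParams(magnitude_mode="raw")) == -3.0)
    ramp = np.broadcast_to(np.arange(7.0)[:, None, None], (7, 7, 7)).copy()
    lm = local_mean(ramp, AlphaParams(magnitude_mode="raw"))
    np.testing.assert_allclose(lm[1:-1, 1:-1, 1:-1],
                               ramp[1:-1, 1:-1, 1:-1], atol=1e-12)
    with pytest.raises(ValueError):
        local_mean(np.zeros((2, 6, 6)), AlphaParams())


@pytest.mark.parametrize("mode", ["centered", "literal"])
def test_memberships_match_formula_oracle(rng, mode):
    band = rng.normal(size=(6, 6, 6))
    params = AlphaParams(window_mode=mode)
    field = to_neutrosophic(band, params)
    T, F, U = oracle_memberships(band, 3, mode)
    np.testing.assert_allclose(field.T, T, atol=1e-12)
    np.testing.assert_allclose(field.F, F, atol=1e-12)
    np.testing.assert_allclose(field.U, U, atol=1e-12)
    assert np.all(field.T + field.F == pytest.approx(1.0))
    for g in (field.T, field.F, field.U):
        assert g.min() >= 0.0 and g.max() <= 1.0


def test_membership_endpoints_and_degenerate_case(rng):
    band = rng.normal(size=(6, 6, 6))
    field = to_neutrosophic(band)
    hbar = local_mean(band, AlphaParams())
    lo = np.unravel_index(hbar.argmin(), hbar.shape)
    hi = np.unravel_index(hbar.argmax(), hbar.shape)
    assert field.T[lo] == 0.0 and field.F[lo] == 1.0
    assert field.T[hi] == 1.0 and field.F[hi] == 0.0
    const = to_neutrosophic(np.full((5, 5, 5), 2.0))
    assert np.all(const.T == 0.0) and np.all(const.F == 1.0)
    assert np.all(const.U == 0.0)


@pytest.mark.parametrize("mode", ["centered", "literal"])
def test_alpha_means_matches_formula_oracle(rng, mode):
    band = rng.normal(size=(6, 6, 6))
    params = AlphaParams(alpha=0.2, window_mode=mode)
    field = to_neutrosophic(band, params)
    out = alpha_means(field, band, params)
    T, F, U = oracle_alpha_means(field.T, field.U, 0.2, 3, mode)
    np.testing.assert_allclose(out.T, T, atol=1e-12)
    np.testing.assert_allclose(out.F, F, atol=1e-12)
    np.testing.assert_allclose(out.U, U, atol=1e-12)


def test_alpha_means_identity_and_full_smoothing(rng):
    band = rng.normal(size=(6, 6, 6))
    field = to_neutrosophic(band)
    same = alpha_means(field, band, AlphaParams(alpha=1.01))
    np.testing.assert_array_equal(same.T, field.T)
    np.testing.assert_array_equal(same.U, field.U)
    full = alpha_means(field, band, AlphaParams(alpha=0.0))
    smoothed = local_mean(field.T, AlphaParams(magnitude_mode="raw"))
    # U >= 0 everywhere, so T is replaced by its local mean everywhere
    np.testing.assert_allclose(full.T, smoothed, atol=1e-12)
    with pytest.raises(ValueError):
        alpha_means(field, band[:-1], AlphaParams())


def test_alpha_means_reduces_mean_uncertainty_on_phantom_band(quick_phantom):
    """The stated purpose of α-means is uncertainty reduction.  The smoothed
    field's deviations are re-normalized to their own extrema, so the count
    above any fixed threshold is not comparable across the two scales; the
    mean indeterminacy is, and must not increase."""
    sb = dwt3(quick_phantom.volume)
    hhh = sb.bands["HHH"]
    params = AlphaParams(alpha=0.2)
    field = to_neutrosophic(hhh, params)
    out = alpha_means(field, hhh, params)
    assert out.U.mean() <= field.U.mean()


class TestTrueVolume:
    def test_identity_weighting_reconstructs_input(self, rng):
        v = rng.normal(size=(8, 8, 8))
        sb = dwt3(v)
        field = to_neutrosophic(sb.bands["HHH"])
        field.T[...] = 1.0
        field.F[...] = 0.0
        out = true_volume(sb, field, mode="weight")
        np.testing.assert_allclose(out.values, v, atol=1e-9)

    def test_zero_weighting_removes_hhh_only(self, rng):
        v = rng.normal(size=(8, 8, 8))
        sb = dwt3(v)
        field = to_neutrosophic(sb.bands["HHH"])
        field.T[...] = 0.0
        field.F[...] = 1.0
        out = true_volume(sb, field, mode="weight")
        zeroed = dwt3(v)
        zeroed.bands["HHH"] = np.zeros_like(zeroed.bands["HHH"])
        np.testing.assert_allclose(out.values, idwt3(zeroed).values, atol=1e-9)

    def test_half_weighting_by_idwt_linearity(self, rng):
        v = rng.normal(size=(8, 8, 8))
        sb = dwt3(v)
        field = to_neutrosophic(sb.bands["HHH"])
        field.T[...] = 0.5
        field.F[...] = 0.5
        out = true_volume(sb, field, mode="weight")
        hhh_only = dwt3(v)
        for label in hhh_only.bands:
            if label != "HHH":
                hhh_only.bands[label] = np.zeros_like(hhh_only.bands[label])
        expected = v - 0.5 * idwt3(hhh_only).values
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_rescale_mode_and_shape_mismatch(self, rng):
        v = rng.normal(size=(8, 8, 8))
        sb = dwt3(v)
        field = to_neutrosophic(sb.bands["HHH"])
        out = true_volume(sb, field, mode="rescale")
        assert out.shape == (8, 8, 8)
        with pytest.raises(ValueError):
            true_volume(sb, field, mode="nope")


def test_alpha_params_validation():
    for bad in (dict(alpha=-0.1), dict(window=2), dict(window=1),
                dict(window_mode="x"), dict(magnitude_mode="x")):
        with pytest.raises(ValueError):
            AlphaParams(**bad)
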