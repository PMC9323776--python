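"""Spectral preprocessing, PLS calibration/CV, and external validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from palmfiber.chemometrics import (
    ExternalValidation,
    PreprocessChain,
    PreprocessStep,
    SpectraMatrix,
    T_CRITICAL_3,
    cross_validate,
    external_validate,
    fit_pls,
    paired_t_test,
    select_factors,
    sg_first_derivative,
    snv,
    vector_normalize,
)
from palmfiber.simulate import MixtureSimConfig, simulate_components, simulate_spectra

spectrum_arrays = st.lists(
    st.floats(-5, 5, allow_nan=False), min_size=8, max_size=64
).map(np.asarray).filter(lambda a: a.std() > 1e-6)


# ---------------------------------------------------------------------------
# preprocessing


def test_vector_normalize_examples():
    np.testing.assert_allclose(vector_normalize(np.array([3.0, 4.0])), [0.6, 0.8])
    with pytest.raises(ValueError):
        vector_normalize(np.zeros(4))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(spectrum_arrays)
def test_vector_normalize_idempotent_unit_norm(a):
    once = vector_normalize(a)
    assert np.linalg.norm(once) == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(vector_normalize(once), once, atol=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(spectrum_arrays, st.floats(-10, 10), st.floats(0.01, 100))
def test_snv_affine_invariant(a, offset, scale):
    out = snv(a)
    assert out.mean() == pytest.approx(0.0, abs=1e-9)
    assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(snv(offset + scale * a), out, atol=1e-7)


def test_snv_matches_direct_formula(rng):
    a = rng.normal(size=200)
    np.testing.assert_allclose(
        snv(a), (a - a.mean()) / a.std(ddof=1), atol=1e-12
    )
    with pytest.raises(ValueError):
        snv(np.full(10, 2.5))


def test_sg_derivative_linear_and_constant():
    grid = np.arange(4000.0, 5000.0, 4.0)
    slope = 3.5e-4
    deriv = sg_first_derivative(slope * grid + 2.0, grid, window=15, polyorder=2)
    interior = deriv[14:-14]
    np.testing.assert_allclose(interior, slope, rtol=1e-8)
    flat = sg_first_derivative(np.full_like(grid, 1.3), grid)
    np.testing.assert_allclose(flat, 0.0, atol=1e-12)


def test_sg_derivative_quadratic_matches_analytic():
    grid = np.arange(4000.0, 6000.0, 4.0)
    x = (grid - 5000.0) / 1000.0
    deriv = sg_first_derivative(x**2, grid, window=15, polyorder=2)
    analytic = 2.0 * x / 1000.0
    np.testing.assert_allclose(deriv[14:-14], analytic[14:-14], atol=1e-6)


@pytest.mark.parametrize("window,polyorder", [(14, 2), (3, 5), (9001, 2)])
def test_sg_derivative_invalid_params(window, polyorder):
    grid = np.arange(4000.0, 4400.0, 4.0)
    with pytest.raises(ValueError):
        sg_first_derivative(np.ones_like(grid), grid, window, polyorder)


def test_chain_rejects_unknown_step():
    with pytest.raises(ValueError):
        PreprocessChain(["fourier_phase_scramble"])


def test_chain_applies_rowwise(rng):
    grid = np.arange(4000.0, 4400.0, 4.0)
    spectra = rng.normal(size=(5, grid.size)) + 2.0
    chain = PreprocessChain.default()
    together = chain.apply(spectra, grid)
    for i in range(5):
        np.testing.assert_allclose(together[i], chain.apply(spectra[i], grid), atol=1e-12)


# ---------------------------------------------------------------------------
# PLS calibration


@pytest.fixture(scope="module")
def clean_mixtures():
    """Noise-free, scatter-free 3-component mixtures (exact linear system)."""
    cfg = MixtureSimConfig(
        noise_sd=0.0,
        scatter=(0.0, 0.0),
        baseline_offset=(0.0, 0.0),
        baseline_slope=(0.0, 0.0),
        grid_stop=9000.0,
    )
    comps = simulate_components(cfg, seed=21)
    return simulate_spectra(comps, cfg, seed=21)


@pytest.fixture(scope="module")
def default_mixtures():
    cfg = MixtureSimConfig()
    comps = simulate_components(cfg, seed=8)
    return simulate_spectra(comps, cfg, seed=8), cfg


def test_noise_free_pls_interpolates(clean_mixtures):
    data = clean_mixtures.matrix("cellulose")
    res = fit_pls(data, chain=PreprocessChain([]), n_factors=3)
    assert res.rmsec < 1e-6
    assert res.r2c > 1 - 1e-12


def test_constant_response_predicts_constant(clean_mixtures):
    data = clean_mixtures.matrix("cellulose")
    data = SpectraMatrix(data.grid, data.absorbance, np.full(data.n_samples, 42.0))
    res = fit_pls(data, chain=PreprocessChain([]), n_factors=2)
    np.testing.assert_allclose(res.predict_matrix(data), 42.0, atol=1e-8)


def test_permuting_samples_leaves_regression_vector(default_mixtures, rng):
    spectra, _ = default_mixtures
    data = spectra.matrix("lignin")
    perm = rng.permutation(data.n_samples)
    res1 = fit_pls(data, n_factors=4)
    res2 = fit_pls(data.subset(perm), n_factors=4)
    np.testing.assert_allclose(
        res1.regression_vector, res2.regression_vector, atol=1e-10
    )


def test_loo_matches_brute_force_oracle(default_mixtures):
    """cross_validate's held-out predictions equal an explicit refit loop."""
    spectra, _ = default_mixtures
    data = spectra.matrix("cellulose")
    stats = cross_validate(data, n_factors=4)
    preds = np.empty(data.n_samples)
    for i in range(data.n_samples):
        train = np.delete(np.arange(data.n_samples), i)
        res = fit_pls(data.subset(train), n_factors=4)
        preds[i] = res.predict_matrix(data.subset([i]))[0]
    rmsep = np.sqrt(np.mean((preds - data.reference) ** 2))
    assert stats.rmsep == pytest.approx(rmsep, rel=1e-10)


def test_cv_r2_not_clamped(rng):
    """Uninformative predictors + noise response give r2cv <= 0, reported as-is."""
    grid = np.arange(4000.0, 4400.0, 4.0)
    data = SpectraMatrix(grid, rng.normal(size=(20, grid.size)), rng.normal(size=20))
    stats = cross_validate(data, chain=PreprocessChain([]), n_factors=2)
    assert stats.r2cv < 0.5  # typically negative; never clamped to [0, 1]


def test_select_factors_known_rank(clean_mixtures):
    data = clean_mixtures.matrix("hemicellulose")
    assert select_factors(data, chain=PreprocessChain([]), max_factors=6) == 3


def test_select_factors_single_component():
    cfg = MixtureSimConfig(
        ranges={"cellulose": (10.0, 80.0)},
        total_range=(0.0, 100.0),
        noise_sd=0.0,
        scatter=(0.0, 0.0),
        baseline_offset=(0.0, 0.0),
        baseline_slope=(0.0, 0.0),
    )
    comps = simulate_components(cfg, seed=3)
    spectra = simulate_spectra(comps, cfg, seed=3)
    data = spectra.matrix("cellulose")
    assert select_factors(data, chain=PreprocessChain([]), max_factors=4) == 1


def test_pls_accuracy_and_noise_monotonicity():
    """Default-condition r2cv is high for the wide-range components and
    degrades monotonically as additive noise grows."""
    cfg = MixtureSimConfig()
    comps = simulate_components(cfg, seed=8)
    spectra = simulate_spectra(comps, cfg, seed=8)
    for component in ("cellulose", "lignin"):
        stats = cross_validate(spectra.matrix(component), n_factors=6)
        assert stats.r2cv >= 0.95
    r2s = []
    for noise in (0.002, 0.05, 0.5):
        sp = simulate_spectra(comps, MixtureSimConfig(noise_sd=noise), seed=8)
        r2s.append(cross_validate(sp.matrix("cellulose"), n_factors=6).r2cv)
    assert r2s[0] > r2s[1] > r2s[2]


# ---------------------------------------------------------------------------
# external validation


PRINTED_PAIRS = {
    "cellulose": ([57.67, 37.93, 80.58], [58.88, 38.76, 78.48], 0.019),
    "hemicellulose": ([13.19, 12.23, 14.12], [13.53, 11.83, 14.46], 0.378),
    "lignin": ([20.66, 30.82, 3.94], [21.10, 31.55, 3.85], 1.500),
}


@pytest.mark.parametrize("component", list(PRINTED_PAIRS))
def test_t_test_reproduces_printed_values(component):
    measured, predicted, expected = PRINTED_PAIRS[component]
    t_abs, df = paired_t_test(measured, predicted)
    assert df == 2
    assert round(t_abs, 3) == expected
    val = ExternalValidation.from_pairs(measured, predicted)
    assert not val.significant and val.t_critical == T_CRITICAL_3
    np.testing.assert_allclose(
        val.abs_error, np.abs(np.subtract(measured, predicted)), atol=1e-12
    )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    st.lists(st.floats(0.1, 99.0), min_size=3, max_size=3),
    st.lists(st.floats(0.1, 99.0), min_size=3, max_size=3),
)
def test_t_test_matches_independent_formula(measured, predicted):
    d = np.subtract(predicted, measured)
    t_abs, _ = paired_t_test(measured, predicted)
    if d.std(ddof=1) == 0:
        assert t_abs == (0.0 if d.mean() == 0 else math.inf)
    else:
        ref = sps.ttest_rel(predicted, measured)
        assert t_abs == pytest.approx(abs(ref.statistic), rel=1e-10)


def test_t_test_degenerate_cases():
    assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[0] == 0.0
    t, _ = paired_t_test([1.0, 2.0], [2.0, 3.0])  # constant nonzero shift
    assert t == math.inf
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_external_validate_end_to_end(default_mixtures):
    spectra, _ = default_mixtures
    data = spectra.matrix("cellulose")
    train = np.arange(0, data.n_samples - 3)
    hold = np.arange(data.n_samples - 3, data.n_samples)
    res = fit_pls(data.subset(train), n_factors=5)
    val = external_validate(res, data.subset(hold))
    assert val.df == 2
    assert np.isfinite(val.t_abs)
    with pytest.raises(ValueError):
        external_validate(res, data.subset([0]))
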