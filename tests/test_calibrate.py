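"""System-characterization normalization, homogeneous fitting, model offsets."""

import numpy as np
import pytest

from specdot import calibrate as cal
from specdot import phantoms
from specdot.fem import MeasurementSet


@pytest.fixture(scope="module")
def homogeneous_data(coarse_block, coarse_block_optodes):
    hom = phantoms.homogeneous_like(coarse_block)
    data = phantoms.simulate_phantom_data(hom, coarse_block_optodes,
                                          wavelengths=(730.0,))
    return hom, data


def _unit_char(optodes, wavelengths):
    return cal.SystemCharacterization(
        {i: 1.0 for i in range(len(optodes.sources))},
        {l: 1.0 for l in wavelengths})


def test_normalize_identity_factors(homogeneous_data, coarse_block_optodes):
    _, data = homogeneous_data
    out = cal.normalize_raw(data, _unit_char(coarse_block_optodes, [730.0]))
    np.testing.assert_array_equal(out.amplitudes(), data.amplitudes())


def test_normalize_halves_one_sources_links(homogeneous_data,
                                            coarse_block_optodes):
    _, data = homogeneous_data
    char = _unit_char(coarse_block_optodes, [730.0])
    victim = int(data.table["source"].iloc[0])
    char.source_strength[victim] = 2.0
    out = cal.normalize_raw(data, char)
    hit = data.table["source"].to_numpy() == victim
    np.testing.assert_allclose(out.amplitudes()[hit],
                               data.amplitudes()[hit] / 2.0, rtol=1e-15)
    np.testing.assert_array_equal(out.amplitudes()[~hit],
                                  data.amplitudes()[~hit])


def test_normalize_roundtrip_recovers_truth(homogeneous_data,
                                            coarse_block_optodes):
    """raw = truth x factors; normalization inverts to 1e-12 relative."""
    _, truth = homogeneous_data
    rng = np.random.default_rng(5)
    char = cal.SystemCharacterization(
        {i: float(f) for i, f in enumerate(
            rng.uniform(0.5, 2.0, len(coarse_block_optodes.sources)))},
        {730.0: 1.37})
    factors = np.array([char.factor(s, l) for s, l in
                        zip(truth.table["source"], truth.table["wavelength"])])
    raw = truth.with_amplitudes(truth.amplitudes() * factors, role="raw")
    out = cal.normalize_raw(raw, char)
    np.testing.assert_allclose(out.amplitudes(), truth.amplitudes(), rtol=1e-12)


def test_normalize_missing_factor_names_the_source(homogeneous_data,
                                                   coarse_block_optodes):
    _, data = homogeneous_data
    char = _unit_char(coarse_block_optodes, [730.0])
    victim = int(data.table["source"].iloc[0])
    del char.source_strength[victim]
    with pytest.raises(KeyError, match=str(victim)):
        cal.normalize_raw(data, char)


def test_homogeneous_fit_recovers_mua(homogeneous_data, coarse_block_optodes):
    """Noiseless homogeneous slab at 730 nm, musp fixed at truth: mua to 5%."""
    hom, data = homogeneous_data
    from specdot.spectra import musp_from_mie
    bg = hom.region_params[0]
    musp_truth = musp_from_mie(bg.a, bg.b, 730.0)
    mua, musp = cal.homogeneous_fit(data, hom.mesh, coarse_block_optodes,
                                    730.0, musp_prior=musp_truth)
    assert mua == pytest.approx(0.0179, rel=0.05)
    assert musp == musp_truth


def test_homogeneous_fit_is_a_fixed_point(homogeneous_data,
                                          coarse_block_optodes):
    """Data generated from the fitted values has ~zero residual."""
    hom, data = homogeneous_data
    from specdot.spectra import musp_from_mie
    bg = hom.region_params[0]
    musp_truth = musp_from_mie(bg.a, bg.b, 730.0)
    mua, _ = cal.homogeneous_fit(data, hom.mesh, coarse_block_optodes, 730.0,
                                 musp_prior=musp_truth)
    logF = cal._homog_log_forward(hom.mesh, coarse_block_optodes, mua,
                                  musp_truth, n_rel=1.33, c0=1.0)
    refit, _ = cal.homogeneous_fit(
        data.with_amplitudes(np.exp(logF)), hom.mesh, coarse_block_optodes,
        730.0, musp_prior=musp_truth, xatol=1e-9)
    r = logF - cal._homog_log_forward(hom.mesh, coarse_block_optodes, refit,
                                      musp_truth, n_rel=1.33, c0=1.0)
    assert float(r @ r) < 1e-10


def test_homogeneous_fit_noise_monte_carlo(coarse_block, coarse_block_optodes):
    """1% amplitude noise, 20 seeds: median recovered mua within 10%."""
    from specdot.spectra import musp_from_mie
    hom = phantoms.homogeneous_like(coarse_block)
    bg = hom.region_params[0]
    musp_truth = musp_from_mie(bg.a, bg.b, 730.0)
    fits = []
    for seed in range(20):
        data = phantoms.simulate_phantom_data(hom, coarse_block_optodes,
                                              wavelengths=(730.0,),
                                              noise_fraction=0.01, seed=seed)
        mua, _ = cal.homogeneous_fit(data, hom.mesh, coarse_block_optodes,
                                     730.0, musp_prior=musp_truth, xatol=1e-5)
        fits.append(mua)
    assert np.median(fits) == pytest.approx(0.0179, rel=0.10)


def test_homogeneous_fit_needs_two_separations(homogeneous_data):
    hom, data = homogeneous_data
    from specdot.meshing import OptodeSet
    z_top = hom.mesh.nodes[:, 2].max()
    opt1 = OptodeSet(np.array([[0.0, 0.0, 0.0]]),
                     np.array([[0.0, 0.0, z_top]]))
    one = MeasurementSet(data.table.iloc[:1].reset_index(drop=True))
    with pytest.raises(ValueError, match="separations"):
        cal.homogeneous_fit(one, hom.mesh, opt1, 730.0)


def test_offsets_trivials_and_identity(homogeneous_data):
    _, data = homogeneous_data
    zero = cal.compute_data_offset(data, data)
    assert np.allclose(zero["offset"], 0.0)
    shift = data.with_amplitudes(data.amplitudes() * np.exp(0.31), role="measured")
    off = cal.compute_data_offset(shift, data)
    np.testing.assert_allclose(off["offset"], 0.31, rtol=1e-12)
    # applying the offsets recovers the model exactly
    corrected = cal.apply_data_offset(shift, off)
    np.testing.assert_allclose(corrected.amplitudes(), data.amplitudes(),
                               rtol=1e-12)


def test_offset_link_mismatch_raises(homogeneous_data):
    _, data = homogeneous_data
    other = MeasurementSet(data.table.iloc[:-1].reset_index(drop=True))
    with pytest.raises(ValueError):
        cal.compute_data_offset(data, other)


def test_full_chain_recovers_ideal_dataset(coarse_block, coarse_block_optodes):
    """Known gains + per-link bias: calibrated heterogeneous data equals the
    ideal simulation up to a per-link constant that cancels in the offsets."""
    from specdot.spectra import musp_from_mie
    lams = (730.0, 850.0)
    opt = coarse_block_optodes
    het_ideal = phantoms.simulate_phantom_data(coarse_block, opt, wavelengths=lams)
    hom = phantoms.homogeneous_like(coarse_block)
    hom_ideal = phantoms.simulate_phantom_data(hom, opt, wavelengths=lams)
    rng = np.random.default_rng(9)
    char = cal.SystemCharacterization(
        {i: float(f) for i, f in enumerate(
            rng.uniform(0.5, 2.0, len(opt.sources)))},
        {730.0: 0.8, 850.0: 1.9})
    bias = rng.uniform(-0.2, 0.2, len(het_ideal))  # per-link log bias

    def corrupt(ms):
        f = np.array([char.factor(s, l) for s, l in
                      zip(ms.table["source"], ms.table["wavelength"])])
        return ms.with_amplitudes(ms.amplitudes() * f * np.exp(bias), role="raw")

    bg = coarse_block.region_params[0]
    musp_prior = {l: musp_from_mie(bg.a, bg.b, l) for l in lams}
    calibrated, result = cal.calibrate_dataset(
        corrupt(het_ideal), corrupt(hom_ideal), char, hom.mesh, opt, musp_prior)
    # gains and per-link biases cancel in the log-difference to the
    # homogeneous reference: calibrated het / model hom == ideal het / ideal hom
    for lam in lams:
        mua = result.bulk_mua[lam]
        logF = cal._homog_log_forward(hom.mesh, opt, mua, musp_prior[lam],
                                      n_rel=1.33, c0=1.0)
        lhs = np.log(calibrated.amplitudes(lam)) - logF
        rhs = np.log(het_ideal.amplitudes(lam)) - np.log(hom_ideal.amplitudes(lam))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_characterization_csv_roundtrip(tmp_path, coarse_block_optodes):
    char = cal.SystemCharacterization(
        {i: 1.0 + 0.1 * i for i in range(4)}, {690.0: 0.9, 730.0: 1.1})
    char.to_csv(tmp_path / "s.csv", tmp_path / "r.csv")
    back = cal.SystemCharacterization.from_csv(tmp_path / "s.csv",
                                               tmp_path / "r.csv")
    assert back.source_strength == char.source_strength
    assert back.spectral_response == char.spectral_response
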