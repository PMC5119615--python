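"""Jacobians, pixel basis, LM update and the reconstruction driver."""

import numpy as np
import pytest

from specdot import fem, phantoms, recon, spectra
from specdot.meshing import box_volume, volume_to_mesh
from specdot.recon import PixelBasis, ReconSettings, lm_update
from specdot.spectra import OpticalProps, SpectralParams


# ---------------------------------------------------------------------------
# adjoint Jacobian
# ---------------------------------------------------------------------------

def test_adjoint_jacobian_matches_finite_differences(small_slab_mesh,
                                                     small_slab_optodes,
                                                     homogeneous_props):
    """Adjoint vs forward-difference sensitivities, < 1e-3 relative on the
    dominant entries (mua perturbed at fixed kappa)."""
    mesh, opt, props = small_slab_mesh, small_slab_optodes, homogeneous_props
    J, amps0 = recon.jacobian_single_wavelength(mesh, props, opt)
    assert J.shape == (opt.n_links, mesh.n_nodes)
    rng = np.random.default_rng(0)
    h = 1e-6
    worst = 0.0
    for node in rng.choice(mesh.n_nodes, 6, replace=False):
        mua = props.mua.copy()
        mua[node] += h
        perturbed = OpticalProps(mua=mua, musp=props.musp, kappa=props.kappa)
        _, _, _, amps1 = recon.forward_amplitudes(mesh, perturbed, opt)
        fd = (np.log(amps1) - np.log(amps0)) / h
        col = J[:, node]
        big = np.abs(col) >= 0.1 * np.abs(col).max() + 1e-300
        worst = max(worst, np.max(np.abs(fd[big] - col[big]) / np.abs(fd[big])))
    assert worst < 1e-3


def test_jacobian_entries_nonpositive(small_slab_mesh, small_slab_optodes,
                                      homogeneous_props):
    """More absorption never increases transmitted amplitude."""
    J, _ = recon.jacobian_single_wavelength(small_slab_mesh, homogeneous_props,
                                            small_slab_optodes)
    assert J.max() <= 0.0


def test_jacobian_row_count_is_link_count(coarse_block, coarse_block_optodes):
    lam = 730.0
    props = fem.nodal_props(coarse_block.mesh, coarse_block.region_params,
                            coarse_block.table, lam)
    J, _ = recon.jacobian_single_wavelength(coarse_block.mesh, props,
                                            coarse_block_optodes)
    assert J.shape[0] == 504


# ---------------------------------------------------------------------------
# spectral Jacobian
# ---------------------------------------------------------------------------

def _unit_table(eps_values):
    lams = [690.0, 730.0]
    return spectra.ExtinctionTable(lams, ("c1",), [[e] for e in eps_values])


def test_spectral_jacobian_unit_extinction_stacks_mua_blocks(small_slab_mesh,
                                                             small_slab_optodes,
                                                             homogeneous_props):
    J, _ = recon.jacobian_single_wavelength(small_slab_mesh, homogeneous_props,
                                            small_slab_optodes)
    jacs = {690.0: J, 730.0: J}
    stacked = recon.spectral_jacobian(jacs, _unit_table([1.0, 1.0]),
                                      SpectralParams(concentrations={"c1": 1.0}))
    np.testing.assert_array_equal(stacked.spectral, np.vstack([J, J]))
    zero = recon.spectral_jacobian(jacs, _unit_table([0.0, 0.0]),
                                   SpectralParams(concentrations={"c1": 1.0}))
    assert np.all(zero.spectral == 0.0)


def test_spectral_jacobian_concentration_finite_difference(small_slab_mesh,
                                                           small_slab_optodes):
    """Perturbing one nodal concentration moves all wavelengths consistently."""
    mesh, opt = small_slab_mesh, small_slab_optodes
    table = spectra.phantom_dye_table().subset(wavelengths=[730.0, 850.0])
    conc = np.ones(mesh.n_nodes)
    musp = {730.0: 1.0662, 850.0: 0.9825}
    kappa0 = {lam: spectra.diffusion_coefficient(
        table.epsilon_of("dye", lam) * conc, musp[lam]) for lam in musp}

    def forward(c):
        out = []
        solved = {}
        for lam in sorted(musp):  # kappa held at the linearization point
            props = OpticalProps(mua=table.epsilon_of("dye", lam) * c,
                                 musp=np.full(mesh.n_nodes, musp[lam]),
                                 kappa=kappa0[lam])
            solved[lam] = recon.forward_amplitudes(mesh, props, opt)
            out.append(np.log(solved[lam][3]))
        return solved, np.concatenate(out)

    solved, log0 = forward(conc)
    jacs = {lam: recon.jacobian_single_wavelength(mesh, None, opt,
                                                  _solved=solved[lam])[0]
            for lam in sorted(musp)}
    stacked = recon.spectral_jacobian(jacs, table,
                                      SpectralParams(concentrations={"dye": 1.0}))
    node, h = mesh.n_nodes // 3, 1e-3  # mua step ~2e-5 mm^-1
    c2 = conc.copy()
    c2[node] += h
    _, log1 = forward(c2)
    fd = (log1 - log0) / h
    col = stacked.spectral[:, node]
    big = np.abs(col) >= 0.1 * np.abs(col).max()
    rel = np.abs(fd[big] - col[big]) / np.abs(fd[big])
    assert rel.max() < 1e-3


def test_spectral_jacobian_unknown_chromophore_errors(small_slab_mesh,
                                                      small_slab_optodes,
                                                      homogeneous_props):
    J, _ = recon.jacobian_single_wavelength(small_slab_mesh, homogeneous_props,
                                            small_slab_optodes)
    table = spectra.phantom_dye_table()
    params = SpectralParams(concentrations={"dye": 1.0})
    with pytest.raises(spectra.WavelengthLookupError):
        recon.spectral_jacobian({800.0: J}, table, params)


# ---------------------------------------------------------------------------
# LM update
# ---------------------------------------------------------------------------

def test_lm_update_scalar_case():
    assert lm_update(np.array([[1.0]]), np.array([0.5]), reg=0.0) == \
        pytest.approx(0.5)


def test_lm_update_huge_regularization_damps_step():
    rng = np.random.default_rng(1)
    J = rng.normal(size=(12, 6))
    r = rng.normal(size=12)
    step = lm_update(J, r, reg=1e12)
    assert np.linalg.norm(step) < 1e-6 * np.linalg.norm(r)


def test_lm_update_matches_dense_normal_equation_oracle():
    rng = np.random.default_rng(2)
    J = rng.normal(size=(10, 5))
    r = rng.normal(size=10)
    reg = 1.0
    alpha = reg * np.max(np.sum(J * J, axis=0))
    oracle = np.linalg.solve(J.T @ J + alpha * np.eye(5), J.T @ r)
    np.testing.assert_allclose(lm_update(J, r, reg), oracle, atol=1e-10)
    # wide system exercises the dual (J J^T) path against the same oracle
    Jw, rw = J.T, r[:5]
    alpha_w = reg * np.max(np.sum(Jw * Jw, axis=0))
    oracle_w = np.linalg.solve(Jw.T @ Jw + alpha_w * np.eye(10), Jw.T @ rw)
    np.testing.assert_allclose(lm_update(Jw, rw, reg), oracle_w, atol=1e-10)


# ---------------------------------------------------------------------------
# pixel basis
# ---------------------------------------------------------------------------

def test_basis_constant_field_roundtrips_exactly(small_slab_mesh):
    basis = PixelBasis.for_mesh(small_slab_mesh, pixel_size=4.0)
    v = np.full(small_slab_mesh.n_nodes, 3.7)
    c = basis.mesh_to_basis(v, small_slab_mesh)
    back = basis.basis_to_mesh(c, small_slab_mesh)
    np.testing.assert_allclose(back, v, atol=1e-10)


def test_basis_linear_ramp_roundtrips(small_slab_mesh):
    """Both maps are linear-exact, so a ramp survives the round trip."""
    basis = PixelBasis.for_mesh(small_slab_mesh, pixel_size=4.0)
    v = (1.0 + 0.2 * small_slab_mesh.nodes[:, 0]
         - 0.1 * small_slab_mesh.nodes[:, 2])
    c = basis.mesh_to_basis(v, small_slab_mesh)
    back = basis.basis_to_mesh(c, small_slab_mesh)
    np.testing.assert_allclose(back, v, atol=1e-10)


def test_single_voxel_constant_basis_is_volume_weighted_mean(small_slab_mesh):
    mesh = small_slab_mesh
    basis = PixelBasis(origin=mesh.nodes.min(axis=0),
                       extent=mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0),
                       dims=(1, 1, 1), order="constant")
    rng = np.random.default_rng(3)
    v = rng.uniform(1, 2, mesh.n_nodes)
    c = basis.mesh_to_basis(v, mesh)
    vol = mesh.element_volumes()
    w = np.zeros(mesh.n_nodes)
    for k in range(4):
        np.add.at(w, mesh.elements[:, k], vol / 4)
    assert c[0] == pytest.approx(np.sum(w * v) / np.sum(w), rel=1e-12)


def test_basis_coverage_error():
    mesh = volume_to_mesh(box_volume((8, 8, 8), 2.0))
    basis = PixelBasis(origin=(0, 0, 0), extent=(4, 8, 8), dims=(2, 4, 4))
    with pytest.raises(recon.CoverageError):
        basis.interpolation_matrix(mesh)


def test_map_mesh_basis_direction_dispatch(small_slab_mesh):
    basis = PixelBasis.for_mesh(small_slab_mesh, pixel_size=4.0)
    v = np.ones(small_slab_mesh.n_nodes)
    c = recon.map_mesh_basis(v, basis, small_slab_mesh, "mesh_to_basis")
    v2 = recon.map_mesh_basis(c, basis, small_slab_mesh, "basis_to_mesh")
    np.testing.assert_allclose(v2, v, atol=1e-12)
    with pytest.raises(ValueError):
        recon.map_mesh_basis(v, basis, small_slab_mesh, "sideways")


# ---------------------------------------------------------------------------
# reconstruction driver
# ---------------------------------------------------------------------------

def _tiny_problem():
    phantom = phantoms.build_block_phantom(resolution=4.0)
    opt = phantoms.single_view_optodes(phantom.mesh)
    musp = {lam: spectra.musp_from_mie(phantom.region_params[0].a,
                                       phantom.region_params[0].b, lam)
            for lam in (730.0, 850.0)}
    return phantom, opt, musp


def test_reconstruct_fixed_point_converges_immediately():
    """Data generated from the initial guess: first update is ~zero."""
    phantom, opt, musp = _tiny_problem()
    hom = phantoms.homogeneous_like(phantom)
    data = phantoms.simulate_phantom_data(hom, opt, wavelengths=sorted(musp))
    settings = ReconSettings(pixel_size=4.0, max_iterations=5)
    res = recon.reconstruct(data, hom.mesh, opt, phantom.table,
                            phantom.region_params[0], settings,
                            musp_by_wavelength=musp)
    assert res.converged
    assert res.n_iterations == 1
    norm_c = np.linalg.norm(res.concentrations_basis["dye"])
    assert res.update_norms[0] / norm_c < 1e-8


def test_projection_error_trace_non_increasing():
    phantom, opt, musp = _tiny_problem()
    hom = phantoms.homogeneous_like(phantom)
    data = phantoms.simulate_phantom_data(phantom, opt, wavelengths=sorted(musp))
    settings = ReconSettings(pixel_size=4.0, max_iterations=6)
    res = recon.reconstruct(data, hom.mesh, opt, phantom.table,
                            phantom.region_params[0], settings,
                            musp_by_wavelength=musp)
    E = np.array(res.projection_errors)
    assert np.all(np.diff(E) <= 0)
    assert E[-1] < E[0]


def test_reconstruct_rejects_mismatched_links():
    phantom, opt, musp = _tiny_problem()
    data = phantoms.simulate_phantom_data(phantom, opt, wavelengths=sorted(musp))
    fewer = opt.without_source(int(opt.links[0, 0]))
    with pytest.raises(ValueError, match="links"):
        recon.reconstruct(data, phantom.mesh, fewer, phantom.table,
                          phantom.region_params[0],
                          ReconSettings(pixel_size=4.0),
                          musp_by_wavelength=musp)


def test_separation_ratio_classifies_profiles():
    x = np.arange(0, 21.0)
    two = 1.0 + 0.05 * (np.exp(-0.5 * ((x - 5) / 2) ** 2)
                        + np.exp(-0.5 * ((x - 15) / 2) ** 2))
    one = 1.0 + 0.05 * np.exp(-0.5 * ((x - 10) / 4) ** 2)
    assert recon.separation_ratio(x, two, 5.0, 15.0) > 0.5
    assert recon.separation_ratio(x, one, 5.0, 15.0) < 0.05
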