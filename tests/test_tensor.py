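"""Tensor fit, scalar maps and brain masking against hand oracles."""

import numpy as np
import pytest

from dwiqc import phantom
from dwiqc.io import DWIScan, GradientTable, StructuralError
from dwiqc.tensor import (FitError, TensorField, brain_mask,
                          components_to_matrices, design_matrix,
                          fa_from_eigenvalues, fit_tensors_wls, fit_wls,
                          matrices_to_components, scalar_maps)


def random_spd_tensor(rng, scale=1e-3):
    A = rng.normal(size=(3, 3))
    return scale * (A @ A.T / 3.0 + 0.2 * np.eye(3))


def signals_for(D, dirs, bvals, s0=1.0):
    quad = np.einsum("ni,ij,nj->n", dirs, D, dirs)
    return s0 * np.exp(-bvals * quad)


def seven_volume_table(scheme6):
    dirs, bvals = scheme6.full_table()
    return dirs, bvals


# ---------------------------------------------------------------------------
# design matrix and WLS solver
# ---------------------------------------------------------------------------

def test_design_matrix_rows_reproduce_log_model(rng, scheme42):
    dirs, bvals = scheme42.full_table()
    X = design_matrix(bvals, dirs)
    assert X.shape == (43, 7)
    D = random_spd_tensor(rng)
    beta = np.array([np.log(2.5), D[0, 0], D[0, 1], D[0, 2],
                     D[1, 1], D[1, 2], D[2, 2]])
    lhs = X @ beta
    expected = np.log(2.5) - bvals * np.einsum("ni,ij,nj->n", dirs, D, dirs)
    np.testing.assert_allclose(lhs, expected, rtol=1e-12, atol=1e-15)


def test_fit_recovers_noise_free_tensor_exactly(rng, scheme42):
    dirs, bvals = scheme42.full_table()
    D = random_spd_tensor(rng)
    S = signals_for(D, dirs, bvals, s0=1200.0)
    beta, n_clamped = fit_tensors_wls(S[None, :], bvals, dirs)
    assert n_clamped == 0
    fitted = components_to_matrices(beta[0, 1:])
    np.testing.assert_allclose(fitted, D, rtol=1e-9, atol=1e-15)
    assert np.exp(beta[0, 0]) == pytest.approx(1200.0, rel=1e-9)


def test_fit_matches_independent_ols_oracle(rng, scheme6):
    """Noise-free data: the two-pass WLS must agree with a from-scratch
    OLS solve of the log-linear system built independently here."""
    dirs, bvals = scheme6.full_table()
    D = random_spd_tensor(rng)
    S = signals_for(D, dirs, bvals)
    # independent construction of the normal equations
    g = dirs
    M = np.column_stack([
        np.ones(len(bvals)),
        -bvals * g[:, 0] ** 2, -2 * bvals * g[:, 0] * g[:, 1],
        -2 * bvals * g[:, 0] * g[:, 2], -bvals * g[:, 1] ** 2,
        -2 * bvals * g[:, 1] * g[:, 2], -bvals * g[:, 2] ** 2])
    oracle = np.linalg.lstsq(M, np.log(S), rcond=None)[0]
    beta, _ = fit_tensors_wls(S[None, :], bvals, dirs)
    np.testing.assert_allclose(beta[0], oracle, rtol=1e-8, atol=1e-12)


def test_fit_rank_deficient_design_raises(rng):
    # 6 coplanar directions span only 2 dimensions -> unfittable
    angles = np.linspace(0.0, np.pi, 6, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles),
                            np.zeros(6)])
    dirs = np.vstack([np.zeros(3), dirs])
    bvals = np.array([0.0] + [1000.0] * 6)
    with pytest.raises(FitError, match="2 independent directions"):
        fit_tensors_wls(np.ones((1, 7)), bvals, dirs)


def test_fit_clamps_nonpositive_signals(scheme6):
    dirs, bvals = scheme6.full_table()
    S = np.ones((1, 7))
    S[0, 3] = -4.0
    _, n_clamped = fit_tensors_wls(S, bvals, dirs, signal_floor=1e-8)
    assert n_clamped == 1


# ---------------------------------------------------------------------------
# whole-scan fit
# ---------------------------------------------------------------------------

def test_fit_wls_recovers_phantom_field(scheme6):
    scan, manifest = phantom.make_phantom(
        dims=(16, 16, 16), scheme=scheme6, snr=None, seed=2)
    true_tensors, true_mask, _ = phantom.true_tensor_field(
        manifest.dims, manifest.tensor_layout)
    field = fit_wls(scan, true_mask)
    fitted = components_to_matrices(field.tensors[true_mask])
    truth = true_tensors[true_mask]
    rel = np.abs(fitted - truth).max(axis=(1, 2)) \
        / np.abs(truth).max(axis=(1, 2))
    assert rel.max() < 1e-6
    np.testing.assert_allclose(field.s0[true_mask], 1000.0, rtol=1e-6)


def test_fit_wls_requires_enough_volumes(scheme6):
    scan, _ = phantom.make_phantom(dims=(16, 16, 16), scheme=scheme6,
                                   snr=None, seed=2)
    mask = np.ones(scan.shape3d, dtype=bool)
    work = scan.copy()
    work.exclude(1, "test")
    with pytest.raises(FitError, match="at least 6"):
        fit_wls(work, mask)
    work2 = scan.copy()
    work2.exclude(0, "test")                    # the only baseline
    with pytest.raises(FitError, match="baseline"):
        fit_wls(work2, mask)


def test_fit_wls_applies_measurement_frame(scheme6):
    """Rotating gradients and the measurement frame oppositely leaves
    the image-space design, hence the fit, unchanged."""
    scan, _ = phantom.make_phantom(dims=(16, 16, 16), scheme=scheme6,
                                   snr=None, seed=2)
    mask = brain_mask(scan)
    ref = fit_wls(scan, mask)
    theta = np.radians(30.0)
    R = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                  [np.sin(theta), np.cos(theta), 0.0], [0.0, 0.0, 1.0]])
    rot = scan.copy()
    rot.gradients.directions = scan.gradients.directions @ R.T
    rot.gradients.measurement_frame = R.T       # maps back to image frame
    out = fit_wls(rot, mask)
    np.testing.assert_allclose(out.tensors, ref.tensors, rtol=1e-6,
                               atol=1e-12)


def test_negative_eigenvalues_clamped_and_counted(scheme6):
    dirs, bvals = scheme6.full_table()
    D = np.diag([-0.3e-3, 0.3e-3, 0.3e-3])      # unphysical on purpose
    S = signals_for(D, dirs, bvals, s0=100.0)
    signal = np.tile(S, (2, 2, 2, 1))
    scan = DWIScan(signal, [2, 2, 2], np.zeros(3), np.eye(3),
                   GradientTable(dirs, bvals))
    field = fit_wls(scan, np.ones((2, 2, 2), dtype=bool))
    assert field.n_negative_eigenvalues == 8
    evals = np.linalg.eigvalsh(field.as_matrices())
    assert (evals >= -1e-18).all()


# ---------------------------------------------------------------------------
# scalar maps
# ---------------------------------------------------------------------------

def one_voxel_field(D):
    mask = np.ones((1, 1, 1), dtype=bool)
    tensors = matrices_to_components(np.asarray(D, float))[None, None, None]
    return TensorField(tensors=tensors, mask=mask, s0=np.ones((1, 1, 1)))


def test_scalar_maps_hand_formulas():
    maps = scalar_maps(one_voxel_field(np.diag([2.0, 1.0, 1.0])))
    assert maps.fa[0, 0, 0] == pytest.approx(1.0 / np.sqrt(6.0), abs=1e-12)
    assert maps.md[0, 0, 0] == pytest.approx(4.0 / 3.0)
    assert maps.ad[0, 0, 0] == pytest.approx(2.0)
    assert maps.rd[0, 0, 0] == pytest.approx(1.0)
    np.testing.assert_allclose(np.abs(maps.pd[0, 0, 0]), [1.0, 0.0, 0.0],
                               atol=1e-12)

    iso = scalar_maps(one_voxel_field(np.diag([0.7, 0.7, 0.7])))
    assert iso.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    stick = scalar_maps(one_voxel_field(np.diag([1.0, 0.0, 0.0])))
    assert stick.fa[0, 0, 0] == pytest.approx(1.0, abs=1e-12)


def test_scalar_maps_pd_sign_canonical():
    # principal axis -z must be reported with non-negative z
    v = np.array([0.0, 0.0, -1.0])
    D = 1.7 * np.outer(v, v) + 0.3 * np.eye(3)
    maps = scalar_maps(one_voxel_field(D))
    assert maps.pd[0, 0, 0, 2] > 0
    # zero tensor -> PD undefined, flagged
    zero = scalar_maps(one_voxel_field(np.zeros((3, 3))))
    assert zero.pd_undefined[0, 0, 0]
    np.testing.assert_array_equal(zero.pd[0, 0, 0], 0.0)


def test_fa_from_eigenvalues_properties(rng):
    assert fa_from_eigenvalues(np.zeros(3)) == pytest.approx(0.0)
    lam = rng.uniform(0.1, 2.0, size=(50, 3))
    fa = fa_from_eigenvalues(lam)
    assert ((fa >= 0) & (fa <= 1)).all()
    np.testing.assert_allclose(fa_from_eigenvalues(lam[:, ::-1]), fa,
                               rtol=1e-12)
    np.testing.assert_allclose(fa_from_eigenvalues(3.7 * lam), fa,
                               rtol=1e-9)


# ---------------------------------------------------------------------------
# brain mask
# ---------------------------------------------------------------------------

def test_brain_mask_matches_phantom_ellipsoid(clean_phantom):
    scan, manifest = clean_phantom
    _, true_mask, _ = phantom.true_tensor_field(manifest.dims,
                                                manifest.tensor_layout)
    mask = brain_mask(scan)
    dice = 2.0 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum())
    assert dice >= 0.99


def test_brain_mask_uniform_image_fallback():
    table = GradientTable(np.zeros((1, 3)), [0.0])
    scan = DWIScan(np.full((6, 6, 6, 1), 50.0), [1, 1, 1], np.zeros(3),
                   np.eye(3), table)
    assert brain_mask(scan).all()


def test_brain_mask_zero_baseline_raises():
    table = GradientTable(np.zeros((1, 3)), [0.0])
    scan = DWIScan(np.zeros((6, 6, 6, 1)), [1, 1, 1], np.zeros(3),
                   np.eye(3), table)
    with pytest.raises(StructuralError, match="zero"):
        brain_mask(scan)


def test_brain_mask_keeps_largest_component():
    table = GradientTable(np.zeros((1, 3)), [0.0])
    signal = np.zeros((12, 12, 12, 1))
    signal[2:9, 2:9, 2:9, 0] = 100.0            # big blob
    signal[10, 10, 10, 0] = 100.0               # speck
    scan = DWIScan(signal, [1, 1, 1], np.zeros(3), np.eye(3), table)
    mask = brain_mask(scan)
    assert mask[4, 4, 4]
    assert not mask[10, 10, 10]
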