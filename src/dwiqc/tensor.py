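"""Single-tensor reconstruction and scalar diffusion maps.

The signal model is S_i = S0 * exp(-b_i g_i' D g_i) with D a symmetric
3x3 tensor per voxel.  Taking logs makes the model linear in
(ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz); the fit is a two-pass weighted
least squares: an ordinary least-squares solve on the log-signals
followed by one weighted refit with weights equal to the squared
predicted signals, the standard heteroscedasticity correction for
log-transformed magnitude data.

From the fitted eigenvalues (l1 >= l2 >= l3) the usual maps follow:
MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2 and

    FA = sqrt(3/2) * sqrt(sum (l_i - MD)^2) / sqrt(sum l_i^2)

with the principal direction (PD) the unit eigenvector of l1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import DWIScan, StructuralError

__all__ = ["TensorField", "ScalarMaps", "brain_mask", "fit_wls",
           "scalar_maps", "design_matrix", "fit_tensors_wls",
           "fa_from_eigenvalues"]

#: index order of the 6 unique tensor components
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


class FitError(RuntimeError):
    pass


@dataclass
class TensorField:
    """Per-voxel fitted tensors (6 unique components) on a mask."""
    tensors: np.ndarray        # (x, y, z, 6)
    mask: np.ndarray           # (x, y, z) bool
    s0: np.ndarray             # (x, y, z)
    n_clamped_signals: int = 0
    n_negative_eigenvalues: int = 0

    def as_matrices(self) -> np.ndarray:
        """Masked tensors as an (n_voxels, 3, 3) stack."""
        return components_to_matrices(self.tensors[self.mask])


@dataclass
class ScalarMaps:
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    pd: np.ndarray             # (x, y, z, 3) principal eigenvector
    mask: np.ndarray
    pd_undefined: np.ndarray   # (x, y, z) bool, zero tensors


def components_to_matrices(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, float)
    out = np.empty(c.shape[:-1] + (3, 3))
    out[..., 0, 0] = c[..., 0]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 1]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 2]
    out[..., 1, 1] = c[..., 3]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 4]
    out[..., 2, 2] = c[..., 5]
    return out


def matrices_to_components(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, float)
    return np.stack([m[..., 0, 0], m[..., 0, 1], m[..., 0, 2],
                     m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]], axis=-1)


def brain_mask(scan: DWIScan) -> np.ndarray:
    """Foreground mask from the mean baseline volume.

    Otsu threshold on the mean of the retained baseline volumes, then
    largest connected component and hole filling.  When the histogram is
    degenerate (uniform image), falls back to thresholding at half the
    maximum.
    """
    base = scan.baseline_mask & scan.retained_mask
    if not base.any():
        raise StructuralError("no retained baseline volume for masking")
    mean_b0 = np.asarray(scan.signal[..., base], float).mean(axis=3)
    if mean_b0.max() <= 0:
        raise StructuralError("baseline volume is all zero; cannot mask")
    lo, hi = mean_b0.min(), mean_b0.max()
    if hi - lo < 1e-12 * max(hi, 1.0):
        thr = hi / 2.0
    else:
        thr = _otsu(mean_b0)
        if thr <= lo or thr >= hi:
            thr = hi / 2.0
    mask = mean_b0 > thr
    if not mask.any():
        raise StructuralError("empty brain mask")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _otsu(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(centers[int(np.argmax(sigma_b))])


def design_matrix(b_values: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """(N, 7) log-linear design: columns [1 | -b B(g)] for the 6 components.

    Row i maps (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) to ln S_i with the
    off-diagonal components doubled (symmetry of g g').
    """
    b = np.asarray(b_values, float).ravel()
    g = np.asarray(directions, float).reshape(-1, 3)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    X = np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -2 * b * gx * gy, -2 * b * gx * gz,
        -b * gy * gy, -2 * b * gy * gz, -b * gz * gz])
    return X


def fit_tensors_wls(signals: np.ndarray, b_values: np.ndarray,
                    directions: np.ndarray, signal_floor: float = 1e-8):
    """Two-pass WLS tensor fit for a batch of voxels sharing one design.

    Parameters
    ----------
    signals : (V, N) array of measured signals (one row per voxel).
    b_values, directions : per-volume diffusion weighting.
    signal_floor : non-positive signals are clamped here before the log.

    Returns
    -------
    beta : (V, 7) array [ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz].
    n_clamped : number of clamped signal samples.
    """
    S = np.atleast_2d(np.asarray(signals, float))
    X = design_matrix(b_values, directions)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        ndir = np.linalg.matrix_rank(
            np.asarray(directions, float).reshape(-1, 3))
        raise FitError(
            f"rank-deficient design (rank {rank} < 7; gradient set spans "
            f"{ndir} independent directions)")
    n_clamped = int(np.count_nonzero(S < signal_floor))
    lnS = np.log(np.maximum(S, signal_floor))
    # pass 1: OLS
    beta = np.linalg.lstsq(X, lnS.T, rcond=None)[0].T       # (V, 7)
    # pass 2: weights = squared predicted signals
    w = np.exp(2.0 * (beta @ X.T))                           # (V, N)
    Xw = w[:, :, None] * X[None, :, :]                       # (V, N, 7)
    A = np.einsum("ni,vnj->vij", X, Xw)                      # (V, 7, 7)
    rhs = np.einsum("vn,vn,ni->vi", w, lnS, X)               # (V, 7)
    try:
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack([np.linalg.lstsq(a, r, rcond=None)[0]
                         for a, r in zip(A, rhs)])
    return beta, n_clamped


def fit_wls(scan: DWIScan, mask: np.ndarray) -> TensorField:
    """Fit the single-tensor model on every masked voxel of a scan.

    Only retained volumes enter the fit; gradients are rotated into
    image space through the measurement frame before the design matrix
    is built.  Negative eigenvalues (noise) are clamped to zero and
    counted.
    """
    retained = scan.retained_mask
    baseline = scan.baseline_mask
    n_dwi = int((retained & ~baseline).sum())
    if n_dwi < 6:
        raise FitError(f"only {n_dwi} retained diffusion-weighted volumes; "
                       "need at least 6")
    if not (retained & baseline).any():
        raise FitError("no retained baseline volume")
    idx = np.flatnonzero(retained)
    dirs = scan.gradients.image_frame_directions()[idx]
    bvals = scan.gradients.b_values[idx]
    S = np.asarray(scan.signal, float)[..., idx]
    mask = np.asarray(mask, bool)
    V = S[mask]                                              # (nvox, N)
    floor = max(float(V.max()) * 1e-8, 1e-30)
    beta, n_clamped = fit_tensors_wls(V, bvals, dirs, signal_floor=floor)

    D = components_to_matrices(beta[:, 1:])
    evals, evecs = np.linalg.eigh(D)
    n_neg = int(np.count_nonzero(evals < 0))
    evals = np.maximum(evals, 0.0)
    D = np.einsum("vij,vj,vkj->vik", evecs, evals, evecs)

    shape = scan.shape3d
    tensors = np.zeros(shape + (6,))
    tensors[mask] = matrices_to_components(D)
    s0 = np.zeros(shape)
    s0[mask] = np.exp(beta[:, 0])
    return TensorField(tensors=tensors, mask=mask, s0=s0,
                       n_clamped_signals=n_clamped,
                       n_negative_eigenvalues=n_neg)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalue triples (any order); 0 for zero tensors."""
    lam = np.asarray(evals, float)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - md) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0),
                                     0.0)
    return np.clip(fa, 0.0, 1.0)


def _canonical_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvectors to non-negative z (tie -> y, then x)."""
    v = vecs.copy()
    z, y, x = v[..., 2], v[..., 1], v[..., 0]
    flip = (z < 0) | ((z == 0) & (y < 0)) | ((z == 0) & (y == 0) & (x < 0))
    v[flip] *= -1.0
    return v


def scalar_maps(field: TensorField) -> ScalarMaps:
    """Eigen-decompose the tensor field into FA/MD/AD/RD and PD maps."""
    D = field.as_matrices()
    evals, evecs = np.linalg.eigh(D)          # ascending
    evals = evals[:, ::-1]                    # l1 >= l2 >= l3
    evecs = evecs[:, :, ::-1]
    l1, l2, l3 = evals[:, 0], evals[:, 1], evals[:, 2]

    md = evals.mean(axis=1)
    fa = fa_from_eigenvalues(evals)
    pd = _canonical_sign(evecs[:, :, 0])
    undefined = l1 <= 0
    pd[undefined] = 0.0

    shape = field.mask.shape
    out = ScalarMaps(
        fa=np.zeros(shape), md=np.zeros(shape), ad=np.zeros(shape),
        rd=np.zeros(shape), pd=np.zeros(shape + (3,)), mask=field.mask,
        pd_undefined=np.zeros(shape, dtype=bool))
    out.fa[field.mask] = fa
    out.md[field.mask] = md
    out.ad[field.mask] = l1
    out.rd[field.mask] = 0.5 * (l2 + l3)
    out.pd[field.mask] = pd
    out.pd_undefined[field.mask] = undefined
    return out
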