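"""Intensity-inconsistency artifact detection.

Two stages operate on the raw DWI signal before any model fitting:

* slice-wise check — normalized correlation between successive slices
  within each volume; a brightness dropout in one slice breaks the
  correlation with its neighbours and the volume is rejected whole;
* interlace check — correlation between the odd and even slice
  interleaves of each volume; interleaved acquisition inconsistency
  ("venetian blind" artifact) and within-volume motion depress it.

Baseline and diffusion-weighted volumes have very different contrast, so
each group is thresholded against its own mean/stdev statistics.  A
volume is excluded whole rather than slice-by-slice, so that the
retained data keep a spatially uniform number of measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIScan, Protocol, StructuralError

__all__ = ["SliceCorrelationMatrix", "InterlaceResult",
           "normalized_correlation", "slice_wise_check", "interlace_check",
           "rotate_gradients"]


def normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine-type normalized correlation sum(a*b)/sqrt(sum(a^2)sum(b^2)).

    No mean subtraction (this is not the Pearson coefficient): a
    brightness dropout changes both the mean and the magnitude of a
    slice, and subtracting means would hide part of that.  Degenerate
    input (either norm zero) returns 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = float(np.sqrt(np.sum(a * a)))
    nb = float(np.sqrt(np.sum(b * b)))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.sum(a * b) / (na * nb))


@dataclass
class SliceCorrelationMatrix:
    """(volume, slice-pair) normalized correlations plus group labels."""
    values: np.ndarray              # (n_volumes, n_slices - 1)
    is_baseline: np.ndarray         # (n_volumes,) bool
    warnings: list = field(default_factory=list)


@dataclass
class InterlaceResult:
    correlations: np.ndarray        # (n_volumes,)
    flagged: np.ndarray             # (n_volumes,) bool
    is_baseline: np.ndarray
    thresholds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _slice_pair_correlations(signal: np.ndarray) -> np.ndarray:
    """Correlation of successive z-slices for every volume.

    signal: (x, y, z, n) -> (n, z-1) matrix.
    """
    s = np.asarray(signal, float)
    a = s[:, :, :-1, :]
    b = s[:, :, 1:, :]
    num = np.einsum("xyzn,xyzn->zn", a, b)
    na = np.sqrt(np.einsum("xyzn,xyzn->zn", a, a))
    nb = np.sqrt(np.einsum("xyzn,xyzn->zn", b, b))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return corr.T


def slice_wise_check(scan: DWIScan, protocol: Protocol):
    """Detect slice-wise brightness artifacts; exclude affected volumes.

    For each slice-pair position j the mean and stdev of the correlation
    across the volumes of a group define a lower bound mu_j - k*sigma_j
    (k = ``slice_check_stdev_factor``); any cell below it marks its whole
    volume excluded.  Already-excluded volumes neither contribute to the
    statistics nor get re-flagged.

    Returns ``(SliceCorrelationMatrix, verdicts)`` where ``verdicts`` is
    a per-volume list, ``None`` for clean volumes and a reason string for
    flagged ones.
    """
    nz = scan.shape3d[2]
    if nz < 3:
        raise StructuralError("slice-wise check needs at least 3 slices")
    corr = _slice_pair_correlations(scan.signal)
    baseline = scan.baseline_mask
    matrix = SliceCorrelationMatrix(values=corr, is_baseline=baseline)
    k = protocol.slice_check_stdev_factor
    verdicts = [None] * scan.n_volumes
    retained = scan.retained_mask
    for label, group in (("baseline", baseline & retained),
                         ("weighted", ~baseline & retained)):
        idx = np.flatnonzero(group)
        if idx.size < 2:
            if idx.size:
                matrix.warnings.append(
                    f"{label} group has {idx.size} volume(s); "
                    "slice-wise check skipped for this group")
            continue
        sub = corr[idx]                       # (m, z-1)
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        bad = sub < (mu - k * sd)[None, :]
        for row, vol in enumerate(idx):
            if bad[row].any():
                pairs = np.flatnonzero(bad[row])
                slices = sorted({int(p) for p in pairs}
                                | {int(p) + 1 for p in pairs})
                reason = (f"slice-wise intensity artifact near slice(s) "
                          f"{slices} ({label} group)")
                verdicts[vol] = reason
                scan.exclude(int(vol), reason)
    return matrix, verdicts


def interlace_check(scan: DWIScan, protocol: Protocol) -> InterlaceResult:
    """Detect venetian-blind/interleave artifacts; exclude flagged volumes.

    Each volume's odd-slice substack is correlated against its even-slice
    substack (slice 2i paired with 2i+1; a trailing unpaired slice is
    ignored).  A volume is flagged iff its correlation falls below
    mu - k*sigma of its contrast group, k = ``interlace_corr_stdev_factor``.
    """
    nz = scan.shape3d[2]
    if nz < 4:
        raise StructuralError("interlace check needs at least 4 slices")
    npairs = nz // 2
    even = np.asarray(scan.signal[:, :, 0:2 * npairs:2, :], float)
    odd = np.asarray(scan.signal[:, :, 1:2 * npairs:2, :], float)
    num = np.einsum("xyzn,xyzn->n", even, odd)
    ne = np.sqrt(np.einsum("xyzn,xyzn->n", even, even))
    no = np.sqrt(np.einsum("xyzn,xyzn->n", odd, odd))
    denom = ne * no
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)

    baseline = scan.baseline_mask
    retained = scan.retained_mask
    flagged = np.zeros(scan.n_volumes, dtype=bool)
    result = InterlaceResult(correlations=corr, flagged=flagged,
                             is_baseline=baseline)
    k = protocol.interlace_corr_stdev_factor
    for label, group in (("baseline", baseline & retained),
                         ("weighted", ~baseline & retained)):
        idx = np.flatnonzero(group)
        if idx.size < 2:
            if idx.size:
                result.warnings.append(
                    f"{label} group has {idx.size} volume(s); "
                    "interlace check skipped for this group")
            continue
        mu = float(corr[idx].mean())
        sd = float(corr[idx].std(ddof=1))
        thr = mu - k * sd
        result.thresholds[label] = thr
        for vol in idx:
            if corr[vol] < thr:
                flagged[vol] = True
                scan.exclude(int(vol),
                             f"interlace (venetian blind) artifact: "
                             f"odd/even correlation {corr[vol]:.4f} < "
                             f"{thr:.4f} ({label} group)")
    return result


def rotate_gradients(scan: DWIScan, rotations) -> DWIScan:
    """Apply per-volume rotations to the gradient directions.

    Bookkeeping for externally-supplied motion-correction transforms:
    each direction g becomes R @ g (renormalized); b-values and signal
    are untouched.  ``rotations`` is an (n, 3, 3) stack or a list of 3x3
    orthonormal matrices.
    """
    R = np.asarray(rotations, float)
    if R.shape != (scan.n_volumes, 3, 3):
        raise ValueError(f"expected {(scan.n_volumes, 3, 3)} rotation "
                         f"stack, got {R.shape}")
    eye = np.eye(3)
    for i, r in enumerate(R):
        if not np.allclose(r @ r.T, eye, atol=1e-6):
            raise ValueError(f"rotation {i} is not orthonormal")
    out = scan.copy()
    rotated = np.einsum("nij,nj->ni", R, scan.gradients.directions)
    norms = np.linalg.norm(rotated, axis=1)
    rotated = np.where(norms[:, None] > 1e-12,
                       rotated / np.where(norms[:, None] > 1e-12,
                                          norms[:, None], 1.0), 0.0)
    out.gradients.directions = rotated
    return out
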