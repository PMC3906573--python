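"""Entropy-based detection and correction of dominating-direction artifacts.

Scanner-table vibration can bias the fitted principal diffusion
direction (PD) of a whole scan toward one axis (typically left-right).
Because healthy anatomy spreads PDs over many orientations, such a bias
shows up as clustering of the PD distribution on the sphere.  The
distribution is summarized by a spherical histogram whose bins are the
faces of a subdivided icosahedron, folded by antipodal symmetry (a PD is
an axis: v and -v are the same orientation); its Shannon entropy
H = -sum p ln p is then compared to statistics learned from artifact-free
training scans.  Low entropy (clustering) yields a high z-score
z = (mu - H)/sigma, and the scan is categorized as acceptable
(z < 1.64), suspicious (1.64 <= z < 2.58) or unacceptable (z >= 2.58) —
one-sided 90th / 99th percentile boundaries.

Suspicious scans are corrected by an iterative leave-one-out strategy:
the diffusion-weighted volume whose omission most improves entropy is
excluded, and the process repeats until the z-score is acceptable, no
candidate improves entropy, or too few volumes remain.  Unacceptable
scans are rejected whole: removing the many volumes needed would leave a
strongly non-uniform gradient scheme and a biased fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import ConvexHull

from .io import DWIScan, Protocol
from .tensor import brain_mask, fit_wls, scalar_maps

__all__ = ["SphericalHistogram", "EntropyStats", "DirectionalVerdict",
           "build_bins", "accumulate", "entropy", "train_stats",
           "categorize", "correct_leave_one_out", "leave_one_out",
           "scan_entropy"]


class TrainingError(ValueError):
    pass


class EmptyHistogramError(ValueError):
    pass


@dataclass
class SphericalHistogram:
    """Histogram over orientation axes on the half-sphere.

    ``bin_axes`` are the antipodally folded face centroids of a
    subdivided icosahedron: 20 * 4**level faces fold to half that many
    bins (level 0 -> 10, 1 -> 40, 2 -> 160).  A PD is assigned to the
    bin whose axis maximizes |axis . pd|.
    """
    subdivision_level: int
    bin_axes: np.ndarray              # (B, 3) unit vectors
    counts: np.ndarray                # (B,) non-negative
    empty: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bin_axes)

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            return np.zeros_like(self.counts)
        return self.counts / total


@dataclass
class EntropyStats:
    """Mean/stdev of entropy over an artifact-free training set."""
    mean_entropy: float
    sd_entropy: float
    n_training: int
    region: str = "whole-brain"
    subdivision_level: int = 2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EntropyStats":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class DirectionalVerdict:
    entropy: float
    z: float
    category: str                          # acceptable/suspicious/unacceptable
    removed_volumes: list = field(default_factory=list)
    scan_rejected: bool = False
    detail: str = ""


def _icosahedron():
    """Vertices/faces of the regular icosahedron on the unit sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1.0, phi)]:
        verts += [(0, +a, +b), (0, +a, -b), (0, -a, +b), (0, -a, -b),
                  (+a, +b, 0), (+a, -b, 0), (-a, +b, 0), (-a, -b, 0),
                  (+b, 0, +a), (-b, 0, +a), (+b, 0, -a), (-b, 0, -a)]
    v = np.array(verts, float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    hull = ConvexHull(v)
    return v, hull.simplices                 # (12, 3), (20, 3)


def _subdivide(vertices: np.ndarray, faces: np.ndarray):
    """One 4-to-1 triangle subdivision with midpoints pushed to the sphere."""
    verts = list(vertices)
    cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            m = m / np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.array(verts), np.array(new_faces)


def _fold_axes(axes: np.ndarray) -> np.ndarray:
    """Keep one representative of each antipodal pair (canonical sign)."""
    a = axes.copy()
    z, y, x = a[:, 2], a[:, 1], a[:, 0]
    tol = 1e-9
    flip = (z < -tol) | ((np.abs(z) <= tol) & (y < -tol)) \
        | ((np.abs(z) <= tol) & (np.abs(y) <= tol) & (x < -tol))
    a[flip] *= -1.0
    _, keep = np.unique(np.round(a, 6), axis=0, return_index=True)
    return a[np.sort(keep)]


def build_bins(level: int) -> SphericalHistogram:
    """Empty spherical histogram at the given icosahedron subdivision level."""
    if not 0 <= level <= 4:
        raise ValueError("subdivision level must be in [0, 4]")
    verts, faces = _icosahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    centroids = verts[faces].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    axes = _fold_axes(centroids)
    expected = 20 * 4 ** level // 2
    assert len(axes) == expected, (len(axes), expected)
    return SphericalHistogram(subdivision_level=level, bin_axes=axes,
                              counts=np.zeros(len(axes)))


def accumulate(hist: SphericalHistogram, pd_map: np.ndarray,
               region_mask: np.ndarray = None,
               weights: np.ndarray = None) -> SphericalHistogram:
    """Add PD axes to the histogram (axial |dot| assignment).

    ``pd_map`` is (..., 3); ``region_mask`` selects voxels; ``weights``
    (same leading shape) default to 1 per voxel.  Returns a new
    histogram; the input is not modified.
    """
    pds = np.asarray(pd_map, float).reshape(-1, 3) if region_mask is None \
        else np.asarray(pd_map, float)[np.asarray(region_mask, bool)]
    if weights is not None:
        w = np.asarray(weights, float).ravel() if region_mask is None \
            else np.asarray(weights, float)[np.asarray(region_mask, bool)]
    else:
        w = np.ones(len(pds))
    out = SphericalHistogram(hist.subdivision_level, hist.bin_axes,
                             hist.counts.copy())
    if len(pds) == 0:
        out.empty = out.counts.sum() <= 0
        return out
    scores = np.abs(pds @ hist.bin_axes.T)       # (V, B)
    assign = np.argmax(scores, axis=1)
    np.add.at(out.counts, assign, w)
    out.empty = out.counts.sum() <= 0
    return out


def entropy(hist: SphericalHistogram) -> float:
    """Shannon entropy (nats) of the bin distribution."""
    total = hist.counts.sum()
    if total <= 0:
        raise EmptyHistogramError("entropy of an empty histogram is undefined")
    p = hist.counts / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) + 0.0)   # +0.0 avoids -0.0


def train_stats(entropies, region: str = "whole-brain",
                subdivision_level: int = 2) -> EntropyStats:
    """Sample mean and stdev (n-1) of training-set entropies."""
    h = np.asarray(list(entropies), float)
    if h.size < 2:
        raise TrainingError(f"need at least 2 training scans, got {h.size}")
    sd = float(h.std(ddof=1))
    if sd <= 0:
        raise TrainingError("zero variance in training entropies")
    return EntropyStats(mean_entropy=float(h.mean()), sd_entropy=sd,
                        n_training=int(h.size), region=region,
                        subdivision_level=subdivision_level)


def categorize(H: float, stats: EntropyStats,
               protocol: Protocol) -> DirectionalVerdict:
    """z-score a scan's entropy against training statistics.

    z = (mu - H)/sigma: directional clustering lowers entropy, so low H
    means high z.  Boundaries are one-sided (90th / 99th percentile).
    """
    z = (stats.mean_entropy - H) / stats.sd_entropy
    if z < protocol.entropy_z_suspicious:
        cat = "acceptable"
    elif z < protocol.entropy_z_unacceptable:
        cat = "suspicious"
    else:
        cat = "unacceptable"
    return DirectionalVerdict(entropy=float(H), z=float(z), category=cat)


def _region_mask(scan: DWIScan, protocol: Protocol, maps, mask: np.ndarray):
    if protocol.region_selector == "wm-like":
        return mask & (maps.fa > 0.25)
    return mask


def scan_entropy(scan: DWIScan, protocol: Protocol,
                 mask: np.ndarray = None) -> float:
    """Fit tensors on the retained volumes and return the PD entropy."""
    if mask is None:
        mask = brain_mask(scan)
    field_ = fit_wls(scan, mask)
    maps = scalar_maps(field_)
    region = _region_mask(scan, protocol, maps, mask)
    hist = build_bins(protocol.histogram_subdivision_level)
    weights = maps.fa if protocol.fa_weighted_histogram else None
    hist = accumulate(hist, maps.pd, region,
                      None if weights is None else weights)
    return entropy(hist)


def correct_leave_one_out(scan: DWIScan, stats: EntropyStats,
                          protocol: Protocol,
                          mask: np.ndarray = None) -> DirectionalVerdict:
    """Categorize a scan and, if suspicious, correct it by leave-one-out.

    Acceptable scans pass untouched; unacceptable scans are rejected
    whole.  For suspicious scans, each retained diffusion-weighted
    volume is tentatively omitted, the tensor field refitted and the
    entropy recomputed; the omission with the largest entropy gain (ties
    broken toward the lowest volume index) becomes a permanent
    exclusion.  Iteration stops when the z-score is acceptable, when no
    candidate improves entropy, when the retained fraction would fall
    below ``retained_fraction_threshold`` (scan rejected), or when fewer
    than 7 volumes remain (tensor no longer estimable; scan rejected).
    """
    if mask is None:
        mask = brain_mask(scan)
    H = scan_entropy(scan, protocol, mask)
    verdict = categorize(H, stats, protocol)
    if verdict.category == "acceptable":
        verdict.detail = "entropy within the acceptable range"
        return verdict
    if verdict.category == "unacceptable":
        verdict.scan_rejected = True
        verdict.detail = ("severe dominating-direction artifact; whole scan "
                          "rejected (correction would bias the scheme)")
        return verdict
    return leave_one_out(scan, stats, protocol, mask=mask, start_entropy=H)


def leave_one_out(scan: DWIScan, stats: EntropyStats, protocol: Protocol,
                  mask: np.ndarray = None,
                  start_entropy: float = None) -> DirectionalVerdict:
    """The leave-one-out entropy-maximizing removal loop itself.

    Unlike :func:`correct_leave_one_out` this applies no category gate:
    it removes the diffusion-weighted volume whose omission most
    improves entropy until the z-score is acceptable, no candidate
    improves entropy, the retained fraction would drop below the
    protocol threshold (scan rejected), or fewer than 7 volumes remain
    (scan rejected).  Entropy strictly increases at every accepted
    removal, so the loop terminates in at most one pass per
    diffusion-weighted volume.
    """
    if mask is None:
        mask = brain_mask(scan)
    H = (scan_entropy(scan, protocol, mask)
         if start_entropy is None else start_entropy)
    removed = []
    n_total = scan.n_volumes
    current_H = H
    while True:
        z = (stats.mean_entropy - current_H) / stats.sd_entropy
        if z < protocol.entropy_z_suspicious:
            break
        if scan.retained_mask.sum() < 7:
            v = categorize(current_H, stats, protocol)
            v.removed_volumes = removed
            v.scan_rejected = True
            v.detail = "fewer than 7 retained volumes; tensor not estimable"
            return v
        candidates = np.flatnonzero(scan.retained_mask & ~scan.baseline_mask)
        best_H, best_vol = -np.inf, None
        for vol in candidates:
            trial = scan.copy()
            trial.exclude(int(vol), "trial")
            try:
                h = scan_entropy(trial, protocol, mask)
            except Exception:
                continue
            if h > best_H + 1e-15:
                best_H, best_vol = h, int(vol)
        if best_vol is None or best_H <= current_H:
            break  # no candidate improves entropy
        retained_after = scan.retained_mask.sum() - 1
        if retained_after / n_total < protocol.retained_fraction_threshold:
            v = categorize(current_H, stats, protocol)
            v.removed_volumes = removed
            v.scan_rejected = True
            v.detail = ("retained fraction would fall below "
                        f"{protocol.retained_fraction_threshold:g}")
            return v
        scan.exclude(best_vol, "dominating-direction artifact "
                               "(leave-one-out entropy correction)")
        removed.append(best_vol)
        current_H = best_H

    out = categorize(current_H, stats, protocol)
    out.removed_volumes = removed
    out.detail = (f"corrected by removing {len(removed)} volume(s)"
                  if removed else "no removal improved entropy")
    if out.category == "unacceptable":
        out.scan_rejected = True
    return out
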