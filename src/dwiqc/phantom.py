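"""Synthetic DWI phantoms with ground-truth manifests.

Every QC stage in this package is exercised on generated data: a
brain-like ellipsoid containing three anisotropic "tract" blocks whose
principal directions run along x, y and z (echoing the white-matter
anatomy that makes the entropy detector work: left-right,
anterior-posterior and inferior-superior fiber populations), embedded in
isotropic filler.  Signals follow the single-tensor model with Rician
noise at a configurable SNR.  Artifact injectors then corrupt a clean
phantom in controlled, manifest-recorded ways: single-slice brightness
dropouts, venetian-blind interleave scaling, and directional bias
(suppressing the signal of all volumes whose gradient is close to a
chosen axis, which drags the fitted principal directions toward it).

Default tensors are physiologic white/gray-matter scale values:
tract eigenvalues (1.7, 0.3, 0.3)e-3 mm^2/s, isotropic filler MD
0.8e-3 mm^2/s.  Artifact magnitude presets: mild 0.85, moderate 0.6,
severe 0.35 (multiplicative signal factors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .bias import Scheme, rician_sample
from .io import DWIScan, GradientTable

__all__ = ["PhantomManifest", "make_phantom", "inject_slice_dropout",
           "inject_venetian_blind", "inject_directional_bias",
           "make_cohort", "ARTIFACT_PRESETS", "TRACT_LAMBDAS", "FILLER_MD"]

ARTIFACT_PRESETS = {"mild": 0.85, "moderate": 0.6, "severe": 0.35}
TRACT_LAMBDAS = (1.7e-3, 0.3e-3, 0.3e-3)   # mm^2/s
FILLER_MD = 0.8e-3                          # mm^2/s
S0 = 1000.0


@dataclass
class PhantomManifest:
    """Ground truth for a generated phantom."""
    dims: tuple
    spacing: tuple
    snr: float                    # inf/None = noise-free
    seed: int
    tensor_layout: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PhantomManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["dims"] = tuple(d["dims"])
        d["spacing"] = tuple(d["spacing"])
        if d["snr"] is not None:
            d["snr"] = float(d["snr"])
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if obj in (np.inf, float("inf")):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sample_layout(rng: np.random.Generator) -> dict:
    """Draw the inter-subject variability of a phantom layout.

    Emulates the anatomical variability a real training cohort has:
    tract-block proportions, a uniformly random global rotation of the
    tract frame, and the head-size scale of the ellipsoid.  Without it
    every phantom would be identical up to noise and the trained entropy
    stdev would be unrealistically small.
    """
    from .bias import random_rotations

    w = rng.dirichlet([25.0, 25.0, 25.0])
    R = random_rotations(1, rng)[0]
    return {
        "proportions": w.tolist(),
        "axis_rotation": R.tolist(),
        "ellipsoid_factor": float(rng.uniform(0.42, 0.48)),
        "dispersion": 0.27,
        "dispersion_seed": int(rng.integers(0, 2 ** 31 - 1)),
    }


CANONICAL_LAYOUT = {
    "proportions": [1 / 3, 1 / 3, 1 / 3],
    "axis_rotation": np.eye(3).tolist(),
    "ellipsoid_factor": 0.45,
    "dispersion": 0.27,
    "dispersion_seed": 0,
}


def true_tensor_field(dims, layout: dict = None) -> tuple:
    """Ground-truth tensor field: (tensors (x,y,z,3,3), mask, layout dict).

    An ellipsoid mask contains a central cuboid split along x into three
    slabs with principal directions (rotated) x, y, z; the rest of the
    ellipsoid is isotropic filler.  Within each slab the per-voxel fiber
    axis disperses around the block axis (``dispersion`` is the tangent
    scale of the angular spread, ~15 degrees by default), emulating the
    orientation dispersion of real tracts; the dispersion draw is pinned
    by ``dispersion_seed`` so the truth is reconstructable from the
    manifest.  ``layout`` carries the variability parameters (see
    :func:`sample_layout`); ``None`` gives the canonical layout.
    """
    nx, ny, nz = dims
    if min(dims) < 16:
        raise ValueError("phantom needs at least 16 voxels per dimension")
    if layout is None:
        layout = dict(CANONICAL_LAYOUT)
    w = np.asarray(layout["proportions"], float)
    w = w / w.sum()
    R = np.asarray(layout["axis_rotation"], float)
    ef = float(layout["ellipsoid_factor"])

    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = ef * nx, ef * ny, ef * nz
    mask = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 \
        + ((z - cz) / rz) ** 2 <= 1.0

    l1, l2, _ = TRACT_LAMBDAS
    tract_axes = [R @ e for e in np.eye(3)]
    tensors = np.zeros(tuple(dims) + (3, 3))
    tensors[mask] = FILLER_MD * np.eye(3)

    # central cuboid, split along x with the drawn proportions
    x0, x1 = int(round(nx * 0.28)), int(round(nx * 0.72))
    y0, y1 = int(round(ny * 0.28)), int(round(ny * 0.72))
    z0, z1 = int(round(nz * 0.32)), int(round(nz * 0.68))
    cuboid = np.zeros(dims, dtype=bool)
    cuboid[x0:x1, y0:y1, z0:z1] = True
    if np.any(cuboid & ~mask):
        raise ValueError("tract cuboid exceeds the ellipsoid mask")
    edges = x0 + np.round(np.cumsum(np.concatenate([[0.0], w]))
                          * (x1 - x0)).astype(int)
    layout = dict(layout)
    layout["tract_lambdas"] = list(TRACT_LAMBDAS)
    layout["filler_md"] = FILLER_MD
    layout["blocks"] = []
    disp = float(layout.get("dispersion", 0.0))
    disp_rng = np.random.default_rng(int(layout.get("dispersion_seed", 0)))
    for k, axis in enumerate(tract_axes):
        a, b = int(edges[k]), int(edges[k + 1])
        if b <= a:
            continue
        nvox = (b - a) * (y1 - y0) * (z1 - z0)
        u = np.asarray(axis)[None, :] + disp * disp_rng.normal(size=(nvox, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        D = (l1 - l2) * np.einsum("vi,vj->vij", u, u) \
            + l2 * np.eye(3)[None, :, :]
        tensors[a:b, y0:y1, z0:z1] = D.reshape(
            (b - a), (y1 - y0), (z1 - z0), 3, 3)
        layout["blocks"].append({
            "x_range": [a, b], "y_range": [y0, y1], "z_range": [z0, z1],
            "pd_axis": np.asarray(axis).tolist()})
    return tensors, mask, layout


def make_phantom(dims=(24, 24, 24), scheme: Scheme = None, snr: float = 15.0,
                 seed: int = 0, spacing=(2.0, 2.0, 2.0), layout: dict = None,
                 vary_layout: bool = True):
    """Generate a clean phantom scan plus its ground-truth manifest.

    ``snr`` is the baseline SNR (S0/sigma); ``None`` or ``inf`` produces
    a noise-free phantom.  By default the layout varies with the seed
    (see :func:`sample_layout`) so cohorts have realistic inter-subject
    spread; pass ``vary_layout=False`` for the canonical layout or
    ``layout`` to pin one.  Deterministic under a fixed seed.
    """
    if scheme is None:
        from .bias import scheme_electrostatic
        scheme = scheme_electrostatic(42, seed=12345)
    if layout is None and vary_layout:
        layout = sample_layout(np.random.default_rng([int(seed), 17]))
    tensors, mask, layout = true_tensor_field(dims, layout)
    dirs, bvals = scheme.full_table()
    quad = np.einsum("ni,xyzij,nj->xyzn", dirs, tensors, dirs)
    signal = S0 * np.exp(-bvals[None, None, None, :] * quad)
    signal[~mask] = 0.0

    rng = np.random.default_rng(seed)
    noise_free = snr is None or not np.isfinite(snr)
    if not noise_free:
        sigma = S0 / snr
        signal = np.where(mask[..., None],
                          rician_sample(signal, sigma, rng), 0.0)

    table = GradientTable(dirs, bvals, np.eye(3))
    scan = DWIScan(signal=signal, spacing=np.asarray(spacing),
                   origin=np.zeros(3), orientation=np.eye(3),
                   gradients=table)
    manifest = PhantomManifest(
        dims=tuple(int(d) for d in dims),
        spacing=tuple(float(s) for s in spacing),
        snr=None if noise_free else float(snr),
        seed=int(seed), tensor_layout=layout)
    return scan, manifest


def _affected_volumes(record) -> list:
    v = record["volume"]
    return list(v) if isinstance(v, list) else [int(v)]


def _regenerate_volumes(scan: DWIScan, manifest: PhantomManifest,
                        volumes) -> None:
    """Rebuild volumes from the clean model, artifact factors and noise.

    Artifact factors multiply the *clean* signal before Rician noise is
    re-applied: signal loss happens during acquisition, so the receiver
    noise keeps its full amplitude and the affected region's SNR drops —
    which is what makes the artifacts detectable downstream.  Noise per
    volume is drawn from a seed derived from the manifest, so injection
    is deterministic.  Factor fields accumulate over all manifest
    records, so repeated injections compose multiplicatively.
    """
    tensors, mask, _ = true_tensor_field(manifest.dims,
                                         manifest.tensor_layout)
    dirs = scan.gradients.directions
    bvals = scan.gradients.b_values
    scan.signal = np.asarray(scan.signal, float)
    for v in sorted(set(int(x) for x in volumes)):
        g = dirs[v]
        quad = np.einsum("i,xyzij,j->xyz", g, tensors, g)
        clean = S0 * np.exp(-bvals[v] * quad)
        fac = np.ones(manifest.dims)
        for rec in manifest.artifacts:
            if v not in _affected_volumes(rec):
                continue
            if rec.get("slices") is not None:
                for s in rec["slices"]:
                    fac[:, :, s] *= rec["magnitude"]
            else:
                fac *= rec["magnitude"]
        sig = clean * fac
        if manifest.snr is not None:
            sigma = S0 / manifest.snr
            rng = np.random.default_rng([int(manifest.seed) & 0x7FFFFFFF,
                                         1000 + v])
            sig = rician_sample(sig, sigma, rng)
        sig[~mask] = 0.0
        scan.signal[..., v] = sig


def inject_slice_dropout(scan: DWIScan, manifest: PhantomManifest,
                         volume: int, slice_index: int,
                         factor: float) -> DWIScan:
    """Brightness dropout: one slice's clean signal scaled by ``factor``."""
    if not 0.0 <= factor < 1.0:
        raise ValueError("factor must be in [0, 1)")
    if not 0 <= volume < scan.n_volumes:
        raise IndexError(f"volume {volume} out of range")
    if not 0 <= slice_index < scan.shape3d[2]:
        raise IndexError(f"slice {slice_index} out of range")
    manifest.artifacts.append({
        "type": "slice_dropout", "volume": int(volume),
        "slices": [int(slice_index)], "magnitude": float(factor)})
    _regenerate_volumes(scan, manifest, [volume])
    return scan


def inject_venetian_blind(scan: DWIScan, manifest: PhantomManifest,
                          volume: int, factor: float) -> DWIScan:
    """Interleave artifact: every even slice of one volume scaled."""
    if not 0.0 < factor < 1.0:
        raise ValueError("factor must be in (0, 1)")
    if not 0 <= volume < scan.n_volumes:
        raise IndexError(f"volume {volume} out of range")
    manifest.artifacts.append({
        "type": "venetian_blind", "volume": int(volume),
        "slices": list(range(0, scan.shape3d[2], 2)),
        "magnitude": float(factor)})
    _regenerate_volumes(scan, manifest, [volume])
    return scan


def inject_directional_bias(scan: DWIScan, manifest: PhantomManifest,
                            axis, threshold: float,
                            factor: float) -> DWIScan:
    """Suppress the signal of volumes with |g . axis| > threshold.

    Lowering the signal along one axis inflates the apparent diffusivity
    there, dragging the fitted principal directions toward the axis —
    the signature of a vibration artifact.  The affected volume indices
    are recorded on the manifest; a warning record with no volumes is
    stored when nothing matches.
    """
    if not 0.0 < factor < 1.0:
        raise ValueError("factor must be in (0, 1)")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    dots = np.abs(scan.gradients.directions @ axis)
    affected = np.flatnonzero((dots > threshold) & ~scan.baseline_mask)
    manifest.artifacts.append({
        "type": "directional_bias", "volume": affected.tolist(),
        "slices": None, "axis": axis.tolist(),
        "threshold": float(threshold), "magnitude": float(factor)})
    if affected.size:
        _regenerate_volumes(scan, manifest, affected)
    return scan


def make_cohort(n_clean: int, n_artifacted: int, seed: int = 0,
                dims=(24, 24, 24), scheme: Scheme = None, snr: float = 15.0,
                artifact: str = "directional_bias", preset: str = "severe",
                axis=(1.0, 0.0, 0.0), threshold: float = 0.8):
    """Generate clean and artifacted phantoms for training/detection runs.

    Returns ``(clean, artifacted)`` where each element is a list of
    ``(DWIScan, PhantomManifest)`` pairs.  Seeds are derived
    deterministically from ``seed``.
    """
    factor = ARTIFACT_PRESETS[preset]
    clean, artifacted = [], []
    for i in range(n_clean):
        clean.append(make_phantom(dims=dims, scheme=scheme, snr=snr,
                                  seed=seed * 10_000 + i))
    for i in range(n_artifacted):
        scan, manifest = make_phantom(dims=dims, scheme=scheme, snr=snr,
                                      seed=seed * 10_000 + n_clean + i)
        weighted = np.flatnonzero(~scan.baseline_mask)
        if artifact == "directional_bias":
            inject_directional_bias(scan, manifest, axis, threshold, factor)
        elif artifact == "slice_dropout":
            # inject inside the object: edge slices can lie outside the
            # ellipsoid where there is no tissue to corrupt
            rng = np.random.default_rng(seed * 10_000 + 7_000 + i)
            vol = int(rng.choice(weighted))
            nz = scan.shape3d[2]
            sl = int(rng.integers(nz // 4, 3 * nz // 4))
            inject_slice_dropout(scan, manifest, vol, sl, factor)
        elif artifact == "venetian_blind":
            rng = np.random.default_rng(seed * 10_000 + 8_000 + i)
            vol = int(rng.choice(weighted))
            inject_venetian_blind(scan, manifest, vol, factor)
        else:
            raise ValueError(f"unknown artifact type {artifact!r}")
        artifacted.append((scan, manifest))
    return clean, artifacted
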