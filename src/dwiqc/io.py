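"""Reading and writing diffusion-weighted MRI scans and QC protocols.

DWI volumes travel as NRRD files following the NA-MIC convention, which
stores the diffusion information inside the header as key/value pairs
(``DWMRI_b-value`` and one ``DWMRI_gradient_NNNN`` per volume), or as a
NIfTI image with FSL-style ``.bvec``/``.bval`` sidecars.  The central
in-memory container is :class:`DWIScan`; every QC stage consumes it and
records exclusions on it rather than mutating the signal.

NA-MIC gradient vectors may encode a per-volume b-value through their
norm: the effective b-value is ``b_nominal * ||g||**2`` and the direction
is the normalized vector.  This scaling is applied on read and inverted
on write.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "GradientTable",
    "DWIScan",
    "Protocol",
    "FormatError",
    "StructuralError",
    "read_nrrd",
    "write_nrrd",
    "read_fsl",
    "write_fsl",
    "read_protocol",
    "write_protocol",
]

#: volumes with b below this (s/mm^2) are treated as baselines; tolerance
#: for scanner rounding of nominally zero b-values.
BASELINE_B_MAX = 10.0


class FormatError(ValueError):
    """A file does not follow the expected on-disk convention."""


class StructuralError(ValueError):
    """Metadata is internally inconsistent (e.g. volume-count mismatch)."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


@dataclass
class GradientTable:
    """Per-volume diffusion gradient directions and b-values.

    Parameters
    ----------
    directions : (N, 3) array
        Unit vectors (zero for baseline volumes).
    b_values : (N,) array
        Non-negative b-values in s/mm^2.
    measurement_frame : (3, 3) array
        Orthonormal matrix mapping gradient coordinates into image space.
    """

    directions: np.ndarray
    b_values: np.ndarray
    measurement_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.measurement_frame = np.asarray(self.measurement_frame, dtype=float)
        if len(self.directions) != len(self.b_values):
            raise StructuralError(
                f"{len(self.directions)} directions but "
                f"{len(self.b_values)} b-values")
        if np.any(self.b_values < 0):
            raise StructuralError("negative b-value")
        M = self.measurement_frame
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-6):
            raise StructuralError("measurement frame is not orthonormal")
        norms = np.linalg.norm(self.directions, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.directions = np.where(
                norms[:, None] > 1e-12, self.directions / np.where(
                    norms[:, None] > 1e-12, norms[:, None], 1.0),
                0.0)

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def baseline_mask(self) -> np.ndarray:
        """Boolean mask of baseline (b~0 or zero-direction) volumes."""
        zero_dir = np.linalg.norm(np.asarray(self.directions, float)
                                  .reshape(-1, 3), axis=1) < 1e-6
        return (self.b_values < BASELINE_B_MAX) | zero_dir

    def image_frame_directions(self) -> np.ndarray:
        """Directions rotated into image space by the measurement frame."""
        return self.directions @ self.measurement_frame.T


@dataclass
class DWIScan:
    """A 4D diffusion-weighted scan with its gradient table and geometry.

    ``signal`` is indexed ``(x, y, z, volume)``.  ``excluded`` carries one
    entry per volume: ``None`` while retained, otherwise a human-readable
    reason recorded by the QC stage that excluded it.
    """

    signal: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray
    gradients: GradientTable
    excluded: list = None  # list[str | None]

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise StructuralError(
                f"signal must be 4D, got {self.signal.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).ravel()
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.signal.shape[3] != len(self.gradients):
            raise StructuralError(
                f"{self.signal.shape[3]} volumes but "
                f"{len(self.gradients)} gradient entries")
        if self.excluded is None:
            self.excluded = [None] * self.n_volumes
        if len(self.excluded) != self.n_volumes:
            raise StructuralError("excluded flags do not match volume count")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def shape3d(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def retained_mask(self) -> np.ndarray:
        return np.array([r is None for r in self.excluded])

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.gradients.baseline_mask

    @property
    def retained_fraction(self) -> float:
        return float(self.retained_mask.sum()) / self.n_volumes

    def exclude(self, index: int, reason: str) -> None:
        """Mark a volume excluded; earlier reasons win."""
        if not 0 <= index < self.n_volumes:
            raise IndexError(f"volume index {index} out of range")
        if self.excluded[index] is None:
            self.excluded[index] = reason

    def copy(self) -> "DWIScan":
        return DWIScan(
            signal=self.signal.copy(),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            orientation=self.orientation.copy(),
            gradients=GradientTable(
                self.gradients.directions.copy(),
                self.gradients.b_values.copy(),
                self.gradients.measurement_frame.copy()),
            excluded=list(self.excluded),
        )


@dataclass
class Protocol:
    """Declarative QC configuration for a study.

    Geometry / diffusion expectations are optional (``None`` disables the
    corresponding comparison); thresholds default to the values the QC
    stages were designed around.
    """

    expected_dims: tuple = None
    expected_spacing: tuple = None
    spacing_tolerance: float = 0.01            # mm
    expected_orientation: tuple = None
    orientation_tolerance: float = 1e-3
    expected_bvalues: tuple = None
    bvalue_tolerance: float = 10.0             # s/mm^2
    expected_gradients: tuple = None
    gradient_angle_tolerance: float = 1.0      # degrees, axial

    check_image_info: bool = True
    check_diffusion_info: bool = True
    check_slice_wise: bool = True
    check_interlace: bool = True
    check_directional: bool = True

    slice_check_stdev_factor: float = 3.5
    interlace_corr_stdev_factor: float = 3.5
    retained_fraction_threshold: float = 0.3

    entropy_z_suspicious: float = 1.64
    entropy_z_unacceptable: float = 2.58
    histogram_subdivision_level: int = 2
    region_selector: str = "whole-brain"       # or "wm-like"
    fa_weighted_histogram: bool = False

    def __post_init__(self):
        if not 0.0 <= self.retained_fraction_threshold <= 1.0:
            raise ValueError("retained_fraction_threshold must be in [0, 1]")
        if not self.entropy_z_suspicious < self.entropy_z_unacceptable:
            raise ValueError(
                "entropy_z_suspicious must be below entropy_z_unacceptable")
        if self.region_selector not in ("whole-brain", "wm-like"):
            raise ValueError(f"unknown region selector {self.region_selector!r}")


def read_protocol(path) -> Protocol:
    """Load a protocol from its flat JSON representation."""
    with open(path) as fh:
        data = json.load(fh)
    for key in ("expected_dims", "expected_spacing", "expected_orientation",
                "expected_bvalues", "expected_gradients"):
        if data.get(key) is not None:
            data[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in data[key])
    return Protocol(**data)


def write_protocol(protocol: Protocol, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(protocol), fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# NRRD
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}
_NRRD_TYPE_NAMES = {
    "i1": "int8", "u1": "uint8", "i2": "int16", "u2": "uint16",
    "i4": "int32", "u4": "uint32", "i8": "int64", "u8": "uint64",
    "f4": "float", "f8": "double",
}


def _parse_vector(text: str) -> np.ndarray:
    return np.array([float(t) for t in
                     text.strip().lstrip("(").rstrip(")").split(",")])


def _parse_vector_list(text: str):
    out = []
    for tok in re.findall(r"\(([^)]*)\)|none", text):
        out.append(None if tok == "" else
                   np.array([float(t) for t in tok.split(",")]))
    return out


def _fmt_vec(v) -> str:
    return "(" + ",".join(repr(float(x)) for x in v) + ")"


def _from_bytes(blob: bytes, dtype: np.dtype) -> np.ndarray:
    """Decode a binary payload, tolerating truncation mid-element so the
    sample-count check can report the mismatch."""
    usable = (len(blob) // dtype.itemsize) * dtype.itemsize
    return np.frombuffer(blob[:usable], dtype=dtype)


def read_nrrd(path) -> DWIScan:
    """Read an NA-MIC DWI NRRD file into a :class:`DWIScan`.

    Supports attached headers with raw, gzip and ascii encodings.  The
    gradient axis is identified from the ``kinds`` field; data axes are
    reordered so volumes come last.  Per-volume b-values follow the
    norm-squared scaling convention.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path} is not an NRRD file")
        fields: dict = {}
        keyvals: dict = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("utf-8", "replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                k, v = text.split(":=", 1)
                keyvals[k.strip()] = v.strip()
            elif ": " in text or text.endswith(":"):
                k, _, v = text.partition(":")
                fields[k.strip().lower()] = v.strip()
            else:
                raise FormatError(f"unparseable header line: {text!r}")
        blob = fh.read()

    try:
        dtype_code = _NRRD_TYPES[fields["type"]]
        sizes = [int(t) for t in fields["sizes"].split()]
        dim = int(fields["dimension"])
    except KeyError as exc:
        raise FormatError(f"missing NRRD field: {exc}") from exc
    if dim != 4 or len(sizes) != 4:
        raise FormatError(f"expected a 4D DWI NRRD, got dimension {dim}")

    endian = "<" if fields.get("endian", "little") == "little" else ">"
    dtype = np.dtype(endian + dtype_code)
    encoding = fields.get("encoding", "raw").lower()
    count = int(np.prod(sizes))
    if encoding == "raw":
        data = _from_bytes(blob, dtype)
    elif encoding in ("gzip", "gz"):
        data = _from_bytes(gzip.decompress(blob), dtype)
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(blob.split(), dtype=float).astype(dtype)
    else:
        raise FormatError(f"unsupported NRRD encoding {encoding!r}")
    if data.size != count:
        raise StructuralError(
            f"data has {data.size} samples, header promises {count}")
    # first size is fastest-varying in the stream
    array = data.reshape(sizes, order="F")

    kinds = fields.get("kinds", "").split()
    grad_axis = 3
    if kinds:
        for i, k in enumerate(kinds):
            if k.lower() in ("list", "vector", "point", "none"):
                grad_axis = i
                break
    array = np.moveaxis(array, grad_axis, 3)
    n_vols = array.shape[3]

    space_dirs = _parse_vector_list(fields.get("space directions", ""))
    spatial_dirs = [d for d in space_dirs if d is not None]
    if len(spatial_dirs) == 3:
        cols = np.stack(spatial_dirs, axis=1)  # world column per axis
        spacing = np.linalg.norm(cols, axis=0)
        orientation = cols / spacing
    else:
        spacing = np.ones(3)
        orientation = np.eye(3)
    origin = (_parse_vector(fields["space origin"])
              if "space origin" in fields else np.zeros(3))
    mframe = np.eye(3)
    if "measurement frame" in fields:
        mcols = _parse_vector_list(fields["measurement frame"])
        mframe = np.stack([c for c in mcols if c is not None], axis=1)

    if "DWMRI_b-value" not in keyvals:
        raise FormatError("missing gradient key: DWMRI_b-value")
    b_nominal = float(keyvals["DWMRI_b-value"])
    raw_grads = []
    for i in range(n_vols):
        key = f"DWMRI_gradient_{i:04d}"
        if key not in keyvals:
            raise FormatError(f"missing gradient key: {key}")
        raw_grads.append(np.array([float(t) for t in keyvals[key].split()]))
    extra = len([k for k in keyvals if k.startswith("DWMRI_gradient_")])
    if extra != n_vols:
        raise StructuralError(
            f"header lists {extra} gradients for {n_vols} volumes")

    raw = np.stack(raw_grads)
    norms = np.linalg.norm(raw, axis=1)
    b_values = b_nominal * norms ** 2
    directions = np.where(norms[:, None] > 1e-12,
                          raw / np.where(norms[:, None] > 1e-12,
                                         norms[:, None], 1.0), 0.0)
    table = GradientTable(directions, b_values, mframe)
    return DWIScan(signal=array, spacing=spacing, origin=origin,
                   orientation=orientation, gradients=table)


def write_nrrd(scan: DWIScan, path, encoding: str = "gzip") -> None:
    """Write a scan as NA-MIC DWI NRRD, dropping excluded volumes.

    Gradient keys are renumbered contiguously over the retained volumes
    and b-value scaling is re-encoded into the gradient norms relative to
    the largest retained b-value.
    """
    retained = np.flatnonzero(scan.retained_mask)
    if retained.size == 0:
        raise StructuralError("refusing to write a scan with zero "
                              "retained volumes")
    sig = np.ascontiguousarray(scan.signal[..., retained])
    bvals = scan.gradients.b_values[retained]
    dirs = scan.gradients.directions[retained]
    b_ref = float(bvals.max()) if bvals.max() > 0 else 0.0
    if b_ref > 0:
        scale = np.sqrt(bvals / b_ref)
    else:
        scale = np.zeros_like(bvals)
    grads_out = dirs * scale[:, None]

    dt = sig.dtype.newbyteorder("=")
    code = dt.str.lstrip("<>=|")
    if code not in _NRRD_TYPE_NAMES:
        sig = sig.astype(np.float64)
        dt = sig.dtype
        code = "f8"
    cols = scan.orientation * scan.spacing[None, :]

    lines = [
        "NRRD0005",
        f"type: {_NRRD_TYPE_NAMES[code]}",
        "dimension: 4",
        "space: left-posterior-superior",
        "sizes: " + " ".join(str(s) for s in sig.shape),
        ("space directions: "
         + " ".join(_fmt_vec(cols[:, j]) for j in range(3)) + " none"),
        "kinds: domain domain domain list",
        "endian: little",
        f"encoding: {encoding}",
        "space origin: " + _fmt_vec(scan.origin),
        ("measurement frame: "
         + " ".join(_fmt_vec(scan.gradients.measurement_frame[:, j])
                    for j in range(3))),
        "modality:=DWMRI",
        f"DWMRI_b-value:={b_ref!r}",
    ]
    for i, g in enumerate(grads_out):
        lines.append(f"DWMRI_gradient_{i:04d}:="
                     + " ".join(repr(float(x)) for x in g))
    header = "\n".join(lines) + "\n\n"

    payload = np.asarray(sig, dtype=dt.newbyteorder("<")) \
        .flatten(order="F").tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding == "ascii":
        payload = " ".join(
            repr(v) if sig.dtype.kind == "f" else str(v)
            for v in sig.flatten(order="F").tolist()).encode()
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(payload)


# ---------------------------------------------------------------------------
# FSL bvec/bval + NIfTI
# ---------------------------------------------------------------------------

def read_fsl(bvec_path, bval_path, image_path) -> DWIScan:
    """Read a NIfTI image with FSL-style ``.bvec``/``.bval`` sidecars."""
    import nibabel as nib

    bvec = np.loadtxt(bvec_path, ndmin=2)
    bval = np.loadtxt(bval_path).ravel()
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise StructuralError("image is not 4D")
    n = data.shape[3]
    if bvec.shape == (3, n):
        # the 3x3 tie resolves here: FSL convention, rows are components
        dirs = bvec.T
    elif bvec.shape == (n, 3):
        dirs = bvec
    else:
        raise StructuralError(
            f"bvec shape {bvec.shape} incompatible with {n} volumes")
    if bval.size != n:
        raise StructuralError(
            f"{bval.size} b-values for {n} volumes")
    affine = img.affine
    cols = affine[:3, :3]
    spacing = np.linalg.norm(cols, axis=0)
    orientation = cols / spacing
    table = GradientTable(dirs, bval, np.eye(3))
    return DWIScan(signal=data, spacing=spacing, origin=affine[:3, 3],
                   orientation=orientation, gradients=table)


def write_fsl(scan: DWIScan, bvec_path, bval_path, image_path) -> None:
    """Write retained volumes as NIfTI + bvec/bval text sidecars."""
    import nibabel as nib

    retained = np.flatnonzero(scan.retained_mask)
    if retained.size == 0:
        raise StructuralError("refusing to write a scan with zero "
                              "retained volumes")
    affine = np.eye(4)
    affine[:3, :3] = scan.orientation * scan.spacing[None, :]
    affine[:3, 3] = scan.origin
    img = nib.Nifti1Image(scan.signal[..., retained], affine)
    nib.save(img, str(image_path))
    np.savetxt(bvec_path, scan.gradients.directions[retained].T, fmt="%.9f")
    np.savetxt(bval_path, scan.gradients.b_values[retained][None, :],
               fmt="%.6g")
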