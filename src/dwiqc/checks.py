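"""Protocol-compliance checks: scan geometry and diffusion metadata.

These are the first automatic QC stages: a scan whose dimensions,
spacing, orientation, b-values or gradient directions disagree with the
study protocol is flagged before any intensity analysis runs.  Both
checks are pure — the scan is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIScan, Protocol

__all__ = ["CheckResult", "check_image_info", "check_diffusion_info",
           "axial_angle_deg"]


@dataclass
class CheckResult:
    check_name: str
    passed: bool
    detail: str = ""
    per_volume_flags: list = None


def check_image_info(scan: DWIScan, protocol: Protocol) -> CheckResult:
    """Compare dimensions, spacing and orientation against the protocol.

    Passes iff dimensions match exactly, every spacing component is
    within ``spacing_tolerance`` and the orientation matrix is within
    elementwise ``orientation_tolerance``.  The detail names the first
    failing property.
    """
    if protocol.expected_dims is not None:
        dims = tuple(int(d) for d in scan.shape3d)
        if dims != tuple(int(d) for d in protocol.expected_dims):
            return CheckResult("image_info", False,
                               f"dimensions {dims} != expected "
                               f"{tuple(protocol.expected_dims)}")
    if protocol.expected_spacing is not None:
        exp = np.asarray(protocol.expected_spacing, float)
        dev = np.abs(scan.spacing - exp)
        if np.any(dev > protocol.spacing_tolerance):
            i = int(np.argmax(dev))
            return CheckResult("image_info", False,
                               f"spacing[{i}] = {scan.spacing[i]:g} mm, "
                               f"expected {exp[i]:g} mm")
    if protocol.expected_orientation is not None:
        exp = np.asarray(protocol.expected_orientation, float)
        if np.any(np.abs(scan.orientation - exp)
                  > protocol.orientation_tolerance):
            return CheckResult("image_info", False,
                               "orientation matrix deviates from expected")
    return CheckResult("image_info", True, "geometry matches protocol")


def axial_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two axes in degrees, sign-invariant (min over ±b).

    Diffusion sensitization is symmetric under g -> -g, so gradient
    directions compare as axes, not as vectors.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 0.0 if na < 1e-12 and nb < 1e-12 else 90.0
    c = abs(float(np.dot(a, b)) / (na * nb))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def check_diffusion_info(scan: DWIScan, protocol: Protocol) -> CheckResult:
    """Compare per-volume b-values and gradient directions to the protocol.

    A volume passes iff its b-value is within ``bvalue_tolerance`` and
    the axial angle to the expected direction is within
    ``gradient_angle_tolerance`` degrees.  The scan passes iff every
    volume does.
    """
    flags = None
    if protocol.expected_bvalues is not None:
        exp_b = np.asarray(protocol.expected_bvalues, float).ravel()
        if exp_b.size != scan.n_volumes:
            return CheckResult("diffusion_info", False,
                               f"gradient count {scan.n_volumes} != "
                               f"expected {exp_b.size}")
        flags = (np.abs(scan.gradients.b_values - exp_b)
                 <= protocol.bvalue_tolerance)
    if protocol.expected_gradients is not None:
        exp_g = np.asarray(protocol.expected_gradients, float).reshape(-1, 3)
        if len(exp_g) != scan.n_volumes:
            return CheckResult("diffusion_info", False,
                               f"gradient count {scan.n_volumes} != "
                               f"expected {len(exp_g)}")
        ang_ok = np.array([
            axial_angle_deg(g, e) <= protocol.gradient_angle_tolerance
            for g, e in zip(scan.gradients.directions, exp_g)])
        flags = ang_ok if flags is None else (flags & ang_ok)
    if flags is None:
        return CheckResult("diffusion_info", True,
                           "no diffusion expectations in protocol")
    passed = bool(flags.all())
    bad = np.flatnonzero(~flags)
    detail = ("diffusion table matches protocol" if passed else
              f"volumes {bad.tolist()} deviate from expected table")
    return CheckResult("diffusion_info", passed, detail,
                       per_volume_flags=flags.tolist())
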