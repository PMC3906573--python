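"""Pipeline orchestration and QC report serialization.

``run_pipeline`` executes the automatic QC stages in acquisition order —
geometry check, diffusion-table check, slice-wise intensity check,
interlace check, retained-fraction gate, tensor fit, directional
detection (with leave-one-out correction for suspicious scans) and a
final retained-fraction gate — accumulating per-volume exclusions
monotonically and recording every verdict in a :class:`QCReport` that
serializes to XML (validating against the shipped schema) or JSON for
post-hoc meta-analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from lxml import etree

from .checks import CheckResult, check_image_info, check_diffusion_info
from .directional import (DirectionalVerdict, EntropyStats,
                          correct_leave_one_out)
from .intensity import slice_wise_check, interlace_check
from .io import DWIScan, Protocol
from .tensor import brain_mask

__all__ = ["QCReport", "run_pipeline", "retained_fraction_gate",
           "write_report", "report_schema"]


@dataclass
class QCReport:
    checks: list = field(default_factory=list)          # CheckResult
    volume_status: list = field(default_factory=list)   # dicts
    slice_correlations: list = None                     # nested list
    interlace_correlations: list = None
    directional: DirectionalVerdict = None
    retained_fraction: float = 1.0
    scan_rejected: bool = False
    reject_reason: str = ""
    incomplete: bool = False
    warnings: list = field(default_factory=list)

    def tally(self, scan: DWIScan) -> None:
        """Refresh per-volume status and retained fraction from a scan."""
        self.volume_status = []
        for i, reason in enumerate(scan.excluded):
            stage = ""
            if reason:
                low = reason.lower()
                if "slice-wise" in low:
                    stage = "slice_wise"
                elif "interlace" in low or "venetian" in low:
                    stage = "interlace"
                elif "dominating-direction" in low:
                    stage = "directional"
                else:
                    stage = "other"
            self.volume_status.append({
                "index": i, "retained": reason is None,
                "stage": stage, "reason": reason or ""})
        self.retained_fraction = scan.retained_fraction


def retained_fraction_gate(report: QCReport, protocol: Protocol) -> bool:
    """True (continue) iff retained/original >= the protocol threshold."""
    return bool(report.retained_fraction
                >= protocol.retained_fraction_threshold)


def run_pipeline(scan: DWIScan, protocol: Protocol,
                 entropy_stats: EntropyStats = None):
    """Run the automatic QC pipeline on a copy of ``scan``.

    Returns ``(report, corrected_scan_or_None)``; the corrected scan is
    ``None`` when the scan is rejected.  ``entropy_stats`` is required
    iff the directional check is enabled.
    """
    if protocol.check_directional and entropy_stats is None:
        raise ValueError("entropy_stats required for the directional check")
    work = scan.copy()
    report = QCReport()
    report.tally(work)

    def reject(reason: str):
        report.scan_rejected = True
        report.reject_reason = reason
        report.tally(work)
        return report, None

    try:
        if protocol.check_image_info:
            res = check_image_info(work, protocol)
            report.checks.append(res)
            if not res.passed:
                return reject(f"image information check failed: {res.detail}")
        if protocol.check_diffusion_info:
            res = check_diffusion_info(work, protocol)
            report.checks.append(res)
            if not res.passed:
                return reject(
                    f"diffusion information check failed: {res.detail}")

        if protocol.check_slice_wise:
            matrix, verdicts = slice_wise_check(work, protocol)
            report.slice_correlations = matrix.values.tolist()
            report.warnings += matrix.warnings
            n_bad = sum(v is not None for v in verdicts)
            report.checks.append(CheckResult(
                "slice_wise", n_bad == 0,
                f"{n_bad} volume(s) excluded for slice-wise artifacts"))
        if protocol.check_interlace:
            inter = interlace_check(work, protocol)
            report.interlace_correlations = inter.correlations.tolist()
            report.warnings += inter.warnings
            n_bad = int(inter.flagged.sum())
            report.checks.append(CheckResult(
                "interlace", n_bad == 0,
                f"{n_bad} volume(s) excluded for interlace artifacts"))

        report.tally(work)
        if not retained_fraction_gate(report, protocol):
            return reject(
                f"retained fraction {report.retained_fraction:.4f} below "
                f"threshold {protocol.retained_fraction_threshold:g}")

        if protocol.check_directional:
            mask = brain_mask(work)
            verdict = correct_leave_one_out(work, entropy_stats, protocol,
                                            mask=mask)
            report.directional = verdict
            report.checks.append(CheckResult(
                "directional", not verdict.scan_rejected,
                f"category {verdict.category}, z = {verdict.z:.3f}, "
                f"{len(verdict.removed_volumes)} volume(s) removed"))
            if verdict.scan_rejected:
                return reject("directional artifact: " + verdict.detail)

        report.tally(work)
        if not retained_fraction_gate(report, protocol):
            return reject(
                f"retained fraction {report.retained_fraction:.4f} below "
                f"threshold {protocol.retained_fraction_threshold:g}")
    except (OSError, RuntimeError, ValueError) as exc:
        report.incomplete = True
        report.tally(work)
        report.scan_rejected = True
        report.reject_reason = f"pipeline aborted: {exc}"
        return report, None

    report.tally(work)
    return report, work


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _report_dict(report: QCReport) -> dict:
    d = {
        "scan_rejected": report.scan_rejected,
        "reject_reason": report.reject_reason,
        "retained_fraction": report.retained_fraction,
        "incomplete": report.incomplete,
        "checks": [asdict(c) for c in report.checks],
        "volumes": report.volume_status,
        "slice_correlations": report.slice_correlations,
        "interlace_correlations": report.interlace_correlations,
        "directional": (asdict(report.directional)
                        if report.directional else None),
        "warnings": report.warnings,
    }
    return d


def write_report(report: QCReport, path, format: str = "xml") -> None:
    """Serialize a report as XML (schema-valid) or JSON."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_report_dict(report), fh, indent=2, default=_jsonable)
            fh.write("\n")
        return
    if format != "xml":
        raise ValueError(f"unknown report format {format!r}")

    root = etree.Element("dwiqc_report", version="1.0")
    summary = etree.SubElement(
        root, "summary",
        scan_rejected=str(report.scan_rejected).lower(),
        retained_fraction=f"{report.retained_fraction:.6f}",
        incomplete=str(report.incomplete).lower())
    if report.reject_reason:
        summary.set("reject_reason", report.reject_reason)

    checks = etree.SubElement(root, "checks")
    for c in report.checks:
        etree.SubElement(checks, "check", name=c.check_name,
                         passed=str(c.passed).lower(), detail=c.detail)

    vols = etree.SubElement(root, "volumes")
    for v in report.volume_status:
        el = etree.SubElement(vols, "volume", index=str(v["index"]),
                              retained=str(v["retained"]).lower())
        if not v["retained"]:
            el.set("stage", v["stage"])
            el.set("reason", v["reason"])

    if report.slice_correlations is not None:
        sc = etree.SubElement(root, "slice_correlations")
        for i, row in enumerate(report.slice_correlations):
            etree.SubElement(sc, "volume", index=str(i)).text = \
                " ".join(f"{x:.6f}" for x in row)
    if report.interlace_correlations is not None:
        ic = etree.SubElement(root, "interlace_correlations")
        ic.text = " ".join(f"{x:.6f}" for x in report.interlace_correlations)
    if report.directional is not None:
        dv = report.directional
        el = etree.SubElement(root, "directional",
                              entropy=f"{dv.entropy:.6f}", z=f"{dv.z:.4f}",
                              category=dv.category,
                              scan_rejected=str(dv.scan_rejected).lower())
        for r in dv.removed_volumes:
            etree.SubElement(el, "removed", volume=str(r))
    if report.warnings:
        ws = etree.SubElement(root, "warnings")
        for w in report.warnings:
            etree.SubElement(ws, "warning").text = w

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def report_schema() -> "etree.XMLSchema":
    """The XML schema the report format validates against."""
    from importlib import resources
    with resources.files("dwiqc").joinpath("schema/qcreport.xsd").open("rb") \
            as fh:
        return etree.XMLSchema(etree.parse(fh))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
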