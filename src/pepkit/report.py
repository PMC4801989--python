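"""Structured report assembly and JSON/TSV serialization.

Numeric formatting is fixed (masses 4 dp, pI 2 dp, extinction integers,
profile values 3 dp) so golden-file comparisons stay stable.
"""

from __future__ import annotations

import io
import json
from typing import Any

from . import properties, salsa
from .assign import AssignmentReport
from .errors import IsoelectricPointUndefinedError, ProfileUnavailableError
from .chem import PEPTIDE
from .sequence import PolymerSequence, canonical_string


def _mass(x: float) -> float:
    return round(x, 4)


def assignment_to_dict(report: AssignmentReport) -> dict[str, Any]:
    return {
        "tolerance": report.config.tolerance,
        "iterations_run": report.iterations_run,
        "peaks": [
            {
                "mz": pa.peak.mz,
                "assigned": pa.assigned,
                "iteration": pa.iteration,
                "candidates": [
                    {
                        "deletions": list(c.deletions),
                        "adducts": list(c.modifications),
                        "calculated_mass": _mass(c.calculated_mass),
                        "delta": _mass(c.delta),
                    }
                    for c in pa.candidates
                ],
            }
            for pa in report.assignments
        ],
    }


def build_report(
    seq: PolymerSequence,
    assignment: AssignmentReport | None = None,
    pka: properties.PKaSet | None = None,
    cf_table: salsa.ChouFasmanTable | None = None,
    masses=None,
) -> dict[str, Any]:
    """Assemble the full property report for a sequence.

    Peptide-only sections (pI, extinction, charge summary, profile) are
    included only for peptides; an out-of-range profile request is reported
    as unavailable rather than failing the run.
    """
    out: dict[str, Any] = {
        "polymer_class": seq.polymer_class,
        "sequence": canonical_string(seq),
        "length": len(seq),
        "n_terminus": seq.n_terminus.name,
        "c_terminus": seq.c_terminus.name,
        "formula": properties.molecular_formula(seq).hill(),
        "molecular_weight": _mass(properties.molecular_weight(seq, masses)),
    }
    if seq.polymer_class == PEPTIDE:
        try:
            out["isoelectric_point"] = round(properties.isoelectric_point(seq, pka), 2)
        except IsoelectricPointUndefinedError as exc:
            out["isoelectric_point"] = None
            out["isoelectric_point_note"] = str(exc)
        ext = properties.extinction_280(seq)
        out["extinction_280"] = {
            "n_trp": ext.n_trp,
            "n_tyr": ext.n_tyr,
            "n_cystine_max": ext.n_cystine_max,
            "oxidized": ext.epsilon_oxidized,
            "reduced": ext.epsilon_reduced,
        }
        summary = properties.charge_summary(seq)
        fractions = summary.fractions
        out["charge_summary"] = {
            "acidic": summary.n_acidic,
            "basic": summary.n_basic,
            "other": summary.n_other,
            "fraction_acidic": round(fractions[0], 4),
            "fraction_basic": round(fractions[1], 4),
            "fraction_other": round(fractions[2], 4),
        }
        try:
            profile = salsa.contiguity_profile(seq, cf_table)
            out["beta_strand_profile"] = {
                "available": True,
                "values": [round(v, 3) for v in profile.values],
            }
        except ProfileUnavailableError as exc:
            out["beta_strand_profile"] = {"available": False, "note": str(exc)}
    if assignment is not None:
        out["assignment"] = assignment_to_dict(assignment)
    return out


def to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def assignment_tsv(report: AssignmentReport) -> str:
    """Assignment table: one row per candidate (or per unassigned peak)."""
    buf = io.StringIO()
    buf.write("peak_mz\tdeletions\tadducts\tcalculated_mass\tdelta\titeration\n")
    for pa in report.assignments:
        if not pa.candidates:
            buf.write(f"{pa.peak.mz:g}\t-\t-\t-\t-\tunassigned\n")
            continue
        for c in pa.candidates:
            dels = ", ".join(c.deletions) or "-"
            mods = ", ".join(c.modifications) or "-"
            buf.write(
                f"{pa.peak.mz:g}\t{dels}\t{mods}\t{c.calculated_mass:.4f}"
                f"\t{c.delta:.4f}\t{pa.iteration}\n"
            )
    return buf.getvalue()


def profile_tsv(seq: PolymerSequence, profile: salsa.ContiguityProfile) -> str:
    """Profile table with 1-based residue numbering."""
    buf = io.StringIO()
    buf.write("position\tresidue\tpropensity\n")
    for i, (code, value) in enumerate(zip(seq.codes, profile.values), start=1):
        buf.write(f"{i}\t{code}\t{value:.3f}\n")
    return buf.getvalue()


def charge_curve_tsv(curve: list[tuple[float, float]]) -> str:
    buf = io.StringIO()
    buf.write("pH\tnet_charge\n")
    for ph, charge in curve:
        buf.write(f"{ph:.1f}\t{charge:.4f}\n")
    return buf.getvalue()


def to_tsv(report: dict[str, Any]) -> str:
    """Flat key/value TSV rendering of the report (assignment as a sub-table)."""
    buf = io.StringIO()

    def emit(prefix: str, value: Any) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                emit(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(value, list) and prefix != "assignment.peaks":
            buf.write(f"{prefix}\t{', '.join(str(v) for v in value)}\n")
        else:
            buf.write(f"{prefix}\t{value}\n")

    assignment = report.get("assignment")
    for key, value in report.items():
        if key == "assignment":
            continue
        emit(key, value)
    if assignment is not None:
        buf.write("\n")
        buf.write("peak_mz\tdeletions\tadducts\tcalculated_mass\tdelta\titeration\n")
        for peak in assignment["peaks"]:
            if not peak["candidates"]:
                buf.write(f"{peak['mz']:g}\t-\t-\t-\t-\tunassigned\n")
                continue
            for c in peak["candidates"]:
                dels = ", ".join(c["deletions"]) or "-"
                mods = ", ".join(c["adducts"]) or "-"
                buf.write(
                    f"{peak['mz']:g}\t{dels}\t{mods}\t{c['calculated_mass']:.4f}"
                    f"\t{c['delta']:.4f}\t{peak['iteration']}\n"
                )
    return buf.getvalue()
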