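"""Cross-technique reconciliation of oligomeric state and dimensions.

Combines the per-technique outputs — monomer mass from MALDI, particle mass
from the SAXS excluded volume, rod diameter from the cross-sectional Guinier
fit, AFM size-class dimensions and SAXS Dmax, ITC trend — into a single
report ranking candidate stoichiometries and auditing the dimensional
cross-checks with explicit tolerance bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StoichiometryCandidate",
    "ConsistencyReport",
    "stoichiometry_from_mw",
    "rod_vs_helix",
    "afm_vs_saxs",
    "build_report",
]

ALPHA_HELIX_DIAMETER = 12.0  # Angstrom, canonical alpha-helix diameter


@dataclass
class StoichiometryCandidate:
    n: int
    residual: float  # |MW - n*M| / M


@dataclass
class ConsistencyReport:
    monomer_mass_kda: Optional[float] = None
    saxs_mw_kda: Optional[float] = None
    stoichiometry: list = field(default_factory=list)
    rod_check: Optional[dict] = None
    afm_saxs_check: Optional[dict] = None
    itc_trend: Optional[dict] = None
    maldi_summary: Optional[dict] = None
    missing: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Oligomeric-state consistency report", ""]
        if self.monomer_mass_kda is not None:
            lines.append(f"- Monomer mass M: {self.monomer_mass_kda:.2f} kDa")
        if self.saxs_mw_kda is not None:
            lines.append(f"- SAXS particle mass: {self.saxs_mw_kda:.1f} kDa")
        if self.stoichiometry:
            lines.append("")
            lines.append("## Candidate stoichiometries (by |MW/M - n|)")
            for c in self.stoichiometry:
                lines.append(f"- n = {c['n']}: residual {c['residual']:.3f}")
        for name, check in (("Rod diameter vs alpha-helix", self.rod_check),
                            ("AFM vs SAXS dimensions", self.afm_saxs_check)):
            if check is not None:
                lines.append("")
                lines.append(f"## {name}")
                for k, v in check.items():
                    lines.append(f"- {k}: {v}")
        if self.itc_trend is not None:
            lines.append("")
            lines.append("## ITC temperature trend")
            for k, v in self.itc_trend.items():
                lines.append(f"- {k}: {v}")
        if self.missing:
            lines.append("")
            lines.append(f"Missing techniques: {', '.join(self.missing)}")
        for f in self.flags:
            lines.append(f"- FLAG: {f}")
        return "\n".join(lines) + "\n"


def stoichiometry_from_mw(mw_kda: float, monomer_kda: float,
                          n_max: int = 10) -> list[StoichiometryCandidate]:
    """Rank oligomer orders n by how well n*M matches the particle mass.

    Candidates are ranked by |MW/M - n|; ties break toward the smaller n.
    """
    if mw_kda <= 0 or monomer_kda <= 0:
        raise ValueError("masses must be positive")
    ratio = mw_kda / monomer_kda
    cands = [StoichiometryCandidate(n=n, residual=abs(ratio - n))
             for n in range(1, n_max + 1)]
    cands.sort(key=lambda c: (c.residual, c.n))
    return cands


def rod_vs_helix(diameter_a: float,
                 helix_diameter: float = ALPHA_HELIX_DIAMETER,
                 tolerance: float = 0.25) -> dict:
    """Compare a rod cross-section diameter with the alpha-helix diameter.

    Verdict "consistent" when the ratio is within +/- ``tolerance`` of 1 —
    i.e. the rod-like scattering cross-section is a single helix wide.
    """
    if diameter_a <= 0:
        raise ValueError("diameter must be positive")
    ratio = diameter_a / helix_diameter
    return {
        "diameter_a": float(diameter_a),
        "helix_diameter_a": float(helix_diameter),
        "ratio": float(ratio),
        "tolerance": float(tolerance),
        "consistent": bool(abs(ratio - 1.0) <= tolerance),
    }


def afm_vs_saxs(range_a1_nm: float, dmax_nm: float,
                tolerance: float = 0.35, borderline_band: float = 0.10) -> dict:
    """Compare the AFM full major axis (2*a1) with the SAXS Dmax.

    Within ``tolerance`` of 1 the dimensions "match"; within an extra
    ``borderline_band`` the verdict is "borderline" (both numbers printed);
    beyond that "mismatch". a1 itself is reported too, since whether the
    semi- or full axis corresponds to Dmax is a modelling choice.
    """
    if range_a1_nm <= 0 or dmax_nm <= 0:
        raise ValueError("dimensions must be positive")
    full_axis = 2.0 * range_a1_nm
    ratio = full_axis / dmax_nm
    dev = abs(ratio - 1.0)
    if dev <= tolerance:
        verdict = "matching"
    elif dev <= tolerance + borderline_band:
        verdict = "borderline"
    else:
        verdict = "mismatch"
    return {
        "a1_nm": float(range_a1_nm),
        "full_major_axis_nm": float(full_axis),
        "dmax_nm": float(dmax_nm),
        "ratio": float(ratio),
        "tolerance": float(tolerance),
        "verdict": verdict,
    }


def build_report(monomer_mass_kda: Optional[float] = None,
                 saxs_mw_kda: Optional[float] = None,
                 rod_diameter_a: Optional[float] = None,
                 afm_range_a1_nm: Optional[float] = None,
                 saxs_dmax_nm: Optional[float] = None,
                 itc_trend=None,
                 maldi_summary: Optional[dict] = None,
                 n_max: int = 10) -> ConsistencyReport:
    """Assemble the cross-technique report from whatever evidence exists.

    Never fails on partial input; techniques that were not supplied are
    listed as missing. Raises only when no evidence at all is provided.
    """
    provided = [v is not None for v in (monomer_mass_kda, saxs_mw_kda,
                                        rod_diameter_a, afm_range_a1_nm,
                                        itc_trend, maldi_summary)]
    if not any(provided):
        raise ValueError("no evidence provided")
    rep = ConsistencyReport(monomer_mass_kda=monomer_mass_kda,
                            saxs_mw_kda=saxs_mw_kda,
                            maldi_summary=maldi_summary)
    if monomer_mass_kda is not None and saxs_mw_kda is not None:
        cands = stoichiometry_from_mw(saxs_mw_kda, monomer_mass_kda, n_max)
        rep.stoichiometry = [asdict(c) for c in cands]
    elif saxs_mw_kda is None:
        rep.missing.append("saxs_mw")
    if rod_diameter_a is not None:
        rep.rod_check = rod_vs_helix(rod_diameter_a)
    else:
        rep.missing.append("rod_diameter")
    if afm_range_a1_nm is not None and saxs_dmax_nm is not None:
        rep.afm_saxs_check = afm_vs_saxs(afm_range_a1_nm, saxs_dmax_nm)
        if rep.afm_saxs_check["verdict"] != "matching":
            rep.flags.append(
                "AFM/SAXS dimension check is %s (2*a1 = %.1f nm vs Dmax = "
                "%.1f nm)" % (rep.afm_saxs_check["verdict"],
                              rep.afm_saxs_check["full_major_axis_nm"],
                              saxs_dmax_nm))
    else:
        rep.missing.append("afm_vs_saxs")
    if itc_trend is not None:
        trend = itc_trend if isinstance(itc_trend, dict) else {
            "totals_uj": {str(k): v for k, v in itc_trend.totals.items()},
            "monotone_decreasing": itc_trend.monotone_decreasing,
            "ties": itc_trend.ties,
        }
        rep.itc_trend = trend
    else:
        rep.missing.append("itc")
    if monomer_mass_kda is None:
        rep.missing.append("monomer_mass")
    return rep
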