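"""MALDI-TOF oligomer series assignment.

Intact-protein MALDI spectra of self-associating proteins show a ladder of
peaks at m/z = (n*M + z*m_H)/z for oligomer order n and charge z. This module
estimates the monomer mass M from anchor peaks with known (n, z), predicts
series positions, assigns every peak to all (n, z) interpretations within a
ppm tolerance, and reports algebraic degeneracies such as (n=3, z=1) vs
(n=6, z=2), which share an identical m/z.

Average (not monoisotopic) masses are assumed throughout: linear-mode MALDI
in the 17-120 kDa range cannot resolve isotopic structure. Peaks are modelled
as protonated ions [nM + zH]^z+; at 17 kDa the proton shifts m/z by ~60 ppm,
well inside the assignment tolerances, and a bare n*M convention is available
via ``proton_mass=0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROTON_MASS = 1.00728  # Da, average mass of H+

__all__ = [
    "PROTON_MASS",
    "PeakList",
    "MonomerEstimate",
    "OligomerAssignment",
    "predict_mz",
    "estimate_monomer_mass",
    "assign_peaks",
    "series_report",
]


@dataclass
class PeakList:
    """A centroided peak list (m/z ascending, optional intensities)."""

    mz: np.ndarray
    intensity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        if self.mz.ndim != 1:
            raise ValueError("mz must be 1-D")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MonomerEstimate:
    mass: float  # Da
    sd: float  # Da
    anchors: list  # (mz, n, z) rows actually used


@dataclass
class OligomerAssignment:
    mz: float
    n: Optional[int]
    z: Optional[int]
    predicted_mz: Optional[float]
    error_ppm: Optional[float]
    ambiguous: bool
    alternatives: list = field(default_factory=list)  # [(n, z, ppm), ...]

    @property
    def assigned(self) -> bool:
        return self.n is not None


def predict_mz(monomer_mass: float, n: int, z: int,
               proton_mass: float = PROTON_MASS) -> float:
    """m/z of the protonated oligomer ion [n*M + z*H]^z+."""
    if n < 1 or z < 1:
        raise ValueError("n and z must be >= 1")
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    return (n * monomer_mass + z * proton_mass) / z


def estimate_monomer_mass(anchors: Sequence[tuple[float, int, int]],
                          weights: Optional[Sequence[float]] = None,
                          proton_mass: float = PROTON_MASS) -> MonomerEstimate:
    """Least-squares monomer mass from anchor peaks with known (n, z).

    Each anchor contributes the linear relation z*(mz - m_H) = n*M, so the
    weighted least-squares solution is M = sum(w n y)/sum(w n^2) with
    y = z*(mz - m_H). Anchors whose residual exceeds 0.1% of M trigger a
    warning (inconsistent series), not a failure.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("need at least one anchor peak")
    mz = np.array([a[0] for a in anchors], dtype=float)
    n = np.array([a[1] for a in anchors], dtype=float)
    z = np.array([a[2] for a in anchors], dtype=float)
    if np.any(n < 1) or np.any(z < 1):
        raise ValueError("anchor n and z must be >= 1")
    w = np.ones_like(mz) if weights is None else np.asarray(weights, float)
    y = z * (mz - proton_mass)
    mass = float(np.sum(w * n * y) / np.sum(w * n**2))
    resid = y - n * mass
    if len(anchors) > 1:
        sd = float(np.sqrt(np.sum(w * resid**2) / (len(anchors) - 1)
                           / np.sum(w * n**2)))
    else:
        sd = 0.0
    if np.any(np.abs(resid / n) > 1e-3 * mass):
        warnings.warn("inconsistent anchors: residual exceeds 0.1% of the "
                      "monomer mass", stacklevel=2)
    return MonomerEstimate(mass=mass, sd=sd, anchors=anchors)


def _tolerance(n: int, tol_ppm: float, tol_ppm_high: float,
               high_n_from: int) -> float:
    return tol_ppm_high if n >= high_n_from else tol_ppm


def assign_peaks(peaks: PeakList, monomer_mass: float, n_max: int = 10,
                 z_max: int = 3, tol_ppm: float = 500.0,
                 tol_ppm_high: float = 2000.0, high_n_from: int = 5,
                 proton_mass: float = PROTON_MASS) -> list[OligomerAssignment]:
    """Assign each peak to all (n, z) series positions within tolerance.

    The primary assignment is the candidate with the smallest charge, then
    the smallest n (MALDI predominantly yields singly charged ions); every
    other candidate is retained as an alternative and the peak flagged
    ambiguous. High-order oligomer peaks are broad, so a wider tolerance
    (``tol_ppm_high``) applies from ``high_n_from`` upward. Peaks with no
    candidate are returned unassigned.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    out = []
    for mz in peaks.mz:
        cands = []
        for z in range(1, z_max + 1):
            for n in range(1, n_max + 1):
                pred = predict_mz(monomer_mass, n, z, proton_mass)
                ppm = (mz - pred) / pred * 1e6
                if abs(ppm) <= _tolerance(n, tol_ppm, tol_ppm_high,
                                          high_n_from):
                    cands.append((n, z, ppm, pred))
        if not cands:
            out.append(OligomerAssignment(mz=float(mz), n=None, z=None,
                                          predicted_mz=None, error_ppm=None,
                                          ambiguous=False))
            continue
        cands.sort(key=lambda c: (c[1], c[0]))
        n, z, ppm, pred = cands[0]
        out.append(OligomerAssignment(
            mz=float(mz), n=n, z=z, predicted_mz=float(pred),
            error_ppm=float(ppm), ambiguous=len(cands) > 1,
            alternatives=[(c[0], c[1], float(c[2])) for c in cands[1:]]))
    return out


def series_report(assignments: Sequence[OligomerAssignment]) -> dict:
    """Summarise an assignment list: stoichiometries seen, errors, degeneracies.

    Counts every candidate interpretation (primary and alternatives), reports
    the per-n ppm error spread of the primaries, and lists peaks with more
    than one (n, z) reading (algebraic series degeneracies).
    """
    assignments = list(assignments)
    rows = []
    degeneracies = []
    for a in assignments:
        if not a.assigned:
            continue
        rows.append({"mz": a.mz, "n": a.n, "z": a.z, "ppm": a.error_ppm,
                     "primary": True})
        for (n, z, ppm) in a.alternatives:
            rows.append({"mz": a.mz, "n": n, "z": z, "ppm": ppm,
                         "primary": False})
        if a.ambiguous:
            degeneracies.append(
                {"mz": a.mz, "candidates": [(a.n, a.z)]
                 + [(n, z) for n, z, _ in a.alternatives]})
    table = pd.DataFrame(rows, columns=["mz", "n", "z", "ppm", "primary"])
    primaries = table[table["primary"]] if len(table) else table
    # stoichiometry census uses primary readings only: every (n, z) has an
    # algebraically degenerate (2n, 2z) twin that would inflate the list
    stoich = sorted(int(v) for v in primaries["n"].unique()) \
        if len(primaries) else []
    per_n = {}
    for nn, grp in (primaries.groupby("n") if len(primaries) else []):
        per_n[int(nn)] = {"count": int(len(grp)),
                          "ppm_mean": float(grp["ppm"].mean()),
                          "ppm_max_abs": float(grp["ppm"].abs().max())}
    return {
        "n_peaks": len(assignments),
        "n_assigned": sum(a.assigned for a in assignments),
        "stoichiometries": stoich,
        "max_n": max(stoich) if stoich else None,
        "per_n": per_n,
        "degeneracies": degeneracies,
        "table": table,
    }
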