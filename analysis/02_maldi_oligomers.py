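#!/usr/bin/env python
"""Assign the MALDI ladder to oligomer stoichiometries.

Estimates the monomer mass from the dimer anchor, assigns every peak to its
(n, z) series positions, and reports which oligomer orders are present and
which peaks are algebraically degenerate (e.g. trimer z=1 vs hexamer z=2).
"""

import sys
from pathlib import Path

from oligostate import io as ogio
from oligostate.maldi import assign_peaks, estimate_monomer_mass, series_report

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module
sim = import_module("01_simulate_datasets")

ROOT = Path(__file__).resolve().parents[1]
PEAKS = ROOT / "results" / "data" / "maldi_peaks.csv"


def main():
    peaks = ogio.read_peaks(PEAKS) if PEAKS.exists() else sim.make_maldi()
    dimer = min(peaks.mz, key=lambda mz: abs(mz - 2 * sim.MONOMER_MASS))
    est = estimate_monomer_mass([(float(dimer), 2, 1)])
    print(f"monomer mass from dimer anchor: {est.mass:.1f} Da")

    assignments = assign_peaks(peaks, est.mass)
    rep = series_report(assignments)
    print(f"assigned {rep['n_assigned']}/{rep['n_peaks']} peaks; "
          f"stoichiometries {rep['stoichiometries']} (max n = {rep['max_n']})")
    for d in rep["degeneracies"]:
        print(f"  degenerate peak {d['mz']:.1f}: {d['candidates']}")

    out = ROOT / "results" / "maldi_report.json"
    payload = {k: v for k, v in rep.items() if k != "table"}
    payload["monomer_mass_da"] = est.mass
    payload["assignments"] = rep["table"]
    ogio.write_json_report(out, payload)
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
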