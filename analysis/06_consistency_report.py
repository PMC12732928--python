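#!/usr/bin/env python
"""Reconcile the four techniques into a candidate oligomeric state.

Combines the MALDI monomer mass, the SAXS model mass and dimensions, the AFM
size classes and the ITC trend into a ranked stoichiometry list plus the two
dimensional cross-checks (rod diameter vs a single alpha-helix; AFM smallest
class vs SAXS Dmax).
"""

import sys
from pathlib import Path
from importlib import import_module

from oligostate import io as ogio
from oligostate.consistency import build_report

sys.path.insert(0, str(Path(__file__).parent))
sim = import_module("01_simulate_datasets")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def _load(name):
    path = RESULTS / name
    return ogio.read_json_report(path) if path.exists() else None


def main():
    maldi = _load("maldi_report.json")
    saxs = _load("saxs_report.json")
    afm = _load("afm_ranges.json")
    itc = _load("itc_report.json")
    missing = [n for n, v in (("maldi", maldi), ("saxs", saxs),
                              ("afm", afm), ("itc", itc)) if v is None]
    if missing:
        sys.exit(f"run drivers 02-05 first; missing: {', '.join(missing)}")

    rep = build_report(
        monomer_mass_kda=maldi["monomer_mass_da"] / 1000.0,
        saxs_mw_kda=saxs["mw"]["mw_kda"],
        rod_diameter_a=saxs["cross_section"]["rod_diameter_a"],
        afm_range_a1_nm=afm["I"]["params"]["a1"]["mean"],
        saxs_dmax_nm=saxs["ift"]["dmax_a"] / 10.0,
        itc_trend={k: itc[k] for k in
                   ("totals_uj", "monotone_decreasing", "ties")},
    )
    top = rep.stoichiometry[:2]
    print("top stoichiometry candidates: "
          + ", ".join(f"n={c['n']} (residual {c['residual']:.2f})"
                      for c in top))
    if rep.afm_saxs_check:
        c = rep.afm_saxs_check
        print(f"AFM range I (2*a1 = {c['full_major_axis_nm']:.1f} nm) vs "
              f"SAXS Dmax = {c['dmax_nm']:.1f} nm: {c['verdict']}")
    print(f"ITC: heat grows on cooling = "
          f"{rep.itc_trend['monotone_decreasing']}")

    (RESULTS / "consistency_report.md").write_text(rep.to_markdown())
    ogio.write_json_report(RESULTS / "consistency_report.json", rep.to_dict())
    print("wrote results/consistency_report.{json,md}")


if __name__ == "__main__":
    main()
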