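#!/usr/bin/env python
"""Integrate the ITC dissociation thermograms and test the temperature trend.

Per-injection heats by baseline-corrected peak integration at 15/25/37 C,
then the qualitative endpoint: does the total dissociation heat increase as
temperature decreases? No binding model is fitted.
"""

import sys
from pathlib import Path
from importlib import import_module

from oligostate import io as ogio
from oligostate.itc import integrate_injections, temperature_trend

sys.path.insert(0, str(Path(__file__).parent))
sim = import_module("01_simulate_datasets")

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "data"


def main():
    series = {}
    for temp in sorted(sim.ITC_TOTALS):
        trace = SCRATCH / f"itc_trace_{int(temp)}C.csv"
        inj = SCRATCH / f"itc_injections_{int(temp)}C.csv"
        if trace.exists() and inj.exists():
            tg = ogio.read_thermogram(trace, inj, temperature_c=temp)
        else:
            tg = sim.make_itc()[temp]
        heats = integrate_injections(tg)
        series[temp] = heats
        total = sum(h.heat for h in heats)
        print(f"{temp:.0f} C: {len(heats)} injections, total heat "
              f"{total:.1f} uJ (specified {sim.ITC_TOTALS[temp]:.0f} uJ)")

    trend = temperature_trend(series)
    verdict = "monotone" if trend.monotone_decreasing else "not strict"
    print(f"|Q| vs temperature: {verdict}; ordering "
          + " > ".join(f"{t:.0f}C" for t in trend.ordering))

    ogio.write_json_report(ROOT / "results" / "itc_report.json", {
        "totals_uj": trend.totals,
        "monotone_decreasing": trend.monotone_decreasing,
        "ties": trend.ties,
        "per_injection": {str(t): [h.heat for h in hs]
                          for t, hs in series.items()},
    })
    print("wrote results/itc_report.json")


if __name__ == "__main__":
    main()
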