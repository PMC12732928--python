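#!/usr/bin/env python
"""Generate the synthetic study datasets for the downstream analyses.

Emulates the four measurements of an oligomerising ~17.4 kDa ice-binding
protein: a MALDI oligomer ladder (dimer..heptamer, z = 1-2), an AFM scan of
the four particle size classes, a SAXS curve of the elongated oligomer
(elliptical cylinder, 16 A thick), and ITC dissociation traces at three
temperatures. Small text datasets go to results/data/; the large AFM matrix
and ITC traces go to scratch/data/ (regenerated on demand by the later
drivers, which share this module's functions).
"""

from pathlib import Path

import numpy as np

from oligostate import io as ogio
from oligostate.synthetic import (AfmSimSpec, ItcSimSpec, MaldiSimSpec,
                                  SaxsSimSpec, simulate_afm, simulate_itc,
                                  simulate_maldi, simulate_saxs)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "data"
SCRATCH = ROOT / "scratch" / "data"

MONOMER_MASS = 17413.8  # Da, implied by the dimer peak at 34,828.6 m/z
SEED = 2026

#: ITC temperature series: total dissociation heat grows as T drops
ITC_TOTALS = {15.0: 300.0, 25.0: 200.0, 37.0: 100.0}  # uJ over 20 injections


def make_saxs(seed=SEED):
    q = np.linspace(0.006, 0.35, 240)
    return simulate_saxs(SaxsSimSpec(
        "elliptical_cylinder", {"a": 77.0, "nu": 1.2, "length": 16.0},
        q, frac_sd=0.02, seed=seed))


def make_maldi(seed=SEED):
    return simulate_maldi(MaldiSimSpec(
        MONOMER_MASS, stoichiometries=range(1, 8), charges=(1, 2),
        mass_error_ppm=200.0, seed=seed))


def make_afm(seed=SEED, n_per_class=500):
    from oligostate.synthetic import DEFAULT_POPULATIONS
    from dataclasses import replace
    pops = [replace(p, n=n_per_class) for p in DEFAULT_POPULATIONS]
    return simulate_afm(AfmSimSpec(populations=pops, seed=seed))


def make_itc(seed=SEED):
    out = {}
    for temp, total in ITC_TOTALS.items():
        out[temp] = simulate_itc(ItcSimSpec(
            heats=[total / 20.0] * 20, temperature_c=temp,
            seed=seed + int(temp)))
    return out


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    prof = make_saxs()
    ogio.write_saxs(RESULTS / "saxs_elliptical_cylinder.dat", prof,
                    header="synthetic SAXS, elliptical cylinder a=77 nu=1.2 "
                           "L=16 A, 2% noise")
    print(f"SAXS: {len(prof)} points, q {prof.q[0]:.3f}-{prof.q[-1]:.3f} 1/A")

    peaks = make_maldi()
    ogio.write_peaks(RESULTS / "maldi_peaks.csv", peaks)
    print(f"MALDI: {len(peaks)} peaks, {peaks.mz[0]:.1f}-{peaks.mz[-1]:.1f} m/z")

    hm, truth = make_afm()
    ogio.write_heightmap(SCRATCH / "afm_mixture.txt", hm)
    truth.to_csv(SCRATCH / "afm_ground_truth.csv", index=False,
                 float_format="%.4f")
    print(f"AFM: {hm.shape[0]}x{hm.shape[1]} px at {hm.pixel_size} nm/px, "
          f"{len(truth)} particles (map in scratch/)")

    for temp, tg in make_itc().items():
        ogio.write_thermogram(SCRATCH / f"itc_trace_{int(temp)}C.csv",
                              SCRATCH / f"itc_injections_{int(temp)}C.csv", tg)
    print(f"ITC: {len(ITC_TOTALS)} temperature series of 20 injections "
          f"(traces in scratch/)")


if __name__ == "__main__":
    main()
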