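"""Shared fixtures: canonical synthetic datasets reused across test modules.

The expensive end-to-end AFM simulation is session-scoped so the module
tests and the acceptance checks measure the same realisation.
"""

from __future__ import annotations

import numpy as np
import pytest

from oligostate.afm import analyze_heightmap, range_statistics
from oligostate.synthetic import (AfmSimSpec, ParticlePopulation, SaxsSimSpec,
                                  simulate_afm, simulate_saxs)

#: reference AFM population parameters of the four size classes
#: (a1 mean/sd, a2 mean/sd, height mean/sd in nm) and their a1 bounds
TABLE1 = {
    "I": {"a1": (14.2, 3.9), "a2": (10.5, 2.8), "ratio": (1.4, 0.2),
          "s": (20.1, 5.5), "z": (1.57, 0.31), "bounds": (5, 20)},
    "II": {"a1": (24.0, 2.5), "a2": (18.6, 1.5), "ratio": (1.3, 0.1),
           "s": (36.3, 3.0), "z": (1.86, 0.46), "bounds": (17, 27)},
    "III": {"a1": (32.8, 4.6), "a2": (20.5, 2.7), "ratio": (1.5, 0.2),
            "s": (44.3, 4.2), "z": (2.43, 0.74), "bounds": (28, 44)},
    "IV": {"a1": (51.1, 4.9), "a2": (27.5, 7.8), "ratio": (1.86, 0.5),
           "s": (60.5, 10.1), "z": (1.90, 0.47), "bounds": (44, 60)},
}

#: printed oligomer ladder of the 17.4 kDa ice-binding protein (m/z)
MALDI_PEAKS = [34828.6, 43573.6, 52245.1, 61003.6, 69653.1, 87145.6,
               104609.9, 122061.4]


@pytest.fixture(scope="session")
def sphere_profile_clean():
    """Noise-free sphere R = 30 A scattering curve."""
    q = np.linspace(0.005, 0.35, 240)
    return simulate_saxs(SaxsSimSpec("sphere", {"radius": 30.0}, q,
                                     frac_sd=0.0))


@pytest.fixture(scope="session")
def sphere_profile_noisy():
    q = np.linspace(0.005, 0.35, 240)
    return simulate_saxs(SaxsSimSpec("sphere", {"radius": 30.0}, q,
                                     frac_sd=0.02, seed=3))


@pytest.fixture(scope="session")
def guinier_profile():
    """Ideal Guinier scatterer, Rg = 60 A, I0 = 1."""
    q = np.linspace(0.001, 0.3, 400)
    return simulate_saxs(SaxsSimSpec("guinier", {"rg": 60.0}, q, frac_sd=0.0))


@pytest.fixture(scope="session")
def afm_mixture():
    """Four-class particle mixture (1000/class, seed 42) and its pipeline run."""
    hm, truth = simulate_afm(AfmSimSpec(seed=42))
    particles = analyze_heightmap(hm)
    stats = range_statistics(particles)
    return {"heightmap": hm, "truth": truth, "particles": particles,
            "stats": stats}


def single_population_run(label: str, pixel_size: float, seed: int, n: int = 1000):
    """Simulate and measure one size-class population end to end."""
    p = TABLE1[label]
    pop = ParticlePopulation(label, n, p["a1"], p["a2"], p["z"])
    hm, truth = simulate_afm(AfmSimSpec(populations=[pop],
                                        pixel_size=pixel_size, seed=seed))
    particles = analyze_heightmap(hm)
    return truth, particles, range_statistics(particles)
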