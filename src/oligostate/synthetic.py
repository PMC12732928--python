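"""Instrument-realistic synthetic data for every analysis stage.

Generators for the four input modalities of the pipeline, each reproducing
the statistical structure the corresponding analysis assumes:

* 1-D SAXS profiles of analytic shapes (Guinier scatterer, sphere, circular
  and elliptical cylinder) with relative Gaussian noise;
* MALDI oligomer peak ladders at m/z = (n*M + z*m_H)/z with ppm jitter and
  intensities decaying with oligomer order (delta-like peak lists — the
  downstream series analysis consumes centroids, not spectra);
* AFM height maps of elliptical-cap particles on a rough background, with a
  ground-truth particle table; the default populations are the four size
  classes of the reference AFM morphometry (see ``DEFAULT_POPULATIONS``);
* ITC power traces of exponential injection-response peaks over a drifting
  baseline, with each peak scaled so its time integral equals the requested
  heat.

All randomness flows from one seeded ``numpy.random.Generator`` per call, so
identical specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maldi import PROTON_MASS, PeakList
from .afm import HeightMap
from .itc import Thermogram
from .saxs import ScatteringProfile, model_intensity, MODELS

__all__ = [
    "SaxsSimSpec",
    "MaldiSimSpec",
    "ParticlePopulation",
    "AfmSimSpec",
    "ItcSimSpec",
    "DEFAULT_POPULATIONS",
    "simulate_saxs",
    "simulate_maldi",
    "simulate_afm",
    "simulate_itc",
]


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------


@dataclass
class SaxsSimSpec:
    """Synthetic 1-D SAXS measurement: shape model + q grid + noise."""

    model: str  # sphere | cylinder | elliptical_cylinder | guinier
    params: dict  # shape parameters, lengths in Angstrom
    q_grid: np.ndarray  # 1/Angstrom, strictly increasing, > 0
    i0: float = 1.0
    frac_sd: float = 0.02  # relative Gaussian noise per point
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {sorted(MODELS)}")
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be positive and strictly increasing")
        for k, v in self.params.items():
            if k != "nu" and v <= 0:
                raise ValueError(f"shape parameter {k} must be positive")
        if self.frac_sd < 0:
            raise ValueError("frac_sd must be >= 0")


def simulate_saxs(spec: SaxsSimSpec) -> ScatteringProfile:
    """Evaluate the shape model on the q grid and apply relative noise.

    I(q) = I0 * model(q) * (1 + eps), eps ~ N(0, frac_sd); the sigma column
    is frac_sd * I_model (omitted entirely for noise-free curves, letting the
    profile's 2% default apply downstream).
    """
    rng = np.random.default_rng(spec.seed)
    ideal = spec.i0 * model_intensity(spec.model, spec.q_grid, spec.params)
    if spec.frac_sd == 0:
        return ScatteringProfile(q=spec.q_grid.copy(), I=ideal)
    eps = rng.normal(0.0, spec.frac_sd, size=ideal.shape)
    sigma = spec.frac_sd * np.abs(ideal)
    return ScatteringProfile(q=spec.q_grid.copy(), I=ideal * (1.0 + eps),
                             sigma=sigma)


# ---------------------------------------------------------------------------
# MALDI
# ---------------------------------------------------------------------------


@dataclass
class MaldiSimSpec:
    """Protonated oligomer ladder [n*M + z*H]^z+ with mass jitter."""

    monomer_mass: float  # Da
    stoichiometries: Sequence[int] = (1, 2, 3, 4, 5, 6, 7)
    charges: Sequence[int] = (1, 2)
    proton_mass: float = PROTON_MASS
    mass_error_ppm: float = 0.0  # per-peak Gaussian jitter
    intensity_decay: float = 0.5  # multiplicative factor per oligomer order
    seed: int = 0

    def __post_init__(self):
        if self.monomer_mass <= 0:
            raise ValueError("monomer_mass must be positive")
        if self.mass_error_ppm < 0:
            raise ValueError("mass_error_ppm must be >= 0")
        if any(n < 1 for n in self.stoichiometries):
            raise ValueError("stoichiometries must be >= 1")
        if any(z < 1 for z in self.charges):
            raise ValueError("charges must be >= 1")


def simulate_maldi(spec: MaldiSimSpec) -> PeakList:
    """One centroid per (n, z) with ppm jitter and order-decaying intensity."""
    rng = np.random.default_rng(spec.seed)
    mzs, intens = [], []
    for n in sorted(set(spec.stoichiometries)):
        for z in sorted(set(spec.charges)):
            mz = (n * spec.monomer_mass + z * spec.proton_mass) / z
            if spec.mass_error_ppm > 0:
                mz *= 1.0 + rng.normal(0.0, spec.mass_error_ppm * 1e-6)
            mzs.append(mz)
            intens.append(spec.intensity_decay ** (n - 1) / z)
    return PeakList(mz=np.array(mzs), intensity=np.array(intens))


# ---------------------------------------------------------------------------
# AFM
# ---------------------------------------------------------------------------


@dataclass
class ParticlePopulation:
    """Gaussian particle-parameter distribution of one size class (nm)."""

    label: str
    n: int
    a1: tuple[float, float]  # (mean, sd) semi-major axis
    a2: tuple[float, float]  # (mean, sd) semi-minor axis
    height: tuple[float, float]  # (mean, sd) cap height
    axis_corr: float = 0.7  # correlation between the a1 and a2 draws


#: Default four-class particle mixture emulated by the generator: the size
#: classes of the reference AFM morphometry of ice-binding protein oligomers
#: (semi-major axis classes I-IV with their Gaussian means/sds in nm).
DEFAULT_POPULATIONS: tuple[ParticlePopulation, ...] = (
    ParticlePopulation("I", 1000, (14.2, 3.9), (10.5, 2.8), (1.57, 0.31)),
    ParticlePopulation("II", 1000, (24.0, 2.5), (18.6, 1.5), (1.86, 0.46)),
    ParticlePopulation("III", 1000, (32.8, 4.6), (20.5, 2.7), (2.43, 0.74)),
    ParticlePopulation("IV", 1000, (51.1, 4.9), (27.5, 7.8), (1.90, 0.47)),
)


@dataclass
class AfmSimSpec:
    """Synthetic AFM scan: particle mixture, pixel size, background noise."""

    populations: Sequence[ParticlePopulation] = DEFAULT_POPULATIONS
    pixel_size: float = 2.0  # nm/px
    background_sd: float = 0.05  # nm
    margin_nm: float = 10.0  # clearance around each particle cell
    image_size: Optional[int] = None  # px; auto grid layout when None
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


def _draw_axes(pop: ParticlePopulation, rng: np.random.Generator,
               max_tries: int = 1000) -> tuple[float, float]:
    """Draw (a1, a2): correlated Gaussians, a1 > 0, a2 conditioned on (0, a1].

    a1 is resampled until positive (its marginal stays the specified
    truncated Gaussian); a2 is then resampled conditional on 0 < a2 <= a1 so
    the semi-major/semi-minor ordering holds by construction.
    """
    mu1, sd1 = pop.a1
    mu2, sd2 = pop.a2
    rho = pop.axis_corr
    for _ in range(max_tries):
        z1 = rng.standard_normal()
        a1 = mu1 + sd1 * z1
        if a1 > 0:
            break
    else:
        raise RuntimeError("could not draw a positive a1")
    mu2c = mu2 + rho * sd2 * z1
    sd2c = sd2 * np.sqrt(1.0 - rho**2)
    for _ in range(max_tries):
        a2 = mu2c + sd2c * rng.standard_normal()
        if 0 < a2 <= a1:
            return float(a1), float(a2)
    return float(a1), float(min(a1, max(mu2c, pop.a2[0] * 0.5)))


def _draw_height(pop: ParticlePopulation, rng: np.random.Generator) -> float:
    mu, sd = pop.height
    for _ in range(1000):
        h = mu + sd * rng.standard_normal()
        if h > 0:
            return float(h)
    raise RuntimeError("could not draw a positive height")


def simulate_afm(spec: AfmSimSpec) -> tuple[HeightMap, pd.DataFrame]:
    """Render non-overlapping elliptical-cap particles on a noisy background.

    Each particle is a smooth cap h * max(0, 1 - (x'/a1)^2 - (y'/a2)^2) in
    its own rotated frame, placed on a jittered grid whose cell size clears
    the largest expected particle, which guarantees non-overlap while keeping
    positions and orientations random. Returns the height map and the
    ground-truth particle table (label, a1, a2, height, centre, orientation).
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size

    draws = []
    for pop in spec.populations:
        for _ in range(pop.n):
            a1, a2 = _draw_axes(pop, rng)
            h = _draw_height(pop, rng)
            draws.append({"range": pop.label, "a1": a1, "a2": a2, "height": h,
                          "theta": rng.uniform(0, np.pi)})
    n_part = len(draws)

    if n_part == 0:
        size = spec.image_size or 256
        heights = (rng.normal(0.0, spec.background_sd, (size, size))
                   if spec.background_sd > 0 else np.zeros((size, size)))
        return (HeightMap(heights, px, {"background_sd": spec.background_sd}),
                pd.DataFrame(columns=["range", "a1", "a2", "height", "theta",
                                      "row", "col"]))

    max_extent = max(d["a1"] for d in draws)
    cell_px = int(np.ceil(2.0 * (max_extent + spec.margin_nm) / px))
    grid = int(np.ceil(np.sqrt(n_part)))
    size = grid * cell_px
    if spec.image_size is not None:
        if spec.image_size < size:
            raise ValueError(
                f"image_size {spec.image_size} px cannot hold {n_part} "
                f"particles of extent {max_extent:.1f} nm (need >= {size} px)")
        size = spec.image_size
        grid = size // cell_px
        if grid * grid < n_part:
            raise ValueError("particles do not fit within the image")

    heights = np.zeros((size, size))
    cells = [(r, c) for r in range(grid) for c in range(grid)]
    order = rng.permutation(len(cells))[:n_part]
    truth_rows = []
    for d, cell_idx in zip(draws, order):
        r, c = cells[cell_idx]
        ext_px = d["a1"] / px  # cap extent in px (a1 >= a2)
        half = cell_px / 2.0
        slack = max(half - ext_px - 1.0, 0.0)
        cy = r * cell_px + half + rng.uniform(-slack, slack)
        cx = c * cell_px + half + rng.uniform(-slack, slack)
        _render_cap(heights, cy, cx, d["a1"] / px, d["a2"] / px, d["height"],
                    d["theta"])
        truth_rows.append({**d, "row": cy, "col": cx})
    if spec.background_sd > 0:
        heights += rng.normal(0.0, spec.background_sd, heights.shape)
    truth = pd.DataFrame(truth_rows,
                         columns=["range", "a1", "a2", "height", "theta",
                                  "row", "col"])
    return HeightMap(heights, px, {"background_sd": spec.background_sd}), truth


def _render_cap(img: np.ndarray, cy: float, cx: float, a1_px: float,
                a2_px: float, h: float, theta: float) -> None:
    ext = int(np.ceil(a1_px)) + 1
    r0, r1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
    c0, c1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, img.shape[0]), min(c1, img.shape[1])
    yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
    dy, dx = yy - cy, xx - cx
    xr = np.cos(theta) * dx + np.sin(theta) * dy
    yr = -np.sin(theta) * dx + np.cos(theta) * dy
    cap = h * np.maximum(0.0, 1.0 - (xr / a1_px) ** 2 - (yr / a2_px) ** 2)
    img[r0c:r1c, c0c:c1c] += cap


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------


@dataclass
class ItcSimSpec:
    """Synthetic ITC run: injection schedule, heats, instrument response."""

    heats: Sequence[float] = (10.0,) * 20  # uJ per injection, signed
    spacing: float = 300.0  # s between injections
    first_injection: float = 60.0  # s of pre-injection baseline
    tau: float = 15.0  # s, single-exponential instrument response
    dt: float = 1.0  # s sampling interval
    baseline_drift: float = 0.0  # uW/s
    noise_sd: float = 0.02  # uW
    tail: float = 300.0  # s of trace after the last injection window
    temperature_c: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0 or self.spacing <= 0:
            raise ValueError("tau, dt and spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_itc(spec: ItcSimSpec) -> Thermogram:
    """Power trace = drift baseline + exponential peaks + white noise.

    Each injection contributes (q/tau) * exp(-(t - t_k)/tau) for t >= t_k,
    whose analytic time integral is exactly the requested heat q (uJ); with
    the 1 s default sampling the trapezoidal integral of the rendered trace
    matches to ~0.01%. Zero injections yield a flat (possibly drifting,
    noisy) baseline.
    """
    rng = np.random.default_rng(spec.seed)
    n_inj = len(spec.heats)
    t_end = spec.first_injection + max(n_inj - 1, 0) * spec.spacing + spec.tail
    time = np.arange(0.0, t_end + spec.dt / 2, spec.dt)
    power = spec.baseline_drift * time
    inj_times = spec.first_injection + spec.spacing * np.arange(n_inj)
    for q, t_k in zip(spec.heats, inj_times):
        after = time >= t_k
        power[after] += (q / spec.tau) * np.exp(-(time[after] - t_k) / spec.tau)
    if spec.noise_sd > 0:
        power += rng.normal(0.0, spec.noise_sd, power.shape)
    return Thermogram(time=time, power=power, injection_times=inj_times,
                      temperature_c=spec.temperature_c)
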