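"""Small-angle X-ray scattering reductions for oligomer shape analysis.

Implements the 1-D SAXS toolchain used to characterise protein oligomers in
solution: Guinier and cross-sectional (rod) Guinier fits, the dimensionless
Kratky transform, a Tikhonov-regularised indirect Fourier transform (IFT) to
the pair distance distribution function P(r) with evidence-based selection of
the regularisation weight, analytic form factors (sphere, circular cylinder,
elliptical cylinder) with multi-start weighted least-squares fitting, and the
excluded-volume to molecular-weight conversion.

Unit conventions are fixed throughout the package: momentum transfer q in
1/Angstrom, lengths in Angstrom, excluded volumes in nm^3, masses in kDa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import linalg, optimize, special

AVOGADRO = 6.02214076e23

__all__ = [
    "ScatteringProfile",
    "GuinierFit",
    "CrossSectionFit",
    "KratkyCurve",
    "PairDistribution",
    "FormFactorFit",
    "MwEstimate",
    "GuinierRegionError",
    "RodRegimeError",
    "FormFactorFitError",
    "sphere_intensity",
    "cylinder_intensity",
    "elliptical_cylinder_intensity",
    "guinier_intensity",
    "guinier_fit",
    "cross_section_guinier",
    "dimensionless_kratky",
    "ift",
    "scan_dmax",
    "fit_form_factor",
    "model_rg",
    "volume_to_mw",
]


class GuinierRegionError(ValueError):
    """Raised when no decaying low-q (Guinier) region exists in the data."""


class RodRegimeError(ValueError):
    """Raised when ln(qI) vs q^2 has no negative slope (no rod-like regime)."""


class FormFactorFitError(RuntimeError):
    """Raised when no optimisation start converges; carries per-start info."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ScatteringProfile:
    """A 1-D background-subtracted scattering curve I(q).

    ``sigma`` defaults to 2% of |I| when not measured. Negative intensities
    are permitted only when uncertainties are supplied (subtracted data).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("q values must be positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")
        elif np.any(self.I < 0):
            raise ValueError("negative I requires explicit sigma")

    @property
    def sigma_eff(self) -> np.ndarray:
        """Measured sigma, or the 2% default for synthetic/ideal curves."""
        if self.sigma is not None:
            return self.sigma
        s = 0.02 * np.abs(self.I)
        floor = 0.02 * np.max(np.abs(self.I)) * 1e-12
        return np.maximum(s, floor if floor > 0 else 1e-300)

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_min: float
    q_max: float
    qrg_max: float
    rg_sd: float
    n_points: int


@dataclass
class CrossSectionFit:
    rc: float
    rc_sd: float
    q_min: float
    q_max: float
    n_points: int

    @property
    def diameter(self) -> float:
        """Diameter of the equivalent uniform rod, 2*Rc*sqrt(2)."""
        return 2.0 * self.rc * np.sqrt(2.0)


@dataclass
class KratkyCurve:
    x: np.ndarray  # q*Rg
    y: np.ndarray  # (q*Rg)^2 * I/I0
    peak_x: Optional[float]
    peak_y: Optional[float]


@dataclass
class PairDistribution:
    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    alpha: float
    chi2_red: float
    evidence: float

    def back_transform(self, q: np.ndarray) -> np.ndarray:
        """Re-predict I(q) = 4*pi * int P(r) sinc(qr) dr from the solution."""
        q = np.asarray(q, dtype=float)
        kern = np.sinc(np.outer(q, self.r) / np.pi)
        return 4.0 * np.pi * np.trapezoid(kern * self.p, self.r, axis=1)


@dataclass
class FormFactorFit:
    model: str
    params: dict
    fixed: dict
    scale: float
    background: float
    chi2_red: float
    n_starts: int
    start_costs: list = field(default_factory=list)

    @property
    def rg(self) -> float:
        allp = {**self.params, **self.fixed}
        return model_rg(self.model, allp)


@dataclass
class MwEstimate:
    volume_nm3: float
    vbar: float
    mw_kda: float
    divisor_nm3_per_kda: float


# ---------------------------------------------------------------------------
# form factors (normalised so I(0) = 1)
# ---------------------------------------------------------------------------


def guinier_intensity(q, rg: float, i0: float = 1.0) -> np.ndarray:
    """Ideal Guinier scatterer I(q) = I0 exp(-q^2 Rg^2 / 3)."""
    q = np.asarray(q, dtype=float)
    return i0 * np.exp(-(q**2) * rg**2 / 3.0)


def _sphere_amp(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3 with the x -> 0 limit handled."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    big = np.abs(x) > 1e-4
    xb = x[big]
    out[big] = 3.0 * (np.sin(xb) - xb * np.cos(xb)) / xb**3
    small = ~big
    out[small] = 1.0 - x[small] ** 2 / 10.0
    return out


def sphere_intensity(q, radius: float) -> np.ndarray:
    """Form factor of a homogeneous sphere, normalised to I(0)=1."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(q, dtype=float)
    return _sphere_amp(q * radius) ** 2


def _j1_over(u: np.ndarray) -> np.ndarray:
    """2 J1(u)/u with the u -> 0 limit (=1)."""
    out = np.ones_like(u)
    big = np.abs(u) > 1e-8
    ub = u[big]
    out[big] = 2.0 * special.j1(ub) / ub
    return out


@lru_cache(maxsize=8)
def _gauss_legendre_half_pi(order: int):
    x, w = np.polynomial.legendre.leggauss(order)
    return 0.25 * np.pi * (x + 1.0), 0.25 * np.pi * w


def elliptical_cylinder_intensity(q, a: float, nu: float, length: float,
                                  order: int = 76) -> np.ndarray:
    """Orientationally averaged elliptical-cylinder form factor, I(0)=1.

    ``a`` is the minor semi-axis of the elliptical cross-section, ``nu >= 1``
    the axis ratio (major semi-axis b = nu*a) and ``length`` the cylinder
    height. The double orientation average over the cylinder tilt and the
    cross-section azimuth is evaluated with fixed-order Gauss-Legendre
    quadrature on [0, pi/2] x [0, pi/2].
    """
    if a <= 0 or length <= 0:
        raise ValueError("a and length must be positive")
    if nu < 1:
        raise ValueError("axis ratio nu must be >= 1")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    an, aw = _gauss_legendre_half_pi(order)
    pn, pw = _gauss_legendre_half_pi(order)
    sin_a, cos_a = np.sin(an), np.cos(an)
    r_eff = a * np.sqrt(np.cos(pn) ** 2 + nu**2 * np.sin(pn) ** 2)  # (P,)
    # u has shape (Q, A, P)
    u = q[:, None, None] * sin_a[None, :, None] * r_eff[None, None, :]
    rod = np.sinc(q[:, None] * length * cos_a[None, :] / 2.0 / np.pi)  # (Q, A)
    amp2 = _j1_over(u) ** 2 * rod[:, :, None] ** 2
    inner = amp2 @ pw  # integrate over psi -> (Q, A)
    outer = (inner * sin_a[None, :]) @ aw  # integrate over alpha -> (Q,)
    return outer / (np.pi / 2.0)


def cylinder_intensity(q, radius: float, length: float,
                       order: int = 256) -> np.ndarray:
    """Orientationally averaged circular-cylinder form factor, I(0)=1."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    an, aw = _gauss_legendre_half_pi(order)
    sin_a, cos_a = np.sin(an), np.cos(an)
    u = q[:, None] * radius * sin_a[None, :]
    rod = np.sinc(q[:, None] * length * cos_a[None, :] / 2.0 / np.pi)
    amp2 = _j1_over(u) ** 2 * rod**2
    return (amp2 * sin_a[None, :]) @ aw  # int_0^{pi/2} sin(a) da = 1


# model registry: name -> (ordered parameter names, callable)
MODELS: dict[str, tuple[tuple[str, ...], Callable]] = {
    "sphere": (("radius",), sphere_intensity),
    "cylinder": (("radius", "length"), cylinder_intensity),
    "elliptical_cylinder": (("a", "nu", "length"), elliptical_cylinder_intensity),
    "guinier": (("rg",), guinier_intensity),
}


def model_intensity(model: str, q, params: dict) -> np.ndarray:
    """Evaluate a registered form-factor model on q."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    names, fn = MODELS[model]
    return fn(q, **{k: params[k] for k in names})


# ---------------------------------------------------------------------------
# Guinier analyses
# ---------------------------------------------------------------------------


def _weighted_line(x, y, w):
    """Weighted straight-line fit; returns slope, intercept, sd(slope)."""
    coef, cov = np.polyfit(x, y, 1, w=w, cov="unscaled")
    return coef[0], coef[1], float(np.sqrt(cov[0, 0]))


def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.3,
                q_min: Optional[float] = None, min_points: int = 5) -> GuinierFit:
    """Guinier fit ln I vs q^2 on the largest low-q window with q*Rg <= limit.

    The window is found iteratively: fit, recompute Rg, shrink the window to
    satisfy the q*Rg bound, repeat to a fixed point. Weights come from the
    propagated log-intensity uncertainties sigma/I.
    """
    q, I, sig = profile.q, profile.I, profile.sigma_eff
    valid = I > 0
    if q_min is not None:
        valid &= q >= q_min
    idx = np.flatnonzero(valid)
    if len(idx) < min_points:
        raise ValueError(f"need >= {min_points} positive-intensity points")
    # use the leading contiguous run of valid points
    run_end = len(idx)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    if len(breaks):
        run_end = breaks[0] + 1
    idx = idx[:run_end]

    i1 = len(idx)
    seen = set()
    for _ in range(200):
        sel = idx[:i1]
        if len(sel) < min_points:
            raise GuinierRegionError(
                "no Guinier region: window shrank below the minimum point count")
        x = q[sel] ** 2
        y = np.log(I[sel])
        w = I[sel] / sig[sel]
        slope, intercept, slope_sd = _weighted_line(x, y, w)
        if slope >= 0:
            raise GuinierRegionError("no Guinier region: non-negative slope")
        rg = float(np.sqrt(-3.0 * slope))
        new_i1 = int(np.searchsorted(q[idx] * rg, qrg_limit, side="right"))
        new_i1 = max(new_i1, min_points)
        if new_i1 == i1 or new_i1 in seen:
            i1 = min(i1, new_i1)
            break
        seen.add(i1)
        i1 = new_i1
    sel = idx[:i1]
    x = q[sel] ** 2
    y = np.log(I[sel])
    w = I[sel] / sig[sel]
    slope, intercept, slope_sd = _weighted_line(x, y, w)
    if slope >= 0:
        raise GuinierRegionError("no Guinier region: non-negative slope")
    rg = float(np.sqrt(-3.0 * slope))
    rg_sd = 3.0 * slope_sd / (2.0 * rg)
    return GuinierFit(rg=rg, i0=float(np.exp(intercept)),
                      q_min=float(q[sel[0]]), q_max=float(q[sel[-1]]),
                      qrg_max=float(q[sel[-1]] * rg), rg_sd=rg_sd,
                      n_points=len(sel))


def cross_section_guinier(profile: ScatteringProfile,
                          window: Optional[tuple[float, float]] = None,
                          min_points: int = 5) -> CrossSectionFit:
    """Cross-sectional Guinier fit for elongated particles.

    Fits ln(q I(q)) vs q^2 inside ``window``; Rc = sqrt(-2*slope) and the
    equivalent uniform-rod diameter is 2*Rc*sqrt(2). When no window is given
    it is initialised to [1/Rg, q_max] from an overall Guinier fit and then
    iterated to [1/Rg, 1/Rc].
    """

    def _fit(qlo, qhi):
        sel = (profile.q >= qlo) & (profile.q <= qhi) & (profile.I > 0)
        if np.count_nonzero(sel) < min_points:
            raise ValueError(
                f"cross-section window [{qlo:.4g}, {qhi:.4g}] has fewer than "
                f"{min_points} usable points")
        q, I, sig = profile.q[sel], profile.I[sel], profile.sigma_eff[sel]
        x = q**2
        y = np.log(q * I)
        w = I / sig  # d ln(qI) = dI/I
        slope, intercept, slope_sd = _weighted_line(x, y, w)
        if slope >= 0:
            raise RodRegimeError("no rod-like regime: non-negative slope of ln(qI)")
        rc = float(np.sqrt(-2.0 * slope))
        return rc, slope_sd, float(q[0]), float(q[-1]), int(len(q))

    if window is not None:
        rc, slope_sd, qlo, qhi, n = _fit(*window)
    else:
        rg = guinier_fit(profile).rg
        qlo, qhi = 1.0 / rg, float(profile.q[-1])
        rc = None
        for _ in range(3):
            rc, slope_sd, qlo_u, qhi_u, n = _fit(qlo, qhi)
            new_qhi = min(1.0 / rc, float(profile.q[-1]))
            if abs(new_qhi - qhi) / qhi < 1e-3:
                break
            qhi = new_qhi
        qlo, qhi = qlo_u, qhi_u
    rc_sd = slope_sd / rc  # d rc/d slope = -1/rc at slope=-rc^2/2
    return CrossSectionFit(rc=rc, rc_sd=rc_sd, q_min=qlo, q_max=qhi, n_points=n)


def dimensionless_kratky(profile: ScatteringProfile,
                         guinier: GuinierFit) -> KratkyCurve:
    """Dimensionless Kratky transform (qRg)^2 I/I0 vs qRg.

    A compact globular particle peaks near (sqrt(3), 3/e ~ 1.104); flexible
    chains plateau instead. The peak is located by quadratic interpolation
    through the maximum sample and its neighbours; a maximum on the boundary
    of the curve is reported as no interior peak (None).
    """
    if guinier.i0 <= 0:
        raise ValueError("guinier.i0 must be positive")
    x = profile.q * guinier.rg
    y = x**2 * profile.I / guinier.i0
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return KratkyCurve(x=x, y=y, peak_x=None, peak_y=None)
    x3, y3 = x[k - 1:k + 2], y[k - 1:k + 2]
    c = np.polyfit(x3, y3, 2)
    if c[0] >= 0:  # not a local max after interpolation
        return KratkyCurve(x=x, y=y, peak_x=float(x[k]), peak_y=float(y[k]))
    px = -c[1] / (2 * c[0])
    py = np.polyval(c, px)
    return KratkyCurve(x=x, y=y, peak_x=float(px), peak_y=float(py))


# ---------------------------------------------------------------------------
# indirect Fourier transform
# ---------------------------------------------------------------------------


def _second_difference(m: int) -> np.ndarray:
    """Second-difference operator on the interior nodes with zero boundaries."""
    D = np.zeros((m, m))
    for j in range(m):
        D[j, j] = -2.0
        if j > 0:
            D[j, j - 1] = 1.0
        if j < m - 1:
            D[j, j + 1] = 1.0
    return D


def _ift_solve(A, b, D, alpha):
    """Non-negative least squares on the Tikhonov-augmented system.

    Solves min_p>=0 ||A p - b||^2 + alpha ||D p||^2 exactly via NNLS on the
    stacked design [A; sqrt(alpha) D]. P(r) of any mass density is
    non-negative, so the constraint is physical, and it regularises the
    inversion far better than an after-the-fact penalty.
    """
    m = A.shape[1]
    aug = np.vstack([A, np.sqrt(alpha) * D])
    rhs = np.concatenate([b, np.zeros(m)])
    try:
        p, _ = optimize.nnls(aug, rhs, maxiter=50 * m)
    except RuntimeError as exc:  # non-convergence at this alpha
        raise np.linalg.LinAlgError(
            f"NNLS did not converge (alpha={alpha:g}): {exc}") from exc
    return p


def ift(profile: ScatteringProfile, dmax: float, n_r: int = 101,
        alpha: Optional[float] = None,
        alpha_grid: Optional[Sequence[float]] = None) -> PairDistribution:
    """Regularised indirect Fourier transform of I(q) to P(r) on [0, Dmax].

    Minimises chi^2 between the data and 4*pi*int P(r) sinc(qr) dr plus
    alpha * ||second difference of P||^2, with P(0) = P(Dmax) = 0 enforced and
    P constrained non-negative (NNLS). When ``alpha`` is not given
    it is selected by maximising a Gaussian-evidence score over a log-spaced
    grid (Bayesian IFT style), trading data fit against smoothness.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if n_r < 5:
        raise ValueError("n_r too small")
    q, I, sig = profile.q, profile.I, profile.sigma_eff
    if dmax < np.pi / q[-1]:
        warnings.warn("Dmax below the pi/q_max resolution limit of the data",
                      stacklevel=2)
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    interior = r[1:-1]
    m = n_r - 2
    kern = 4.0 * np.pi * np.sinc(np.outer(q, interior) / np.pi) * dr
    A = kern / sig[:, None]
    b = I / sig
    H0 = A.T @ A
    ridge = 1e-12 * np.trace(H0) / m * np.eye(m)  # conditioning floor only
    D = _second_difference(m)
    DtD = D.T @ D
    sign, ld_dtd = np.linalg.slogdet(DtD)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular regulariser (diagnostics: DtD "
                                    "not positive definite)")

    def _evaluate(a):
        p = _ift_solve(A, b, D, a)
        H = H0 + a * DtD + ridge
        resid = A @ p - b
        chi2 = float(resid @ resid)
        signH, ldH = np.linalg.slogdet(H)
        if signH <= 0:
            raise np.linalg.LinAlgError(
                "singular IFT system (diagnostics: alpha=%g, dmax=%g)" % (a, dmax))
        ev = 0.5 * (m * np.log(a) + ld_dtd) - 0.5 * ldH \
            - 0.5 * chi2 - 0.5 * a * float(p @ DtD @ p)
        return p, H, chi2, ev

    if alpha is None:
        grid = np.asarray(alpha_grid) if alpha_grid is not None \
            else np.logspace(-2, 8, 50)
        best = None
        for a in grid:
            try:
                out = _evaluate(a)
            except np.linalg.LinAlgError:
                continue
            if best is None or out[3] > best[1][3]:
                best = (a, out)
        if best is None:
            raise np.linalg.LinAlgError("IFT failed for every alpha on the grid")
        alpha = float(best[0])
        p, H, chi2, ev = best[1]
    else:
        p, H, chi2, ev = _evaluate(alpha)

    # effective number of parameters -> reduced chi^2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        n_eff = float(np.trace(linalg.solve(H, H0, assume_a="pos")))
    dof = max(len(q) - n_eff, 1.0)
    chi2_red = chi2 / dof

    p_full = np.zeros(n_r)
    p_full[1:-1] = p
    norm = np.trapezoid(p_full, r)
    if norm <= 0:
        raise np.linalg.LinAlgError("IFT produced a non-positive integral of P(r)")
    rg = float(np.sqrt(np.trapezoid(r**2 * p_full, r) / (2.0 * norm)))
    i0 = float(4.0 * np.pi * norm)
    return PairDistribution(r=r, p=p_full, dmax=float(dmax), rg=rg, i0=i0,
                            alpha=float(alpha), chi2_red=float(chi2_red),
                            evidence=float(ev))


def scan_dmax(profile: ScatteringProfile, candidates: Sequence[float],
              n_r: int = 101) -> tuple[float, dict[float, float]]:
    """Score IFT solutions over candidate Dmax values and pick the best.

    The score is the IFT evidence minus a penalty on a non-smooth approach of
    P(r) to zero at Dmax. Deterministic tie-break: the smallest Dmax whose
    score is within 1% of the best (relative to the score spread).
    """
    candidates = sorted(float(c) for c in candidates)
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    if len(candidates) == 1:
        fit = ift(profile, candidates[0], n_r=n_r)
        return candidates[0], {candidates[0]: fit.evidence}
    scores: dict[float, float] = {}
    for d in candidates:
        fit = ift(profile, d, n_r=n_r)
        pmax = np.max(np.abs(fit.p))
        endpoint = 0.0 if pmax == 0 else (fit.p[-2] / pmax) ** 2
        scores[d] = fit.evidence - endpoint
    vals = np.array(list(scores.values()))
    best = vals.max()
    thr = best - max(0.01 * abs(best), 1e-12)
    chosen = min(d for d, s in scores.items() if s >= thr)
    return chosen, scores


# ---------------------------------------------------------------------------
# form-factor fitting
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "radius": (2.0, 500.0),
    "length": (2.0, 1000.0),
    "a": (2.0, 500.0),
    "nu": (1.0, 5.0),
    "rg": (2.0, 500.0),
}


def _profiled_scale_bg(imod, I, sig, fit_background=True):
    """Best weighted scale (+ background) for a given model curve."""
    if fit_background:
        X = np.column_stack([imod, np.ones_like(imod)]) / sig[:, None]
        coef, *_ = np.linalg.lstsq(X, I / sig, rcond=None)
        return float(coef[0]), float(coef[1])
    num = np.sum(imod * I / sig**2)
    den = np.sum(imod**2 / sig**2)
    return float(num / den), 0.0


def fit_form_factor(profile: ScatteringProfile, model: str,
                    fixed: Optional[dict] = None,
                    bounds: Optional[dict] = None,
                    n_starts: int = 9,
                    fit_background: bool = True,
                    quad_order: int = 76) -> FormFactorFit:
    """Weighted least-squares fit of an analytic form factor to I(q).

    Shape parameters listed in ``fixed`` are held at the given values; the
    remainder are optimised from a coarse multi-start grid (>= 5 starts) to
    avoid local minima, with the overall scale and a constant background
    profiled out analytically at every evaluation.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    names, fn = MODELS[model]
    fixed = dict(fixed or {})
    free = [p for p in names if p not in fixed]
    if not free:
        raise ValueError("at least one free shape parameter is required")
    bnds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bnds[p][0] for p in free])
    hi = np.array([bnds[p][1] for p in free])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite")
    q, I, sig = profile.q, profile.I, profile.sigma_eff

    kw = {"order": quad_order} if model in ("cylinder", "elliptical_cylinder") \
        else {}

    def residual(theta):
        params = dict(zip(free, theta), **fixed)
        imod = fn(q, **{k: params[k] for k in names}, **kw)
        scale, bg = _profiled_scale_bg(imod, I, sig, fit_background)
        return (scale * imod + bg - I) / sig

    # coarse start grid: geometric interior points per free parameter
    per_axis = max(2, int(np.ceil(n_starts ** (1.0 / len(free)))))
    axes = [np.geomspace(max(l, 1e-3) * 1.2, h * 0.8, per_axis)
            for l, h in zip(lo, hi)]
    mesh = np.meshgrid(*axes, indexing="ij")
    starts = np.column_stack([mm.ravel() for mm in mesh])

    best = None
    diagnostics = []
    for s in starts:
        try:
            res = optimize.least_squares(residual, s, bounds=(lo, hi),
                                         method="trf")
        except Exception as exc:  # noqa: BLE001 - recorded per start
            diagnostics.append({"start": s.tolist(), "error": str(exc)})
            continue
        diagnostics.append({"start": s.tolist(), "cost": float(res.cost),
                            "success": bool(res.success)})
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FormFactorFitError("no optimisation start converged", diagnostics)

    params = dict(zip(free, (float(v) for v in best.x)))
    allp = {**params, **fixed}
    imod = fn(q, **{k: allp[k] for k in names}, **kw)
    scale, bg = _profiled_scale_bg(imod, I, sig, fit_background)
    k_par = len(free) + (2 if fit_background else 1)
    chi2 = float(np.sum(((scale * imod + bg - I) / sig) ** 2))
    chi2_red = chi2 / max(len(q) - k_par, 1)
    return FormFactorFit(model=model, params=params, fixed=fixed, scale=scale,
                         background=bg, chi2_red=chi2_red,
                         n_starts=len(starts), start_costs=diagnostics)


def model_rg(model: str, params: dict) -> float:
    """Closed-form radius of gyration of a homogeneous shape model."""
    if model == "sphere":
        return float(np.sqrt(3.0 / 5.0) * params["radius"])
    if model == "cylinder":
        return float(np.sqrt(params["radius"] ** 2 / 2.0
                             + params["length"] ** 2 / 12.0))
    if model == "elliptical_cylinder":
        a = params["a"]
        b = params.get("b", params["nu"] * a)
        return float(np.sqrt((a**2 + b**2) / 4.0 + params["length"] ** 2 / 12.0))
    if model == "guinier":
        return float(params["rg"])
    raise ValueError(f"unknown model {model!r}")


def volume_to_mw(volume_nm3: float, vbar: float = 0.73) -> MwEstimate:
    """Convert an excluded volume (nm^3) to molecular weight (kDa).

    MW = V * N_A / (vbar * 1e21) ; at the protein default vbar = 0.73 cm^3/g
    this is V[nm^3] / 1.212 kDa. The divisor is reported alongside the value
    because published MW figures often imply slightly different effective
    densities.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    if vbar <= 0:
        raise ValueError("vbar must be positive")
    mw_kda = volume_nm3 * 1e-21 / vbar * AVOGADRO / 1000.0
    return MwEstimate(volume_nm3=float(volume_nm3), vbar=float(vbar),
                      mw_kda=float(mw_kda),
                      divisor_nm3_per_kda=float(volume_nm3 / mw_kda))
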