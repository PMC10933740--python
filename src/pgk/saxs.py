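"""Small-angle scattering forward models and fitting for sphere assemblies.

The measured intensity of a dense assembly of (nearly) monodisperse spheres
is modelled as

    I(q) = scale * <P(q; R)>_R * S(q; R_hs, phi [, tau]) + background

with the sphere form factor P, a Gaussian diameter distribution (truncated
at R > 0, local-monodisperse approximation: S evaluated at the mean
radius), and either the Percus–Yevick hard-sphere structure factor or the
Baxter sticky-hard-sphere solution with stickiness tau.  A Debye-sum
oracle computes I(q) directly from particle coordinates for cross-checks.

q is in nm^-1, lengths in nm, intensities in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import lmfit

from pgk.assembly import ScatteringProfile, SphereAssembly

__all__ = ["SAXSModelParams", "sphere_form_factor", "py_structure_factor",
           "sticky_hs_structure_factor", "model_intensity", "debye_intensity",
           "fit_saxs", "synthetic_profile", "default_q_grid"]


def default_q_grid(n: int = 200, q_min: float = 0.004,
                   q_max: float = 0.2) -> np.ndarray:
    """Log-spaced q grid (nm^-1) covering the usual USAXS window."""
    return np.geomspace(q_min, q_max, n)


@dataclass
class SAXSModelParams:
    """Parameters of the sphere + structure-factor model.

    d_mean, d_sd : mean and Gaussian sd of the sphere *diameter*, nm
    phi          : hard-sphere volume fraction
    r_hs         : effective hard-sphere radius, nm (defaults to d_mean/2)
    tau          : Baxter stickiness (sticky model only; larger = less sticky)
    """

    d_mean: float
    d_sd: float = 0.0
    phi: float = 0.0
    r_hs: Optional[float] = None
    tau: Optional[float] = None
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.d_mean <= 0:
            raise ValueError("d_mean must be positive")
        if self.d_sd < 0:
            raise ValueError("d_sd must be >= 0")
        if not 0 <= self.phi < 0.74:
            raise ValueError("phi must lie in [0, 0.74)")
        if self.r_hs is None:
            self.r_hs = self.d_mean / 2.0
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x)/x^3, the normalised sphere scattering amplitude."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    out[small] = 1.0 - x[small] ** 2 / 10.0
    return out


def sphere_form_factor(q, R: float) -> np.ndarray:
    """Normalised sphere form factor P(q) = [3 (sin qR - qR cos qR)/(qR)^3]^2.

    P(0) = 1 by continuous extension; first zero at qR ~= 4.4934.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    return _sphere_amplitude(q * R) ** 2


def py_structure_factor(q, r_hs: float, phi: float) -> np.ndarray:
    """Percus–Yevick hard-sphere S(q) (Ashcroft–Lekner analytic solution).

    S(0) = (1-phi)^4 / (1+2 phi)^2 and S -> 1 at large q.
    """
    if not 0 <= phi < 0.74:
        raise ValueError("phi must lie in [0, 0.74)")
    q = np.asarray(q, dtype=float)
    if phi == 0:
        return np.ones_like(q)
    eta = phi
    al = (1 + 2 * eta) ** 2 / (1 - eta) ** 4
    be = -6 * eta * (1 + eta / 2) ** 2 / (1 - eta) ** 4
    ga = eta * al / 2
    A = 2.0 * q * r_hs
    big = A > 0.2
    b1 = np.empty_like(A)
    b2 = np.empty_like(A)
    b3 = np.empty_like(A)
    Ab = A[big]
    sA, cA = np.sin(Ab), np.cos(Ab)
    b1[big] = (sA - Ab * cA) / Ab ** 3
    b2[big] = (2 * Ab * sA + (2 - Ab ** 2) * cA - 2) / Ab ** 4
    b3[big] = (-(Ab ** 4) * cA + 4 * ((3 * Ab ** 2 - 6) * cA
                                      + (Ab ** 3 - 6 * Ab) * sA + 6)) / Ab ** 6
    As = A[~big]
    A2 = As * As
    b1[~big] = 1 / 3 - A2 / 30 + A2 * A2 / 840
    b2[~big] = 1 / 4 - A2 / 36 + A2 * A2 / 1152
    b3[~big] = 1 / 6 - A2 / 48
    nc = -24 * eta * (al * b1 + be * b2 + ga * b3)
    return 1.0 / (1.0 - nc)


def _baxter_lambda(phi: float, tau: float) -> float:
    """Physical root of the Baxter quadratic for the sticky parameter lambda."""
    eta = phi
    a = eta / 12.0
    b = tau + eta / (1.0 - eta)
    c = (1.0 + eta / 2.0) / (1.0 - eta) ** 2
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError(
            f"no real Baxter solution for phi={phi}, tau={tau} "
            "(inside the spinodal/unphysical region)")
    return (b - np.sqrt(disc)) / (2.0 * a)


def sticky_hs_structure_factor(q, r_hs: float, phi: float,
                               tau: float) -> np.ndarray:
    """Baxter one-component sticky-hard-sphere S(q) in the PY closure.

    ``tau`` is the stickiness parameter; tau -> infinity recovers the plain
    Percus–Yevick hard-sphere result.  Raises for (phi, tau) outside the
    physical branch (the Baxter quadratic has no real root).
    """
    if not 0 <= phi < 0.74:
        raise ValueError("phi must lie in [0, 0.74)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    q = np.asarray(q, dtype=float)
    if phi == 0:
        return np.ones_like(q)
    eta = phi
    lam = _baxter_lambda(phi, tau)
    mu = lam * eta * (1.0 - eta)
    onemineta = 1.0 - eta
    alpha = (1.0 + 2.0 * eta - mu) / onemineta ** 2
    beta = (mu - 3.0 * eta) / (2.0 * onemineta ** 2)
    k = 2.0 * q * r_hs
    out = np.empty_like(k)
    small = k < 1e-6
    k_ = np.where(small, 1.0, k)
    s, c = np.sin(k_), np.cos(k_)
    k2, k3 = k_ ** 2, k_ ** 3
    aq = 1.0 + 12.0 * eta * (alpha * (s - k_ * c) / k3
                             + beta * (1.0 - c) / k2
                             - lam * s / (12.0 * k_))
    bq = 12.0 * eta * (alpha * (0.5 / k_ - s / k2 + (1.0 - c) / k3)
                       + beta * (1.0 / k_ - s / k2)
                       - lam * (1.0 - c) / (12.0 * k_))
    out = 1.0 / (aq * aq + bq * bq)
    if np.any(small):
        a0 = 1.0 + 12.0 * eta * (alpha / 3.0 + beta / 2.0 - lam / 12.0)
        out[small] = 1.0 / (a0 * a0)
    return out


def _gauss_radius_quadrature(d_mean: float, d_sd: float, npts: int = 35):
    """Radii and weights for the truncated Gaussian diameter distribution."""
    if d_sd == 0:
        return np.array([d_mean / 2.0]), np.array([1.0])
    lo = max(d_mean - 4.0 * d_sd, 1e-3 * d_mean)
    hi = d_mean + 4.0 * d_sd
    d = np.linspace(lo, hi, npts)
    w = np.exp(-0.5 * ((d - d_mean) / d_sd) ** 2)
    # volume-square weighting: scattering power scales with V^2
    w = w * (d ** 6)
    w /= w.sum()
    return d / 2.0, w


def model_intensity(q, params: SAXSModelParams,
                    model: str = "py") -> np.ndarray:
    """Forward model I(q) = scale * <P>_polydispersity * S + background.

    ``model`` is 'py' (hard spheres) or 'sticky' (Baxter, requires tau).
    Polydispersity uses the local-monodisperse approximation: the form
    factor is averaged over the truncated Gaussian diameter distribution
    (volume-square weighted) while S is evaluated at the effective
    hard-sphere radius.
    """
    q = np.asarray(q, dtype=float)
    radii, w = _gauss_radius_quadrature(params.d_mean, params.d_sd)
    P = np.zeros_like(q)
    for r, wi in zip(radii, w):
        P += wi * sphere_form_factor(q, r)
    if params.phi == 0:
        S = np.ones_like(q)
    elif model == "py":
        S = py_structure_factor(q, params.r_hs, params.phi)
    elif model == "sticky":
        if params.tau is None:
            raise ValueError("sticky model requires tau")
        S = sticky_hs_structure_factor(q, params.r_hs, params.phi, params.tau)
    else:
        raise ValueError(f"unknown model {model!r}")
    return params.scale * P * S + params.background


def debye_intensity(a: SphereAssembly, q, n_cap: int = 2000) -> np.ndarray:
    """Orientation-averaged Debye sum over sphere pairs.

    I(q) = sum_ij F_i(q) F_j(q) sinc(q d_ij) with per-sphere amplitudes
    F_i = V_i * 3(sin qR_i - qR_i cos qR_i)/(qR_i)^3.  O(N^2) per q point;
    refuses assemblies above ``n_cap`` particles (subsample instead).
    Distances use the minimum image on periodic axes.
    """
    if a.n > n_cap:
        raise ValueError(f"N = {a.n} exceeds the Debye cap {n_cap}; "
                         "subsample the assembly")
    q = np.asarray(q, dtype=float).ravel()
    V = 4.0 / 3.0 * np.pi * a.radii ** 3
    F = V[None, :] * _sphere_amplitude(np.outer(q, a.radii))  # (nq, N)
    I = np.sum(F * F, axis=1)
    if a.n > 1:
        ii, jj = np.triu_indices(a.n, k=1)
        dr = a.minimum_image(a.positions[ii] - a.positions[jj])
        d = np.linalg.norm(dr, axis=1)
        qd = np.outer(q, d)
        sinc = np.where(qd < 1e-8, 1.0, np.sin(qd) / np.where(qd < 1e-8, 1.0, qd))
        I = I + 2.0 * np.sum(F[:, ii] * F[:, jj] * sinc, axis=1)
    return I


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_FIT_FIELDS = ("d_mean", "d_sd", "phi", "r_hs", "tau", "scale", "background")


def fit_saxs(profile: ScatteringProfile, model: str,
             init: SAXSModelParams,
             fixed: Sequence[str] = (),
             tie_r_hs: bool = True):
    """Weighted least-squares fit of the sphere + structure-factor model.

    Weights are 1/sigma^2 when the profile carries uncertainties, applied
    to log-free residuals; deterministic given ``init``.  ``fixed`` names
    parameters held at their initial value; ``tie_r_hs`` constrains the
    effective hard-sphere radius to d_mean/2 (the default geometry).

    Returns (params, uncertainties, redchi) where ``uncertainties`` maps
    free parameter names to 1-sigma estimates (None when the covariance is
    degenerate).
    """
    if len(profile.q) < 10:
        raise ValueError("need at least 10 data points")
    if model == "sticky" and init.tau is None:
        raise ValueError("sticky model requires an initial tau")

    p = lmfit.Parameters()
    p.add("d_mean", value=init.d_mean, min=init.d_mean * 0.2,
          max=init.d_mean * 5.0)
    p.add("d_sd", value=max(init.d_sd, 1e-3), min=0.0,
          max=0.5 * init.d_mean)
    p.add("phi", value=max(init.phi, 1e-4), min=0.0, max=0.72)
    if tie_r_hs:
        p.add("r_hs", expr="d_mean / 2")
    else:
        p.add("r_hs", value=init.r_hs, min=init.r_hs * 0.3,
              max=init.r_hs * 3.0)
    if model == "sticky":
        p.add("tau", value=init.tau, min=0.06, max=1e6)
    p.add("scale", value=init.scale, min=0.0)
    p.add("background", value=init.background, min=0.0)
    for name in fixed:
        if name in p:
            p[name].vary = False

    q = profile.q
    y = profile.intensity
    w = 1.0 / profile.sigma if profile.sigma is not None else None

    def residual(pars):
        kw = {k: pars[k].value for k in ("d_mean", "d_sd", "phi", "r_hs",
                                         "scale", "background")}
        if model == "sticky":
            kw["tau"] = pars["tau"].value
        try:
            mp = SAXSModelParams(**kw)
            ym = model_intensity(q, mp, model=model)
        except ValueError:
            return np.full_like(y, 1e6)
        r = ym - y
        return r * w if w is not None else r

    result = lmfit.minimize(residual, p, method="leastsq", nan_policy="raise")
    if not result.success:
        raise RuntimeError(f"fit did not converge: {result.message}")
    v = result.params
    fitted = SAXSModelParams(
        d_mean=v["d_mean"].value, d_sd=v["d_sd"].value, phi=v["phi"].value,
        r_hs=v["r_hs"].value,
        tau=v["tau"].value if model == "sticky" else None,
        scale=v["scale"].value, background=v["background"].value)
    unc = {}
    for name, par in v.items():
        if par.vary:
            unc[name] = float(par.stderr) if par.stderr is not None else None
    return fitted, unc, float(result.redchi)


def synthetic_profile(params: SAXSModelParams, model: str = "py",
                      q: Optional[np.ndarray] = None,
                      noise: float = 0.02,
                      rng: Optional[np.random.Generator] = None
                      ) -> ScatteringProfile:
    """Generate a noisy synthetic scattering profile from the forward model.

    ``noise`` is the relative (counting-statistics-like) noise level; the
    per-point sigma is recorded in the profile.
    """
    if q is None:
        q = default_q_grid()
    rng = rng or np.random.default_rng(0)
    I = model_intensity(q, params, model=model)
    sigma = np.maximum(noise * I, 1e-12)
    if noise > 0:
        I = np.clip(I + rng.normal(0.0, sigma), 0.0, None)
    return ScatteringProfile(q, I, sigma,
                             meta={"model": model, **asdict(params)})
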