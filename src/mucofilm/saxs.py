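"""Bulk-solution SAXS analysis.

Form-factor models for a Gaussian polymer coil (Debye function) and for
mucin's dumbbell architecture (flexible glycopeptide chain + compact
hydrophobic globules with hard-sphere interactions), Guinier and
power-law analysis, and the two-component additive mixture test used to
detect polymer-mucin clustering: if a mixed solution scatters more at
low q than the weighted sum of its components, large phase-separated
clusters have formed.

Unit convention: q in A^-1, real-space lengths (Rg, xi, Xi, R) in nm, so
dimensionless products use q*length*10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit
from numpy.polynomial import polynomial as _poly

from .core import FitResult, ScatteringCurve

__all__ = [
    "GaussianCoilModel",
    "DumbbellModel",
    "GuinierResult",
    "PowerLawResult",
    "debye_form_factor",
    "fit_gaussian_coil",
    "guinier_fit",
    "power_law_fit",
    "py_structure_factor",
    "sphere_form_factor",
    "dumbbell_intensity",
    "mixture_model",
    "excess_intensity",
]

NM_PER_AINV = 10.0  # q[A^-1] * L[nm] * 10 is dimensionless


@dataclass
class GaussianCoilModel:
    rg: float  # nm
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("rg must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class DumbbellModel:
    """Two-level mucin model: an Ornstein-Zernike chain term with
    correlation length ``xi`` plus a low-q power law of amplitude ``i2``
    and exponent ``n_exp`` over the large-scale length ``Xi`` (the
    glycopeptide mesh), and a globule term of Schulz-polydisperse spheres
    of mean radius ``r_globule`` interacting as Percus-Yevick hard
    spheres with volume fraction ``phi_hs``."""

    xi: float = 5.0       # nm
    Xi: float = 50.0      # nm
    n_exp: float = 3.0
    i1: float = 1.0
    i2: float = 0.01
    r_globule: float = 10.0  # nm
    poly: float = 0.2
    phi_hs: float = 0.15
    scale: float = 1.0    # absorbs N V^2 (rho_m - rho_s)^2
    background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.xi, self.Xi, self.r_globule) <= 0:
            raise ValueError("lengths must be > 0")
        if not 0.0 <= self.phi_hs < 0.74:
            raise ValueError("phi_hs must lie in [0, 0.74)")
        if self.poly < 0:
            raise ValueError("poly must be >= 0")
        if self.n_exp <= 0:
            raise ValueError("n_exp must be > 0")


@dataclass
class GuinierResult:
    rg: float            # nm
    i0: float
    q_window: tuple[float, float]  # A^-1
    qrg_max: float
    is_lower_bound: bool
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("rg must be > 0")


@dataclass
class PowerLawResult:
    exponent: float
    prefactor: float
    q_window: tuple[float, float]
    fractal_class: str = ""

    def __post_init__(self) -> None:
        if not self.fractal_class:
            self.fractal_class = classify_fractal(self.exponent)


def classify_fractal(exponent: float) -> str:
    """Surface fractal for slopes in (-4, -3], mass fractal in (-3, -1.5]."""
    if -4.0 < exponent <= -3.0:
        return "surface"
    if -3.0 < exponent <= -1.5:
        return "mass"
    return "other"


def debye_form_factor(q: np.ndarray, rg: float) -> np.ndarray:
    """Debye function P(q) = 2(exp(-x) + x - 1)/x^2 with x = (q Rg)^2.

    Normalised to P(0)=1, strictly decreasing; a series expansion is used
    for x < 1e-4 to avoid catastrophic cancellation.
    """
    if rg <= 0:
        raise ValueError("rg must be > 0")
    q = np.asarray(q, dtype=float)
    x = (q * rg * NM_PER_AINV) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs**2 / 12.0 - xs**3 / 60.0
    xl = x[~small]
    out[~small] = 2.0 * (np.expm1(-xl) + xl) / xl**2
    return out


def fit_gaussian_coil(curve: ScatteringCurve, init: GaussianCoilModel) -> FitResult:
    """Weighted bounded least squares of scale*P_Debye(q; Rg) + background."""
    params = lmfit.Parameters()
    params.add("rg", value=init.rg, min=1e-3, max=1e3)
    params.add("scale", value=init.scale, min=1e-12)
    params.add("background", value=init.background, min=0.0)

    sigma = curve.sigma
    weights = None if sigma is None else 1.0 / np.where(sigma > 0, sigma, np.inf)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = p["scale"] * debye_form_factor(curve.q, p["rg"].value) + p["background"]
        r = curve.intensity - model
        return r if weights is None else r * weights

    res = lmfit.minimize(residual, params, method="least_squares")
    return _to_fitresult(res, len(curve))


def _to_fitresult(res, n_points: int) -> FitResult:
    params = {k: float(v.value) for k, v in res.params.items() if v.vary}
    stderr = {
        k: (float(v.stderr) if v.stderr is not None else None)
        for k, v in res.params.items()
        if v.vary
    }
    return FitResult(
        params=params,
        stderr=stderr,
        chi2=float(res.chisqr),
        n_points=n_points,
        converged=bool(res.success),
        redchi=float(res.redchi),
        message=str(res.message),
    )


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.0) -> GuinierResult:
    """Guinier analysis: ln I = ln I0 - q^2 Rg^2 / 3 on the self-consistent
    low-q window q*Rg <= qrg_limit.

    The window is found by fixed-point iteration: fit on the current
    window, recompute qmax = qrg_limit/Rg, repeat until Rg moves by less
    than 0.1%.  If even the smallest measured q violates qmin*Rg < 1 the
    result is flagged as a lower bound (``is_lower_bound``), mirroring the
    "Rg >= ..." convention for cluster sizes that exceed the resolved
    window.
    """
    q, i = curve.q, curve.intensity
    pos = i > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 points with positive intensity")
    q, i = q[pos], i[pos]

    def linfit(mask: np.ndarray) -> tuple[float, float]:
        c0, c1 = _poly.polyfit(q[mask] ** 2, np.log(i[mask]), 1)
        if c1 >= 0:  # non-decreasing curve: no Guinier decay
            raise ValueError("intensity does not decay; Guinier fit undefined")
        rg_nm = np.sqrt(-3.0 * c1) / NM_PER_AINV
        return rg_nm, float(np.exp(c0))

    # start from the full curve (over-wide window biases Rg low, which the
    # fixed-point iteration then relaxes outward)
    mask = np.ones_like(q, dtype=bool)
    rg, i0 = linfit(mask)
    for _ in range(100):
        qmax = qrg_limit / (rg * NM_PER_AINV)
        new = q <= qmax
        if new.sum() < 3:
            new = np.zeros_like(mask)
            new[:3] = True
        if new.sum() == mask.sum() and np.array_equal(new, mask):
            break
        rg_new, i0 = linfit(new)
        mask = new
        if abs(rg_new - rg) <= 1e-3 * rg:
            rg = rg_new
            break
        rg = rg_new
    qwin = (float(q[mask][0]), float(q[mask][-1]))
    qrg_max = qwin[1] * rg * NM_PER_AINV
    lower_bound = bool(qwin[0] * rg * NM_PER_AINV > 1.0)
    return GuinierResult(
        rg=rg,
        i0=i0,
        q_window=qwin,
        qrg_max=qrg_max,
        is_lower_bound=lower_bound,
        n_points=int(mask.sum()),
    )


def power_law_fit(curve: ScatteringCurve, q_window: tuple[float, float]) -> PowerLawResult:
    """Slope of log I vs log q over the window; classifies the fractal
    regime from the exponent."""
    sub = curve.select(*q_window)
    if len(sub) < 4:
        raise ValueError("need at least 4 points in the q window")
    if np.any(sub.intensity <= 0):
        raise ValueError("nonpositive intensity in the power-law window")
    c0, c1 = _poly.polyfit(np.log(sub.q), np.log(sub.intensity), 1)
    return PowerLawResult(
        exponent=float(c1),
        prefactor=float(np.exp(c0)),
        q_window=(float(sub.q[0]), float(sub.q[-1])),
    )


def py_structure_factor(q: np.ndarray, r_hs: float, phi_hs: float) -> np.ndarray:
    """Percus-Yevick hard-sphere structure factor (Ashcroft-Lekner analytic
    solution) for monodisperse spheres of radius ``r_hs`` (nm).

    S(0) = (1-phi)^4 / (1+2 phi)^2 (compressibility limit) and S -> 1 at
    large q; phi_hs = 0 returns S = 1 exactly.
    """
    if not 0.0 <= phi_hs < 0.74:
        raise ValueError("phi_hs must lie in [0, 0.74)")
    if r_hs <= 0:
        raise ValueError("r_hs must be > 0")
    q = np.asarray(q, dtype=float)
    if phi_hs == 0.0:
        return np.ones_like(q)
    phi = phi_hs
    alpha = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
    beta = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
    gamma = phi * alpha / 2

    A = 2.0 * q * r_hs * NM_PER_AINV  # q * sphere diameter
    sinA, cosA = np.sin(A), np.cos(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = (sinA - A * cosA) / A**3
        f2 = (2 * A * sinA + (2 - A**2) * cosA - 2) / A**4
        f3 = (-(A**4) * cosA + 4 * ((3 * A**2 - 6) * cosA + (A**3 - 6 * A) * sinA + 6)) / A**6
    # series for small A (cancellation-safe)
    small = A < 0.5
    As = A**2
    f1 = np.where(small, 1 / 3 - As / 30 + As**2 / 840 - As**3 / 45360 + As**4 / 3991680, f1)
    f2 = np.where(small, 1 / 4 - As / 36 + As**2 / 960 - As**3 / 50400
                  + As**4 * (11 / 47900160), f2)
    f3 = np.where(small, 1 / 6 - As / 48 + As**2 / 1200 - As**3 / 60480
                  + As**4 * (17160 / 87178291200), f3)
    G_over_A = alpha * f1 + beta * f2 + gamma * f3
    return 1.0 / (1.0 + 24.0 * phi * G_over_A)


def sphere_form_factor(q: np.ndarray, r: float) -> np.ndarray:
    """Normalised form factor of a homogeneous sphere of radius r (nm);
    first zero at q*r = 4.493."""
    q = np.asarray(q, dtype=float)
    x = q * r * NM_PER_AINV
    out = np.ones_like(x)
    nz = x > 1e-6
    xn = x[nz]
    out[nz] = (3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn**3) ** 2
    return out


def _schulz_average_sphere(q: np.ndarray, r_mean: float, poly: float, npts: int = 61) -> np.ndarray:
    """<P_sphere(q; R)> over a Schulz radius distribution of relative
    polydispersity ``poly`` (sigma_R / R).  poly = 0 returns the
    monodisperse form factor."""
    if poly <= 0:
        return sphere_form_factor(q, r_mean)
    z = 1.0 / poly**2 - 1.0
    # integrate over +-5 sigma, clipped to positive radii
    sigma = poly * r_mean
    radii = np.linspace(max(r_mean - 5 * sigma, 1e-3 * r_mean), r_mean + 5 * sigma, npts)
    with np.errstate(over="ignore"):
        logw = z * np.log(radii / r_mean) - (z + 1) * radii / r_mean
    w = np.exp(logw - logw.max())
    w /= w.sum()
    P = np.stack([sphere_form_factor(q, r) for r in radii])
    return w @ P


def dumbbell_intensity(q: np.ndarray, model: DumbbellModel) -> np.ndarray:
    """Two-term mucin intensity: peptide chain + interacting globules.

    I(q) = i1/(1 + xi^2 q^2) + i2/(Xi q)^n
         + scale * <P_sphere>_Schulz(q; R, poly) * S_PY(q; R, phi_hs)

    The structure factor uses the mean radius (local-monodisperse
    approximation).
    """
    q = np.asarray(q, dtype=float)
    qn = q * NM_PER_AINV  # nm^-1
    peptide = model.i1 / (1.0 + (model.xi * qn) ** 2)
    if model.i2:
        peptide = peptide + model.i2 / (model.Xi * qn) ** model.n_exp
    P = _schulz_average_sphere(q, model.r_globule, model.poly)
    S = py_structure_factor(q, model.r_globule, model.phi_hs)
    return peptide + model.scale * P * S + model.background


def mixture_model(i_pgm: np.ndarray, i_argo: np.ndarray, a: float) -> np.ndarray:
    """Additive two-component prediction I_mixed = I_PGM + A * I_ARGO.

    The two intensity grids must share identical q sampling (enforced by
    length; no silent interpolation)."""
    i_pgm = np.asarray(i_pgm, dtype=float)
    i_argo = np.asarray(i_argo, dtype=float)
    if i_pgm.shape != i_argo.shape:
        raise ValueError("component intensity grids have different shapes")
    return i_pgm + a * i_argo


def excess_intensity(measured: ScatteringCurve, i_pgm: np.ndarray, i_argo: np.ndarray, a: float) -> np.ndarray:
    """Measured minus the additive mixture prediction; positive low-q
    excess signals cluster formation."""
    pred = mixture_model(i_pgm, i_argo, a)
    if pred.shape != measured.intensity.shape:
        raise ValueError("prediction grid does not match the measured curve")
    return measured.intensity - pred
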