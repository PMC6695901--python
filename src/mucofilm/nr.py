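"""Specular neutron reflectometry slab models and multi-contrast fitting.

A sample is a :class:`LayerStack`: semi-infinite fronting (silicon, beam
through the substrate), an ordered list of :class:`Slab` layers, and a
semi-infinite solvent backing.  Reflectivity is computed exactly with the
optical-matrix (Parratt recursion) method; Gaussian interfacial roughness
enters through Nevot-Croce damping of each Fresnel coefficient.  A
kinematic (Born-approximation) reflectivity is provided as an independent
cross-check, and Gaussian dq/q resolution smearing emulates the
wavelength spread of a time-of-flight or monochromatic instrument.

Contrast variation: the same structure measured in H2O and in D2O shares
all structural parameters; only solvent-dependent SLDs differ.
:func:`corefine` fits all contrasts simultaneously with shared structure
and per-contrast scale/background nuisance parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.special import erf

from .constants import SILICA_SLD, SILICON_SLD
from .core import (
    FitResult,
    Material,
    ScatteringCurve,
    Solvent,
    hydrated_layer_sld,
    material_sld,
)

__all__ = [
    "Slab",
    "LayerStack",
    "ContrastSeries",
    "ResolutionSpec",
    "abeles_reflectivity",
    "born_reflectivity",
    "smear",
    "corefine",
    "build_paper_stacks",
    "critical_edge",
    "sld_profile",
    "SCENARIOS",
]


@dataclass
class Slab:
    """One homogeneous layer.

    The layer SLD is resolved per solvent: either ``sld`` is fixed
    (solvent independent), or the layer is a hydrated material --
    ``phi`` volume fraction of material mixed with ``1-phi`` solvent --
    where the dry SLD comes from a :class:`Material` (with labile-H
    exchange) or from an explicit ``dry_sld`` (a number, or an
    ``(H2O, D2O)`` pair interpolated linearly in the solvent D fraction).

    ``roughness`` is the Gaussian sigma of the interface with the layer
    above (towards the fronting), in Angstrom.
    """

    thickness: float
    roughness: float = 0.0
    label: str = ""
    sld: float | None = None
    material: Material | None = None
    dry_sld: float | tuple[float, float] | None = None
    phi: float = 1.0
    exchange_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if self.roughness < 0:
            raise ValueError("roughness must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        specs = sum(x is not None for x in (self.sld, self.material, self.dry_sld))
        if specs != 1 and not (specs == 0 and self.phi == 0.0):
            raise ValueError("specify exactly one of sld / material / dry_sld")

    def resolve_sld(self, solvent: Solvent) -> float:
        if self.sld is not None:
            return self.sld
        if self.material is not None:
            dry = material_sld(self.material, solvent, self.exchange_efficiency)
        elif self.dry_sld is None:  # pure-solvent gap layer
            return solvent.sld
        elif isinstance(self.dry_sld, tuple):
            h, d = self.dry_sld
            dry = (1.0 - solvent.d_fraction) * h + solvent.d_fraction * d
        else:
            dry = self.dry_sld
        return hydrated_layer_sld(dry, self.phi, solvent)


@dataclass
class LayerStack:
    """Fronting / slabs / backing.  The backing is the bulk solvent unless
    an explicit ``backing_sld`` is given."""

    slabs: list[Slab]
    fronting_sld: float = SILICON_SLD
    backing_solvent: Solvent | None = None
    backing_sld: float | None = None
    backing_roughness: float = 3.0

    def __post_init__(self) -> None:
        if self.backing_sld is None and self.backing_solvent is None:
            raise ValueError("provide backing_solvent or backing_sld")

    def resolved(self, solvent: Solvent | None = None):
        """(sld, thickness, roughness) arrays for fronting + slabs + backing.

        ``roughness[j]`` is the sigma of interface j (between layer j and
        layer j+1, counting the fronting as layer 0).
        """
        solv = solvent or self.backing_solvent
        rho = [self.fronting_sld]
        thick = [0.0]
        sigma = []
        for s in self.slabs:
            rho.append(s.resolve_sld(solv))
            thick.append(s.thickness)
            sigma.append(s.roughness)
        rho.append(self.backing_sld if self.backing_sld is not None else solv.sld)
        thick.append(0.0)
        sigma.append(self.backing_roughness)
        return np.asarray(rho), np.asarray(thick), np.asarray(sigma)

    def with_solvent(self, solvent: Solvent) -> "LayerStack":
        out = copy.deepcopy(self)
        out.backing_solvent = solvent
        return out

    def slab(self, label: str) -> Slab:
        for s in self.slabs:
            if s.label == label:
                return s
        raise KeyError(f"no slab labelled {label!r}")


@dataclass
class ResolutionSpec:
    """Constant relative Gaussian q-resolution.  ``dq_over_q`` is sigma/q;
    a FWHM-quoted wavelength spread divides by 2.355."""

    dq_over_q: float = 0.10 / 2.355
    convention: str = "sigma"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dq_over_q < 0.5:
            raise ValueError("dq_over_q must lie in [0, 0.5)")

    @property
    def sigma_over_q(self) -> float:
        return self.dq_over_q / 2.355 if self.convention == "fwhm" else self.dq_over_q


@dataclass
class ContrastSeries:
    """Datasets of one structure measured in several solvent contrasts.

    ``contrasts`` maps a name (e.g. ``"h2o"``) to ``(Solvent, curve)``;
    the stack template's structural parameters are shared across all of
    them.
    """

    stack: LayerStack
    contrasts: dict[str, tuple[Solvent, ScatteringCurve]]
    resolution: ResolutionSpec = field(default_factory=ResolutionSpec)


def _wavevectors(q: np.ndarray, rho: np.ndarray, rho_f: float) -> np.ndarray:
    """k_j(q) = sqrt((q/2)^2 - 4 pi (rho_j - rho_f)), complex, one row per
    layer."""
    k0sq = (q / 2.0) ** 2
    arg = k0sq[None, :] - 4.0 * np.pi * (rho[:, None] - rho_f)
    return np.sqrt(arg.astype(complex))


def abeles_reflectivity(stack: LayerStack, q: np.ndarray, solvent: Solvent | None = None) -> np.ndarray:
    """Exact specular reflectivity by the optical-matrix (Parratt)
    recursion with Nevot-Croce roughness damping.

    Satisfies 0 <= R <= 1 with R = 1 below the critical edge when the
    backing SLD exceeds the fronting SLD.
    """
    q = np.asarray(q, dtype=float)
    rho, thick, sigma = stack.resolved(solvent)
    k = _wavevectors(q, rho, rho[0])
    # recursion from the bottom interface upwards
    r = np.zeros_like(q, dtype=complex)
    for j in range(len(rho) - 2, -1, -1):
        kj, kj1 = k[j], k[j + 1]
        rf = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * sigma[j] ** 2)
        if j == len(rho) - 2:
            r = rf
        else:
            phase = np.exp(2j * kj1 * thick[j + 1])
            r = (rf + r * phase) / (1.0 + rf * r * phase)
    return np.clip(np.abs(r) ** 2, 0.0, 1.0)


def critical_edge(stack: LayerStack, solvent: Solvent | None = None) -> float:
    """q_c = sqrt(16 pi (rho_backing - rho_fronting)); 0 if the contrast is
    negative (no total reflection)."""
    rho, _, _ = stack.resolved(solvent)
    d = rho[-1] - rho[0]
    return float(np.sqrt(16.0 * np.pi * d)) if d > 0 else 0.0


def born_reflectivity(stack: LayerStack, q: np.ndarray, solvent: Solvent | None = None) -> np.ndarray:
    """Kinematic (Born-approximation) reflectivity.

    R(q) = 16 pi^2 / q^4 * |sum_j drho_j exp(i q z_j) exp(-q^2 s_j^2/2)|^2,
    the Fourier transform of the roughness-smoothed SLD profile (the
    1/q^2-of-rho(q) convention and the derivative-profile 1/q^4 form are
    equivalent by integration by parts).  Valid well above the critical
    edge; no multiple scattering, so R may exceed 1 near q_c.
    """
    q = np.asarray(q, dtype=float)
    rho, thick, sigma = stack.resolved(solvent)
    z = np.concatenate([[0.0], np.cumsum(thick[1:-1])])
    drho = np.diff(rho)
    amp = np.zeros_like(q, dtype=complex)
    for dj, zj, sj in zip(drho, z, sigma):
        amp += dj * np.exp(1j * q * zj) * np.exp(-0.5 * (q * sj) ** 2)
    return 16.0 * np.pi**2 / q**4 * np.abs(amp) ** 2


def smear(r: np.ndarray, q: np.ndarray, res: ResolutionSpec) -> np.ndarray:
    """Gaussian resolution smearing with sigma_q = (dq/q) * q pointwise.

    Convolution is evaluated on the given grid with trapezoidal weights;
    dq_over_q = 0 returns the input unchanged.
    """
    s = res.sigma_over_q
    if s == 0.0:
        return np.asarray(r, dtype=float).copy()
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.gradient(q)  # integration weights on a possibly non-uniform grid
    sig = s * q
    kern = np.exp(-0.5 * ((q[None, :] - q[:, None]) / sig[:, None]) ** 2) * w[None, :]
    kern /= kern.sum(axis=1, keepdims=True)
    return kern @ r


def sld_profile(
    stack: LayerStack,
    solvent: Solvent | None = None,
    z: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Roughness-smoothed (erf) SLD depth profile, fronting at z < 0."""
    rho, thick, sigma = stack.resolved(solvent)
    zi = np.concatenate([[0.0], np.cumsum(thick[1:-1])])
    if z is None:
        span = zi[-1] if zi[-1] > 0 else 50.0
        z = np.linspace(-30.0, span + 30.0, 500)
    prof = np.full_like(z, rho[0], dtype=float)
    for j, (zj, sj) in enumerate(zip(zi, sigma)):
        step = rho[j + 1] - rho[j]
        if sj > 0:
            prof += step * 0.5 * (1.0 + erf((z - zj) / (np.sqrt(2.0) * sj)))
        else:
            prof += step * (z >= zj)
    return z, prof


# ---------------------------------------------------------------------------
# Multi-contrast co-refinement
# ---------------------------------------------------------------------------

_SLAB_ATTRS = ("thickness", "phi", "roughness", "sld")


def _stack_parameters(stack: LayerStack, free: set[str], bounds: dict) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for s in stack.slabs:
        if not s.label:
            continue
        for attr in _SLAB_ATTRS:
            val = getattr(s, attr)
            if val is None or isinstance(val, tuple):
                continue
            name = f"{s.label}_{attr}"
            lo, hi = bounds.get(name, _default_bounds(attr, val))
            params.add(name, value=float(val), min=lo, max=hi, vary=name in free)
    return params


def _default_bounds(attr: str, val: float) -> tuple[float, float]:
    if attr == "phi":
        return (0.0, 1.0)
    if attr == "thickness":
        return (0.0, max(4.0 * val, 100.0))
    if attr == "roughness":
        return (0.0, max(3.0 * val, 15.0))
    if attr == "sld":
        return (-1e-6, 1e-5)
    return (-np.inf, np.inf)


def _apply_params(stack: LayerStack, params: lmfit.Parameters) -> LayerStack:
    out = copy.deepcopy(stack)
    for s in out.slabs:
        for attr in _SLAB_ATTRS:
            name = f"{s.label}_{attr}"
            if s.label and name in params:
                setattr(s, attr, float(params[name].value))
    return out


def corefine(
    series: ContrastSeries,
    free: list[str],
    bounds: dict | None = None,
    fit_scale: bool = True,
    fit_background: bool = True,
    n_restarts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Simultaneous bounded least-squares fit of all contrasts.

    Structural parameters (named ``<slab label>_<thickness|phi|roughness|
    sld>``) are shared across contrasts; each contrast gets its own
    intensity scale and constant background nuisance parameter.  The
    summed per-contrast chi^2 is minimised with a trust-region reflective
    solver; ``n_restarts`` seeded multi-starts jitter the free structural
    parameters within bounds and the best minimum is kept.
    """
    bounds = bounds or {}
    params = _stack_parameters(series.stack, set(free), bounds)
    missing = [f for f in free if f not in params]
    if missing:
        raise ValueError(f"unknown free parameters: {missing}")
    for name in series.contrasts:
        params.add(f"scale_{name}", value=1.0, min=0.3, max=3.0, vary=fit_scale)
        params.add(f"background_{name}", value=0.0, min=0.0, max=1e-4, vary=fit_background)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        stack = _apply_params(series.stack, p)
        out = []
        for name, (solvent, curve) in series.contrasts.items():
            model = abeles_reflectivity(stack, curve.q, solvent)
            model = smear(model, curve.q, series.resolution)
            model = p[f"scale_{name}"].value * model + p[f"background_{name}"].value
            r = curve.intensity - model
            if curve.sigma is not None:
                r = r / np.where(curve.sigma > 0, curve.sigma, np.inf)
            out.append(r)
        return np.concatenate(out)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_restarts)):
        p0 = copy.deepcopy(params)
        if start > 0:  # jitter free structural params within bounds
            for f in free:
                par = p0[f]
                span = par.max - par.min
                if np.isfinite(span):
                    par.value = float(
                        np.clip(par.value + rng.uniform(-0.15, 0.15) * span, par.min, par.max)
                    )
        res = lmfit.minimize(residual, p0, method="least_squares")
        if best is None or res.chisqr < best.chisqr:
            best = res

    n_points = sum(len(c) for _, c in series.contrasts.values())
    per_ds: dict[str, float] = {}
    stack = _apply_params(series.stack, best.params)
    for name, (solvent, curve) in series.contrasts.items():
        model = abeles_reflectivity(stack, curve.q, solvent)
        model = smear(model, curve.q, series.resolution)
        model = best.params[f"scale_{name}"].value * model + best.params[f"background_{name}"].value
        r = curve.intensity - model
        if curve.sigma is not None:
            r = r / np.where(curve.sigma > 0, curve.sigma, np.inf)
        per_ds[name] = float(np.sum(r**2))

    result = FitResult(
        params={k: float(v.value) for k, v in best.params.items() if v.vary},
        stderr={
            k: (float(v.stderr) if v.stderr is not None else None)
            for k, v in best.params.items()
            if v.vary
        },
        chi2=float(best.chisqr),
        n_points=n_points,
        converged=bool(best.success),
        redchi=float(best.redchi),
        per_dataset_chi2=per_ds,
    )
    return result


# ---------------------------------------------------------------------------
# Named sample scenarios with literature-informed default parameters
# ---------------------------------------------------------------------------

#: Dry mucin SLD in the two pure solvents (A^-2), consistent with a
#: hydrated-layer SLD of 2.5e-6 (H2O) / 5.6e-6 (D2O) at 60% occupancy;
#: the difference reflects labile-H exchange of the sugar -OH/-NH groups.
MUCIN_DRY_SLD = (4.54e-6, 5.09e-6)

#: Amphoteric polyamidoamine polymer, assumed values (not published).
POLYMER_DRY_SLD = (1.8e-6, 2.6e-6)

# d62-DPPC: perdeuterated acyl chains, protiated phosphocholine head.
DPPC_D62_TAIL_SLD = 7.0e-6
PC_HEAD_SLD = (1.88e-6, 1.88e-6)

SCENARIOS = (
    "bare_mucin",
    "mucin_polymer",
    "dppc_membrane",
    "dppc_gm1_mucin",
    "dppc_gm1_mucin_polymer",
)


def _sio2() -> Slab:
    return Slab(thickness=12.0, roughness=3.0, label="sio2", sld=SILICA_SLD)


def _mucin(thickness: float = 22.0, phi: float = 0.60) -> Slab:
    return Slab(thickness=thickness, roughness=4.0, label="mucin",
                dry_sld=MUCIN_DRY_SLD, phi=phi)


def _polymer() -> Slab:
    return Slab(thickness=70.0, roughness=10.0, label="polymer",
                dry_sld=POLYMER_DRY_SLD, phi=0.25)


def _bilayer(solvation: float = 0.05) -> list[Slab]:
    return [
        Slab(thickness=4.0, roughness=3.0, label="water_gap", phi=0.0),
        Slab(thickness=10.0, roughness=3.0, label="head_in",
             dry_sld=PC_HEAD_SLD, phi=0.70),
        Slab(thickness=34.0, roughness=3.0, label="tails",
             sld=DPPC_D62_TAIL_SLD * (1 - solvation), phi=1.0),
        Slab(thickness=10.0, roughness=3.0, label="head_out",
             dry_sld=PC_HEAD_SLD, phi=0.70),
    ]


def build_paper_stacks(scenario: str, solvent: Solvent, rinsed: bool = False) -> LayerStack:
    """Named Si/SiO2/... stacks of the mucin thin-film study, with the
    fitted (or, where unpublished, assumed) values as defaults.

    Scenarios: ``bare_mucin`` (Si/SiO2/mucin 22 A, 60% occupancy),
    ``mucin_polymer`` (adds a highly hydrated 70 A polymer layer; with
    ``rinsed=True`` the polymer is flushed away and the mucin is altered
    to 20 A / 50% occupancy), ``dppc_membrane`` (deuterated-chain DPPC
    bilayer on a thin water gap), ``dppc_gm1_mucin`` (GM1-doped bilayer
    carrying a 30 A mucin cover, membrane solvent penetration raised to
    ~32%), ``dppc_gm1_mucin_polymer`` (the same plus the polymer layer).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")
    slabs: list[Slab] = [_sio2()]
    if scenario == "bare_mucin":
        slabs.append(_mucin())
    elif scenario == "mucin_polymer":
        if rinsed:
            slabs.append(_mucin(thickness=20.0, phi=0.50))
        else:
            m = _mucin()
            m.phi = 0.55  # polymer weakly destabilises the layer (~5% more solvent)
            slabs.extend([m, _polymer()])
    elif scenario == "dppc_membrane":
        slabs.extend(_bilayer())
    elif scenario == "dppc_gm1_mucin":
        slabs.extend(_bilayer(solvation=0.32))
        slabs.append(_mucin(thickness=30.0, phi=0.55))
    elif scenario == "dppc_gm1_mucin_polymer":
        slabs.extend(_bilayer(solvation=0.32))
        slabs.append(_mucin(thickness=30.0, phi=0.55))
        slabs.append(_polymer())
    return LayerStack(slabs=slabs, backing_solvent=solvent)
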