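"""Domain types, unit conventions, file I/O and scattering-length densities.

Conventions
-----------
* Momentum transfer ``q`` is carried in inverse Angstrom everywhere inside
  the package; readers accept nm^-1 and convert (1 nm^-1 = 0.1 A^-1).
* SLDs (scattering length densities) are in A^-2, lengths of layers in
  Angstrom, SAXS real-space lengths (radii of gyration, correlation
  lengths) in nm.
* A :class:`Solvent` is an H2O/D2O mixture described by its D2O mole
  fraction; labile (-OH/-NH) hydrogens of a :class:`Material` exchange
  with the solvent, so a material's SLD depends on the solvent it sits in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    ATOMIC_MASS,
    COHERENT_B_FM,
    D2O_DENSITY,
    FM_TO_A,
    H2O_DENSITY,
    N_A_PER_A3,
)

__all__ = [
    "ScatteringCurve",
    "Material",
    "Solvent",
    "FitResult",
    "parse_formula",
    "format_formula",
    "read_curve",
    "write_curve",
    "material_sld",
    "hydrated_layer_sld",
    "infer_dry_sld",
    "read_materials",
    "write_materials",
    "H2O",
    "D2O",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str | dict[str, float]) -> dict[str, float]:
    """Parse a Hill-style formula string (``"C6H12O6"``, ``"D2O"``) into an
    element -> count map.  H and D are distinct elements."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, float] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            el, n = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0.0) + (float(n) if n else 1.0)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    for el, n in counts.items():
        if el not in COHERENT_B_FM:
            raise ValueError(f"unknown element symbol {el!r} (no scattering length tabulated)")
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
    return counts


def format_formula(counts: dict[str, float]) -> str:
    def fmt(n: float) -> str:
        if n == 1:
            return ""
        return f"{n:g}"

    return "".join(f"{el}{fmt(n)}" for el, n in sorted(counts.items()))


@dataclass(frozen=True)
class Material:
    """A chemical species: formula, bulk mass density and the number of
    exchangeable (labile) hydrogens per formula unit."""

    name: str
    formula: dict[str, float]
    mass_density: float  # g/cm^3
    n_labile_h: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", parse_formula(self.formula))
        object.__setattr__(self, "mass_density", float(self.mass_density))
        object.__setattr__(self, "n_labile_h", float(self.n_labile_h))
        if self.mass_density <= 0:
            raise ValueError("mass_density must be > 0")
        if self.n_labile_h < 0 or self.n_labile_h > self.formula.get("H", 0.0):
            raise ValueError("n_labile_h must be between 0 and the H count")

    @property
    def molar_mass(self) -> float:
        return sum(n * ATOMIC_MASS[el] for el, n in self.formula.items())

    @property
    def number_density(self) -> float:
        """Formula units per A^3."""
        return self.mass_density * N_A_PER_A3 / self.molar_mass


@dataclass(frozen=True)
class Solvent:
    """H2O/D2O mixture; ``d_fraction`` is the D2O mole fraction."""

    d_fraction: float
    salt_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_fraction <= 1.0:
            raise ValueError("d_fraction must lie in [0, 1]")

    @property
    def sld(self) -> float:
        """Solvent SLD in A^-2, linear in the D2O fraction between the pure
        endpoints.  Salt is neglected (a 150 mM shift is below 1%)."""
        return (1.0 - self.d_fraction) * _H2O_SLD + self.d_fraction * _D2O_SLD


@dataclass
class FitResult:
    """Outcome of a bounded least-squares fit."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    chi2: float
    n_points: int
    converged: bool
    redchi: float | None = None
    per_dataset_chi2: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


def material_sld(
    material: Material,
    solvent: Solvent | None = None,
    exchange_efficiency: float = 0.9,
) -> float:
    """Neutron SLD of a material, rho = sum_j b_j n_j, in A^-2.

    Each labile hydrogen's scattering length is replaced by
    ``b_H + x*e*(b_D - b_H)`` where ``x`` is the solvent D2O fraction and
    ``e`` the exchange efficiency; in pure H2O the result is independent
    of ``e``.  The mass density (hence number density) is taken as that of
    the protiated formula: H/D substitution of a few labile sites changes
    the molar volume negligibly.
    """
    if not 0.0 <= exchange_efficiency <= 1.0:
        raise ValueError("exchange_efficiency must lie in [0, 1]")
    b_sum_fm = sum(n * COHERENT_B_FM[el] for el, n in material.formula.items())
    if material.n_labile_h and solvent is not None:
        shift = solvent.d_fraction * exchange_efficiency * (
            COHERENT_B_FM["D"] - COHERENT_B_FM["H"]
        )
        b_sum_fm += material.n_labile_h * shift
    return b_sum_fm * FM_TO_A * material.number_density


def hydrated_layer_sld(dry_sld: float, phi_material: float, solvent: Solvent) -> float:
    """Volume-weighted SLD of a layer that is ``phi_material`` material and
    ``1 - phi_material`` solvent."""
    if not 0.0 <= phi_material <= 1.0:
        raise ValueError("phi_material must lie in [0, 1]")
    return phi_material * dry_sld + (1.0 - phi_material) * solvent.sld


def infer_dry_sld(layer_sld: float, phi_material: float, solvent: Solvent) -> float:
    """Exact algebraic inverse of :func:`hydrated_layer_sld`."""
    if not 0.0 < phi_material <= 1.0:
        raise ValueError("phi_material must lie in (0, 1]")
    return (layer_sld - (1.0 - phi_material) * solvent.sld) / phi_material


# Reference solvent endpoint materials and SLDs.
WATER_H = Material("H2O", {"H": 2, "O": 1}, H2O_DENSITY, n_labile_h=0)
WATER_D = Material("D2O", {"D": 2, "O": 1}, D2O_DENSITY, n_labile_h=0)
_H2O_SLD = material_sld(WATER_H)
_D2O_SLD = material_sld(WATER_D)

H2O = Solvent(0.0)
D2O = Solvent(1.0)


# ---------------------------------------------------------------------------
# Reduced 1D scattering curves
# ---------------------------------------------------------------------------

@dataclass
class ScatteringCurve:
    """A reduced 1D pattern (q, I, sigma) for SAXS or reflectivity.

    ``q`` is stored in A^-1 and must be strictly increasing and positive;
    ``sigma`` may be None (unweighted downstream fits).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    kind: str = "saxs"  # {"saxs", "reflectivity"}
    absolute_units: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.kind not in ("saxs", "reflectivity"):
            raise ValueError("kind must be 'saxs' or 'reflectivity'")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity length differs from q length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma length differs from q length")
        if np.any(self.q <= 0):
            raise ValueError("q must be > 0")
        dq = np.diff(self.q)
        if np.any(dq <= 0):
            i = int(np.argmax(dq <= 0))
            raise ValueError(f"q must be strictly increasing (violated after point {i})")
        if self.kind == "reflectivity" and np.any(self.intensity < 0):
            raise ValueError("reflectivity must be >= 0")
        if self.sigma is not None and np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")

    def __len__(self) -> int:
        return self.q.size

    def select(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringCurve":
        """Sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not m.any():
            raise ValueError(f"no points in q window [{qmin}, {qmax}]")
        return replace(
            self,
            q=self.q[m],
            intensity=self.intensity[m],
            sigma=None if self.sigma is None else self.sigma[m],
        )


def read_curve(path, unit_hint: str = "A_inv", kind: str = "saxs") -> ScatteringCurve:
    """Read a 2- or 3-column ASCII curve (whitespace or comma delimited,
    ``#`` comments).  ``unit_hint`` is ``A_inv`` or ``nm_inv``; nm^-1 input
    is converted to the canonical A^-1."""
    if unit_hint not in ("A_inv", "nm_inv"):
        raise ValueError("unit_hint must be 'A_inv' or 'nm_inv'")
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            try:
                vals = [float(p) for p in parts if p]
            except ValueError:
                raise ValueError(f"{path}: non-numeric data on line {lineno}: {raw.strip()!r}")
            if len(vals) not in (2, 3):
                raise ValueError(f"{path}: expected 2 or 3 columns on line {lineno}")
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(f"{path}: inconsistent column count on line {lineno}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    q = arr[:, 0]
    if unit_hint == "nm_inv":
        q = q * 0.1
    dq = np.diff(q)
    if np.any(dq <= 0):
        i = int(np.argmax(dq <= 0)) + 2  # 1-based data row of the offender
        raise ValueError(f"{path}: q not strictly increasing at data row {i}")
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return ScatteringCurve(q=q, intensity=arr[:, 1], sigma=sigma, kind=kind)


def write_curve(curve: ScatteringCurve, path, header: str = "") -> None:
    """Write a curve as 3-column (or 2-column if sigma absent) ASCII, q in A^-1."""
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q(A^-1) intensity" + (" sigma\n" if curve.sigma is not None else "\n"))
        np.savetxt(fh, np.column_stack(cols), fmt="%.10g")


# ---------------------------------------------------------------------------
# Plain-text material/solvent config, bit-exact round trip
# ---------------------------------------------------------------------------

def write_materials(materials: list[Material], path) -> None:
    with open(path, "w") as fh:
        for m in materials:
            fh.write("[material]\n")
            fh.write(f"name: {m.name}\n")
            fh.write(f"formula: {format_formula(m.formula)}\n")
            fh.write(f"mass_density: {m.mass_density!r}\n")
            fh.write(f"n_labile_h: {m.n_labile_h!r}\n\n")


def read_materials(path) -> list[Material]:
    materials: list[Material] = []
    block: dict[str, str] = {}

    def flush() -> None:
        if block:
            materials.append(
                Material(
                    name=block["name"],
                    formula=block["formula"],
                    mass_density=float(block["mass_density"]),
                    n_labile_h=float(block["n_labile_h"]),
                )
            )
            block.clear()

    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line == "[material]":
                flush()
                continue
            key, _, val = line.partition(":")
            block[key.strip()] = val.strip()
    flush()
    return materials
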