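"""Quartz crystal microbalance with dissipation (QCM-D) analysis.

Parses multi-overtone frequency/dissipation time series, segments the
injection/rinse protocol into steps, and converts frequency shifts of a
rigid film into areal mass (Sauerbrey) and thickness.

The Sauerbrey relation Delta_m = -C * Delta_f / n holds for thin rigid
films; rigidity is judged from the dissipation shift (Delta_D below a
threshold, default 0.5e-6).  Soft films need viscoelastic modelling,
which is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import QUARTZ_DENSITY, QUARTZ_SHEAR_MODULUS

__all__ = [
    "QCMDTrace",
    "StepSummary",
    "SauerbreyResult",
    "dissipation_factor",
    "sauerbrey_constant",
    "sauerbrey_mass",
    "thickness_from_mass",
    "segment_trace",
    "rigidity_check",
    "read_qcmd_csv",
    "write_qcmd_csv",
    "SAUERBREY_C_5MHZ",
]

#: Mass-sensitivity constant of a 5 MHz AT-cut crystal, ng/(cm^2 Hz).
SAUERBREY_C_5MHZ = 17.7

DEFAULT_OVERTONES = (1, 3, 5, 7, 9, 11)


def dissipation_factor(f: float, tau0: float, include_pi: bool = False) -> float:
    """Dissipation factor from the ring-down decay time tau0 of the sensor.

    Default is D = 1/(f*tau0); ``include_pi`` selects the conventional
    D = 1/(pi*f*tau0).
    """
    if f <= 0 or tau0 <= 0:
        raise ValueError("f and tau0 must be > 0")
    d = 1.0 / (f * tau0)
    return d / np.pi if include_pi else d


def sauerbrey_constant(
    f0: float = 5e6,
    rho_q: float = QUARTZ_DENSITY,
    mu_q: float = QUARTZ_SHEAR_MODULUS,
) -> float:
    """Mass-sensitivity constant C = sqrt(rho_q * mu_q) / (2 f0^2) in
    ng/(cm^2 Hz); 17.7 for a 5 MHz AT-cut crystal."""
    if min(f0, rho_q, mu_q) <= 0:
        raise ValueError("f0, rho_q, mu_q must be > 0")
    c_si = np.sqrt(rho_q * mu_q) / (2.0 * f0**2)  # kg/(m^2 Hz)
    return c_si * 1e8  # -> ng/(cm^2 Hz)


def sauerbrey_mass(delta_f: float, n: int, c: float = SAUERBREY_C_5MHZ) -> float:
    """Areal mass Delta_m = -C * Delta_f / n in ng/cm^2 from the raw
    (non-normalised) frequency shift of odd overtone ``n``."""
    if n <= 0 or n % 2 == 0:
        raise ValueError("overtone n must be an odd positive integer")
    return -c * delta_f / n


def thickness_from_mass(delta_m: float, rho: float) -> float:
    """Film thickness d = Delta_m / rho, in Angstrom, from areal mass in
    ng/cm^2 and density in g/cm^3."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    # ng/cm^2 / (g/cm^3) = 1e-9 cm = 0.1 A
    return delta_m / rho * 0.1


@dataclass
class QCMDTrace:
    """Multi-overtone Delta_f / Delta_D time series.

    ``delta_f[n]`` and ``delta_d[n]`` are arrays over ``time`` for each odd
    overtone n.  ``normalized`` records whether delta_f is already divided
    by the overtone number.
    """

    time: np.ndarray  # s
    delta_f: dict[int, np.ndarray]  # Hz
    delta_d: dict[int, np.ndarray]  # x 1e-6
    f0: float = 5e6
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.delta_f:
            raise ValueError("at least one overtone required")
        for n in self.delta_f:
            if n <= 0 or n % 2 == 0:
                raise ValueError(f"overtone {n} is not an odd positive integer")
        self.delta_f = {n: np.asarray(v, dtype=float) for n, v in self.delta_f.items()}
        self.delta_d = {n: np.asarray(v, dtype=float) for n, v in self.delta_d.items()}

    @property
    def overtones(self) -> list[int]:
        return sorted(self.delta_f)

    def normalized_f(self, n: int) -> np.ndarray:
        """Delta_f / n regardless of the storage convention."""
        f = self.delta_f[n]
        return f if self.normalized else f / n


@dataclass
class StepSummary:
    label: str
    window: tuple[float, float]  # s
    delta_f_per_overtone: dict[int, float]  # raw Hz, step minus previous plateau
    delta_d_per_overtone: dict[int, float]  # x 1e-6
    harmonic_spread: float  # max-min of Delta_f/n across overtones, Hz
    plateau_f: dict[int, float] = field(default_factory=dict)  # absolute plateau, raw Hz


@dataclass
class SauerbreyResult:
    mass_areal: float  # ng/cm^2
    thickness: float  # A
    rigid_film_ok: bool


def segment_trace(
    trace: QCMDTrace,
    events: list[tuple[float, str]],
    plateau_fraction: float = 0.2,
) -> list[StepSummary]:
    """Split a trace at the event times and summarise each protocol step.

    Each step's plateau is the median of the trailing ``plateau_fraction``
    of its window (robust to the injection transient); per-overtone Delta
    values are differences between consecutive plateaus, with the first
    step (baseline) referenced to zero.
    """
    if not events:
        raise ValueError("at least one event required")
    times = [t for t, _ in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("event times must be strictly increasing")
    if times[0] < trace.time[0] or times[-1] >= trace.time[-1]:
        raise ValueError("events must lie within the trace time span")

    edges = times + [float(trace.time[-1])]
    summaries: list[StepSummary] = []
    prev_f = {n: 0.0 for n in trace.overtones}
    prev_d = {n: 0.0 for n in trace.overtones}
    for (t0, label), t1 in zip(events, edges[1:]):
        in_win = (trace.time >= t0) & (trace.time <= t1)
        idx = np.flatnonzero(in_win)
        frac = plateau_fraction
        tail = idx[int(np.floor(len(idx) * (1 - frac))):]
        if len(tail) < 5:  # widen for sparsely sampled windows
            tail = idx[-min(len(idx), 5):]
        plateau_f = {n: float(np.median(trace.delta_f[n][tail])) for n in trace.overtones}
        plateau_d = {n: float(np.median(trace.delta_d[n][tail])) for n in trace.overtones}
        raw = {
            n: (plateau_f[n] - prev_f[n]) * (n if trace.normalized else 1)
            for n in trace.overtones
        }
        dd = {n: plateau_d[n] - prev_d[n] for n in trace.overtones}
        norm = [raw[n] / n for n in trace.overtones]
        summaries.append(
            StepSummary(
                label=label,
                window=(float(t0), float(t1)),
                delta_f_per_overtone=raw,
                delta_d_per_overtone=dd,
                harmonic_spread=float(max(norm) - min(norm)),
                plateau_f={n: plateau_f[n] * (n if trace.normalized else 1) for n in trace.overtones},
            )
        )
        prev_f, prev_d = plateau_f, plateau_d
    return summaries


def rigidity_check(step: StepSummary, dd_threshold: float = 0.5) -> bool:
    """True if the film deposited in this step behaves rigidly: the largest
    dissipation shift across overtones stays at or below ``dd_threshold``
    (in units of 1e-6)."""
    if not step.delta_d_per_overtone:
        raise ValueError("step carries no dissipation data")
    return max(abs(v) for v in step.delta_d_per_overtone.values()) <= dd_threshold


def step_sauerbrey(
    step: StepSummary,
    rho: float = 1.05,
    c: float = SAUERBREY_C_5MHZ,
    overtone: int | None = None,
    dd_threshold: float = 0.5,
) -> SauerbreyResult:
    """Sauerbrey mass and thickness for one protocol step.

    Uses the requested overtone (default: the lowest available above the
    fundamental, n=3, the usual choice) and flags the result when the
    dissipation criterion rejects the rigid-film assumption.
    """
    ns = sorted(step.delta_f_per_overtone)
    if overtone is None:
        overtone = ns[1] if len(ns) > 1 and ns[0] == 1 else ns[0]
    mass = sauerbrey_mass(step.delta_f_per_overtone[overtone], overtone, c)
    return SauerbreyResult(
        mass_areal=mass,
        thickness=thickness_from_mass(mass, rho),
        rigid_film_ok=rigidity_check(step, dd_threshold),
    )


# ---------------------------------------------------------------------------
# CSV I/O: one time column + paired f{n}/D{n} columns per overtone
# ---------------------------------------------------------------------------

def read_qcmd_csv(path, f0: float = 5e6, normalized: bool = False) -> QCMDTrace:
    df = pd.read_csv(path, comment="#")
    tcol = df.columns[0]
    delta_f: dict[int, np.ndarray] = {}
    delta_d: dict[int, np.ndarray] = {}
    for col in df.columns[1:]:
        m = col.strip().lower()
        if m.startswith("f"):
            delta_f[int(m[1:])] = df[col].to_numpy(float)
        elif m.startswith("d"):
            delta_d[int(m[1:])] = df[col].to_numpy(float)
    return QCMDTrace(
        time=df[tcol].to_numpy(float),
        delta_f=delta_f,
        delta_d=delta_d,
        f0=f0,
        normalized=normalized,
    )


def write_qcmd_csv(trace: QCMDTrace, path) -> None:
    data = {"time": trace.time}
    for n in trace.overtones:
        data[f"f{n}"] = trace.delta_f[n]
        data[f"D{n}"] = trace.delta_d[n]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")
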