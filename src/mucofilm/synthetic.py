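"""Synthetic data generators for every pipeline stage.

These emulate the statistical structure of reduced beamline and
microbalance data -- not the instruments themselves -- so that each
analysis stage can be exercised and its parameter recovery scored
without access to raw data.  All generators are deterministic given
(parameters, seed) and embed both in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ScatteringCurve, Solvent
from .nr import (
    ContrastSeries,
    LayerStack,
    ResolutionSpec,
    abeles_reflectivity,
    build_paper_stacks,
    smear,
)
from .qcmd import DEFAULT_OVERTONES, QCMDTrace, SAUERBREY_C_5MHZ
from .saxs import DumbbellModel, debye_form_factor, dumbbell_intensity, mixture_model

__all__ = [
    "NoiseSpec",
    "SaxsDataset",
    "make_saxs_dataset",
    "make_nr_dataset",
    "make_qcmd_trace",
    "default_saxs_qgrid",
    "default_nr_qgrid",
]

#: Fractal exponent of the low-q cluster tail in the mixed mucin/polymer
#: system (surface-fractal clusters).
CLUSTER_EXPONENT = -3.7


@dataclass
class NoiseSpec:
    """Noise model: 'gaussian_relative' (sigma = level * I) or
    'poisson_counts' (level = mean counts at the first point)."""

    kind: str = "gaussian_relative"
    level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_relative", "poisson_counts", "none"):
            raise ValueError("kind must be gaussian_relative, poisson_counts or none")
        if self.kind != "none" and self.level <= 0:
            raise ValueError("level must be > 0")


def default_saxs_qgrid(n: int = 200) -> np.ndarray:
    """Log-spaced q covering 7e-3 to 6 nm^-1 (7e-4 to 0.6 A^-1)."""
    return np.logspace(np.log10(7e-4), np.log10(0.6), n)


def default_nr_qgrid(n: int = 90) -> np.ndarray:
    """Log-spaced q from 0.008 to 0.25 A^-1."""
    return np.logspace(np.log10(0.008), np.log10(0.25), n)


def _apply_noise(q: np.ndarray, intensity: np.ndarray, noise: NoiseSpec, rng: np.random.Generator,
                 kind: str = "saxs") -> ScatteringCurve:
    if noise.kind == "none":
        return ScatteringCurve(q, intensity, None, kind=kind)
    if noise.kind == "gaussian_relative":
        sigma = noise.level * np.abs(intensity)
        noisy = intensity + rng.normal(0.0, 1.0, intensity.shape) * sigma
    else:  # poisson_counts: counts scaled so the first point has `level` mean counts
        scale = noise.level / intensity[0]
        counts = rng.poisson(np.clip(intensity * scale, 0, None))
        noisy = counts / scale
        sigma = np.sqrt(np.clip(counts, 1, None)) / scale
    if kind == "reflectivity":
        noisy = np.clip(noisy, 0.0, None)
    return ScatteringCurve(q, noisy, sigma, kind=kind)


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

@dataclass
class SaxsDataset:
    """Component curves plus the additive and the clustered ('interacting')
    mixtures, with the generating truth recorded."""

    q: np.ndarray
    components: dict[str, ScatteringCurve]
    additive_mixture: ScatteringCurve
    interacting_mixture: ScatteringCurve
    truth: dict = field(default_factory=dict)


def make_saxs_dataset(
    rg_coil: float = 2.5,  # nm
    dumbbell: DumbbellModel | None = None,
    a: float = 1.0,
    coil_scale: float = 1.0,
    cluster_amplitude: float = 1e-9,
    qgrid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> SaxsDataset:
    """Synthetic bulk-SAXS experiment: a Gaussian-coil polymer (Rg 2.5 nm),
    a dumbbell-model mucin, their additive mixture I_PGM + A*I_polymer,
    and an 'interacting' mixture carrying an extra low-q cluster tail
    ~ q^-3.7 -- the diagnostic signature of phase-separated
    polymer/mucin clusters.
    """
    if coil_scale < 0 or cluster_amplitude < 0 or a < 0:
        raise ValueError("component weights must be >= 0")
    q = default_saxs_qgrid() if qgrid is None else np.asarray(qgrid, float)
    noise = noise or NoiseSpec()
    dumbbell = dumbbell or DumbbellModel()
    rng = np.random.default_rng(noise.seed)

    i_coil = coil_scale * debye_form_factor(q, rg_coil)
    i_pgm = dumbbell_intensity(q, dumbbell)
    i_add = mixture_model(i_pgm, i_coil, a)
    i_cluster = cluster_amplitude * q**CLUSTER_EXPONENT
    i_int = i_add + i_cluster

    curves = {
        "coil": _apply_noise(q, i_coil, noise, rng),
        "pgm": _apply_noise(q, i_pgm, noise, rng),
    }
    return SaxsDataset(
        q=q,
        components=curves,
        additive_mixture=_apply_noise(q, i_add, noise, rng),
        interacting_mixture=_apply_noise(q, i_int, noise, rng),
        truth={
            "rg_coil_nm": rg_coil,
            "a": a,
            "coil_scale": coil_scale,
            "cluster_amplitude": cluster_amplitude,
            "cluster_exponent": CLUSTER_EXPONENT,
            "dumbbell": dumbbell,
            "noise": noise,
        },
    )


# ---------------------------------------------------------------------------
# Neutron reflectometry
# ---------------------------------------------------------------------------

def _nr_sigma_rel(r: np.ndarray, floor: float = 0.01, ceil: float = 0.20) -> np.ndarray:
    """Relative uncertainty growing as R falls (counting statistics):
    1% at R = 1 rising logarithmically to a 20% ceiling."""
    with np.errstate(divide="ignore"):
        rel = floor + 0.02 * (-np.log10(np.clip(r, 1e-12, None)))
    return np.clip(rel, floor, ceil)


def make_nr_dataset(
    scenario: str,
    contrasts: dict[str, Solvent] | None = None,
    noise: NoiseSpec | None = None,
    res: ResolutionSpec | None = None,
    qgrid: np.ndarray | None = None,
    rinsed: bool = False,
    stack: LayerStack | None = None,
) -> ContrastSeries:
    """Forward-model a named scenario in each contrast, smear with the
    instrument resolution, and add noise.  The generating stack (the
    truth) is stored as the series' stack template, so recovery scoring
    never re-enters parameters by hand."""
    contrasts = contrasts or {"h2o": Solvent(0.0), "d2o": Solvent(1.0)}
    noise = noise or NoiseSpec(kind="gaussian_relative", level=1.0)
    res = res or ResolutionSpec()
    q = default_nr_qgrid() if qgrid is None else np.asarray(qgrid, float)
    rng = np.random.default_rng(noise.seed)

    first = next(iter(contrasts.values()))
    truth = stack if stack is not None else build_paper_stacks(scenario, first, rinsed=rinsed)

    datasets: dict[str, tuple[Solvent, ScatteringCurve]] = {}
    for name, solvent in contrasts.items():
        r = smear(abeles_reflectivity(truth, q, solvent), q, res)
        if noise.kind == "none":
            curve = ScatteringCurve(q, r, None, kind="reflectivity")
        else:
            rel = _nr_sigma_rel(r) * noise.level
            sigma = rel * r
            noisy = np.clip(r + rng.normal(0.0, 1.0, r.shape) * sigma, 0.0, None)
            curve = ScatteringCurve(q, noisy, sigma, kind="reflectivity")
        datasets[name] = (solvent, curve)
    return ContrastSeries(stack=truth, contrasts=datasets, resolution=res)


# ---------------------------------------------------------------------------
# QCM-D
# ---------------------------------------------------------------------------

#: The five-step deposition protocol used for mucin films: buffer
#: baseline, mucin adsorption (55 ng/cm^2, rigid), buffer rinse (stable),
#: polymer injection (delta f = -6 Hz), final rinse (partial desorption).
PAPER_QCMD_STEPS = [
    ("baseline", 0.0, 0.0),
    ("adsorb", -55.0 / SAUERBREY_C_5MHZ, 0.3),   # delta f/n from 55 ng/cm^2
    ("rinse1", 0.0, 0.0),
    ("polymer", -6.0, 0.4),
    ("rinse2", +2.0, -0.2),
]


def make_qcmd_trace(
    steps: list[tuple[str, float, float]] | None = None,
    duration: float = 900.0,
    dt: float = 1.0,
    overtones: tuple[int, ...] = DEFAULT_OVERTONES,
    tau: float = 30.0,
    noise_level: float = 0.02,
    drift: float = 0.0,  # Hz/h on delta f/n
    seed: int = 0,
    f0: float = 5e6,
) -> tuple[QCMDTrace, list[tuple[float, str]]]:
    """Staircase injection/rinse trace with exponential approach to each
    plateau.

    ``steps`` is a list of (label, delta f/n increment in Hz, delta D
    increment in 1e-6) applied at equal intervals; defaults to the mucin
    deposition protocol.  Returns the trace (raw, non-normalised delta f)
    and the event list consumed by ``segment_trace``.
    """
    steps = steps if steps is not None else PAPER_QCMD_STEPS
    rng = np.random.default_rng(seed)
    n_steps = len(steps)
    t = np.arange(0.0, duration * n_steps, dt)
    events = [(i * duration, label) for i, (label, _, _) in enumerate(steps)]

    fn = np.zeros_like(t)  # delta f / n, identical across overtones for a rigid film
    dd = np.zeros_like(t)
    for i, (_, df_step, dd_step) in enumerate(steps):
        t0 = i * duration
        rise = np.where(t >= t0, 1.0 - np.exp(-(t - t0) / tau), 0.0)
        fn = fn + df_step * rise
        dd = dd + dd_step * rise
    fn = fn + drift / 3600.0 * t

    delta_f: dict[int, np.ndarray] = {}
    delta_d: dict[int, np.ndarray] = {}
    for n in overtones:
        delta_f[n] = n * (fn + rng.normal(0.0, noise_level, t.shape))
        delta_d[n] = dd + rng.normal(0.0, noise_level, t.shape)
    trace = QCMDTrace(
        time=t,
        delta_f=delta_f,
        delta_d=delta_d,
        f0=f0,
        normalized=False,
        metadata={"steps": steps, "seed": seed, "tau": tau,
                  "noise_level": noise_level, "drift": drift},
    )
    return trace, events
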