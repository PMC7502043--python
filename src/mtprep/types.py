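"""Domain types for the two-pool MT-prepared sequence simulator.

The model describes two exchanging proton pools: a mobile "free" water pool A
(observable transverse magnetization) and a motion-restricted macromolecular
"bound" pool B whose transverse components decay too fast (T2 of order tens of
microseconds) to be tracked explicitly.  The bound pool is represented by its
longitudinal component only and is saturated by off-resonance RF through an
absorption-lineshape term.

Conventions
-----------
* Total equilibrium magnetization is 1: ``M0A = 1 - psr`` and ``M0B = psr``
  with ``psr = M0B / (M0A + M0B)`` the pool size ratio.
* All quantities are SI (seconds, Hz, rad/s) unless a name says otherwise.
* Angles in degrees carry a ``_deg`` suffix or a "degrees" note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueParameters",
    "RFPulse",
    "MTPreparation",
    "ImagingModule",
    "SimulationProtocol",
    "MagnetizationState",
    "MYOCARDIUM",
]


class ParameterError(ValueError):
    """Invalid physical or protocol parameter."""


@dataclass(frozen=True)
class TissueParameters:
    """Two-pool tissue constants.

    Parameters
    ----------
    t1_free, t2_free : float
        Longitudinal / transverse relaxation times of the free water pool,
        seconds.
    psr : float
        Pool size ratio ``M0B / (M0A + M0B)``, dimensionless in ``[0, 1)``.
    exchange_rate : float
        Fundamental exchange rate constant R (Hz); the free->bound and
        bound->free pseudo-first-order rates are ``R*M0B`` and ``R*M0A``.
    t1_bound : float
        Longitudinal relaxation time of the bound pool, seconds. Not
        measurable from MTR data; the conventional 1.0 s is the default.
    t2_bound : float
        Transverse relaxation time of the bound pool, seconds; enters only
        through the absorption lineshape. Default 14 microseconds.
    """

    t1_free: float
    t2_free: float
    psr: float
    exchange_rate: float
    t1_bound: float = 1.0
    t2_bound: float = 14e-6

    def __post_init__(self) -> None:
        for name in ("t1_free", "t2_free", "t1_bound", "t2_bound"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.psr < 1.0:
            raise ParameterError("psr must be in [0, 1)")
        if self.exchange_rate < 0:
            raise ParameterError("exchange_rate must be >= 0")

    @property
    def m0_free(self) -> float:
        return 1.0 - self.psr

    @property
    def m0_bound(self) -> float:
        return self.psr

    def astuple(self) -> tuple:
        return (
            self.t1_free,
            self.t2_free,
            self.psr,
            self.exchange_rate,
            self.t1_bound,
            self.t2_bound,
        )

    def replace(self, **kw) -> "TissueParameters":
        return replace(self, **kw)


#: Myocardium-like tissue used throughout the simulation studies:
#: T1/T2 = 1100/55 ms, PSR 15 %, exchange rate 50 Hz, bound-pool T2 14 us.
MYOCARDIUM = TissueParameters(
    t1_free=1.1, t2_free=0.055, psr=0.15, exchange_rate=50.0
)


@dataclass(frozen=True)
class RFPulse:
    """Sampled RF pulse.

    ``samples`` holds the complex RF amplitude omega1(t) in rad/s at a uniform
    step ``dt``; the carrier offset (``offset_hz``) is metadata only --
    off-resonance precession is applied by the propagator, not baked into the
    samples.
    """

    samples: np.ndarray
    dt: float
    flip_deg: float
    duration: float
    bandwidth: float
    shape: str = "sinc"
    offset_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.dt > 100e-6:
            raise ParameterError("RF sample step dt must be <= 100 us")
        object.__setattr__(
            self, "samples", np.ascontiguousarray(self.samples, dtype=complex)
        )
        integral = float(np.sum(np.abs(self.samples)) * self.dt)
        nominal = np.deg2rad(self.flip_deg)
        if nominal == 0.0:
            if integral > 1e-12:
                raise ParameterError("zero-flip pulse must have zero samples")
        elif abs(integral - nominal) > 1e-6 * abs(nominal):
            raise ParameterError(
                f"pulse area {integral:.8g} rad does not match nominal flip "
                f"{nominal:.8g} rad"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def with_offset(self, offset_hz: float) -> "RFPulse":
        return replace(self, offset_hz=offset_hz)

    def with_flip(self, flip_deg: float) -> "RFPulse":
        """Rescale the waveform linearly to a new nominal flip angle."""
        if self.flip_deg == 0.0:
            raise ParameterError("cannot rescale a zero-flip pulse")
        scale = flip_deg / self.flip_deg
        return replace(self, samples=self.samples * scale, flip_deg=flip_deg)

    def cache_key(self) -> tuple:
        return (
            hash(self.samples.tobytes()),
            self.dt,
            round(self.offset_hz, 9),
        )


@dataclass(frozen=True)
class MTPreparation:
    """Off-resonance saturation train: ``n_pulses`` copies of ``pulse``
    separated by ``gap`` seconds; when ``spoil_in_gap`` the transverse free
    pool is zeroed at the end of each gap (3D spoiler gradients)."""

    pulse: RFPulse
    n_pulses: int = 20
    gap: float = 1.5e-3
    spoil_in_gap: bool = True

    def __post_init__(self) -> None:
        if self.n_pulses < 0:
            raise ParameterError("n_pulses must be >= 0")
        if self.gap < 0:
            raise ParameterError("gap must be >= 0")

    @property
    def duration(self) -> float:
        if self.n_pulses == 0:
            return 0.0
        return self.n_pulses * (self.pulse.duration + self.gap)


@dataclass(frozen=True)
class ImagingModule:
    """Cardiac-gated readout train played each heartbeat.

    variant "spgr": ideal spoiling of the free-pool transverse magnetization
    at the end of every TR.  variant "bssfp": balanced, no spoiling, RF phase
    alternated by ``rf_phase_cycling`` degrees per TR, optional linear
    flip-angle ramp over the start-up pulses.
    """

    variant: str
    tr: float
    te: float
    flip_deg: float
    n_startup: int = 14
    echo_index: int = 15
    profiles_per_beat: int = 30
    startup_ramp: bool = True
    rf_phase_cycling: float = 180.0

    def __post_init__(self) -> None:
        if self.variant not in ("spgr", "bssfp"):
            raise ParameterError("variant must be 'spgr' or 'bssfp'")
        if self.tr <= 0 or self.te <= 0 or self.te >= self.tr:
            raise ParameterError("need 0 < TE < TR")
        if self.echo_index < 1 or self.echo_index > self.n_startup + self.profiles_per_beat:
            raise ParameterError(
                "echo_index must lie within the start-up + profile train"
            )

    @property
    def n_pulses(self) -> int:
        return self.n_startup + self.profiles_per_beat

    @property
    def duration(self) -> float:
        return self.n_pulses * self.tr


@dataclass(frozen=True)
class SimulationProtocol:
    """Cardiac timing of the simulation: constant heart rate, number of
    simulated heartbeats, global B0 offset, and the heartbeat whose echo is
    reported (pseudo steady state)."""

    heart_rate: float = 65.0
    n_heartbeats: int = 5
    b0_offset: float = 0.0
    measure_beat: int = 5

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be > 0")
        if not 1 <= self.measure_beat <= self.n_heartbeats:
            raise ParameterError("measure_beat must be within n_heartbeats")

    @property
    def rr(self) -> float:
        """Heartbeat period in seconds."""
        return 60.0 / self.heart_rate


@dataclass
class MagnetizationState:
    """4-component magnetization state (fractions of total equilibrium)."""

    mx_free: float = 0.0
    my_free: float = 0.0
    mz_free: float = 1.0
    mz_bound: float = 0.0

    @classmethod
    def equilibrium(cls, tissue: TissueParameters) -> "MagnetizationState":
        return cls(0.0, 0.0, tissue.m0_free, tissue.m0_bound)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MagnetizationState":
        return cls(float(v[0]), float(v[1]), float(v[2]), float(v[3]))

    def to_vector(self) -> np.ndarray:
        """Augmented 5-vector [MxA, MyA, MzA, MzB, 1]."""
        return np.array(
            [self.mx_free, self.my_free, self.mz_free, self.mz_bound, 1.0]
        )

    @property
    def mxy_free(self) -> complex:
        return self.mx_free + 1j * self.my_free

    def is_finite(self) -> bool:
        return bool(
            np.all(
                np.isfinite(
                    [self.mx_free, self.my_free, self.mz_free, self.mz_bound]
                )
            )
        )
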