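"""RF pulse construction."""

from __future__ import annotations

import numpy as np

from .types import ParameterError, RFPulse

__all__ = ["make_sinc_pulse"]


def make_sinc_pulse(
    flip_deg: float,
    duration: float,
    bandwidth: float,
    dt: float = 50e-6,
    offset_hz: float = 0.0,
) -> RFPulse:
    """Hann-apodized symmetric sinc pulse.

    The time-bandwidth product is ``duration * bandwidth`` and the waveform is
    scaled so that the integral of |omega1| over the pulse equals the nominal
    flip angle in radians.  The carrier offset is stored as metadata; the
    propagator applies the corresponding precession.

    Parameters
    ----------
    flip_deg : float
        Nominal flip angle, degrees (>= 0; 0 gives an all-zero waveform).
    duration : float
        Pulse length, seconds.
    bandwidth : float
        Pulse bandwidth, Hz.
    dt : float
        Sample step, seconds (<= 100 us).
    offset_hz : float
        Carrier offset from water resonance, Hz.
    """
    if duration <= 0 or bandwidth <= 0 or dt <= 0:
        raise ParameterError("duration, bandwidth and dt must be > 0")
    if dt > 100e-6:
        raise ParameterError("dt must be <= 100 us")
    n = max(1, int(round(duration / dt)))
    dt_eff = duration / n
    t = (np.arange(n) + 0.5) * dt_eff - duration / 2.0
    wave = np.sinc(bandwidth * t)  # np.sinc(x) = sin(pi x)/(pi x)
    wave *= 0.5 * (1.0 + np.cos(2.0 * np.pi * t / duration))  # Hann window
    flip_rad = np.deg2rad(flip_deg)
    area = np.sum(np.abs(wave)) * dt_eff
    samples = np.zeros(n, dtype=complex) if flip_rad == 0 else wave * (flip_rad / area)
    return RFPulse(
        samples=samples,
        dt=dt_eff,
        flip_deg=flip_deg,
        duration=duration,
        bandwidth=bandwidth,
        shape="sinc",
        offset_hz=offset_hz,
    )
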