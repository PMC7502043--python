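"""Plain-text run configuration.

INI-style ``key = value`` files with one section per protocol block; all
values SI (seconds, Hz, fractions) -- display units such as ms or percent
appear only in output tables.  Any omitted key falls back to the documented
study default.

Example::

    [tissue]
    t1_free = 1.1
    t2_free = 0.055
    psr = 0.15
    exchange_rate = 50

    [prep]
    flip_deg = 800
    offset_hz = 3000
    n_pulses = 20

    [imaging]
    variant = spgr

    [protocol]
    heart_rate = 65
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

from .phantom import AcquisitionSpec, MotionModel
from .pulses import make_sinc_pulse
from .types import (
    ImagingModule,
    MTPreparation,
    SimulationProtocol,
    TissueParameters,
)

__all__ = ["RunConfig", "load_config", "default_imaging"]

_IMAGING_DEFAULTS = {
    "spgr": dict(variant="spgr", tr=3.8e-3, te=1.6e-3, flip_deg=15.0),
    "bssfp": dict(variant="bssfp", tr=3.2e-3, te=1.4e-3, flip_deg=70.0),
}


def default_imaging(variant: str = "spgr", **overrides) -> ImagingModule:
    kw = dict(_IMAGING_DEFAULTS[variant])
    kw.update(overrides)
    return ImagingModule(**kw)


@dataclass
class RunConfig:
    tissue: TissueParameters
    prep: MTPreparation
    imaging: ImagingModule
    protocol: SimulationProtocol
    acquisition: AcquisitionSpec
    motion: MotionModel
    seed: int = 1234
    smoothing_kernel: int = 5
    smoothing_sigma: float = 3.0
    mtr_floor: float = 0.05

    @classmethod
    def defaults(cls, variant: str = "spgr", seed: int = 1234) -> "RunConfig":
        pulse = make_sinc_pulse(800.0, 20.48e-3, 270.0, 50e-6, 3000.0)
        return cls(
            tissue=TissueParameters(1.1, 0.055, 0.15, 50.0),
            prep=MTPreparation(pulse=pulse),
            imaging=default_imaging(variant),
            protocol=SimulationProtocol(),
            acquisition=AcquisitionSpec(seed=seed),
            motion=MotionModel(seed=seed),
            seed=seed,
        )


def _get(cp, section, key, cast, default):
    if cp.has_option(section, key):
        raw = cp.get(section, key)
        if cast is bool:
            return raw.strip().lower() in ("1", "true", "yes", "on")
        return cast(raw)
    return default


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an INI file (all keys optional)."""
    cp = configparser.ConfigParser()
    if path is not None:
        with open(path) as f:
            cp.read_file(f)
    if overrides:
        cp.read_dict(overrides)

    seed = _get(cp, "run", "seed", int, 1234)
    tissue = TissueParameters(
        t1_free=_get(cp, "tissue", "t1_free", float, 1.1),
        t2_free=_get(cp, "tissue", "t2_free", float, 0.055),
        psr=_get(cp, "tissue", "psr", float, 0.15),
        exchange_rate=_get(cp, "tissue", "exchange_rate", float, 50.0),
        t1_bound=_get(cp, "tissue", "t1_bound", float, 1.0),
        t2_bound=_get(cp, "tissue", "t2_bound", float, 14e-6),
    )
    pulse = make_sinc_pulse(
        flip_deg=_get(cp, "prep", "flip_deg", float, 800.0),
        duration=_get(cp, "prep", "duration", float, 20.48e-3),
        bandwidth=_get(cp, "prep", "bandwidth", float, 270.0),
        dt=_get(cp, "prep", "dt", float, 50e-6),
        offset_hz=_get(cp, "prep", "offset_hz", float, 3000.0),
    )
    prep = MTPreparation(
        pulse=pulse,
        n_pulses=_get(cp, "prep", "n_pulses", int, 20),
        gap=_get(cp, "prep", "gap", float, 1.5e-3),
        spoil_in_gap=_get(cp, "prep", "spoil_in_gap", bool, True),
    )
    variant = _get(cp, "imaging", "variant", str, "spgr")
    imaging = default_imaging(
        variant,
        tr=_get(cp, "imaging", "tr", float, _IMAGING_DEFAULTS[variant]["tr"]),
        te=_get(cp, "imaging", "te", float, _IMAGING_DEFAULTS[variant]["te"]),
        flip_deg=_get(
            cp, "imaging", "flip_deg", float, _IMAGING_DEFAULTS[variant]["flip_deg"]
        ),
        n_startup=_get(cp, "imaging", "n_startup", int, 14),
        echo_index=_get(cp, "imaging", "echo_index", int, 15),
        profiles_per_beat=_get(cp, "imaging", "profiles_per_beat", int, 30),
        startup_ramp=_get(cp, "imaging", "startup_ramp", bool, True),
    )
    protocol = SimulationProtocol(
        heart_rate=_get(cp, "protocol", "heart_rate", float, 65.0),
        n_heartbeats=_get(cp, "protocol", "n_heartbeats", int, 5),
        b0_offset=_get(cp, "protocol", "b0_offset", float, 0.0),
        measure_beat=_get(cp, "protocol", "measure_beat", int, 5),
    )
    acquisition = AcquisitionSpec(
        profiles_per_beat=_get(cp, "acquisition", "profiles_per_beat", int, 30),
        ordering=_get(cp, "acquisition", "ordering", str, "spiral"),
        n_coils=_get(cp, "acquisition", "n_coils", int, 4),
        noise_sd=_get(cp, "acquisition", "noise_sd", float, 0.0),
        heart_rate=protocol.heart_rate,
        seed=seed,
    )
    motion = MotionModel(
        period=_get(cp, "motion", "period", float, 4.0),
        amplitude_fh=_get(cp, "motion", "amplitude_fh", float, 8.0),
        amplitude_lr=_get(cp, "motion", "amplitude_lr", float, 2.0),
        drift=_get(cp, "motion", "drift", float, 0.0),
        nonrigid_amplitude=_get(cp, "motion", "nonrigid_amplitude", float, 0.0),
        nonrigid_scale=_get(cp, "motion", "nonrigid_scale", float, 60.0),
        seed=seed,
    )
    return RunConfig(
        tissue=tissue,
        prep=prep,
        imaging=imaging,
        protocol=protocol,
        acquisition=acquisition,
        motion=motion,
        seed=seed,
        smoothing_kernel=_get(cp, "analysis", "smoothing_kernel", int, 5),
        smoothing_sigma=_get(cp, "analysis", "smoothing_sigma", float, 3.0),
        mtr_floor=_get(cp, "analysis", "mtr_floor", float, 0.05),
    )
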