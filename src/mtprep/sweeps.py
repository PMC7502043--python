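"""Parameter sweeps of the simulated MTR sequence.

A sweep runs one MT/REF simulation pair per value of a single axis and
tabulates the resulting signals and MTR.  The reference acquisition is only
recomputed when the swept axis affects it (the MT-pulse offset and flip angle
do not; tissue and B0 changes do).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bloch import compute_mtr, simulate_sequence
from .types import (
    ImagingModule,
    MTPreparation,
    ParameterError,
    SimulationProtocol,
    TissueParameters,
)

__all__ = ["sweep", "SweepResult", "SWEEP_AXES"]

#: Swept-axis name -> display units.
SWEEP_AXES = {
    "delta_f": "Hz",
    "mt_flip": "deg",
    "b0": "Hz",
    "T1_free": "s",
    "T2_free": "s",
    "exchange_rate": "Hz",
    "psr": "fraction",
}

_TISSUE_FIELD = {
    "T1_free": "t1_free",
    "T2_free": "t2_free",
    "exchange_rate": "exchange_rate",
    "psr": "psr",
}

# Axes that leave the no-preparation acquisition unchanged.
_MT_ONLY_AXES = {"delta_f", "mt_flip"}


@dataclass
class SweepResult:
    axis: str
    units: str
    table: pd.DataFrame  # columns: value, signal_mt, signal_ref, mtr_percent

    def to_csv(self, path, **kw) -> None:
        self.table.to_csv(path, index=False, **kw)


def _apply_axis(
    tissue: TissueParameters,
    prep: MTPreparation,
    protocol: SimulationProtocol,
    axis: str,
    value: float,
):
    if axis == "delta_f":
        prep = replace(prep, pulse=prep.pulse.with_offset(value))
    elif axis == "mt_flip":
        prep = replace(prep, pulse=prep.pulse.with_flip(value))
    elif axis == "b0":
        protocol = replace(protocol, b0_offset=value)
    elif axis in _TISSUE_FIELD:
        tissue = tissue.replace(**{_TISSUE_FIELD[axis]: value})
    else:
        raise ParameterError(f"unknown sweep axis {axis!r}")
    return tissue, prep, protocol


def sweep(
    tissue: TissueParameters,
    prep: MTPreparation,
    imaging: ImagingModule,
    protocol: SimulationProtocol,
    axis: str,
    values,
) -> SweepResult:
    """Simulate the MT/REF pair across ``values`` of ``axis``.

    Returns a :class:`SweepResult` whose table has one row per value with the
    MT signal, the reference signal and the MTR in percent.
    """
    if axis not in SWEEP_AXES:
        raise ParameterError(f"unknown sweep axis {axis!r}")
    values = np.asarray(values, dtype=float)
    rows = []
    ref_cached: float | None = None
    for v in values:
        t_i, p_i, proto_i = _apply_axis(tissue, prep, protocol, axis, float(v))
        s_mt = simulate_sequence(t_i, p_i, imaging, proto_i)
        if axis in _MT_ONLY_AXES:
            if ref_cached is None:
                ref_cached = simulate_sequence(t_i, None, imaging, proto_i)
            s_ref = ref_cached
        else:
            s_ref = simulate_sequence(t_i, None, imaging, proto_i)
        rows.append((float(v), s_mt, s_ref, compute_mtr(s_mt, s_ref)))
    table = pd.DataFrame(
        rows, columns=["value", "signal_mt", "signal_ref", "mtr_percent"]
    )
    return SweepResult(axis=axis, units=SWEEP_AXES[axis], table=table)
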