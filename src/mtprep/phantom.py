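"""Digital phantoms and synthetic MT-prepared acquisitions.

Two phantoms are provided: a vial phantom emulating agar samples of graded
concentration (the classic MT calibration object -- higher agar concentration
means a larger macromolecular pool and thus higher MTR) and a short-axis
cardiac phantom with an LV annulus, blood pool, an infarct sector of reduced
bound-pool fraction, two cardiac veins with exported centerlines, and
lung/liver/pectoral blocks.

``simulate_acquisition`` turns a phantom into segmented Cartesian k-space:
per-voxel steady-state signals from the Bloch module (cached per unique
tissue), a per-heartbeat respiratory warp, analytic coil sensitivities, FFT
sampling on a spiral-profile Cartesian trajectory, and complex Gaussian
noise.  The exact displacement trace and motion fields are emitted as ground
truth for the reconstruction chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .bloch import simulate_sequence
from .recon import (
    CartesianKSpace,
    DisplacementTrace,
    MotionFieldSet,
    RespiratoryBins,
    fft3c,
)
from .types import (
    ImagingModule,
    MTPreparation,
    ParameterError,
    SimulationProtocol,
    TissueParameters,
)

__all__ = [
    "DigitalPhantom",
    "MotionModel",
    "AcquisitionSpec",
    "SimulatedAcquisition",
    "make_agar_phantom",
    "make_cardiac_phantom",
    "spiral_profile_ordering",
    "simulate_acquisition",
    "analytic_coils",
    "ground_truth_bin_fields",
    "CARDIAC_LABELS",
]

GOLDEN_ANGLE_DEG = 137.50776405003785

#: label ids of the cardiac phantom
CARDIAC_LABELS = {
    "background": 0,
    "myocardium": 1,
    "scar": 2,
    "blood": 3,
    "vein": 4,
    "lungs": 5,
    "liver": 6,
    "pectoral": 7,
}


@dataclass
class DigitalPhantom:
    """Voxelized tissue-parameter phantom with ground-truth labels."""

    labels: np.ndarray  # int volume
    label_names: dict  # name -> id
    tissues: dict  # id -> TissueParameters (background omitted)
    density: np.ndarray  # relative proton density per voxel
    voxel_size: tuple  # mm
    centerlines: dict = field(default_factory=dict)  # name -> (n, 3) voxels

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_names[name]

    def signal_volume(self, signal_by_label: dict) -> np.ndarray:
        """Map per-label signals onto the grid, weighted by proton density."""
        out = np.zeros(self.shape, dtype=float)
        for lab, sig in signal_by_label.items():
            out[self.labels == lab] = sig
        return out * self.density


@dataclass
class MotionModel:
    """Respiratory motion: sinusoidal translation plus an optional smooth
    non-rigid modulation (a spatially varying gain on the translation field,
    which keeps the deformation Jacobian positive for modest amplitudes)."""

    period: float = 4.0  # s
    amplitude_fh: float = 8.0  # mm
    amplitude_lr: float = 2.0  # mm
    drift: float = 0.0  # mm/min, FH
    nonrigid_amplitude: float = 0.0  # mm, extra FH spatial modulation
    nonrigid_scale: float = 60.0  # mm, spatial wavelength of the modulation
    seed: int = 1234

    def __post_init__(self) -> None:
        if min(self.amplitude_fh, self.amplitude_lr, self.nonrigid_amplitude) < 0:
            raise ParameterError("motion amplitudes must be >= 0")

    def phase(self, t: float) -> float:
        """Respiratory phase in [0, 1]; 0 = end-expiration."""
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / self.period))

    def translation(self, t: float) -> tuple[float, float]:
        s = self.phase(t)
        drift = self.drift * t / 60.0
        return self.amplitude_lr * s, self.amplitude_fh * s + drift

    def field(self, t: float, shape, voxel_size) -> np.ndarray:
        """Dense displacement field (3, nx, ny, nz) in mm at time t."""
        d_lr, d_fh = self.translation(t)
        nx, ny, nz = shape
        f = np.zeros((3,) + tuple(shape))
        f[0] = d_lr
        f[1] = d_fh
        if self.nonrigid_amplitude > 0:
            x = np.arange(nx) * voxel_size[0]
            y = np.arange(ny) * voxel_size[1]
            mod = np.sin(2 * np.pi * x[:, None] / self.nonrigid_scale) * np.cos(
                2 * np.pi * y[None, :] / self.nonrigid_scale
            )
            f[1] += (
                self.phase(t) * self.nonrigid_amplitude * mod[:, :, None]
            )
        return f


@dataclass
class AcquisitionSpec:
    """Sampling and hardware parameters of the synthetic acquisition."""

    profiles_per_beat: int = 30
    ordering: str = "spiral"  # spiral | linear | full
    n_coils: int = 4
    noise_sd: float = 0.0
    heart_rate: float = 65.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.ordering not in ("spiral", "linear", "full"):
            raise ParameterError("ordering must be spiral, linear or full")


@dataclass
class SimulatedAcquisition:
    kspace: CartesianKSpace
    trace: DisplacementTrace
    beat_times: np.ndarray
    motion: MotionModel
    coils: np.ndarray
    truth_mt: np.ndarray | None  # noise-free static signal volume
    signal_by_label: dict


# ---------------------------------------------------------------------------
# phantom construction


def _default_agar_tissue(concentration: float) -> TissueParameters:
    """Documented heuristic mapping agar % (w/w) to two-pool parameters:
    psr = 0.012 * c, T2 shortening with concentration, T1 ~ 2.5 s, R = 50 Hz."""
    return TissueParameters(
        t1_free=2.5,
        t2_free=0.2 / (1.0 + 0.6 * concentration),
        psr=0.012 * concentration,
        exchange_rate=50.0,
    )


def make_agar_phantom(
    concentrations=(1.0, 2.0, 2.5, 5.0),
    shape=(64, 64, 8),
    voxel_size=(2.0, 2.0, 4.0),
    vial_radius_vox: float = 6.0,
    tissue_map=None,
) -> DigitalPhantom:
    """Cylindrical agar vials of the given concentrations on a circle.

    ``tissue_map`` overrides the concentration->TissueParameters heuristic.
    """
    conc = list(concentrations)
    if any(c <= 0 or c > 10 for c in conc):
        raise ParameterError("concentrations must lie in (0, 10] percent")
    tissue_map = tissue_map or _default_agar_tissue
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ring = min(nx, ny) / 2.0 - vial_radius_vox - 2.0
    n = len(conc)
    if n > 1 and ring * np.sin(np.pi / n) < vial_radius_vox + 1:
        raise ParameterError("vials would overlap at the requested radius")
    labels = np.zeros(shape, dtype=np.int8)
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    tissues = {}
    for i, c in enumerate(conc):
        ang = 2.0 * np.pi * i / max(n, 1)
        vx, vy = cx + ring * np.cos(ang), cy + ring * np.sin(ang)
        disk = (xg - vx) ** 2 + (yg - vy) ** 2 <= vial_radius_vox**2
        labels[disk] = i + 1
        tissues[i + 1] = tissue_map(c)
    density = (labels > 0).astype(float)
    names = {"background": 0}
    names.update({f"vial_{c:g}pct": i + 1 for i, c in enumerate(conc)})
    return DigitalPhantom(labels, names, tissues, density, tuple(voxel_size))


#: default tissue parameters of the cardiac phantom compartments
_CARDIAC_TISSUES = {
    "myocardium": TissueParameters(1.1, 0.055, 0.15, 50.0),
    "blood": TissueParameters(1.55, 0.25, 0.03, 30.0),
    "vein": TissueParameters(1.55, 0.15, 0.03, 30.0),
    "lungs": TissueParameters(1.2, 0.03, 0.10, 50.0),
    "liver": TissueParameters(0.58, 0.046, 0.11, 50.0),
    "pectoral": TissueParameters(1.0, 0.035, 0.17, 50.0),
}
_DENSITY = {"lungs": 0.2}


def make_cardiac_phantom(
    shape=(96, 96, 12),
    voxel_size=(1.5, 1.5, 4.0),
    r_outer_vox: float | None = None,
    r_inner_vox: float | None = None,
    scar_sector=(0.0, 90.0),
    psr_remote: float = 0.15,
    psr_scar: float = 0.08,
    tissues=None,
) -> DigitalPhantom:
    """Short-axis cardiac phantom with an infarct sector and cardiac veins.

    The scar sector (degrees, counterclockwise in the index plane) carries
    ``psr_scar`` < ``psr_remote``; two tubular veins run through the slab
    just outside the annulus and their centerlines are exported.
    """
    lo, hi = scar_sector
    if not (0 <= lo < 360 and 0 < hi <= 360 and lo < hi):
        raise ParameterError("scar sector must lie within [0, 360)")
    if psr_scar >= psr_remote:
        raise ParameterError("psr_scar must be < psr_remote")
    tissues = dict(_CARDIAC_TISSUES, **(tissues or {}))
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    if r_outer_vox is None:
        r_outer_vox = min(nx, ny) / 4.0
    if r_inner_vox is None:
        r_inner_vox = 0.625 * r_outer_vox
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = (xg - cx) ** 2 + (yg - cy) ** 2
    annulus = (r2 <= r_outer_vox**2) & (r2 >= r_inner_vox**2)
    blood = r2 < r_inner_vox**2
    theta = np.mod(np.degrees(np.arctan2(yg - cy, xg - cx)), 360.0)
    sector = (theta >= lo) & (theta < hi)

    labels = np.zeros(shape, dtype=np.int8)
    L = CARDIAC_LABELS
    labels[annulus & ~sector] = L["myocardium"]
    labels[annulus & sector] = L["scar"]
    labels[blood] = L["blood"]

    # two veins: straight tubes along z just outside the annulus, with a
    # gentle in-plane wiggle so their centerlines are genuinely 3D
    centerlines = {}
    vein_r = 1.4
    for name, base_ang in (("gcv", 135.0), ("pcv", 250.0)):
        pts = []
        rad = min(r_outer_vox + 3.5, min(cx, cy) - vein_r - 1.0)
        for z in range(nz):
            ang = np.radians(base_ang + 4.0 * np.sin(2 * np.pi * z / max(nz, 1)))
            px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            pts.append((px, py, z))
            tube = (xg - px) ** 2 + (yg - py) ** 2 <= vein_r**2
            labels[:, :, z][tube & (labels[:, :, z] == 0)] = L["vein"]
        centerlines[name] = np.asarray(pts)

    # static torso blocks in free corners
    labels[2 : nx // 5, 2 : ny // 3][labels[2 : nx // 5, 2 : ny // 3] == 0] = L["lungs"]
    labels[-nx // 5 :, 2 : ny // 3][labels[-nx // 5 :, 2 : ny // 3] == 0] = L["liver"]
    labels[2 : nx // 5, -ny // 4 :][labels[2 : nx // 5, -ny // 4 :] == 0] = L["pectoral"]

    tis = {
        L["myocardium"]: tissues["myocardium"].replace(psr=psr_remote),
        L["scar"]: tissues["myocardium"].replace(psr=psr_scar),
        L["blood"]: tissues["blood"],
        L["vein"]: tissues["vein"],
        L["lungs"]: tissues["lungs"],
        L["liver"]: tissues["liver"],
        L["pectoral"]: tissues["pectoral"],
    }
    density = np.zeros(shape)
    for name, lab in L.items():
        if name == "background":
            continue
        density[labels == lab] = _DENSITY.get(name, 1.0)
    return DigitalPhantom(
        labels, dict(L), tis, density, tuple(voxel_size), centerlines
    )


# ---------------------------------------------------------------------------
# trajectory and coils


def spiral_profile_ordering(
    matrix: tuple,
    profiles_per_beat: int,
    n_beats: int,
    seed: int = 1234,
    full: bool = False,
) -> np.ndarray:
    """Per-beat phase-encode orderings on the (line, partition) plane.

    Points are taken centre-out along an Archimedean-spiral-like ordering
    (radius-major, angle relative to a per-beat golden-angle-rotated ray) so
    that every beat samples the k-space centre region first and the DC point
    falls in the first beat.  With ``full=True`` the beats partition the whole
    grid exactly once.  Deterministic given ``seed``.

    Returns int array (n_beats, profiles_per_beat, 2).
    """
    nx, ny = matrix
    total = nx * ny
    if full and profiles_per_beat * n_beats != total:
        raise ParameterError(
            "full sampling requires profiles_per_beat * n_beats == grid size"
        )
    if profiles_per_beat * n_beats > total and full:
        raise ParameterError("oversubscribed full-sampling trajectory")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 360.0)
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx, dy = xg - nx // 2, yg - ny // 2
    rad = np.hypot(dx, dy).ravel()
    ang = np.degrees(np.arctan2(dy, dx)).ravel()
    flat = np.stack([xg.ravel(), yg.ravel()], axis=1)
    if full:
        taken = np.zeros(total, dtype=bool)
        out = np.empty((n_beats, profiles_per_beat, 2), dtype=int)
        for b in range(n_beats):
            rel = np.mod(ang - theta0 - b * GOLDEN_ANGLE_DEG, 360.0)
            order = np.lexsort((rel, rad))
            order = order[~taken[order]][:profiles_per_beat]
            taken[order] = True
            out[b] = flat[order]
        return out
    out = np.empty((n_beats, profiles_per_beat, 2), dtype=int)
    for b in range(n_beats):
        rel = np.mod(ang - theta0 - b * GOLDEN_ANGLE_DEG, 360.0)
        order = np.lexsort((rel, rad))[:profiles_per_beat]
        out[b] = flat[order]
    return out


def analytic_coils(shape, n_coils: int = 4) -> np.ndarray:
    """Smooth analytic coil sensitivities, RSS-normalized to 1."""
    nx, ny, nz = shape
    xg, yg = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij"
    )
    coils = np.empty((n_coils, nx, ny, nz), dtype=complex)
    sigma = 1.0
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        px, py = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        mag = np.exp(-((xg - px) ** 2 + (yg - py) ** 2) / (2 * sigma**2))
        phase = np.exp(1j * (0.5 * ang + 0.7 * (xg * py - yg * px)))
        coils[c] = (mag * phase)[:, :, None]
    rss = np.sqrt(np.sum(np.abs(coils) ** 2, axis=0))
    return coils / rss[None]


def ground_truth_bin_fields(
    motion: MotionModel,
    beat_times: np.ndarray,
    bins: RespiratoryBins,
    shape,
    voxel_size,
) -> MotionFieldSet:
    """Average the true per-beat fields within each bin, relative to the
    reference bin (whose field becomes identically zero)."""
    mean_fields = {}
    for b in range(bins.n_bins):
        members = bins.members(b)
        fs = [motion.field(beat_times[i], shape, voxel_size) for i in members]
        mean_fields[b] = np.mean(fs, axis=0)
    ref = mean_fields[bins.reference]
    return MotionFieldSet(
        {b: f - ref for b, f in mean_fields.items()}, bins.reference
    )


# ---------------------------------------------------------------------------
# acquisition simulation


def _warp_volume(vol: np.ndarray, field_mm: np.ndarray, voxel_size) -> np.ndarray:
    grid = np.indices(vol.shape, dtype=float)
    src = grid - field_mm / np.asarray(voxel_size).reshape(3, 1, 1, 1)
    return map_coordinates(vol, src, order=1, mode="constant")


def simulate_acquisition(
    phantom: DigitalPhantom,
    acq: AcquisitionSpec,
    prep: MTPreparation | None,
    imaging: ImagingModule,
    motion: MotionModel | None = None,
    n_beats: int | None = None,
    b0: float = 0.0,
) -> SimulatedAcquisition:
    """Simulate the segmented Cartesian acquisition of a phantom.

    Per heartbeat: the pseudo-steady-state signal volume (one Bloch run per
    unique tissue) is warped by the respiratory motion state, multiplied by
    the analytic coil maps, Fourier transformed, sampled on that beat's
    spiral-profile mask and corrupted with complex Gaussian noise.  The exact
    displacement trace is emitted alongside.
    """
    nx, ny, nz = phantom.shape
    total = nx * ny
    if n_beats is None:
        n_beats = int(np.ceil(total / acq.profiles_per_beat))
    protocol = SimulationProtocol(heart_rate=acq.heart_rate)

    signal_by_label = {}
    cache = {}
    for lab, tis in phantom.tissues.items():
        key = tis.astuple()
        if key not in cache:
            cache[key] = simulate_sequence(tis, prep, imaging, protocol)
        signal_by_label[lab] = cache[key]
    truth = phantom.signal_volume(signal_by_label)

    full = acq.ordering == "full" or (
        acq.ordering == "spiral" and acq.profiles_per_beat * n_beats == total
    )
    if acq.ordering == "linear":
        order = np.stack(
            np.unravel_index(np.arange(total), (nx, ny)), axis=1
        )[: acq.profiles_per_beat * n_beats]
        indices = order.reshape(n_beats, acq.profiles_per_beat, 2)
    else:
        indices = spiral_profile_ordering(
            (nx, ny), acq.profiles_per_beat, n_beats, seed=acq.seed, full=full
        )

    coils = analytic_coils(phantom.shape, acq.n_coils)
    rr = 60.0 / acq.heart_rate
    beat_times = np.arange(n_beats) * rr
    rng = np.random.default_rng(acq.seed + 1)
    d_lr = np.empty(n_beats)
    d_fh = np.empty(n_beats)
    data = np.empty((acq.n_coils, n_beats, acq.profiles_per_beat, nz), dtype=complex)
    for b in range(n_beats):
        if motion is not None:
            fld = motion.field(beat_times[b], phantom.shape, phantom.voxel_size)
            vol = _warp_volume(truth, fld, phantom.voxel_size)
            d_lr[b], d_fh[b] = motion.translation(beat_times[b])
        else:
            vol = truth
            d_lr[b] = d_fh[b] = 0.0
        ix = indices[b, :, 0]
        iy = indices[b, :, 1]
        for c in range(acq.n_coils):
            k = fft3c(coils[c] * vol)
            samples = k[ix, iy, :]
            if acq.noise_sd > 0:
                samples = samples + acq.noise_sd * (
                    rng.standard_normal(samples.shape)
                    + 1j * rng.standard_normal(samples.shape)
                ) / np.sqrt(2.0)
            data[c, b] = samples
    ksp = CartesianKSpace(
        data=data,
        indices=indices,
        shape=phantom.shape,
        voxel_size=phantom.voxel_size,
    )
    return SimulatedAcquisition(
        kspace=ksp,
        trace=DisplacementTrace(d_lr, d_fh),
        beat_times=beat_times,
        motion=motion if motion is not None else MotionModel(amplitude_fh=0, amplitude_lr=0),
        coils=coils,
        truth_mt=truth,
        signal_by_label=signal_by_label,
    )
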