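"""Synthetic inputs: CT-like vessel phantoms, inlet waveforms, paired flows.

Everything the downstream pipeline consumes is generated here, so no imaging
or Doppler data ever needs to be downloaded.  The phantom emulates a
contrast-filled lumen (bright cylinder, optionally split by an intimal flap)
on a darker soft-tissue background with additive Gaussian noise, at the
brightness-to-noise / contrast-to-noise regime of clinical angio-CT
(BI ~ 28, CNR ~ 3.7 with the default intensities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ImageVolume, SegmentationMask

__all__ = [
    "PhantomSpec",
    "InletWaveform",
    "generate_phantom",
    "generate_inlet_waveform",
    "generate_paired_flows",
    "paper_regime_spec",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a CT-like vessel phantom.

    Intensities use an 8-bit-like arbitrary scale (not Hounsfield units).
    The lumen is a straight tube of radius ``lumen_radius`` (mm) along the z
    axis through ``centerline_xy`` (mm, in-plane); when ``flap_present`` an
    intraluminal flap of thickness ``flap_thickness`` splits it at fraction
    ``flap_offset`` of the diameter, interrupted at ``tear_positions`` (axial
    mm, each opened over ``tear_length`` mm).
    """

    grid_shape: tuple = (64, 64, 40)
    voxel_spacing: tuple = (0.78, 0.78, 1.0)  # mm, matches clinical angio-CT
    lumen_radius: float = 10.0  # mm
    centerline_xy: tuple | None = None  # mm; defaults to grid centre
    flap_present: bool = False
    flap_thickness: float = 1.5  # mm
    flap_offset: float = 0.5
    tear_positions: tuple = ()
    tear_length: float = 4.0  # mm
    object_intensity: float = 100.0
    background_intensity: float = 87.0
    noise_sd: float = 3.59
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.lumen_radius <= 0:
            raise ValueError("lumen_radius must be positive")
        if self.object_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.object_intensity <= self.background_intensity:
            raise ValueError("object_intensity must exceed background_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 < self.flap_offset < 1.0:
            raise ValueError("flap_offset must lie strictly inside (0, 1)")
        if self.flap_present and self.flap_thickness >= 2.0 * self.lumen_radius:
            raise ValueError("flap thicker than the lumen diameter")


def _lumen_and_flap_masks(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_spacing
    cx, cy = spec.centerline_xy or (0.5 * (nx - 1) * sx, 0.5 * (ny - 1) * sy)
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    X, Y = np.meshgrid(x, y, indexing="ij")
    in_lumen_2d = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.lumen_radius**2
    lumen = np.repeat(in_lumen_2d[:, :, None], nz, axis=2)

    flap = np.zeros_like(lumen)
    if spec.flap_present:
        # flap is a chord-aligned slab at offset*diameter from the lumen bottom
        y_flap = cy - spec.lumen_radius + spec.flap_offset * 2.0 * spec.lumen_radius
        in_flap_2d = in_lumen_2d & (np.abs(Y - y_flap) <= 0.5 * spec.flap_thickness)
        flap = np.repeat(in_flap_2d[:, :, None], nz, axis=2)
        z = np.arange(nz) * sz
        for z_tear in spec.tear_positions:
            open_z = np.abs(z - z_tear) <= 0.5 * spec.tear_length
            flap[:, :, open_z] = False
    return lumen, flap


def generate_phantom(spec: PhantomSpec):
    """Build the noisy volume and its exact ground-truth lumen mask.

    Returns ``(ImageVolume, SegmentationMask)``.  Lumen voxels (minus flap
    voxels) carry ``object_intensity``, everything else (including the flap)
    ``background_intensity``; iid Gaussian noise of sd ``noise_sd`` is added
    everywhere.  The mask is noise-free and independent of the seed.
    """
    lumen, flap = _lumen_and_flap_masks(spec)
    bright = lumen & ~flap
    vox = np.where(bright, spec.object_intensity, spec.background_intensity).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape)
    volume = ImageVolume(vox, spec.voxel_spacing)
    mask = SegmentationMask(bright, spec.voxel_spacing)
    return volume, mask


def paper_regime_spec(**overrides) -> PhantomSpec:
    """Phantom at the clinical image-quality regime (BI ~ 27.9, CNR ~ 3.6)."""
    defaults = dict(object_intensity=100.0, background_intensity=87.0, noise_sd=3.59)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@dataclass(frozen=True)
class InletWaveform:
    """Periodic inlet velocity waveform over one cardiac cycle.

    ``time_samples`` strictly increase from 0 to ``period`` inclusive and the
    first and last velocity samples are equal (periodicity).
    """

    period: float
    time_samples: np.ndarray
    velocity_samples: np.ndarray
    intensity_label: str = "real"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_samples, dtype=float)
        v = np.asarray(self.velocity_samples, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t.shape != v.shape or t.ndim != 1 or t.size < 3:
            raise ValueError("time and velocity samples must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time samples must be strictly increasing")
        if abs(t[0]) > 1e-12 or abs(t[-1] - self.period) > 1e-9:
            raise ValueError("time samples must cover [0, period]")
        if np.any(v < 0):
            raise ValueError("velocity samples must be non-negative")
        if abs(v[0] - v[-1]) > 1e-9 * max(1.0, float(np.max(v))):
            raise ValueError("waveform must be periodic (first == last sample)")
        object.__setattr__(self, "time_samples", t)
        object.__setattr__(self, "velocity_samples", v)

    def __call__(self, t) -> np.ndarray:
        """Velocity at arbitrary times by periodic linear interpolation."""
        tau = np.mod(np.asarray(t, dtype=float), self.period)
        return np.interp(tau, self.time_samples, self.velocity_samples)

    def mean(self) -> float:
        """Time average over one period (trapezoidal)."""
        return float(
            np.trapezoid(self.velocity_samples, self.time_samples) / self.period
        )

    def peak(self) -> float:
        return float(np.max(self.velocity_samples))


#: fraction of the cycle occupied by systole
SYSTOLE_FRACTION = 0.35
#: default ratio of peak to mean velocity of the base waveform
PEAK_TO_MEAN = 2.5
#: default multiplier applied for the "high" intensity label
HIGH_INTENSITY_FACTOR = 1.5


def generate_inlet_waveform(
    kind: str,
    mean_velocity: float,
    period: float = 1.0,
    seed: int = 0,
    n_samples: int = 201,
    peak_to_mean: float = PEAK_TO_MEAN,
    high_factor: float = HIGH_INTENSITY_FACTOR,
) -> InletWaveform:
    """Raised-cosine systole + flat diastole inlet waveform.

    ``mean_velocity`` (m/s) is the time average of the *real*-intensity
    waveform; ``kind="high"`` scales the whole waveform (mean and peak alike)
    by ``high_factor``.  The waveform is fully deterministic; ``seed`` is
    accepted for interface uniformity and unused.
    """
    del seed
    if kind not in ("real", "high"):
        raise ValueError(f"kind must be 'real' or 'high', got {kind!r}")
    if mean_velocity <= 0 or period <= 0:
        raise ValueError("mean_velocity and period must be positive")
    if peak_to_mean <= 1.0:
        raise ValueError("peak_to_mean must exceed 1")

    ts = SYSTOLE_FRACTION * period
    # shape s(t) = d + A/2 (1 - cos(2 pi t/ts)) on [0, ts], d elsewhere;
    # mean(s) = d + A*ts/(2*period); peak = d + A.  Solve for mean 1, peak r.
    A = (peak_to_mean - 1.0) / (1.0 - 0.5 * SYSTOLE_FRACTION)
    d = 1.0 - 0.5 * A * SYSTOLE_FRACTION
    if d < 0:
        raise ValueError("peak_to_mean too large for a non-negative diastole")
    t = np.linspace(0.0, period, n_samples)
    shape = np.full_like(t, d)
    sys_mask = t <= ts
    shape[sys_mask] = d + 0.5 * A * (1.0 - np.cos(2.0 * np.pi * t[sys_mask] / ts))
    scale = mean_velocity * (high_factor if kind == "high" else 1.0)
    return InletWaveform(period, t, scale * shape, intensity_label=kind)


def generate_paired_flows(
    n: int,
    true_bias: float,
    sd: float,
    level_range: tuple = (0.5, 5.0),
    seed: int = 0,
):
    """Paired pseudo-measurements (a_i, b_i) for agreement testing.

    a_i ~ Uniform(level_range) plays the CFD flow (mL/s); b_i = a_i +
    true_bias + N(0, sd) plays the Doppler reading.  Reproducible under seed.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs for agreement analysis")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    lo, hi = level_range
    if not hi > lo:
        raise ValueError("level_range must be a non-empty interval")
    rng = np.random.default_rng(seed)
    a = rng.uniform(lo, hi, size=n)
    b = a + true_bias + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    return a, b
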