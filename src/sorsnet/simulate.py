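"""Synthetic line-scan SORS data generator.

Emulates a two-layer sample (a thin translucent shell over meat) imaged by a
line-scan Raman hyperspectral system: a point laser hits the sample at one
pixel of a 512-pixel / 102.4 mm line, and the camera records a full spectrum
at every pixel, so lateral distance from the laser point is the spatial
offset of SORS.  Each acquisition is repeated several times at slightly
different platform positions; repeats share the same noiseless signal and
differ only in noise and transient artifacts (cosmic rays).

Signal model per pixel at offset ``d`` mm from the incidence point::

    s(d, lam; day) = w_shell(d) * shell(lam) * g(day)
                   + (1 - w_shell(d)) * meat(lam, day)

with ``w_shell(d) = s0 * exp(-|d| / L)`` (surface contribution dominates at
the laser point and decays with offset, the basic SORS mechanism),
``g(day) = 1 + growth * (day - 1)`` (fluorescence background rises as tissue
decays), and meat Raman peak amplitudes for the protein bands at 1148, 1269
and 1311 cm-1 shrinking geometrically with storage day.  The shell spectrum
is a broad, featureless fluorescence curve; the meat spectrum is a sum of
narrow Gaussian peaks on a low baseline.  Weights satisfy
``w_shell + w_meat = 1`` at every offset (unit total throughput).

Cubes are generated on a wavelength axis (nm) obtained from the target
Raman-shift range through the inverse Stokes relation, so downstream
preprocessing genuinely performs the shift conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

# the five reference meat peak positions (cm-1): phenylalanine, C-N stretch,
# the two amide-III / protein secondary-structure bands, CH bending
DEFAULT_PEAK_CENTERS = (1003.0, 1148.0, 1269.0, 1311.0, 1487.0)
# the three protein bands whose amplitude decays with storage day
DECAYING_PEAKS = (1148.0, 1269.0, 1311.0)

SHIFT_MIN = 600.0
SHIFT_MAX = 1800.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and signal-model parameters.

    Counts and geometry mirror the acquisition design (100 shrimp followed
    daily for 7 days, 10 repeat line scans, 512 pixels over 102.4 mm,
    785 nm excitation).  Signal-model scales are simulator choices.
    """

    n_shrimp: int = 100
    n_days: int = 7
    n_repeats: int = 10
    n_pixels: int = 512
    window_mm: float = 102.4
    excitation_nm: float = 785.0
    native_band_count: int = 1000
    peak_centers: tuple[float, ...] = DEFAULT_PEAK_CENTERS
    peak_amplitudes: tuple[float, ...] = (1.0, 0.8, 0.7, 0.75, 0.6)
    peak_width_cm1: float = 12.0
    meat_baseline: float = 0.15
    shell_amplitude: float = 2.5
    day_decay_rate: float = 0.08      # per-day fractional decay, protein peaks
    fluorescence_growth_rate: float = 0.10  # per-day background increase
    surface_mixing_scale: float = 2.0  # mm, offset decay length of the shell term
    surface_mixing_max: float = 0.85   # shell weight at zero offset
    cosmic_ray_rate: float = 0.01      # per (repeat, pixel)
    cosmic_ray_amplitude: float = 25.0
    anomaly_rate: float = 0.02         # per spatial position
    noise_sd: float = 0.05
    gain_jitter_sd: float = 0.05        # per-sample multiplicative lognormal sd
    shell_scale_jitter_sd: float = 0.20  # shell thickness/transmittance spread
    bio_day_jitter_sd: float = 0.35     # days; individual spoilage-rate spread
    seed: int = 0

    def __post_init__(self):
        for name in ("n_shrimp", "n_days", "n_repeats", "n_pixels",
                     "native_band_count"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("cosmic_ray_rate", "anomaly_rate", "day_decay_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0.0 < self.surface_mixing_max < 1.0:
            raise ConfigError("surface_mixing_max must lie in (0, 1)")
        if len(self.peak_amplitudes) != len(self.peak_centers):
            raise ConfigError("peak_amplitudes must match peak_centers")
        for c in self.peak_centers:
            if not SHIFT_MIN <= c <= SHIFT_MAX:
                raise ConfigError(
                    f"peak center {c} cm-1 outside the "
                    f"{SHIFT_MIN:.0f}-{SHIFT_MAX:.0f} cm-1 band of interest")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.window_mm / self.n_pixels

    @property
    def shift_axis(self) -> np.ndarray:
        """Native Raman-shift axis, uniform over the band of interest."""
        return np.linspace(SHIFT_MIN, SHIFT_MAX, self.native_band_count)

    @property
    def wavelength_axis_nm(self) -> np.ndarray:
        """Native wavelength axis via the inverse Stokes relation."""
        return 1e7 / (1e7 / self.excitation_nm - self.shift_axis)


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Single-layer backscatter reference spectrum."""

    layer: str                      # "meat" or "shell"
    shift_axis: np.ndarray          # cm-1, strictly increasing
    intensity: np.ndarray           # >= 0
    typical_peaks: tuple[float, ...] = ()

    def __post_init__(self):
        if np.any(np.diff(self.shift_axis) <= 0):
            raise InputError("shift_axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InputError("reference intensities must be nonnegative")


@dataclass
class ScatterCube:
    """One sample's raw acquisition: repeats x pixels x native bands."""

    data: np.ndarray
    wavelength_axis: np.ndarray     # nm per native band
    laser_index: int
    shrimp_id: int
    day: int
    # ground truth bookkeeping for recovery tests (not used by the pipeline)
    anomaly_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    n_cosmic_rays: int = 0

    def __post_init__(self):
        if self.data.ndim != 3:
            raise InputError("cube data must be repeats x pixels x bands")
        if not 0 <= self.laser_index < self.data.shape[1]:
            raise InputError("laser_index outside the spatial axis")
        if not np.all(np.isfinite(self.data)):
            raise InputError("cube intensities must be finite")


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _shell_curve(shift: np.ndarray) -> np.ndarray:
    """Broad smooth fluorescence profile with no narrow features.

    The flank of a very wide emission bump whose maximum lies below the
    band of interest, so the curve decays smoothly across the window and
    has no interior local maximum; scale is 1 (multiplied by
    shell_amplitude by callers).
    """
    span = shift[-1] - shift[0]
    u = (shift - shift[0]) / span
    return 0.55 + 0.45 * np.exp(-0.5 * ((u + 0.15) / 0.55) ** 2)


def meat_peak_amplitudes(config: SimulationConfig, day: float) -> np.ndarray:
    """Peak amplitudes on the given (possibly fractional) storage day.

    The protein bands at 1148/1269/1311 cm-1 decay geometrically with day;
    the remaining peaks are stable.  A fractional day expresses the
    individual shrimp's biological spoilage state, which scatters around
    the nominal storage day.
    """
    amps = np.asarray(config.peak_amplitudes, dtype=float).copy()
    decay = (1.0 - config.day_decay_rate) ** (day - 1)
    for i, c in enumerate(config.peak_centers):
        if c in DECAYING_PEAKS:
            amps[i] *= decay
    return amps


def meat_spectrum(config: SimulationConfig, day: float = 1) -> np.ndarray:
    """Noiseless meat-layer spectrum on the native shift axis."""
    shift = config.shift_axis
    amps = meat_peak_amplitudes(config, day)
    out = np.full_like(shift, config.meat_baseline)
    for a, c in zip(amps, config.peak_centers):
        out += a * _gaussian(shift, c, config.peak_width_cm1)
    return out


def shell_spectrum(config: SimulationConfig) -> np.ndarray:
    """Noiseless shell-layer fluorescence spectrum (day-1 scale)."""
    return config.shell_amplitude * _shell_curve(config.shift_axis)


def generate_reference_spectra(
    config: SimulationConfig,
) -> tuple[ReferenceSpectrum, ReferenceSpectrum]:
    """Backscatter reference spectra for the meat and shell layers."""
    shift = config.shift_axis
    meat = ReferenceSpectrum(
        layer="meat", shift_axis=shift, intensity=meat_spectrum(config, day=1),
        typical_peaks=tuple(config.peak_centers))
    shell = ReferenceSpectrum(
        layer="shell", shift_axis=shift, intensity=shell_spectrum(config),
        typical_peaks=())
    return meat, shell


def shell_weight(config: SimulationConfig, offset_mm: np.ndarray,
                 shell_scale: float = 1.0) -> np.ndarray:
    """Surface-layer mixing weight w_shell(d); w_meat = 1 - w_shell.

    ``shell_scale`` expresses the individual's shell optical thickness: a
    thicker shell both keeps a larger surface share at any given offset
    (longer decay length) and emits more fluorescence (radiance factor,
    applied by the caller).
    """
    return config.surface_mixing_max * np.exp(
        -np.abs(offset_mm) / (config.surface_mixing_scale * shell_scale))


def fluorescence_growth(config: SimulationConfig, day: float) -> float:
    """Day-dependent scale g(day) of the shell fluorescence term."""
    return 1.0 + config.fluorescence_growth_rate * (day - 1)


def noiseless_signal(
    config: SimulationConfig,
    day: float,
    offsets_mm: np.ndarray,
    shell_scale: float = 1.0,
) -> np.ndarray:
    """Noiseless pixel spectra (len(offsets) x bands) of a normal sample.

    Mixing weights always satisfy w_shell + w_meat = 1; ``shell_scale``
    models between-individual shell optical thickness, stretching the
    mixing decay length and scaling the shell radiance.
    """
    w_sh = shell_weight(config, offsets_mm, shell_scale)[:, None]
    sh = shell_spectrum(config)[None, :] * fluorescence_growth(config, day)
    mt = meat_spectrum(config, day)[None, :]
    return w_sh * shell_scale * sh + (1.0 - w_sh) * mt


def _anomaly_spectrum(config: SimulationConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    """Shell-like spectrum replacing meat at an anomalous shell position."""
    scale = 0.8 + 0.4 * rng.random()
    return scale * shell_spectrum(config) * _shell_curve(
        config.shift_axis[::-1])  # slightly different broad shape, no peaks


def simulate_sample(
    shrimp_id: int,
    day: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ScatterCube:
    """Simulate one raw scattering cube (repeats x pixels x native bands)."""
    if not 1 <= day <= config.n_days:
        raise InputError(f"day {day} outside 1..{config.n_days}")
    n_px, n_rep, n_band = config.n_pixels, config.n_repeats, config.native_band_count

    # laser point placed in the central region so the +/-5 mm ROI always fits
    margin = int(np.ceil(5.0 / config.pixel_pitch_mm)) + 2
    laser_index = int(rng.integers(margin, n_px - margin))

    offsets = (np.arange(n_px) - laser_index) * config.pixel_pitch_mm
    shell_scale = float(np.exp(rng.normal(0.0, config.shell_scale_jitter_sd)))
    gain = float(np.exp(rng.normal(0.0, config.gain_jitter_sd)))
    # biological spoilage state: individuals scatter around the nominal
    # storage day, the dominant irreducible error source in freshness data
    day_eff = day
    if config.bio_day_jitter_sd > 0:
        day_eff = float(np.clip(day + rng.normal(0.0, config.bio_day_jitter_sd),
                                0.5, config.n_days + 0.5))

    signal = noiseless_signal(config, day_eff, offsets, shell_scale)  # px x band

    # anomalous shell positions: the meat term is replaced by a second
    # broad shell-like term, so the pixel shows no meat Raman peaks
    anomaly_mask = rng.random(n_px) < config.anomaly_rate
    anomaly_positions = np.flatnonzero(anomaly_mask)
    if anomaly_positions.size:
        w_sh = shell_weight(config, offsets[anomaly_positions],
                            shell_scale)[:, None]
        sh = shell_spectrum(config)[None, :] * fluorescence_growth(config, day_eff)
        anom = _anomaly_spectrum(config, rng)[None, :]
        signal[anomaly_positions] = (w_sh * shell_scale * sh
                                     + (1.0 - w_sh) * anom)

    data = np.broadcast_to(signal * gain, (n_rep, n_px, n_band)).copy()

    # cosmic rays: isolated single-band spikes, independent per repeat
    ray_mask = rng.random((n_rep, n_px)) < config.cosmic_ray_rate
    ray_reps, ray_px = np.nonzero(ray_mask)
    if ray_reps.size:
        bands = rng.integers(0, n_band, size=ray_reps.size)
        heights = config.cosmic_ray_amplitude * (0.5 + rng.random(ray_reps.size))
        data[ray_reps, ray_px, bands] += heights

    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)

    return ScatterCube(
        data=data,
        wavelength_axis=config.wavelength_axis_nm,
        laser_index=laser_index,
        shrimp_id=shrimp_id,
        day=day,
        anomaly_positions=anomaly_positions,
        n_cosmic_rays=int(ray_reps.size),
    )


@dataclass
class Dataset:
    """Lazy collection of scattering cubes plus a metadata table.

    Cubes are large (tens of MB each), so they are regenerated on demand
    from per-sample RNG streams spawned deterministically from the root
    seed; iterating twice yields bit-identical cubes.
    """

    config: SimulationConfig
    metadata: pd.DataFrame  # sample_id, shrimp_id, day, laser_index

    def __len__(self) -> int:
        return len(self.metadata)

    def _rng_for(self, sample_index: int) -> np.random.Generator:
        seq = np.random.SeedSequence(self.config.seed).spawn(len(self))
        return np.random.default_rng(seq[sample_index])

    def cube(self, sample_index: int) -> ScatterCube:
        row = self.metadata.iloc[sample_index]
        return simulate_sample(int(row.shrimp_id), int(row.day),
                               self.config, self._rng_for(sample_index))

    def __iter__(self) -> Iterator[ScatterCube]:
        for i in range(len(self)):
            yield self.cube(i)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Plan the full study: n_shrimp x n_days cubes with metadata.

    The returned dataset is lazy; the metadata table (including each
    sample's laser position) is computed up front and is cheap.
    """
    rows = []
    children = np.random.SeedSequence(config.seed).spawn(
        config.n_shrimp * config.n_days)
    margin = int(np.ceil(5.0 / config.pixel_pitch_mm)) + 2
    i = 0
    for shrimp in range(config.n_shrimp):
        for day in range(1, config.n_days + 1):
            # the laser index is the first draw of the sample's RNG stream,
            # reproduced here without materializing the cube
            rng = np.random.default_rng(children[i])
            laser_index = int(rng.integers(margin, config.n_pixels - margin))
            rows.append((i, shrimp, day, laser_index))
            i += 1
    meta = pd.DataFrame(rows, columns=["sample_id", "shrimp_id", "day",
                                       "laser_index"])
    return Dataset(config=config, metadata=meta)


def scaled_config(n_shrimp: int, seed: int = 0, **overrides) -> SimulationConfig:
    """Default study conditions at a reduced number of shrimp."""
    return replace(SimulationConfig(), n_shrimp=n_shrimp, seed=seed, **overrides)
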