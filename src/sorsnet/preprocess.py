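"""Preprocessing chain: raw scattering cube -> 200 x 11 offset matrix.

The stages, applied in order:

1.  ROI crop — keep pixels within +/-5 mm of the laser point (0.2 mm pixel
    pitch -> 51 columns) and bands whose Raman shift falls in 600–1800 cm-1,
    converting the native wavelength axis to Raman shift (Stokes lines).
2.  Anomalous-spectrum removal — spatial positions whose repeat-averaged
    spectrum fails to show enough of the meat reference peaks are flagged
    (shell regions without meat signal); their columns are excluded and the
    symmetric partner fills in during folding.
3.  Cosmic-ray trimming — per (pixel, band), drop the max and min across
    the repeated acquisitions; single-acquisition spikes land in the
    extremes and vanish from the trimmed mean.
4.  Averaging + Savitzky-Golay smoothing along the band axis.
5.  Adjacent-band averaging — non-overlapping blocks reduce the native
    bands to 200, removing the redundancy of strongly correlated
    neighbouring wavebands.
6.  Symmetric fold — columns left and right of the laser point at equal
    distance are averaged, and the 26 folded distances (0–5 mm at 0.2 mm)
    are binned into 11 uniform 0.5 mm offset bins.

The output matrix keeps the fluorescence baseline: the background level is
itself informative about tissue decay, so no baseline subtraction is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ConfigError, InputError, ROIError, SampleRejectionError
from .simulate import ReferenceSpectrum, ScatterCube


@dataclass(frozen=True)
class PreprocessConfig:
    roi_halfwidth_mm: float = 5.0
    shift_range: tuple[float, float] = (600.0, 1800.0)
    sg_window: int = 11
    sg_polyorder: int = 3
    n_bands_out: int = 200
    n_offsets_out: int = 11
    peak_tolerance_cm1: float = 10.0
    min_peaks_matched: int = 3
    peak_prominence: float = 0.02   # fraction of the spectrum's range
    normalize: bool = False         # optional per-sample max normalization

    def __post_init__(self):
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must be odd and > sg_polyorder")
        if self.n_offsets_out < 2:
            raise ConfigError("n_offsets_out must be >= 2")
        if self.peak_tolerance_cm1 <= 0:
            raise ConfigError("peak_tolerance_cm1 must be positive")
        if self.roi_halfwidth_mm < 0:
            raise ConfigError("roi_halfwidth_mm must be nonnegative")


@dataclass
class ProcessedSample:
    """The model-ready waveband x offset matrix for one sample."""

    matrix: np.ndarray        # n_bands_out x n_offsets_out
    band_centers: np.ndarray  # cm-1, strictly increasing
    offsets_mm: np.ndarray    # bin left edges, strictly increasing from 0
    day: int
    shrimp_id: int

    def __post_init__(self):
        if self.matrix.shape != (self.band_centers.size, self.offsets_mm.size):
            raise InputError("matrix shape inconsistent with axes")
        if np.any(np.diff(self.band_centers) <= 0):
            raise InputError("band_centers must be strictly increasing")
        if self.offsets_mm[0] != 0 or np.any(np.diff(self.offsets_mm) <= 0):
            raise InputError("offsets_mm must increase strictly from 0")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("processed matrix contains non-finite values")


@dataclass
class _RoiCube:
    """Intermediate: ROI-cropped cube on a Raman-shift axis."""

    data: np.ndarray          # repeats x roi-pixels x bands
    shift_axis: np.ndarray    # cm-1
    laser_column: int         # index of the laser pixel within the ROI
    pixel_pitch_mm: float
    shrimp_id: int
    day: int
    removed_columns: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))


def to_raman_shift(wavelength_nm: np.ndarray, excitation_nm: float
                   ) -> np.ndarray:
    """Stokes conversion: shift (cm-1) = 1e7 * (1/lambda_ex - 1/lambda)."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0) or excitation_nm <= 0:
        raise InputError("wavelengths must be positive")
    return 1e7 * (1.0 / excitation_nm - 1.0 / wavelength_nm)


def crop_roi(cube: ScatterCube, config: PreprocessConfig,
             window_mm: float = 102.4, excitation_nm: float = 785.0
             ) -> _RoiCube:
    """Restrict to +/- roi_halfwidth_mm around the laser point and the
    shift band of interest."""
    n_pixels = cube.data.shape[1]
    pitch = window_mm / n_pixels
    half_px = int(round(config.roi_halfwidth_mm / pitch))
    lo, hi = cube.laser_index - half_px, cube.laser_index + half_px
    if lo < 0 or hi >= n_pixels:
        raise ROIError(
            f"sample (shrimp {cube.shrimp_id}, day {cube.day}): laser index "
            f"{cube.laser_index} leaves no room for a +/-{half_px}-pixel ROI")

    shift = to_raman_shift(cube.wavelength_axis, excitation_nm)
    # tolerance absorbs float round-trip through the wavelength axis
    tol = 1e-6 * (config.shift_range[1] - config.shift_range[0])
    band_mask = ((shift >= config.shift_range[0] - tol)
                 & (shift <= config.shift_range[1] + tol))
    data = cube.data[:, lo:hi + 1, :][:, :, band_mask]
    return _RoiCube(
        data=data, shift_axis=shift[band_mask], laser_column=half_px,
        pixel_pitch_mm=pitch, shrimp_id=cube.shrimp_id, day=cube.day)


def detect_typical_peaks(spectrum: np.ndarray, shift_axis: np.ndarray,
                         config: PreprocessConfig) -> np.ndarray:
    """Prominence-thresholded local maxima, as shift positions (cm-1)."""
    spectrum = np.asarray(spectrum, dtype=float)
    rng = spectrum.max() - spectrum.min()
    if rng == 0:
        return np.empty(0)
    idx, _ = find_peaks(spectrum, prominence=config.peak_prominence * rng)
    return shift_axis[idx]


def _matches_reference(spectrum: np.ndarray, shift_axis: np.ndarray,
                       typical_peaks: np.ndarray,
                       config: PreprocessConfig) -> bool:
    if config.min_peaks_matched == 0:
        return True
    # narrow Raman peaks riding the steep fluorescence flank need not form
    # local maxima of the raw spectrum; detrend with a wide smoother first,
    # but keep the prominence floor anchored to the undetrended range so
    # residual noise bumps stay sub-threshold
    n_bands = spectrum.size
    win = min(n_bands if n_bands % 2 else n_bands - 1, 201)
    if win > config.sg_polyorder:
        baseline = savgol_filter(spectrum, win, config.sg_polyorder)
        residual = spectrum - baseline
    else:
        residual = spectrum
    # two-part prominence floor: the configured fraction of the spectrum
    # range, and 5x a robust (MAD) estimate of the residual noise scale so
    # chance noise bumps cannot accumulate into spurious reference matches
    sigma = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    floor = max(config.peak_prominence * (spectrum.max() - spectrum.min()),
                5.0 * sigma)
    if floor == 0:
        return False
    idx, _ = find_peaks(residual, prominence=floor)
    found = shift_axis[idx]
    if found.size == 0:
        return False
    n = sum(np.min(np.abs(found - p)) <= config.peak_tolerance_cm1
            for p in typical_peaks)
    return n >= config.min_peaks_matched


def remove_anomalous_spectra(roi: _RoiCube, meat_reference: ReferenceSpectrum,
                             config: PreprocessConfig) -> _RoiCube:
    """Flag spatial positions whose repeat-averaged spectrum lacks the
    reference meat peaks; record them for exclusion during folding."""
    peaks = np.asarray(meat_reference.typical_peaks, dtype=float)
    if peaks.size == 0:
        raise InputError("meat reference has no typical peaks")
    # provisional repeat average for flagging; max/min-trimmed when there
    # are enough repeats, since cosmic rays are still present at this stage
    # and a single spike would inflate the prominence denominator
    if roi.data.shape[0] >= 3:
        mean_spec = np.sort(roi.data, axis=0)[1:-1].mean(axis=0)
    else:
        mean_spec = roi.data.mean(axis=0)  # pixels x bands
    # peak matching runs on a lightly smoothed copy of the repeat-averaged
    # spectrum: residual per-band noise would otherwise seed spurious
    # low-prominence maxima near the reference positions
    if mean_spec.shape[1] >= config.sg_window:
        mean_spec = savgol_filter(mean_spec, config.sg_window,
                                  config.sg_polyorder, axis=-1)
    removed = [c for c in range(mean_spec.shape[0])
               if not _matches_reference(mean_spec[c], roi.shift_axis,
                                         peaks, config)]
    if len(removed) == mean_spec.shape[0]:
        raise SampleRejectionError(
            f"sample (shrimp {roi.shrimp_id}, day {roi.day}): every spatial "
            "position was flagged anomalous")
    roi.removed_columns = np.asarray(removed, dtype=int)
    return roi


def remove_cosmic_rays(data: np.ndarray) -> np.ndarray:
    """Drop the max and min across repeats for every (pixel, band) cell.

    Returns the remaining repeats (sorted along the repeat axis); a cosmic
    ray, being an isolated single-acquisition spike, sits in the dropped
    extreme and no longer reaches the trimmed mean.
    """
    if data.shape[0] < 3:
        raise InputError("cosmic-ray trimming needs at least 3 repeats")
    return np.sort(data, axis=0)[1:-1]


def average_and_smooth(data: np.ndarray, config: PreprocessConfig
                       ) -> np.ndarray:
    """Trimmed mean over repeats, then Savitzky-Golay along the band axis."""
    if data.shape[-1] < config.sg_window:
        raise ConfigError("band count smaller than the Savitzky-Golay window")
    mean = data.mean(axis=0)  # pixels x bands
    return savgol_filter(mean, config.sg_window, config.sg_polyorder, axis=-1)


def band_average(image: np.ndarray, band_centers: np.ndarray,
                 n_bands_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Average non-overlapping adjacent-band blocks down to n_bands_out."""
    n_native = image.shape[-1]
    if n_native % n_bands_out != 0:
        raise ConfigError(
            f"{n_native} native bands not divisible by {n_bands_out}; adjust "
            "the native band axis so adjacent-band blocks are integral")
    block = n_native // n_bands_out
    out = image.reshape(*image.shape[:-1], n_bands_out, block).mean(axis=-1)
    centers = band_centers.reshape(n_bands_out, block).mean(axis=-1)
    return out, centers


def fold_offsets(image: np.ndarray, laser_column: int, pixel_pitch_mm: float,
                 n_offsets_out: int, roi_halfwidth_mm: float,
                 removed_columns: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Average mirror columns about the laser point and bin the folded
    distances into uniform offset bins.

    ``image`` is pixels x bands.  Returns (bands x n_offsets_out matrix,
    offsets_mm bin left edges).  A column flagged anomalous contributes
    nothing; its mirror partner is used alone.
    """
    n_cols = image.shape[0]
    if n_cols % 2 == 0:
        raise InputError("ROI must have an odd column count (laser centered)")
    if laser_column != n_cols // 2:
        raise InputError("laser column must be centered in the ROI")

    keep = np.ones(n_cols, dtype=bool)
    if removed_columns is not None and len(removed_columns):
        keep[np.asarray(removed_columns, dtype=int)] = False

    half = n_cols // 2
    n_bands = image.shape[1]
    # uniform bins [k*w, (k+1)*w), w = halfwidth/(n_out-1) (0.5 mm for the
    # default 11 bins over 0-5 mm); the terminal distance (exactly the ROI
    # halfwidth) falls in the last, closed bin
    bin_width = roi_halfwidth_mm / (n_offsets_out - 1)

    sums = np.zeros((n_bands, n_offsets_out))
    counts = np.zeros(n_offsets_out)
    for d in range(half + 1):
        cols = [half] if d == 0 else [half - d, half + d]
        vals = [image[c] for c in cols if keep[c]]
        if not vals:
            continue
        folded = np.mean(vals, axis=0)
        dist = d * pixel_pitch_mm
        k = int(dist // bin_width)
        if k >= n_offsets_out:   # last bin closed at roi_halfwidth
            k = n_offsets_out - 1
        sums[:, k] += folded
        counts[k] += 1
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise InputError(f"offset bins {empty.tolist()} received no columns")
    matrix = sums / counts[None, :]
    offsets = np.arange(n_offsets_out) * bin_width
    return matrix, offsets


def preprocess_pipeline(cube: ScatterCube, meat_reference: ReferenceSpectrum,
                        config: PreprocessConfig,
                        window_mm: float = 102.4,
                        excitation_nm: float = 785.0) -> ProcessedSample:
    """Full chain from raw cube to the n_bands_out x n_offsets_out matrix."""
    stage = "crop_roi"
    try:
        roi = crop_roi(cube, config, window_mm, excitation_nm)
        stage = "remove_anomalous_spectra"
        roi = remove_anomalous_spectra(roi, meat_reference, config)
        stage = "remove_cosmic_rays"
        trimmed = remove_cosmic_rays(roi.data)
        stage = "average_and_smooth"
        image = average_and_smooth(trimmed, config)
        stage = "band_average"
        image, centers = band_average(image, roi.shift_axis, config.n_bands_out)
        stage = "fold_offsets"
        matrix, offsets = fold_offsets(
            image, roi.laser_column, roi.pixel_pitch_mm,
            config.n_offsets_out, config.roi_halfwidth_mm,
            roi.removed_columns)
    except (ConfigError, InputError, ROIError, SampleRejectionError) as exc:
        raise type(exc)(
            f"[stage {stage}, shrimp {cube.shrimp_id} day {cube.day}] {exc}"
        ) from exc
    if config.normalize:
        matrix = matrix / matrix.max()
    return ProcessedSample(matrix=matrix, band_centers=centers,
                           offsets_mm=offsets, day=cube.day,
                           shrimp_id=cube.shrimp_id)
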