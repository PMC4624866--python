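"""Amplitude spectra, band-restricted ALFF, global-mean normalization and fALFF.

ALFF (amplitude of low-frequency fluctuation) at a voxel is the mean of the
one-sided FFT amplitude spectrum over a frequency band; fALFF is the band's
amplitude sum divided by the amplitude sum over the whole detectable spectrum
(0-0.25 Hz at TR = 2 s), DC excluded from both.

Amplitude convention: amp_k = 2|X_k|/N for interior bins, so a sinusoid of
amplitude A centred on bin k reads off as amp_k = A.  The DC bin carries |X_0|/N
and the Nyquist bin (even N) |X_{N/2}|/N; both are reported but DC never enters
ALFF or fALFF.  Any fixed positive rescaling of the spectrum cancels in
normalized ALFF and in fALFF.

Canonical sub-bands (half-open [low, high); slow-2 closed at the 0.25 Hz
Nyquist):  slow-6 [0, 0.01), slow-5 [0.01, 0.027), slow-4 [0.027, 0.073),
slow-3 [0.073, 0.198), slow-2 [0.198, 0.25].  The boundary 0.027 Hz belongs to
slow-4.  Bin membership is decided by bin-centre frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError, EmptyBandError, InvalidBandError
from .io_qc import BoldRun


@dataclass(frozen=True)
class FrequencyBand:
    """Named frequency interval [f_low, f_high) in Hz; optionally closed above."""

    name: str
    f_low: float
    f_high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise InvalidBandError(f"need 0 <= f_low < f_high, got [{self.f_low}, {self.f_high})")

    def contains(self, f):
        """Vectorized membership of frequencies in the band."""
        f = np.asarray(f, dtype=float)
        inside = (f >= self.f_low) & (f < self.f_high)
        if self.closed_high:
            inside |= np.isclose(f, self.f_high, rtol=0.0, atol=1e-12)
        return inside


SLOW_6 = FrequencyBand("slow-6", 0.0, 0.01)
SLOW_5 = FrequencyBand("slow-5", 0.01, 0.027)
SLOW_4 = FrequencyBand("slow-4", 0.027, 0.073)
SLOW_3 = FrequencyBand("slow-3", 0.073, 0.198)
SLOW_2 = FrequencyBand("slow-2", 0.198, 0.25, closed_high=True)

_CANONICAL = (SLOW_6, SLOW_5, SLOW_4, SLOW_3, SLOW_2)


def standard_bands() -> tuple[FrequencyBand, ...]:
    """The five canonical LFO sub-bands, slow-6 ... slow-2.

    They partition (0, 0.25] Hz with no gaps or overlaps under the half-open
    convention (slow-2 closed at Nyquist).
    """
    return _CANONICAL


def band_by_name(name: str) -> FrequencyBand:
    key = name.lower().replace("_", "-").replace("slow", "slow-").replace("--", "-")
    for band in _CANONICAL:
        if band.name == key:
            return band
    raise InvalidBandError(f"unknown band {name!r}; expected one of "
                           f"{[b.name for b in _CANONICAL]}")


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum; last axis of ``amplitudes`` is frequency."""

    amplitudes: np.ndarray  # (..., n_bins), >= 0
    frequencies: np.ndarray  # (n_bins,), k * df for k = 0 .. floor(N/2)
    df: float  # Hz, = 1 / (N * TR)
    n_timepoints: int
    tr_seconds: float

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


def amplitude_spectrum(series: np.ndarray, tr_seconds: float) -> AmplitudeSpectrum:
    """One-sided FFT amplitude spectrum of (already detrended) series.

    Accepts any array with time on the last axis.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 8:
        raise DomainError("amplitude_spectrum needs at least 8 timepoints")
    if tr_seconds <= 0:
        raise DomainError("tr_seconds must be positive")
    x = np.fft.rfft(series, axis=-1)
    amp = (2.0 / n) * np.abs(x)
    amp[..., 0] /= 2.0  # DC: |X_0| / N
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist: |X_{N/2}| / N
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return AmplitudeSpectrum(
        amplitudes=amp,
        frequencies=freqs,
        df=1.0 / (n * tr_seconds),
        n_timepoints=n,
        tr_seconds=tr_seconds,
    )


def band_bin_mask(spectrum: AmplitudeSpectrum, band: FrequencyBand) -> np.ndarray:
    """Boolean mask over bins whose centre lies in the band (DC always excluded)."""
    if band.f_low >= spectrum.nyquist_hz + 1e-12:
        raise InvalidBandError(
            f"band {band.name} [{band.f_low}, {band.f_high}) lies above the "
            f"Nyquist frequency {spectrum.nyquist_hz} Hz"
        )
    mask = band.contains(spectrum.frequencies) & (spectrum.frequencies > 0)
    if not mask.any():
        raise EmptyBandError(f"band {band.name} contains no frequency bin at df={spectrum.df}")
    return mask


def band_alff(spectrum: AmplitudeSpectrum, band: FrequencyBand) -> np.ndarray:
    """Mean amplitude over the band's bins — the (raw) ALFF. Scalar for 1D input."""
    mask = band_bin_mask(spectrum, band)
    out = spectrum.amplitudes[..., mask].mean(axis=-1)
    return out if out.ndim else float(out)


def falff(spectrum: AmplitudeSpectrum, band: FrequencyBand) -> np.ndarray:
    """Band amplitude sum over total nonzero-frequency amplitude sum, in [0, 1].

    Voxels with zero total amplitude get NaN (undefined), not an exception.
    """
    mask = band_bin_mask(spectrum, band)
    nonzero = spectrum.frequencies > 0
    num = spectrum.amplitudes[..., mask].sum(axis=-1)
    den = spectrum.amplitudes[..., nonzero].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if np.ndim(out) else float(out)


def normalize_global(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a map by its in-mask mean; out-of-mask voxels become NaN."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise DomainError("map and mask shapes differ")
    if not mask.any():
        raise DomainError("mask is empty")
    mean = float(np.nanmean(values[mask]))
    if not np.isfinite(mean) or mean <= 0:
        raise DegenerateInputError(f"in-mask mean must be positive, got {mean}")
    out = np.full(values.shape, np.nan)
    out[mask] = values[mask] / mean
    return out


@dataclass
class BandMaps:
    """Per-band voxel maps for one subject: raw ALFF, normalized ALFF, fALFF."""

    alff: dict[str, np.ndarray]
    alff_norm: dict[str, np.ndarray]
    falff: dict[str, np.ndarray]
    mask: np.ndarray
    df: float
    n_timepoints: int
    tr_seconds: float


def compute_band_maps(
    run: BoldRun,
    mask: Optional[np.ndarray] = None,
    bands: Optional[Sequence[FrequencyBand]] = None,
    normalize: bool = True,
) -> BandMaps:
    """Voxelwise amplitude spectra then ALFF / normalized ALFF / fALFF per band.

    Expects a preprocessed (detrended, optionally smoothed) run.  Out-of-mask
    voxels are NaN in every output map.
    """
    if mask is None:
        mask = np.ones(run.grid.dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.grid.dims:
        raise DomainError("mask shape does not match run grid")
    if not mask.any():
        raise DomainError("mask is empty")
    if bands is None:
        bands = standard_bands()

    spec = amplitude_spectrum(run.data[mask], run.tr_seconds)  # (V, n_bins)

    def fill(values: np.ndarray) -> np.ndarray:
        out = np.full(run.grid.dims, np.nan)
        out[mask] = values
        return out

    alff_maps: dict[str, np.ndarray] = {}
    norm_maps: dict[str, np.ndarray] = {}
    falff_maps: dict[str, np.ndarray] = {}
    for band in bands:
        raw = fill(np.asarray(band_alff(spec, band)))
        alff_maps[band.name] = raw
        if normalize:
            norm_maps[band.name] = normalize_global(raw, mask)
        falff_maps[band.name] = fill(np.asarray(falff(spec, band)))
    return BandMaps(
        alff=alff_maps,
        alff_norm=norm_maps,
        falff=falff_maps,
        mask=mask,
        df=spec.df,
        n_timepoints=spec.n_timepoints,
        tr_seconds=run.tr_seconds,
    )
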