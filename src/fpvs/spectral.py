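"""Amplitude spectra and oddball quantification.

The dependent measure of the whole pipeline is computed here: single-sided
FFT amplitude spectra normalised by N/2 (so a cosine of peak amplitude A at
a bin-centred frequency reads A µV in its bin), baseline subtraction
against the surrounding noise bins, z-scores against the same noise bins,
data-driven harmonic selection, and the summed oddball response.

No taper is applied: epochs are cropped to an integer number of oddball
cycles, which makes the stimulation frequencies (and their harmonics)
essentially bin-centred, so the rectangular window is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import (F_BASE, F_ODD, MAX_HARMONIC_MULTIPLE, Z_THRESHOLD,
                     NoiseWindow)
from .containers import Epoch


@dataclass
class AmplitudeSpectrum:
    """Per-channel single-sided amplitude spectrum on a uniform grid."""

    freqs: np.ndarray
    amps: np.ndarray          # channels x bins, µV
    labels: tuple[str, ...]

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if self.amps.shape != (len(self.labels), len(self.freqs)):
            raise ValueError("amps must be (n_channels, n_bins)")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def channel_amps(self, channel) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.channel_index(channel)
        return self.amps[channel]

    def mean_over_channels(self) -> "AmplitudeSpectrum":
        return AmplitudeSpectrum(freqs=self.freqs,
                                 amps=self.amps.mean(axis=0, keepdims=True),
                                 labels=("grand-average",))


@dataclass
class OddballResponse:
    """Baseline-subtracted oddball amplitudes for one channel."""

    channel: str
    target_freqs: np.ndarray
    per_freq_bs: np.ndarray
    z_per_freq: np.ndarray
    summed_bs: float = field(init=False)

    def __post_init__(self):
        self.summed_bs = float(np.sum(self.per_freq_bs))


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """N/2-normalised single-sided amplitude spectrum of an epoch."""
    n = epoch.n_samples
    if n == 0:
        raise ValueError("empty epoch")
    amps = np.abs(np.fft.rfft(epoch.data, axis=1)) / (n / 2.0)
    amps[:, 0] /= 2.0          # DC is not split across +/- frequencies
    if n % 2 == 0:
        amps[:, -1] /= 2.0     # neither is Nyquist
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, labels=epoch.labels)


def grand_average(spectra) -> AmplitudeSpectrum:
    """Mean amplitude spectrum over spectra (and their channels)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0].freqs
    for s in spectra[1:]:
        if len(s.freqs) != len(ref) or abs(s.df - spectra[0].df) > 1e-12:
            raise ValueError("spectra are on different frequency grids")
    mean = np.mean([s.amps.mean(axis=0) for s in spectra], axis=0)
    return AmplitudeSpectrum(freqs=ref, amps=mean[None, :],
                             labels=("grand-average",))


def harmonic_frequencies(f_odd: float = F_ODD,
                         max_multiple: int = MAX_HARMONIC_MULTIPLE,
                         f_base: float = F_BASE) -> np.ndarray:
    """Oddball multiples 1..max, excluding multiples of the base rate."""
    if max_multiple < 1:
        raise ValueError("max_multiple must be >= 1")
    out = []
    for k in range(1, max_multiple + 1):
        ratio = k * f_odd / f_base
        if abs(ratio - round(ratio)) < 1e-9:
            continue
        out.append(k * f_odd)
    return np.array(out)


def nearest_bin(spectrum: AmplitudeSpectrum, target: float) -> int:
    """Index of the grid bin nearest ``target``; ties go to the lower bin."""
    if not 0 <= target <= spectrum.freqs[-1]:
        raise ValueError(f"target {target} Hz outside the spectrum")
    q = target / spectrum.df
    lo = int(np.floor(q))
    return lo if q - lo <= 0.5 else lo + 1


def _noise_offsets(window: NoiseWindow) -> np.ndarray:
    # n_side bins per side surround the target; the n_exclude nearest of
    # them are dropped, so 2 * (n_side - n_exclude) bins contribute
    one_side = np.arange(window.n_exclude + 1, window.n_side + 1)
    return np.concatenate([-one_side[::-1], one_side])


def noise_bin_indices(spectrum: AmplitudeSpectrum, bin_index: int,
                      window: NoiseWindow) -> np.ndarray:
    """Indices of the noise bins around ``bin_index``.

    If the window would cross a spectrum edge it is shrunk symmetrically
    (with a warning) so both sides always contribute equally.
    """
    offsets = _noise_offsets(window)
    n_bins = len(spectrum.freqs)
    max_off = window.n_side
    over = max(0, max_off - bin_index, bin_index + max_off - (n_bins - 1))
    if over:
        warnings.warn("noise window exceeds spectrum edge; shrinking "
                      f"symmetrically by {over} bins per side", stacklevel=2)
        keep = np.abs(offsets) <= max_off - over
        offsets = offsets[keep]
        if len(offsets) == 0:
            raise ValueError("no noise bins available at spectrum edge")
    return bin_index + offsets


def baseline_subtracted_amplitude(spectrum: AmplitudeSpectrum, channel,
                                  bin_index: int,
                                  window: NoiseWindow | None = None
                                  ) -> float:
    """Amplitude at a bin minus the mean of its surrounding noise bins.

    May be negative; no clipping is applied.
    """
    window = window or NoiseWindow()
    amps = spectrum.channel_amps(channel)
    noise = amps[noise_bin_indices(spectrum, bin_index, window)]
    return float(amps[bin_index] - noise.mean())


def zscore_amplitude(spectrum: AmplitudeSpectrum, channel, bin_index: int,
                     window: NoiseWindow | None = None) -> float:
    """(amplitude - noise mean) / noise SD over the same noise bins.

    Sample SD (n-1).  Zero noise SD maps to +/-inf for a non-zero
    numerator and to 0.0 for a zero numerator.
    """
    window = window or NoiseWindow()
    amps = spectrum.channel_amps(channel)
    noise = amps[noise_bin_indices(spectrum, bin_index, window)]
    num = amps[bin_index] - noise.mean()
    sd = noise.std(ddof=1)
    if sd == 0:
        return 0.0 if num == 0 else float(np.sign(num) * np.inf)
    return float(num / sd)


def significant_run(z_by_multiple: dict[int, float],
                    z_threshold: float = Z_THRESHOLD,
                    base_every: int = 5) -> list[int]:
    """Maximal consecutive run of significant oddball multiples.

    Starts at the fundamental (always retained); multiples coinciding with
    the base rate (every ``base_every``-th) are skipped without breaking
    the run; the first non-significant multiple ends it.
    """
    retained = [1]
    if z_by_multiple.get(1, -np.inf) <= z_threshold:
        return retained  # run broken at the fundamental (still retained)
    k = 2
    while k in z_by_multiple or k % base_every == 0:
        if k % base_every == 0:
            k += 1
            continue
        if z_by_multiple[k] > z_threshold:
            retained.append(k)
            k += 1
        else:
            break
    return retained


def select_harmonics(grand_avg: AmplitudeSpectrum,
                     f_odd: float = F_ODD, f_base: float = F_BASE,
                     z_threshold: float = Z_THRESHOLD,
                     window: NoiseWindow | None = None,
                     max_multiple: int = 20) -> np.ndarray:
    """Data-driven harmonic set from grand-average z-scores.

    Scans oddball multiples (base multiples excluded) and keeps the maximal
    consecutive significant run starting at the fundamental.
    """
    window = window or NoiseWindow()
    spec = (grand_avg if len(grand_avg.labels) == 1
            else grand_avg.mean_over_channels())
    z = {}
    for k in range(1, max_multiple + 1):
        f = k * f_odd
        ratio = f / f_base
        if abs(ratio - round(ratio)) < 1e-9 or f > spec.freqs[-1]:
            continue
        z[k] = zscore_amplitude(spec, 0, nearest_bin(spec, f), window)
    retained = significant_run(z, z_threshold)
    return np.array([k * f_odd for k in retained])


def oddball_response(spectrum: AmplitudeSpectrum, channel,
                     target_freqs, window: NoiseWindow | None = None
                     ) -> OddballResponse:
    """Baseline-subtracted amplitudes at the target bins and their sum."""
    window = window or NoiseWindow()
    target_freqs = np.asarray(target_freqs, dtype=float)
    bs, z = [], []
    for f in target_freqs:
        b = nearest_bin(spectrum, f)
        bs.append(baseline_subtracted_amplitude(spectrum, channel, b,
                                                window))
        z.append(zscore_amplitude(spectrum, channel, b, window))
    label = channel if isinstance(channel, str) \
        else spectrum.labels[channel]
    return OddballResponse(channel=label, target_freqs=target_freqs,
                           per_freq_bs=np.array(bs), z_per_freq=np.array(z))


def base_response(spectrum: AmplitudeSpectrum, channel,
                  f_base: float = F_BASE,
                  window: NoiseWindow | None = None,
                  f_max: float = 70.0) -> float:
    """Summed baseline-subtracted response at the base rate + harmonics."""
    targets = base_target_frequencies(f_base, f_max,
                                      float(spectrum.freqs[-1]))
    return oddball_response(spectrum, channel, targets, window).summed_bs


def base_target_frequencies(f_base: float = F_BASE, f_max: float = 70.0,
                            grid_max: float = np.inf) -> np.ndarray:
    """Multiples of the base rate up to ``f_max`` (and the grid limit)."""
    out, k = [], 1
    while k * f_base <= min(f_max, grid_max):
        out.append(k * f_base)
        k += 1
    return np.array(out)
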