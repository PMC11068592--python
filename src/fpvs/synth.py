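"""Ground-truthed synthetic EEG for the oddball frequency-tagging design.

The generator emulates what the analysis chain assumes about the real data:

* steady-state sinusoidal responses at the base rate (5.77 Hz) and the
  oddball rate (1.154 Hz) plus harmonics, with a parieto-occipital /
  frontocentral topography,
* condition- and group-dependent oddball amplitudes (the designed effect
  structure lives in :func:`fpvs.config._default_oddball_amp`),
* 1/f background noise, mains interference and blink artifacts.

Two modelling choices matter downstream.  First, every spatial response
pattern sums to zero across the montage (posterior/frontocentral positivity
balanced by a distributed counter-weight over the remaining electrodes), so
common-average re-referencing leaves the injected signal untouched and the
recorded ground-truth amplitudes remain valid after preprocessing.  Second,
with ``snap_to_grid`` (default) the injected frequencies are snapped to the
FFT grid of the integer-cycle analysis window, i.e. the simulated steady
state is exactly periodic over the window the analysis will use — the
idealisation the rectangular-window FFT quantification is built on.

Configured oddball/base amplitudes are *totals*: the summed amplitude over
all injected harmonics of that response, matching the summed
baseline-subtracted amplitude the analysis reports.  Individual harmonics
decay geometrically with ``harmonic_rolloff``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FC, GROUPS, PO, SimulationConfig
from .containers import Event, Recording
from .montage import (CLUSTERS, FRONTOCENTRAL, LEFT_PO, RIGHT_PO,
                      _REGION_NEIGHBOURS, Montage, make_montage)

#: within-region electrode weight: analysis-cluster electrodes respond at
#: full gain, the surrounding region electrodes at half gain
_CLUSTER_GAIN = 1.0
_NEIGHBOUR_GAIN = 0.5

#: blink topography by label prefix (longest prefix wins), peak at Fp1/Fp2
_BLINK_WEIGHTS = (("Fp", 1.0), ("AF", 0.6), ("FT", 0.2), ("FC", 0.15),
                  ("F", 0.35))
_BLINK_FLOOR = 0.02


def oddball_harmonic_orders(n_harmonics: int) -> list[int]:
    """Oddball multiples 1..n that do not coincide with a base multiple."""
    return [k for k in range(1, n_harmonics + 1) if k % 5 != 0]


def _harmonic_weights(orders: list[int], rolloff: float) -> np.ndarray:
    """Per-order fraction of the total amplitude (geometric decay)."""
    w = np.array([rolloff ** (k - 1) for k in orders], dtype=float)
    return w / w.sum()


def blink_weight(label: str) -> float:
    for prefix, w in _BLINK_WEIGHTS:
        if label.startswith(prefix):
            return w
    return _BLINK_FLOOR


def pink_noise(n_samples: int, exponent: float, rng: np.random.Generator,
               n_channels: int = 1) -> np.ndarray:
    """1/f-shaped Gaussian noise, one unit-SD row per channel.

    Power falls as f**-exponent, so the amplitude spectrum falls as
    f**-(exponent/2).
    """
    n_bins = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples)
    shape = np.zeros(n_bins)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, n_bins))
            + 1j * rng.standard_normal((n_channels, n_bins))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@dataclass
class GroundTruth:
    """Injected per-harmonic amplitudes plus the blink regressor."""

    table: pd.DataFrame
    blink_trace: np.ndarray | None = None

    def summed_oddball(self, channels=None) -> float:
        """Total injected oddball amplitude, averaged over ``channels``."""
        t = self.table[self.table["kind"] == "oddball"]
        if channels is not None:
            t = t[t["channel"].isin(list(channels))]
        per_channel = t.groupby("channel")["amplitude_uV"].sum()
        return float(per_channel.mean())


def _subject_rng(config: SimulationConfig, subject_id: str
                 ) -> np.random.Generator:
    crc = zlib.crc32(subject_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 101, crc]))


def _recording_rng(config: SimulationConfig, subject_id: str,
                   condition: str, stimulus_type: str) -> np.random.Generator:
    crc = zlib.crc32(subject_id.encode())
    ci = list(config.conditions).index(condition)
    si = list(config.stimulus_types).index(stimulus_type)
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 202, crc, ci, si]))


def subject_effects(config: SimulationConfig, subject_id: str
                    ) -> tuple[float, float, float]:
    """Per-subject amplitude offset (µV) and response phases (rad)."""
    rng = _subject_rng(config, subject_id)
    delta = rng.normal(0.0, config.between_subject_sd) \
        if config.between_subject_sd > 0 else 0.0
    psi, phi = rng.uniform(0.0, 2 * np.pi, size=2)
    return float(delta), float(psi), float(phi)


def _region_amplitude_map(montage: Montage, amp_po: float, amp_fc: float
                          ) -> np.ndarray:
    """Zero-sum per-channel amplitude pattern (µV) for one response.

    Cluster electrodes carry the configured amplitude at full gain, region
    neighbours at half gain; electrodes outside the three signal regions
    share a uniform negative counter-weight so the pattern sums to zero
    (hence is invariant under common-average re-referencing).
    """
    a = np.zeros(len(montage.labels))
    idx = {ch: i for i, ch in enumerate(montage.labels)}
    for region, amp in ((LEFT_PO, amp_po), (RIGHT_PO, amp_po),
                        (FRONTOCENTRAL, amp_fc)):
        for ch in CLUSTERS[region]:
            a[idx[ch]] += _CLUSTER_GAIN * amp
        for ch in _REGION_NEIGHBOURS[region]:
            a[idx[ch]] += _NEIGHBOUR_GAIN * amp
    other = [i for i, ch in enumerate(montage.labels)
             if montage.region[ch] == "other"]
    a[other] = -a.sum() / len(other)
    return a


def _snap(freqs: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if not config.snap_to_grid:
        return freqs
    df = config.fs / config.n_crop_samples
    return np.round(freqs / df) * df


def simulate_recording(config: SimulationConfig, subject_id: str, group: str,
                       condition: str, stimulus_type: str,
                       montage: Montage | None = None
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one train (with padding) for one subject/condition cell."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if stimulus_type not in config.stimulus_types:
        raise ValueError(f"unknown stimulus type {stimulus_type!r}")
    montage = montage or make_montage()

    n = int(round(config.recording_duration * config.fs))
    if n < config.n_crop_samples:
        raise ValueError("recording shorter than the integer-cycle window")
    t = np.arange(n) / config.fs
    data = np.zeros((len(montage.labels), n))

    delta, psi, phi = subject_effects(config, subject_id)
    amps = config.oddball_amp[group][stimulus_type][condition]
    amp_po = max(0.0, amps[PO] + delta)
    amp_fc = max(0.0, amps[FC] + delta)

    # oddball response
    a_odd = _region_amplitude_map(montage, amp_po, amp_fc)
    odd_orders = oddball_harmonic_orders(config.n_harmonics)
    odd_w = _harmonic_weights(odd_orders, config.harmonic_rolloff)
    f_odd = _snap(np.array(odd_orders) * config.f_odd, config)
    for fk, wk in zip(f_odd, odd_w):
        data += np.outer(a_odd * wk, np.cos(2 * np.pi * fk * t + psi))

    # base-rate response
    a_base = _region_amplitude_map(montage, config.base_amp.get(PO, 0.0),
                                   config.base_amp.get(FC, 0.0))
    base_orders = list(range(1, config.n_base_harmonics + 1))
    base_w = _harmonic_weights(base_orders, config.harmonic_rolloff)
    f_bas = _snap(np.array(base_orders) * config.f_base, config)
    for fj, wj in zip(f_bas, base_w):
        data += np.outer(a_base * wj, np.cos(2 * np.pi * fj * t + phi))

    rng = _recording_rng(config, subject_id, condition, stimulus_type)
    if config.noise_scale > 0:
        data += config.noise_scale * pink_noise(
            n, config.noise_exponent, rng, n_channels=len(montage.labels))
    if config.line_amp > 0:
        gains = rng.uniform(0.5, 1.5, size=len(montage.labels))
        theta = rng.uniform(0, 2 * np.pi)
        data += config.line_amp * np.outer(
            gains, np.sin(2 * np.pi * config.line_freq * t + theta))

    blink_trace = None
    if config.blink_amp > 0 and config.blink_rate > 0:
        blink_trace = np.zeros(n)
        n_blinks = rng.poisson(config.blink_rate / 60.0 * (n / config.fs))
        width = int(round(config.blink_width * config.fs))
        kernel = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        starts = rng.integers(0, max(1, n - width), size=n_blinks)
        for s in starts:
            blink_trace[s:s + width] += kernel
        weights = np.array([blink_weight(ch) for ch in montage.labels])
        data += config.blink_amp * np.outer(weights, blink_trace)

    event = Event(sample=int(round(config.pad_s * config.fs)),
                  condition=condition, stimulus_type=stimulus_type)
    rec = Recording(labels=montage.labels, fs=config.fs, data=data,
                    events=[event])

    rows = []
    for kind, gains, orders, weights, freqs in (
            ("oddball", a_odd, odd_orders, odd_w, f_odd),
            ("base", a_base, base_orders, base_w, f_bas)):
        for ch, g in zip(montage.labels, gains):
            for k, wk, fk in zip(orders, weights, freqs):
                rows.append((subject_id, group, condition, stimulus_type,
                             ch, kind, k, fk, abs(g) * wk))
    gt = GroundTruth(
        table=pd.DataFrame(rows, columns=[
            "subject", "group", "condition", "stimulus_type", "channel",
            "kind", "order", "frequency", "amplitude_uV"]),
        blink_trace=blink_trace)
    return rec, gt


def study_cells(config: SimulationConfig):
    """Yield (subject_id, group, condition, stimulus_type) for the design."""
    for group in GROUPS:
        for i in range(config.n_per_group.get(group, 0)):
            subject_id = f"{group}{i + 1:02d}"
            for stimulus_type in config.stimulus_types:
                for condition in config.conditions:
                    yield subject_id, group, condition, stimulus_type


def iter_study(config: SimulationConfig, montage: Montage | None = None):
    """Stream (Recording, GroundTruth) pairs for the whole study design."""
    montage = montage or make_montage()
    for subject_id, group, condition, stimulus_type in study_cells(config):
        yield simulate_recording(config, subject_id, group, condition,
                                 stimulus_type, montage=montage)


def simulate_study(config: SimulationConfig,
                   montage: Montage | None = None
                   ) -> list[tuple[Recording, GroundTruth]]:
    """Materialise the full study (prefer :func:`iter_study` for large n)."""
    if not any(v >= 1 for v in config.n_per_group.values()):
        raise ValueError("need at least one subject per study")
    return list(iter_study(config, montage=montage))


def inject_bad_channels(recording: Recording, labels, seed: int = 0
                        ) -> Recording:
    """Replace the listed channels with high-variance white noise."""
    labels = list(labels)
    if len(labels) > 2:
        warnings.warn(
            f"injecting {len(labels)} bad channels; recordings with more "
            "than two would normally be excluded", stacklevel=2)
    out = recording.copy()
    if not labels:
        return out
    idx = [recording.channel_index(ch) for ch in labels]
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(50.0) * np.median(recording.data.std(axis=1))
    sigma = sigma if sigma > 0 else 1.0
    out.data[idx] = rng.normal(0.0, sigma,
                               size=(len(idx), recording.n_samples))
    return out


def noise_only_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with every deterministic signal source silenced."""
    zero = {g: {s: {c: {PO: 0.0, FC: 0.0} for c in config.conditions}
                for s in config.stimulus_types} for g in GROUPS}
    return config.replace(oddball_amp=zero, base_amp={PO: 0.0, FC: 0.0},
                          line_amp=0.0, blink_amp=0.0)


# ---------------------------------------------------------------------------
# direct ROI-table generator (for statistical calibration at scale)
# ---------------------------------------------------------------------------

def harmonic_sum_fraction(config: SimulationConfig, max_multiple: int
                          ) -> float:
    """Fraction of the total oddball amplitude carried by multiples
    1..max_multiple (base-coincident multiples excluded)."""
    all_orders = oddball_harmonic_orders(config.n_harmonics)
    w = _harmonic_weights(all_orders, config.harmonic_rolloff)
    return float(sum(wk for k, wk in zip(all_orders, w)
                     if k <= max_multiple))


def simulate_subject_table(config: SimulationConfig, seed: int
                           ) -> pd.DataFrame:
    """Draw a subject x condition ROI table directly from the design.

    Produces the same quantity the full pipeline yields after spectral
    quantification and ROI averaging — cluster value = configured total
    amplitude + subject offset (truncated at zero) + residual cell noise of
    SD ``table_noise_sd`` — without simulating any time series.  Used for
    power and type-I calibration at replicate counts the full chain could
    not reach.
    """
    rng = np.random.default_rng(seed)
    rois = (("left-PO", "left", PO), ("right-PO", "right", PO),
            ("frontocentral", "n/a", FC))
    rows = []
    for group in GROUPS:
        for i in range(config.n_per_group.get(group, 0)):
            subject_id = f"{group}{i + 1:02d}"
            delta = rng.normal(0.0, config.between_subject_sd) \
                if config.between_subject_sd > 0 else 0.0
            for stimulus_type in config.stimulus_types:
                for condition in config.conditions:
                    amps = config.oddball_amp[group][stimulus_type][condition]
                    for roi, lat, region in rois:
                        value = (max(0.0, amps[region] + delta)
                                 + rng.normal(0.0, config.table_noise_sd))
                        rows.append((subject_id, group, stimulus_type,
                                     condition, roi, lat, value))
    return pd.DataFrame(rows, columns=[
        "subject", "group", "stimulus_type", "condition", "roi",
        "laterality", "value"])
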