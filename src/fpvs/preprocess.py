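"""Preprocessing chain: re-reference, interpolate, filter, segment, ICA,
integer-cycle cropping.

The chain mirrors standard frequency-tagging practice: common-average
re-reference, interpolation of (at most a couple of) bad channels, a
0.1–70 Hz zero-phase band-pass, segmentation into one epoch per condition,
ICA-based ocular correction, and cropping to an integer number of oddball
cycles so that the stimulation frequencies fall exactly on FFT bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import signal as sps

from .config import F_ODD, N_CYCLES, SEGMENT_S
from .containers import AS_RECORDED, AVERAGE, Epoch, Recording
from .montage import Montage, make_montage

logger = logging.getLogger(__name__)


def rereference_average(recording: Recording) -> Recording:
    """Re-reference to the common average (cross-channel mean -> 0)."""
    if recording.reference == AVERAGE:
        warnings.warn("recording is already average-referenced; no-op",
                      stacklevel=2)
        return recording.copy()
    out = recording.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    out.reference = AVERAGE
    return out


def interpolate_bad_channels(recording: Recording, bad_labels,
                             montage: Montage | None = None,
                             k: int = 6) -> Recording:
    """Replace bad channels by a distance-weighted local linear fit.

    The ``k`` nearest good neighbours (unit-sphere positions) are fitted
    with an inverse-distance-weighted first-order model (intercept +
    3-D gradient) which is then evaluated at the bad electrode.  Unlike a
    plain weighted mean, this reproduces any linearly varying scalp
    potential exactly, including at edge electrodes where all neighbours
    lie to one side.
    """
    bad_labels = list(bad_labels)
    if not bad_labels:
        return recording.copy()
    if len(bad_labels) > 2:
        warnings.warn(
            f"interpolating {len(bad_labels)} channels; more than two "
            "would normally lead to exclusion", stacklevel=2)
    montage = montage or make_montage()
    good = [ch for ch in recording.labels if ch not in set(bad_labels)]
    if not good:
        raise ValueError("all channels marked bad")
    out = recording.copy()
    for bad in bad_labels:
        bi = recording.channel_index(bad)  # raises KeyError if unknown
        p_bad = montage.positions[bad]
        dists = np.array([np.linalg.norm(montage.positions[ch] - p_bad)
                          for ch in good])
        order = np.argsort(dists)[:k]
        chosen = [good[j] for j in order]
        w = np.sqrt(1.0 / np.maximum(dists[order], 1e-12))
        X = np.column_stack([np.ones(len(chosen)),
                             montage.position_array(chosen)])
        Y = np.array([recording.channel(ch) for ch in chosen])
        beta, *_ = np.linalg.lstsq(X * w[:, None], Y * w[:, None],
                                   rcond=None)
        out.data[bi] = np.concatenate([[1.0], p_bad]) @ beta
        logger.info("interpolated %s from %s", bad, chosen)
    return out


def bandpass(recording: Recording, lo: float = 0.1, hi: float = 70.0
             ) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass."""
    nyq = recording.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz reaches Nyquist ({nyq} Hz)")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=recording.fs,
                     output="sos")
    out = recording.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    return out


def segment(recording: Recording, condition: str, stimulus_type: str,
            duration: float = SEGMENT_S) -> Epoch:
    """Cut the epoch starting at the matching train-onset event."""
    matches = [ev for ev in recording.events
               if ev.condition == condition
               and ev.stimulus_type == stimulus_type]
    if not matches:
        raise ValueError(
            f"no event for {condition!r}/{stimulus_type!r} in recording")
    start = matches[0].sample
    n = int(round(duration * recording.fs))
    if start + n > recording.n_samples:
        raise ValueError("epoch exceeds recording end")
    return Epoch(labels=recording.labels, fs=recording.fs,
                 data=recording.data[:, start:start + n].copy(),
                 condition=condition, stimulus_type=stimulus_type,
                 reference=recording.reference)


def crop_to_integer_cycles(epoch: Epoch, f_odd: float = F_ODD,
                           n_cycles: int = N_CYCLES) -> Epoch:
    """Crop (from epoch start) to exactly ``n_cycles`` oddball cycles."""
    n = int(n_cycles / f_odd * epoch.fs)
    if n > epoch.n_samples:
        raise ValueError("epoch too short for the requested cycle count")
    out = replace(epoch, data=epoch.data[:, :n].copy(), n_cycles=n_cycles)
    return out


def _virtual_eog(epoch: Epoch) -> np.ndarray:
    try:
        return 0.5 * (epoch.channel("Fp1") + epoch.channel("Fp2"))
    except KeyError:
        raise ValueError("ocular correction needs Fp1 and Fp2") from None


#: robust EOG excursion (µV) below which the epoch is treated as blink-free
BLINK_FLOOR_UV = 30.0


def ocular_correct(epoch: Epoch, threshold: float = 0.8,
                   random_state: int = 0, max_iter: int = 200,
                   fit_decim: int = 3) -> tuple[Epoch, int]:
    """Remove ocular components by ICA.

    A square(-up-to-rank) FastICA decomposition is computed and components
    whose absolute correlation with the virtual EOG (mean of Fp1/Fp2)
    exceeds ``threshold`` are zeroed before back-projection.  The unmixing
    matrix is estimated on temporally decimated data (``fit_decim``) and
    applied at the full rate — blink sources are broadband, so decimation
    does not affect their identifiability.  Epochs whose EOG shows no
    blink-scale excursions (robust amplitude below ``BLINK_FLOOR_UV``) are
    returned unchanged — ocular correction has nothing to correct, and
    steady-state signal leaking into a frontal "EOG" must not be
    subtracted.  If the decomposition fails, a regression-based EOG
    subtraction is used instead (logged).
    """
    if len(epoch.labels) < 2:
        raise ValueError("need at least two channels for ICA")
    eog = _virtual_eog(epoch)
    excursion = np.percentile(np.abs(eog - np.median(eog)), 99)
    if excursion < BLINK_FLOOR_UV:
        return epoch.copy(), 0

    X = epoch.data
    mean = X.mean(axis=1, keepdims=True)
    centered = X - mean
    try:
        from sklearn.decomposition import FastICA

        svals = np.linalg.svd(centered, compute_uv=False)
        rank = int((svals > svals[0] * 1e-10).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = FastICA(n_components=rank, random_state=random_state,
                          max_iter=max_iter, tol=1e-3, whiten="unit-variance")
            ica.fit(centered[:, ::fit_decim].T)
        # full-rate sources: S = W (X - mean), back-projection X = A S
        fit_mean = ica.mean_[:, None]
        sources = ica.components_ @ (centered - fit_mean)
        r = np.array([abs(np.corrcoef(s, eog)[0, 1]) if s.std() > 0 else 0.0
                      for s in sources])
        remove = np.where(r > threshold)[0]
        sources[remove] = 0.0
        cleaned = ica.mixing_ @ sources + fit_mean + mean
        out = replace(epoch, data=cleaned)
        logger.info("ICA removed %d/%d components (|r|>%.2f)",
                    len(remove), rank, threshold)
        return out, int(len(remove))
    except Exception as exc:  # decomposition failure -> regression fallback
        logger.warning("ICA failed (%s); falling back to EOG regression",
                       exc)
        eog_c = eog - eog.mean()
        beta = centered @ eog_c / (eog_c @ eog_c)
        cleaned = X - np.outer(beta, eog_c)
        return replace(epoch, data=cleaned), 1


def preprocess_recording(recording: Recording, *,
                         bad_labels=(), band=(0.1, 70.0),
                         conditions=None, stimulus_types=None,
                         f_odd: float = F_ODD, n_cycles: int = N_CYCLES,
                         segment_s: float = SEGMENT_S,
                         ocular: bool = True, ica_threshold: float = 0.8,
                         ica_seed: int = 0,
                         montage: Montage | None = None):
    """Full chain for one recording; yields (Epoch, n_components_removed).

    Epochs are produced for every (condition, stimulus type) pair that has
    a matching event.
    """
    rec = rereference_average(recording)
    if bad_labels:
        rec = interpolate_bad_channels(rec, bad_labels, montage=montage)
    rec = bandpass(rec, *band)
    seen = {(ev.condition, ev.stimulus_type) for ev in rec.events
            if ev.condition is not None}
    if conditions is not None:
        seen = {(c, s) for c, s in seen if c in conditions}
    if stimulus_types is not None:
        seen = {(c, s) for c, s in seen if s in stimulus_types}
    for condition, stimulus_type in sorted(seen):
        ep = segment(rec, condition, stimulus_type, duration=segment_s)
        n_removed = 0
        if ocular:
            ep, n_removed = ocular_correct(ep, threshold=ica_threshold,
                                           random_state=ica_seed)
        ep = crop_to_integer_cycles(ep, f_odd=f_odd, n_cycles=n_cycles)
        yield ep, n_removed
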