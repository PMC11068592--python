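"""Calibration and validation studies for the pipeline.

These functions re-measure, by simulation, the statistical properties the
pipeline relies on: the null behaviour of the z-threshold used for
harmonic selection, the type-I error of the headline group-interaction
test, parameter recovery of injected oddball amplitudes, and the detection
rate of the designed group effect structure.  They are used both by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .montage import CLUSTERS, FRONTOCENTRAL, LEFT_PO, RIGHT_PO, make_montage
from .preprocess import bandpass, crop_to_integer_cycles, rereference_average, segment
from .spectral import (amplitude_spectrum, harmonic_frequencies, nearest_bin,
                       oddball_response, zscore_amplitude)
from .stats import effect_p, mixed_anova, run_study_contrasts
from .synth import (noise_only_config, simulate_recording,
                    simulate_subject_table)


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, tag])
               .generate_state(1)[0] % (2 ** 31))


def null_z_exceedance(seed: int, n_bins: int = 10000,
                      z_threshold: float = 2.32) -> tuple[float, int]:
    """Fraction of signal-free spectrum bins whose z exceeds threshold.

    Simulates noise-only recordings through the preprocessing chain and
    z-scores bins across 2-45 Hz (away from spectrum edges and the
    stimulation frequencies, which carry no signal here anyway).
    """
    montage = make_montage()
    cfg = noise_only_config(SimulationConfig(
        seed=_child_seed(seed, 1), between_subject_sd=0.0))
    count = 0
    total = 0
    subj = 0
    while total < n_bins:
        subj += 1
        rec, _ = simulate_recording(cfg.replace(
            seed=_child_seed(seed, 100 + subj)), f"N{subj:02d}", "NT",
            "Self", "Faces", montage=montage)
        ep = crop_to_integer_cycles(segment(
            bandpass(rereference_average(rec)), "Self", "Faces"))
        spec = amplitude_spectrum(ep)
        lo = nearest_bin(spec, 2.0)
        hi = nearest_bin(spec, 45.0)
        step = max(1, (hi - lo) * len(spec.labels) // n_bins)
        for ci in range(len(spec.labels)):
            for b in range(lo, hi, step):
                z = zscore_amplitude(spec, ci, b)
                count += z > z_threshold
                total += 1
                if total >= n_bins:
                    break
            if total >= n_bins:
                break
    return count / total, total


def anova_type1_rate(seed: int, n_reps: int = 1000,
                     n_per_group: dict | None = None,
                     alpha: float = 0.05) -> tuple[float, int]:
    """Type-I rate of the Condition x Group interaction under a null
    (flat-amplitude) design, at reduced sample size for speed."""
    n_per_group = n_per_group or {"NT": 8, "autism": 8}
    cfg = SimulationConfig(n_per_group=n_per_group).flat_amplitudes()
    hits = 0
    for i in range(n_reps):
        table = simulate_subject_table(cfg, seed=_child_seed(seed,
                                                             2000 + i))
        po = table[table["roi"].isin(["left-PO", "right-PO"])]
        means = (po.groupby(["subject", "group", "stimulus_type",
                             "condition"], sort=False)["value"].mean()
                 .reset_index())
        anova = mixed_anova(means, within=("stimulus_type", "condition"))
        hits += effect_p(anova, "condition * group") < alpha
    return hits / n_reps, n_reps


@dataclass
class RecoveryResult:
    slope: float
    intercept: float
    n_points: int


def recovery_regression(seed: int, n_subjects: int = 50
                        ) -> RecoveryResult:
    """Regress recovered summed baseline-subtracted amplitude on the
    injected ground-truth total, across simulated subjects.

    Each subject contributes one Faces recording (conditions cycled
    across subjects' three trains) at the default noise level; the
    quantification chain is re-reference, band-pass, integer-cycle crop
    and spectral extraction over the design's harmonic set.  Blink
    artifacts are disabled so the regression isolates the spectral
    quantification (artifact correction is validated separately).
    """
    montage = make_montage()
    cfg = SimulationConfig(seed=_child_seed(seed, 3),
                           blink_amp=0.0)
    targets = harmonic_frequencies()
    clusters = {name: CLUSTERS[region] for name, region in (
        ("left-PO", LEFT_PO), ("right-PO", RIGHT_PO),
        ("frontocentral", FRONTOCENTRAL))}
    xs, ys = [], []
    for i in range(n_subjects):
        subject = f"S{i:03d}"
        for cond in cfg.conditions:
            rec, gt = simulate_recording(cfg, subject, "NT", cond,
                                         "Faces", montage=montage)
            ep = crop_to_integer_cycles(segment(
                bandpass(rereference_average(rec)), cond, "Faces"))
            spec = amplitude_spectrum(ep)
            for electrodes in clusters.values():
                ys.append(np.mean([
                    oddball_response(spec, ch, targets).summed_bs
                    for ch in electrodes]))
                xs.append(gt.summed_oddball(electrodes))
    slope, intercept = np.polyfit(xs, ys, 1)
    return RecoveryResult(float(slope), float(intercept), len(xs))


@dataclass
class EffectStructureResult:
    faces_detections: int
    names_detections: int
    reversed_orderings: int
    n_reps: int


def effect_structure_replicates(seed: int, n_reps: int = 100,
                                n_per_group: dict | None = None
                                ) -> EffectStructureResult:
    """Replicate the designed study at the ROI-table level and count how
    often the analysis plan flags the Faces Condition x Group interaction
    (and how often the group difference comes out reversed)."""
    n_per_group = n_per_group or {"NT": 24, "autism": 20}
    cfg = SimulationConfig(n_per_group=n_per_group)
    faces = names = reversed_count = 0
    for i in range(n_reps):
        table = simulate_subject_table(cfg, seed=_child_seed(seed,
                                                             4000 + i))
        rep = run_study_contrasts(table)
        faces += rep.detects_condition_group_interaction("Faces")
        names += rep.detects_condition_group_interaction("Names")
        reversed_count += rep.reversed_self_close_group_difference()
    return EffectStructureResult(faces, names, reversed_count, n_reps)
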