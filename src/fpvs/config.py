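"""Experiment constants and the simulation / pipeline configuration objects.

All frequencies are in Hz, times in seconds, amplitudes in microvolts (µV).
The stimulation constants reproduce the oddball frequency-tagging design:
stimuli at a 5.77 Hz base rate with every fifth stimulus a deviant, giving a
1.154 Hz oddball rate; trains of 96 oddball cycles (~83.2 s) recorded at
500 Hz from 64 channels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

GROUPS = ("NT", "autism")
CONDITIONS = ("Self", "CloseOther", "Stranger")
STIMULUS_TYPES = ("Faces", "Names")

#: scalp regions that carry configured signal amplitude
PO = "parieto-occipital"
FC = "frontocentral"

F_BASE = 5.77
F_ODD = F_BASE / 5.0
FS = 500.0
N_CYCLES = 96
Z_THRESHOLD = 2.32
BAND = (0.1, 70.0)
SEGMENT_S = 84.0
MAX_HARMONIC_MULTIPLE = 8


def _default_oddball_amp() -> dict:
    """Designed total oddball response (µV, summed over harmonics) per
    group x condition x stimulus type x region.

    The structure encodes the target effect pattern: for faces, neurotypical
    responses are graded Self > CloseOther > Stranger in parieto-occipital
    cortex whereas the autism group shows Self = CloseOther > Stranger; for
    names both groups show a familiarity effect only (Self ~ CloseOther >
    Stranger, no group difference).  Absolute values sit on the µV scale
    typical for baseline-subtracted oddball responses and are sized so the
    designed group interaction is detectable at the study's sample sizes.
    """
    faces_nt = {"Self": {PO: 1.50, FC: 0.70},
                "CloseOther": {PO: 0.95, FC: 0.53},
                "Stranger": {PO: 0.36, FC: 0.20}}
    faces_aut = {"Self": {PO: 0.95, FC: 0.70},
                 "CloseOther": {PO: 0.95, FC: 0.53},
                 "Stranger": {PO: 0.36, FC: 0.20}}
    names = {"Self": {PO: 0.46, FC: 0.21},
             "CloseOther": {PO: 0.38, FC: 0.20},
             "Stranger": {PO: 0.22, FC: 0.07}}
    return {
        "NT": {"Faces": faces_nt, "Names": names},
        "autism": {"Faces": faces_aut, "Names": names},
    }


@dataclass
class NoiseWindow:
    """Noise bins used for baseline subtraction and z-scoring.

    ``n_side`` bins per side are treated as noise, after skipping
    ``n_exclude`` bins immediately adjacent to the bin of interest (to avoid
    signal leakage).  The defaults give the 20-bin (±0.12 Hz) surround with
    the two adjacent bins excluded, i.e. 18 usable noise bins.
    """

    n_side: int = 10
    n_exclude: int = 1

    def __post_init__(self):
        if not self.n_side > self.n_exclude >= 0:
            raise ValueError("require n_side > n_exclude >= 0")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-EEG generator."""

    f_base: float = F_BASE
    f_odd: float | None = None          # defaults to f_base / 5
    fs: float = FS
    n_cycles: int = N_CYCLES
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"NT": 24, "autism": 20})
    conditions: tuple[str, ...] = CONDITIONS
    stimulus_types: tuple[str, ...] = STIMULUS_TYPES
    oddball_amp: dict = field(default_factory=_default_oddball_amp)
    base_amp: dict = field(default_factory=lambda: {PO: 2.0, FC: 1.0})
    harmonic_rolloff: float = 0.6
    n_harmonics: int = MAX_HARMONIC_MULTIPLE   # oddball multiples scanned
    n_base_harmonics: int = 4                  # base-rate multiples injected
    noise_scale: float = 0.15                  # time-domain SD of 1/f noise, µV
    noise_exponent: float = 1.0                # power ~ f**-exponent
    line_freq: float = 50.0
    line_amp: float = 1.0
    blink_rate: float = 10.0                   # events / minute
    blink_amp: float = 80.0                    # µV at Fp1/Fp2
    blink_width: float = 0.3                   # seconds
    between_subject_sd: float = 0.15           # µV, on the total response
    table_noise_sd: float = 0.4                # µV, residual cell noise of the
                                               # direct ROI-table generator
    pad_s: float = 1.0                         # pre/post padding around train
    segment_s: float = SEGMENT_S
    snap_to_grid: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.f_odd is None:
            self.f_odd = self.f_base / 5.0
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if abs(self.f_base - 5 * self.f_odd) > 1e-9:
            raise ValueError("base frequency must be 5x the oddball frequency")
        if not 0 < self.harmonic_rolloff <= 1:
            raise ValueError("harmonic_rolloff must lie in (0, 1]")
        for g in self.oddball_amp:
            for s in self.oddball_amp[g]:
                for c in self.oddball_amp[g][s]:
                    for v in self.oddball_amp[g][s][c].values():
                        if v < 0:
                            raise ValueError("amplitudes must be >= 0")
        if any(v < 0 for v in self.base_amp.values()):
            raise ValueError("amplitudes must be >= 0")

    # -- durations -------------------------------------------------------
    @property
    def train_duration(self) -> float:
        """Duration of one integer-cycle train, n_cycles / f_odd (s)."""
        return self.n_cycles / self.f_odd

    @property
    def n_crop_samples(self) -> int:
        """Samples in the integer-cycle analysis window (floor rounding)."""
        return int(self.train_duration * self.fs)

    @property
    def recording_duration(self) -> float:
        return self.segment_s + 2 * self.pad_s

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def flat_amplitudes(self, po: float = 0.6, fc: float = 0.3
                        ) -> "SimulationConfig":
        """Copy of the config with identical oddball amplitudes in every
        group/condition/stimulus-type cell (a null-effect design)."""
        amp = {g: {s: {c: {PO: po, FC: fc} for c in self.conditions}
                   for s in self.stimulus_types} for g in GROUPS}
        return self.replace(oddball_amp=amp)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["stimulus_types"] = list(self.stimulus_types)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key in ("conditions", "stimulus_types"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; one seed governs all randomness."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band: tuple[float, float] = BAND
    ica_threshold: float = 0.8
    ocular_correction: bool = True
    noise_window: NoiseWindow = field(default_factory=NoiseWindow)
    max_harmonic_multiple: int = MAX_HARMONIC_MULTIPLE
    z_threshold: float = Z_THRESHOLD
    roi_mode: str = "fixed"            # "fixed" | "localizer"
    seed: int = 0

    def __post_init__(self):
        if self.roi_mode not in ("fixed", "localizer"):
            raise ValueError("roi_mode must be 'fixed' or 'localizer'")
        self.simulation = (
            self.simulation if isinstance(self.simulation, SimulationConfig)
            else SimulationConfig.from_dict(self.simulation))
        if not isinstance(self.noise_window, NoiseWindow):
            self.noise_window = NoiseWindow(**self.noise_window)
        # one seed governs the whole run; never mutate the caller's config
        self.simulation = self.simulation.replace(seed=self.seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "band": list(self.band),
            "ica_threshold": self.ica_threshold,
            "ocular_correction": self.ocular_correction,
            "noise_window": dataclasses.asdict(self.noise_window),
            "max_harmonic_multiple": self.max_harmonic_multiple,
            "z_threshold": self.z_threshold,
            "roi_mode": self.roi_mode,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
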