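"""Tiny BrainVision fixtures with declared ground truth, for I/O and unit
tests.  Everything is generated programmatically; nothing is shipped."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Event, Recording
from .io_brainvision import write_brainvision

FIXTURE_LABELS = ("Fp1", "Fp2", "Fz", "Cz", "P7", "PO7", "O1", "PO8")
FIXTURE_FS = 500.0
FIXTURE_DURATION = 10.0
TONE_FREQ = 1.154
TONE_AMP = 2.0
MARKER_SAMPLES = (500, 2000, 3500)


def make_fixtures(out_dir) -> dict[str, Path]:
    """Write the two fixture recordings; returns header paths by name.

    * ``tone``: a 2 µV, 1.154 Hz cosine on PO8 (all else silent), one
      Faces/Self marker.
    * ``markers``: low-amplitude fixed-seed noise with three condition
      markers (Faces Self / CloseOther / Stranger).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = int(FIXTURE_DURATION * FIXTURE_FS)
    t = np.arange(n) / FIXTURE_FS

    data = np.zeros((len(FIXTURE_LABELS), n))
    data[FIXTURE_LABELS.index("PO8")] = TONE_AMP * np.cos(
        2 * np.pi * TONE_FREQ * t)
    tone = Recording(labels=FIXTURE_LABELS, fs=FIXTURE_FS, data=data,
                     events=[Event(500, "Self", "Faces")])
    tone_path = write_brainvision(tone, out / "tone.vhdr")

    rng = np.random.default_rng(7)
    noise = 0.5 * rng.standard_normal((len(FIXTURE_LABELS), n))
    events = [Event(s, c, "Faces") for s, c in zip(
        MARKER_SAMPLES, ("Self", "CloseOther", "Stranger"))]
    markers = Recording(labels=FIXTURE_LABELS, fs=FIXTURE_FS, data=noise,
                        events=events)
    markers_path = write_brainvision(markers, out / "markers.vhdr")

    (out / "ground_truth.json").write_text(json.dumps({
        "tone": {"channel": "PO8", "frequency_hz": TONE_FREQ,
                 "amplitude_uV": TONE_AMP, "event_sample": 500},
        "markers": {"event_samples": list(MARKER_SAMPLES),
                    "conditions": ["Self", "CloseOther", "Stranger"]},
    }, indent=2) + "\n")
    return {"tone": tone_path, "markers": markers_path}
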