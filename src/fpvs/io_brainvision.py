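"""BrainVision (.vhdr/.vmrk/.eeg) reading and writing.

Reading goes through :func:`mne.io.read_raw_brainvision` and therefore
accepts any header the BrainVision ecosystem produces.  Writing emits the
minimal well-formed dialect: multiplexed IEEE float32 data, unit resolution,
µV units, and stimulus markers of the form ``Stimulus,S<code>``.

Condition / stimulus-type pairs are encoded in the marker code: tens digit =
stimulus type (1 Faces, 2 Names), units digit = condition (1 Self,
2 CloseOther, 3 Stranger); e.g. ``S 13`` marks a Faces/Stranger train onset.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .config import CONDITIONS, STIMULUS_TYPES
from .containers import AS_RECORDED, Event, Recording

#: marker code table (code -> (condition, stimulus_type))
CODE_TABLE: dict[int, tuple[str, str]] = {
    10 * (si + 1) + (ci + 1): (cond, stim)
    for si, stim in enumerate(STIMULUS_TYPES)
    for ci, cond in enumerate(CONDITIONS)
}
_REVERSE_CODE = {v: k for k, v in CODE_TABLE.items()}


def event_code(condition: str, stimulus_type: str) -> int:
    try:
        return _REVERSE_CODE[(condition, stimulus_type)]
    except KeyError:
        raise ValueError(
            f"no marker code for {condition!r}/{stimulus_type!r}") from None


def _decode(description: str) -> tuple[str | None, str | None]:
    code = description.strip()
    if code.startswith("S"):
        try:
            return CODE_TABLE.get(int(code[1:].strip()), (None, None))
        except ValueError:
            pass
    return None, None


def write_brainvision(recording: Recording, path) -> Path:
    """Write a .vhdr/.vmrk/.eeg triplet; returns the header path.

    ``path`` may carry any of the three extensions (or none); companions are
    derived from the stem.
    """
    if recording.n_samples == 0 or len(recording.labels) == 0:
        raise ValueError("cannot write an empty recording")
    base = Path(path)
    if base.suffix in (".vhdr", ".vmrk", ".eeg"):
        base = base.with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s)
                       for s in (".vhdr", ".vmrk", ".eeg"))

    interval_us = 1e6 / recording.fs
    header = [
        "BrainVision Data Exchange Header File Version 1.0",
        "", "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(recording.labels)}",
        f"SamplingInterval={interval_us:g}",
        "", "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    header += [f"Ch{i + 1}={ch},,1,µV"
               for i, ch in enumerate(recording.labels)]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "", "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "", "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, ev in enumerate(recording.events):
        code = event_code(ev.condition, ev.stimulus_type) \
            if ev.condition else ev.code or "S  0"
        desc = f"S{int(code):3d}" if not isinstance(code, str) else code
        markers.append(
            f"Mk{i + 2}=Stimulus,{desc},{ev.sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_brainvision(header_path) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (µV)."""
    import mne

    mne.set_log_level("ERROR")
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"missing header file {header_path}")
    text = header_path.read_text(encoding="utf-8", errors="replace")
    for line in text.splitlines():
        if line.startswith("DataFile="):
            data_file = header_path.parent / line.split("=", 1)[1].strip()
            if not data_file.exists():
                raise FileNotFoundError(f"missing data file {data_file}")
    raw = mne.io.read_raw_brainvision(os.fspath(header_path), preload=True,
                                      verbose="ERROR")
    data = raw.get_data() * 1e6  # volts -> µV
    events = []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if not desc.startswith("Stimulus"):
            continue
        sample = int(round(float(ann["onset"]) * raw.info["sfreq"]))
        code = desc.split("/", 1)[1] if "/" in desc else desc
        condition, stimulus_type = _decode(code)
        events.append(Event(sample=sample, condition=condition,
                            stimulus_type=stimulus_type, code=code))
    return Recording(labels=tuple(raw.ch_names), fs=float(raw.info["sfreq"]),
                     data=data, events=events, reference=AS_RECORDED)
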