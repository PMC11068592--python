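"""64-channel actiCap montage with scalp-region assignments.

The montage mirrors a standard 64-electrode BrainProducts actiCap layout in
10-20 nomenclature (FCz reference, AFz ground, hence neither appears as a data
channel).  Electrode positions come from the standard 10-20 template shipped
with MNE, normalised to the unit sphere; the analysis only ever uses relative
distances, so a template (rather than digitised) geometry is sufficient.

Each electrode is assigned to one of four scalp regions.  The three signal
regions each contain a four-electrode *cluster* (the electrodes used for ROI
statistics) plus neighbouring electrodes, so that a data-driven localizer has
a genuine within-region choice to make.  TP9/TP10 are kept in the
parieto-occipital regions to match the cluster membership used in the
statistics, despite their nominally temporal position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ordered data-channel labels of the 64-channel actiCap set
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7",
    "FC3", "FC4", "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3",
    "CPz", "CP4", "TP8", "P5", "P1", "P2", "P6", "PO7", "PO3", "POz",
    "PO4", "PO8",
)

LEFT_PO = "left-parieto-occipital"
RIGHT_PO = "right-parieto-occipital"
FRONTOCENTRAL = "frontocentral"
OTHER = "other"

#: the four-electrode analysis clusters
CLUSTERS: dict[str, tuple[str, ...]] = {
    LEFT_PO: ("P7", "PO7", "O1", "TP9"),
    RIGHT_PO: ("P8", "PO8", "O2", "TP10"),
    FRONTOCENTRAL: ("Fz", "FC1", "FC2", "Cz"),
}

#: additional electrodes belonging to each signal region (localizer candidates)
_REGION_NEIGHBOURS: dict[str, tuple[str, ...]] = {
    LEFT_PO: ("P5", "P3", "PO3", "PO9", "TP7", "CP5"),
    RIGHT_PO: ("P6", "P4", "PO4", "PO10", "TP8", "CP6"),
    FRONTOCENTRAL: ("F1", "F2", "FC3", "FC4", "C1", "C2"),
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels, unit-sphere positions and region assignments."""

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    region: dict[str, str] = field(repr=False)

    def region_channels(self, region: str) -> list[str]:
        return [ch for ch in self.labels if self.region[ch] == region]

    def position_array(self, labels=None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        return np.array([self.positions[ch] for ch in labels])


def make_montage() -> Montage:
    """Build the fixed 64-channel montage with region assignments."""
    import mne

    mne.set_log_level("ERROR")
    template = mne.channels.make_standard_montage("standard_1020")
    ch_pos = template.get_positions()["ch_pos"]

    positions: dict[str, np.ndarray] = {}
    for ch in CHANNELS_64:
        p = np.asarray(ch_pos[ch], dtype=float)
        positions[ch] = p / np.linalg.norm(p)

    region = {ch: OTHER for ch in CHANNELS_64}
    for name in (LEFT_PO, RIGHT_PO, FRONTOCENTRAL):
        for ch in CLUSTERS[name] + _REGION_NEIGHBOURS[name]:
            region[ch] = name

    return Montage(labels=CHANNELS_64, positions=positions, region=region)
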