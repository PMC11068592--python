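"""Region-of-interest reduction: fixed clusters, collapsed localizer,
and the subject x condition summary table feeding the statistics.

The fixed clusters are the three four-electrode sets used for the group
statistics (left/right parieto-occipital and frontocentral).  The
collapsed localizer is the automated stand-in for choosing electrodes by
visual inspection of the grand-average topography: within each
predeclared scalp region, the k electrodes with the largest grand-average
baseline-subtracted response are selected, from data collapsed across
subjects, conditions and stimulus types so the choice cannot bias any
condition contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import CLUSTERS, FRONTOCENTRAL, LEFT_PO, RIGHT_PO, Montage

#: short ROI names used in tables, mapped to montage regions / laterality
ROI_REGIONS = {
    "left-PO": (LEFT_PO, "left"),
    "right-PO": (RIGHT_PO, "right"),
    "frontocentral": (FRONTOCENTRAL, "n/a"),
}


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    electrodes: tuple[str, ...]
    laterality: str

    def __post_init__(self):
        if len(self.electrodes) != len(set(self.electrodes)):
            raise ValueError("duplicate electrodes in ROI")


def fixed_rois() -> list[ROIDefinition]:
    """The three predeclared four-electrode analysis clusters."""
    return [ROIDefinition(name=name, electrodes=CLUSTERS[region],
                          laterality=lat)
            for name, (region, lat) in ROI_REGIONS.items()]


def collapsed_localizer(channel_responses, montage: Montage, k: int = 4
                        ) -> list[ROIDefinition]:
    """Top-``k`` electrodes per region from the collapsed grand average.

    ``channel_responses`` is either a mapping / Series of channel ->
    grand-average summed baseline-subtracted amplitude, or a DataFrame
    with ``channel`` and ``summed_bs`` columns (averaged over all its
    rows, i.e. over subjects, conditions and stimulus types).  Ties are
    broken alphabetically by label.
    """
    if isinstance(channel_responses, pd.DataFrame):
        grand = channel_responses.groupby("channel")["summed_bs"].mean()
    else:
        grand = pd.Series(dict(channel_responses), dtype=float)
    out = []
    for name, (region, lat) in ROI_REGIONS.items():
        candidates = [ch for ch in montage.region_channels(region)
                      if ch in grand.index]
        if len(candidates) < k:
            raise ValueError(
                f"region {region} has {len(candidates)} electrodes with "
                f"responses, fewer than k={k}")
        ranked = sorted(candidates, key=lambda ch: (-grand[ch], ch))
        out.append(ROIDefinition(name=name, electrodes=tuple(ranked[:k]),
                                 laterality=lat))
    return out


def summarize(responses: pd.DataFrame, rois) -> pd.DataFrame:
    """Average per-channel summed responses over each ROI's electrodes.

    ``responses`` needs columns subject, group, stimulus_type, condition,
    channel, summed_bs.  Returns the long-format table with one row per
    subject x stimulus type x condition x ROI; raises if any cell is
    missing a ROI electrode.
    """
    required = {"subject", "group", "stimulus_type", "condition",
                "channel", "summed_bs"}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ValueError(f"responses table lacks columns {missing_cols}")
    rows = []
    gaps = []
    cells = responses.groupby(["subject", "group", "stimulus_type",
                               "condition"])
    for (subject, group, stim, cond), cell in cells:
        by_channel = cell.set_index("channel")["summed_bs"]
        for roi in rois:
            have = [ch for ch in roi.electrodes if ch in by_channel.index]
            if len(have) < len(roi.electrodes):
                gaps.append((subject, stim, cond, roi.name,
                             sorted(set(roi.electrodes) - set(have))))
                continue
            rows.append((subject, group, stim, cond, roi.name,
                         roi.laterality,
                         float(by_channel[list(roi.electrodes)].mean())))
    if gaps:
        raise ValueError(f"missing electrodes for cells: {gaps}")
    table = pd.DataFrame(rows, columns=[
        "subject", "group", "stimulus_type", "condition", "roi",
        "laterality", "value"])
    counts = table.groupby("subject").size()
    if counts.nunique() > 1:
        raise ValueError("unbalanced summary table: "
                         f"{counts.to_dict()}")
    return table


def topography_export(channel_responses, montage: Montage) -> pd.DataFrame:
    """Tabular topography (electrode, x, y, z, grand_avg_bs) for plotting."""
    if isinstance(channel_responses, pd.DataFrame):
        grand = channel_responses.groupby("channel")["summed_bs"].mean()
    else:
        grand = pd.Series(dict(channel_responses), dtype=float)
    rows = [(ch, *montage.positions[ch], float(grand[ch]))
            for ch in montage.labels if ch in grand.index]
    return pd.DataFrame(rows, columns=["electrode", "x", "y", "z",
                                       "grand_avg_bs"])
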