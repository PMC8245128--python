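"""Surface enrichment and signal-intensity statistics.

Two complementary summaries of a slide-subtracted surface measurement
against the cytoplasm of the same image and channel:

* enrichment = (surface - cytoplasm) / cytoplasm (dimensionless,
  scale-invariant)
* signal intensity = surface - cytoplasm (AU, offset-invariant)

plus the per-gap lateral/midline/gap triplets used to ask whether signal
inside a midline gap resembles a lateral surface rather than an apical
one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceMeasurement",
    "enrichment",
    "signal_intensity",
    "lat_mid_gap_triplets",
]

logger = logging.getLogger(__name__)

SURFACE_KINDS = ("apical", "junctional", "lateral", "midline_gap", "midline_nongap")


@dataclass(frozen=True)
class SurfaceMeasurement:
    """One slide-subtracted surface-line mean with its matching cytoplasm mean."""

    embryo_id: str
    channel: str
    surface_kind: str
    mean_intensity: float
    cyto_mean: float

    def __post_init__(self) -> None:
        if self.surface_kind not in SURFACE_KINDS:
            raise ValueError(
                f"surface_kind must be one of {SURFACE_KINDS}, got {self.surface_kind!r}"
            )


def enrichment(m: SurfaceMeasurement) -> float:
    """(surface mean - cytoplasm mean) / cytoplasm mean."""
    if m.cyto_mean <= 0:
        raise ValueError("cyto_mean must be > 0 for enrichment")
    return (m.mean_intensity - m.cyto_mean) / m.cyto_mean


def signal_intensity(m: SurfaceMeasurement) -> float:
    """surface mean - cytoplasm mean (AU)."""
    return m.mean_intensity - m.cyto_mean


def lat_mid_gap_triplets(
    measurements: Sequence[SurfaceMeasurement],
    max_gaps_per_embryo: int = 2,
) -> tuple[pd.DataFrame, list[SurfaceMeasurement]]:
    """Per-gap (lateral, midline, gap) signal-intensity records.

    Per embryo and channel, the lateral value is the mean signal
    intensity over its lateral lines and the midline value the mean over
    its ``midline_nongap`` (or ``apical``) lines.  Each ``midline_gap``
    measurement yields one (lat, mid, gap) row, capped at
    ``max_gaps_per_embryo``; the excess is rejected and returned.
    Embryos without gap measurements (controls) contribute one
    (lat, mid, NaN) row.
    """
    rejected: list[SurfaceMeasurement] = []
    rows = []
    df = pd.DataFrame(
        [
            {
                "embryo_id": m.embryo_id,
                "channel": m.channel,
                "surface_kind": m.surface_kind,
                "si": signal_intensity(m),
                "_m": m,
            }
            for m in measurements
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["embryo_id", "channel", "lat", "mid", "gap"]), rejected
    for (eid, channel), grp in df.groupby(["embryo_id", "channel"], sort=False):
        lat_vals = grp.loc[grp.surface_kind == "lateral", "si"]
        mid_vals = grp.loc[grp.surface_kind.isin(["midline_nongap", "apical"]), "si"]
        lat = float(lat_vals.mean()) if len(lat_vals) else np.nan
        mid = float(mid_vals.mean()) if len(mid_vals) else np.nan
        gap_rows = grp.loc[grp.surface_kind == "midline_gap"]
        if len(gap_rows) > max_gaps_per_embryo:
            for m in gap_rows["_m"].iloc[max_gaps_per_embryo:]:
                logger.warning(
                    "embryo %s channel %s: gap measurement beyond the %d allowed, rejected",
                    eid, channel, max_gaps_per_embryo,
                )
                rejected.append(m)
            gap_rows = gap_rows.iloc[:max_gaps_per_embryo]
        if len(gap_rows):
            for g in gap_rows["si"]:
                rows.append(
                    {"embryo_id": eid, "channel": channel, "lat": lat, "mid": mid,
                     "gap": float(g)}
                )
        else:
            rows.append(
                {"embryo_id": eid, "channel": channel, "lat": lat, "mid": mid, "gap": np.nan}
            )
    return pd.DataFrame(rows), rejected
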