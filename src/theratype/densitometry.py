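"""Western-blot densitometry of mature CFTR normalised to a loading control.

Mature, complex-glycosylated CFTR (band C, ~180 kDa) abundance is compared
across lanes loaded with different protein amounts by dividing each lane's
band-C density by its calnexin loading-control density and expressing the
ratio as a percentage of the wild-type control lane's ratio.  Loaded µg is
carried as metadata only: the loading control already absorbs loading
differences, and dividing by µg as well would double-correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LaneDensity", "band_c_percent_of_wt", "quantify_lanes"]


@dataclass
class LaneDensity:
    """Integrated band densities for one blot lane."""

    lane_id: str
    condition: str
    band_c_intensity: float
    loading_control_intensity: float
    protein_ug: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.band_c_intensity) or self.band_c_intensity < 0:
            raise ValueError(f"lane {self.lane_id!r}: band C intensity must be ≥ 0")
        if (
            not math.isfinite(self.loading_control_intensity)
            or self.loading_control_intensity <= 0
        ):
            raise ValueError(
                f"lane {self.lane_id!r}: loading-control intensity must be > 0"
            )

    @property
    def normalized(self) -> float:
        return self.band_c_intensity / self.loading_control_intensity


def band_c_percent_of_wt(sample: LaneDensity, wt: LaneDensity) -> float:
    """Loading-control-normalised band C as percent of the wild-type lane."""
    if wt.band_c_intensity <= 0:
        raise ValueError("wild-type lane has no band C signal; cannot normalise")
    return 100.0 * sample.normalized / wt.normalized


def quantify_lanes(lanes: pd.DataFrame, wt_lane: str) -> pd.DataFrame:
    """Percent-of-WT for every lane of a blot table.

    Expected columns: ``lane_id``, ``condition``, ``band_c_intensity``,
    ``calnexin_intensity`` and optionally ``protein_ug``.
    """
    required = {"lane_id", "condition", "band_c_intensity", "calnexin_intensity"}
    missing = required - set(lanes.columns)
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    objs = {
        str(row.lane_id): LaneDensity(
            lane_id=str(row.lane_id),
            condition=str(row.condition),
            band_c_intensity=float(row.band_c_intensity),
            loading_control_intensity=float(row.calnexin_intensity),
            protein_ug=float(row.protein_ug) if "protein_ug" in lanes.columns else None,
        )
        for row in lanes.itertuples()
    }
    if wt_lane not in objs:
        raise ValueError(f"wild-type lane {wt_lane!r} not in table")
    wt = objs[wt_lane]
    out = lanes.copy()
    out["percent_of_wt"] = [
        band_c_percent_of_wt(objs[str(r.lane_id)], wt) for r in lanes.itertuples()
    ]
    return out
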