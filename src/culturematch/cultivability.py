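"""The great plate count anomaly: what fraction of cells grows on plates.

Cultivability at a station is 100 * cfu/ml / cells/ml, where cfu come from
colony counts on solid media and cells/ml from flow cytometry of the
heterotrophic prokaryote community (phototrophs excluded upstream — the
media never target them).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import pandas as pd

from .seqio import StationCounts


def cultivability_percent(cfu_per_ml: float, cells_per_ml: float) -> float:
    """Percentage of cells recovered as colonies."""
    if cells_per_ml <= 0:
        raise ValueError("cells_per_ml must be > 0")
    pct = 100.0 * cfu_per_ml / cells_per_ml
    if pct > 100.0:
        warnings.warn(
            f"cultivability {pct:.1f}% exceeds 100% (cfu > cytometry counts)"
        )
    return pct


def cultivability_records(stations: Iterable[StationCounts]) -> pd.DataFrame:
    """Per-station cultivability rows."""
    rows = [
        {
            "station_id": s.station_id,
            "layer": s.layer,
            "cfu_per_ml": s.cfu_per_ml,
            "cells_per_ml": s.cells_per_ml,
            "pct_cultivable": cultivability_percent(s.cfu_per_ml, s.cells_per_ml),
        }
        for s in stations
    ]
    return pd.DataFrame(rows)


def layer_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-layer mean, min and max cultivability; layers with no records omitted."""
    grouped = records.groupby("layer")["pct_cultivable"]
    return pd.DataFrame(
        {
            "mean": grouped.mean(),
            "min": grouped.min(),
            "max": grouped.max(),
            "n_stations": grouped.size(),
        }
    )
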