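"""Rank-abundance structure and occurrence classification.

Marine rank-abundance curves show a few abundant taxa (>1% mean relative
abundance), a band of mid-abundant taxa, and a long rare tail (<0.01%) — the
rare biosphere. Genera in a culture collection are likewise classified by how
many stations they were isolated from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .matching import MatchSet
from .seqio import AbundanceTable, IsolateRecord

ABUNDANT = "ABUNDANT"
MID = "MID"
RARE = "RARE"

UBIQUITOUS = "UBIQUITOUS"
WIDESPREAD = "WIDESPREAD"
REGIONAL = "REGIONAL"
LOCAL = "LOCAL"

#: class boundaries on mean relative abundance (fractions, not percent)
ABUNDANT_THRESHOLD = 0.01    # > 1% of reads
RARE_THRESHOLD = 0.0001      # < 0.01% of reads


@dataclass(frozen=True)
class OccurrencePolicy:
    """Station-fraction thresholds for genus occurrence categories.

    Defaults: > 0.80 UBIQUITOUS; else >= 0.50 WIDESPREAD; else > 0.25
    REGIONAL; else LOCAL. The mixed strict/inclusive boundaries reproduce the
    usual verbal categories ("more than 80% of stations", "in 50% of the
    samples", "more than 25%").
    """

    ubiquitous_gt: float = 0.80
    widespread_ge: float = 0.50
    regional_gt: float = 0.25

    def classify(self, fraction: float) -> str:
        if fraction > self.ubiquitous_gt:
            return UBIQUITOUS
        if fraction >= self.widespread_ge:
            return WIDESPREAD
        if fraction > self.regional_gt:
            return REGIONAL
        return LOCAL


def mean_relative_abundance(table: AbundanceTable) -> pd.Series:
    """Unweighted mean over samples of per-sample relative abundances."""
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")
    rel = table.counts.div(sums, axis=0)
    return rel.mean(axis=0)


def classify_biosphere(mean_rel_abund: float) -> str:
    """ABUNDANT above 1%, RARE below 0.01%, MID otherwise (boundaries -> MID)."""
    if mean_rel_abund > ABUNDANT_THRESHOLD:
        return ABUNDANT
    if mean_rel_abund < RARE_THRESHOLD:
        return RARE
    return MID


def rank_plot_table(
    mean_rel_abund: pd.Series, match_set: MatchSet | None = None
) -> pd.DataFrame:
    """Ranked abundance rows: rank, asv_id, abundance, matched flag, class.

    Descending by unrounded mean relative abundance, ties broken
    lexicographically by asv_id; the output is a permutation of the input
    ASV set.
    """
    matched = match_set.matched_asvs if match_set is not None else set()
    order = sorted(mean_rel_abund.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        {
            "rank": r + 1,
            "asv_id": asv,
            "mean_relative_abundance": float(x),
            "matched": asv in matched,
            "biosphere_class": classify_biosphere(float(x)),
        }
        for r, (asv, x) in enumerate(order)
    ]
    return pd.DataFrame(rows)


def matched_class_counts(rank_table: pd.DataFrame) -> pd.Series:
    """How many matched ASVs fall in each biosphere class."""
    sub = rank_table[rank_table["matched"]]
    return sub.groupby("biosphere_class").size().reindex(
        [ABUNDANT, MID, RARE], fill_value=0
    )


def occurrence_classify(
    isolates: Iterable[IsolateRecord],
    policy: OccurrencePolicy = OccurrencePolicy(),
) -> pd.DataFrame:
    """Classify each genus by the fraction of stations it was isolated from.

    The station universe is the distinct station_ids among the isolates;
    isolates without a genus are skipped. Returns genus-indexed rows with
    n_stations, station_fraction and category.
    """
    isolates = list(isolates)
    stations = {iso.station_id for iso in isolates if iso.station_id}
    if not stations:
        raise ValueError("no station ids among isolates")
    per_genus: dict[str, set[str]] = {}
    for iso in isolates:
        if iso.genus and iso.station_id:
            per_genus.setdefault(iso.genus, set()).add(iso.station_id)
    total = len(stations)
    rows = []
    for genus in sorted(per_genus):
        n = len(per_genus[genus])
        frac = n / total
        rows.append(
            {
                "genus": genus,
                "n_stations": n,
                "total_stations": total,
                "station_fraction": frac,
                "category": policy.classify(frac),
            }
        )
    return pd.DataFrame(rows).set_index("genus")
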