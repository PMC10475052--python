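"""Recruitment statistics: how much of the community the collection recovers.

Per sample, two percentages: pct_asvs (diversity — fraction of the ASVs
present that are 100% identical to at least one isolate) and pct_reads
(abundance — fraction of reads carried by those ASVs). Percentages are
computed on rarefied tables; amplicon read counts over-represent taxa with
many rRNA operon copies, so read percentages can additionally be divided by
the median operon copy number of the isolated genera.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import MatchSet
from .region import RegionExtract
from .seqio import AbundanceTable

TAXONOMY_RANKS = ["domain", "phylum", "class", "order", "family", "genus"]


def filter_taxa(
    table: AbundanceTable,
    asv_taxonomy: Mapping[str, str],
    exclude_labels: Iterable[str],
) -> AbundanceTable:
    """Drop ASVs carrying any excluded rank-qualified label.

    Labels look like ``domain:Archaea`` or ``phylum:Cyanobacteria``. A label
    whose rank is one of domain..phylum..genus is compared positionally
    against the semicolon-separated taxonomy string; any other rank
    qualifier (e.g. ``organelle:Chloroplast``) matches if the name appears
    at any rank. Samples left empty are dropped with a warning.
    """
    excl = [lab.split(":", 1) for lab in exclude_labels]
    for e in excl:
        if len(e) != 2:
            raise ValueError(f"exclude label must be rank:name, got {':'.join(e)!r}")

    def excluded(asv_id: str) -> bool:
        tax = asv_taxonomy.get(asv_id)
        if not tax:
            return False
        ranks = [t.strip() for t in tax.split(";")]
        for rank, name in excl:
            if rank in TAXONOMY_RANKS:
                pos = TAXONOMY_RANKS.index(rank)
                if pos < len(ranks) and ranks[pos] == name:
                    return True
            elif name in ranks:
                return True
        return False

    keep = [a for a in table.asv_ids if not excluded(a)]
    out = AbundanceTable(table.counts[keep])
    empty = out.counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} sample(s) emptied by taxon filtering"
        )
        out = out.drop_empty_samples()
    return out


def recruitment_per_sample(table: AbundanceTable, match_set: MatchSet) -> pd.DataFrame:
    """Per-sample recruitment rows.

    An ASV is present in a sample iff its (rarefied) count is > 0; the
    matched set is the union over isolates, so an ASV hit by several
    isolates counts once.
    """
    matched = match_set.matched_asvs
    counts = table.counts
    is_matched = np.array([a in matched for a in counts.columns])

    rows = []
    for sample_id, row in counts.iterrows():
        vec = row.to_numpy()
        total = int(vec.sum())
        if total == 0:
            raise ValueError(
                f"sample {sample_id!r} has zero reads; drop empty samples upstream"
            )
        present = vec > 0
        n_present = int(present.sum())
        n_matched = int((present & is_matched).sum())
        reads_matched = int(vec[is_matched].sum())
        rows.append(
            {
                "sample_id": sample_id,
                "n_asvs_present": n_present,
                "n_asvs_matched": n_matched,
                "pct_asvs": 100.0 * n_matched / n_present,
                "reads_total": total,
                "reads_matched": reads_matched,
                "pct_reads": 100.0 * reads_matched / total,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def copy_number_correct(pct_reads: float, copy_number_median: float) -> float:
    """Divide a read percentage by the median rRNA operon copy number."""
    if copy_number_median < 1:
        raise ValueError("copy-number median must be >= 1")
    return pct_reads / copy_number_median


def format_percent(pct: float) -> str:
    """Report to one decimal, collapsing trailing '.0' (e.g. 8.0 -> '8')."""
    r = round(pct, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


def add_corrected_percentages(
    summary: pd.DataFrame, copy_number_median: float
) -> pd.DataFrame:
    """Append a pct_reads_corrected column to per-sample recruitment rows."""
    out = summary.copy()
    out["pct_reads_corrected"] = out["pct_reads"] / copy_number_median
    return out


def stratum_means(
    summary: pd.DataFrame,
    sample_meta: pd.DataFrame,
    group_keys: Sequence[str] = ("dataset",),
    value_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean and sample sd of each percentage within each stratum.

    Strata with a single sample report sd as NaN (absent), never zero.
    """
    missing = [s for s in summary.index if s not in sample_meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    if value_cols is None:
        value_cols = [c for c in summary.columns if c.startswith("pct_")]
    joined = summary.join(sample_meta[list(group_keys)])
    grouped = joined.groupby(list(group_keys))
    out = {}
    for col in value_cols:
        out[(col, "mean")] = grouped[col].mean()
        out[(col, "sd")] = grouped[col].std(ddof=1)  # NaN when n == 1
    out[("n_samples", "")] = grouped.size()
    res = pd.DataFrame(out)
    res.columns = [f"{a}_{b}".rstrip("_") for a, b in res.columns]
    return res


def pooled_recruitment(table: AbundanceTable, match_set: MatchSet) -> dict[str, float]:
    """Dataset-level pooled variant: one percentage over all samples at once."""
    matched = match_set.matched_asvs
    counts = table.counts
    present_any = counts.sum(axis=0) > 0
    n_present = int(present_any.sum())
    n_matched = sum(1 for a in counts.columns[present_any] if a in matched)
    total = int(counts.to_numpy().sum())
    reads_matched = int(
        counts[[a for a in counts.columns if a in matched]].to_numpy().sum()
    )
    return {
        "pooled_pct_asvs": 100.0 * n_matched / n_present if n_present else 0.0,
        "pooled_pct_reads": 100.0 * reads_matched / total if total else 0.0,
    }


def unmatched_isolate_fraction(
    regions: Iterable[RegionExtract],
    match_set: MatchSet,
    strata: Mapping[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Percentage of isolates with zero hits.

    The denominator is every isolate attempted — ``too_short`` regions are
    excluded. Optionally also per stratum, via an isolate_id -> stratum map.
    """
    attempted = [r.isolate_id for r in regions if not r.too_short]
    if not attempted:
        raise ValueError("no isolates attempted (all regions too short?)")
    matched = match_set.matched_isolates
    unmatched = [i for i in attempted if i not in matched]
    overall = 100.0 * len(unmatched) / len(attempted)

    rows = []
    if strata:
        groups: dict[str, list[str]] = {}
        for iso in attempted:
            groups.setdefault(strata.get(iso, ""), []).append(iso)
        for name, members in sorted(groups.items()):
            miss = sum(1 for i in members if i not in matched)
            rows.append(
                {
                    "stratum": name,
                    "n_isolates": len(members),
                    "n_unmatched": miss,
                    "pct_unmatched": 100.0 * miss / len(members),
                }
            )
    return overall, pd.DataFrame(rows, columns=["stratum", "n_isolates", "n_unmatched", "pct_unmatched"])
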