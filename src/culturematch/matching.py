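"""Exact-containment matching of isolate regions against ASVs.

The recruitment statistic is defined at 100% identity with the ASV fully
covered and ungapped, which for primer-trimmed sequences reduces to: the ASV
sequence occurs verbatim as a contiguous substring of the isolate's extracted
region. A k-mer seed index accelerates the scan; its semantics are exactly
those of a naive substring search, and an isolate region shorter than an ASV
can never match it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .region import IUPAC_EXPANSION, RegionExtract
from .seqio import ASVRecord, AbundanceTable

STRICT = "STRICT"
EXPAND = "EXPAND"


@dataclass
class MatchSet:
    """Bipartite isolate<->ASV mapping at 100% identity / 100% ASV coverage."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    #: (isolate_id, asv_id) -> offset of the ASV inside the region
    offsets: dict[tuple[str, str], int] = field(default_factory=dict)
    #: isolates whose region was shorter than every ASV they were tried against
    region_shorter_than_asv: set[str] = field(default_factory=set)

    @property
    def matched_asvs(self) -> set[str]:
        """Union of matched ASV ids — an ASV hit by several isolates counts once."""
        return {a for _, a in self.pairs}

    @property
    def matched_isolates(self) -> set[str]:
        return {i for i, _ in self.pairs}

    def hits_per_isolate(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for iso, _ in self.pairs:
            counts[iso] += 1
        return dict(counts)

    def hits_of(self, isolate_id: str) -> set[str]:
        return {a for i, a in self.pairs if i == isolate_id}


class AsvIndex:
    """Exact-substring index over a set of ASV sequences.

    Seeds are the first ``k`` bases of each ASV; every candidate is verified
    in full, so the index is only an accelerator. ASVs shorter than ``k``
    are kept on a brute-force list.
    """

    def __init__(self, asv_records: Sequence[ASVRecord], k: int = 31):
        self.k = k
        seen: dict[str, str] = {}
        for rec in asv_records:
            if rec.sequence in seen:
                raise ValueError(
                    f"duplicate ASV sequence: {rec.asv_id!r} == {seen[rec.sequence]!r}"
                )
            seen[rec.sequence] = rec.asv_id
        self._seeds: dict[str, list[ASVRecord]] = defaultdict(list)
        self._short: list[ASVRecord] = []
        for rec in asv_records:
            if len(rec.sequence) >= k:
                self._seeds[rec.sequence[:k]].append(rec)
            else:
                self._short.append(rec)
        self.n_asvs = len(asv_records)

    def query(self, region: str) -> dict[str, int]:
        """ASV ids contained verbatim in ``region``, with their offsets."""
        hits: dict[str, int] = {}
        k = self.k
        for i in range(len(region) - k + 1):
            for rec in self._seeds.get(region[i : i + k], ()):
                if rec.asv_id not in hits and region.startswith(rec.sequence, i):
                    hits[rec.asv_id] = i
        for rec in self._short:
            pos = region.find(rec.sequence)
            if pos >= 0:
                hits[rec.asv_id] = pos
        return hits

    def min_asv_length(self) -> int:
        n = [len(r.sequence) for r in self._short]
        n += [len(r.sequence) for recs in self._seeds.values() for r in recs]
        return min(n) if n else 0


def build_asv_index(asv_records: Sequence[ASVRecord], k: int = 31) -> AsvIndex:
    """Build the containment index; duplicate ASV sequences are an error."""
    return AsvIndex(asv_records, k=k)


def _expand_contains(region: str, asv: str) -> int:
    """Offset of ``asv`` in ``region`` under the EXPAND ambiguity policy, or -1.

    An ambiguity code in the isolate region matches an ASV base iff the base
    lies in the code's expansion.
    """
    n, m = len(region), len(asv)
    for i in range(n - m + 1):
        ok = True
        for j in range(m):
            if asv[j] not in IUPAC_EXPANSION[region[i + j]]:
                ok = False
                break
        if ok:
            return i
    return -1


def match_isolates(
    regions: Iterable[RegionExtract],
    asv_index: AsvIndex,
    ambiguity_policy: str = STRICT,
    asv_records: Sequence[ASVRecord] | None = None,
) -> MatchSet:
    """All (isolate, ASV) pairs where the ASV is a verbatim substring of the region.

    Policies: STRICT (default) — an ambiguous base in the region never
    matches; EXPAND — it matches any base in its expansion (requires
    ``asv_records``). Isolates flagged ``too_short`` are skipped; all hits
    per isolate are retained.
    """
    if ambiguity_policy not in (STRICT, EXPAND):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    if ambiguity_policy == EXPAND and asv_records is None:
        raise ValueError("EXPAND policy requires asv_records")

    out = MatchSet()
    min_len = asv_index.min_asv_length()
    for reg in regions:
        if reg.too_short:
            continue
        if asv_index.n_asvs and len(reg.region_sequence) < min_len:
            out.region_shorter_than_asv.add(reg.isolate_id)
            continue
        if ambiguity_policy == STRICT:
            for asv_id, off in asv_index.query(reg.region_sequence).items():
                out.pairs.add((reg.isolate_id, asv_id))
                out.offsets[(reg.isolate_id, asv_id)] = off
        else:
            for rec in asv_records:  # type: ignore[union-attr]
                off = _expand_contains(reg.region_sequence, rec.sequence)
                if off >= 0:
                    out.pairs.add((reg.isolate_id, rec.asv_id))
                    out.offsets[(reg.isolate_id, rec.asv_id)] = off
    return out


def multi_hit_report(
    match_set: MatchSet, table: AbundanceTable
) -> tuple[pd.DataFrame, float]:
    """Per-isolate hit counts and the read share attributable to extra hits.

    Hits are ranked per isolate by descending mean relative abundance of the
    matched ASV (ties broken lexicographically). The extra-hit read share is
    the dataset-level recruited-read percentage counting all hits minus the
    percentage counting only each isolate's top hit, both computed on union
    sets so shared ASVs are never double counted.
    """
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)

    rows = []
    top_hits: set[str] = set()
    for iso in sorted(match_set.matched_isolates):
        hits = sorted(
            match_set.hits_of(iso),
            key=lambda a: (-float(mean_rel.get(a, 0.0)), a),
        )
        top_hits.add(hits[0])
        rows.append({"isolate_id": iso, "n_hits": len(hits), "top_hit": hits[0]})
    report = pd.DataFrame(rows, columns=["isolate_id", "n_hits", "top_hit"])

    total = float(table.counts.to_numpy().sum())
    if total == 0:
        return report, 0.0
    all_ids = [a for a in match_set.matched_asvs if a in table.counts.columns]
    top_ids = [a for a in top_hits if a in table.counts.columns]
    pct_all = 100.0 * float(table.counts[all_ids].to_numpy().sum()) / total
    pct_top = 100.0 * float(table.counts[top_ids].to_numpy().sum()) / total
    return report, pct_all - pct_top
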