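"""Permutation rarefaction and collector (accumulation) curves.

Rarefaction draws reads without replacement (multivariate hypergeometric),
reflecting that reads are physical draws from a finite pool; the permuted
variant averages many independent draws per sample and rounds half-even,
mirroring the behaviour of permutation-based rarefaction in community
ecology toolkits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AbundanceTable


@dataclass
class RarefiedTable:
    """Rarefied counts plus the unrounded permutation means."""

    table: AbundanceTable
    means: pd.DataFrame  # unrounded permutation means, same shape
    depth: int
    n_permutations: int
    seed: int
    dropped_samples: list[str]


def rarefy_once(counts_row: np.ndarray, depth: int, rng: np.random.Generator,
                sample_id: str = "?") -> np.ndarray:
    """One without-replacement draw of ``depth`` reads from a count vector."""
    row = np.asarray(counts_row, dtype=np.int64)
    total = int(row.sum())
    if depth > total:
        raise ValueError(
            f"sample {sample_id!r}: depth {depth} exceeds row sum {total}"
        )
    return rng.multivariate_hypergeometric(row, depth)


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # per-sample substream: one master seed + the sample's position in the
    # table, so results are reproducible regardless of evaluation order
    return np.random.default_rng([seed, sample_index])


def rarefy_permuted(
    table: AbundanceTable,
    depth: int | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> RarefiedTable:
    """Rarefy every sample to a common depth, averaging permuted draws.

    ``depth`` defaults to the minimum retained row sum (the lowest sampling
    effort). Samples with fewer reads than an explicit depth are dropped
    first. Each cell of the result is the round-half-even of the mean over
    ``n_permutations`` independent hypergeometric draws; the unrounded means
    are kept for downstream ranking.
    """
    sums = table.row_sums()
    if depth is None:
        if table.counts.empty:
            raise ValueError("empty table")
        depth = int(sums.min())
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    df = table.counts.loc[keep]
    if df.empty:
        raise ValueError("no samples retain enough reads for the requested depth")

    mean_rows = []
    for pos, (sample_id, row) in enumerate(df.iterrows()):
        rng = _sample_rng(seed, pos)
        vec = row.to_numpy(dtype=np.int64)
        acc = np.zeros(len(vec), dtype=np.float64)
        for _ in range(n_permutations):
            acc += rng.multivariate_hypergeometric(vec, depth)
        mean_rows.append(acc / n_permutations)

    means = pd.DataFrame(mean_rows, index=df.index, columns=df.columns)
    rounded = AbundanceTable(
        pd.DataFrame(
            np.rint(means.to_numpy()).astype(np.int64),
            index=df.index,
            columns=df.columns,
        )
    )
    return RarefiedTable(
        table=rounded,
        means=means,
        depth=depth,
        n_permutations=n_permutations,
        seed=seed,
        dropped_samples=dropped,
    )


def dereplicate_isolates(sequences: Mapping[str, str]) -> dict[str, list[str]]:
    """Group isolates whose sequences are character-identical (100% OTUs).

    Returns OTU id -> sorted member isolate ids; the OTU id is the
    lexicographically smallest member id.
    """
    by_seq: dict[str, list[str]] = {}
    for iso_id, seq in sequences.items():
        by_seq.setdefault(seq.upper(), []).append(iso_id)
    out = {}
    for members in by_seq.values():
        members = sorted(members)
        out[members[0]] = members
    return out


def collector_curve(
    incidence: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Accumulation curve: distinct units observed vs samples added.

    ``incidence`` is units x samples (bool/0-1). Returns a frame with
    columns ``k``, ``mean``, ``sd`` over ``n_permutations`` random sample
    orderings; the mean is non-decreasing and equals total richness at
    k = n_samples.
    """
    present = incidence.to_numpy() > 0  # units x samples
    n_units, n_samples = present.shape
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, n_samples), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_samples)
        seen = np.zeros(n_units, dtype=bool)
        for k, s in enumerate(order):
            seen |= present[:, s]
            curves[p, k] = int(seen.sum())
    return pd.DataFrame(
        {
            "k": np.arange(1, n_samples + 1),
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n_samples),
        }
    )
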