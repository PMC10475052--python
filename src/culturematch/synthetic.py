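"""Synthetic ocean-community studies with known ground truth.

Generates everything the pipeline consumes — ASV sequences, count tables
across depth layers and plankton size fractions, a biased culture
collection, per-station cfu/cytometry pairs and per-genus rRNA operon copy
numbers — from a lognormal species-abundance model. Every planted quantity
(culturable taxon set, per-stratum culturable read fraction, isolate->taxon
map, copy numbers) is recorded in a truth object so downstream statistics
have exact expected values.

The model: taxon abundances are lognormal (few taxa above 1%, a long rare
tail); a global subset of taxa is culturable, and their abundance mass per
stratum is rescaled to a configured target cell fraction that increases with
depth and particle size; isolates are drawn from culturable taxa with
probability proportional to abundance^beta (copiotroph bias); read counts
are multinomial with probabilities proportional to abundance x operon copy
number, so sequencing over-represents multi-copy genera.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .region import FORWARD_515FY, IUPAC_EXPANSION, REVERSE_926R, reverse_complement
from .seqio import ASVRecord, AbundanceTable, IsolateRecord, StationCounts

Stratum = tuple[str, str]  # (layer, size_fraction)

#: genera commonly recovered on marine rich media, used for culturable taxa
CULTURABLE_GENERA = (
    "Alteromonas", "Erythrobacter", "Sulfitobacter", "Halomonas", "Marinobacter",
    "Pseudoalteromonas", "Idiomarina", "Psychrobacter", "Alcanivorax", "Vibrio",
)

#: default planted culturable CELL fractions per stratum: deeper layers and
#: larger particles carry more culturable signal, photic free-living the
#: least. These are cell-scale values; under the default ~3.5x operon-copy
#: inflation of culturable genera the OBSERVED read percentages come out in
#: the 1.5-33% range field surveys report (e.g. 0.08 cells -> ~23% of reads
#: in the bathypelagic free-living fraction).
DEFAULT_CULTURABLE_FRACTIONS: dict[Stratum, float] = {
    ("SRF", "0.2-0.8"): 0.005,
    ("SRF", "0.8-20"): 0.04,
    ("DCM", "0.2-0.8"): 0.004,
    ("DCM", "0.8-20"): 0.035,
    ("MESO", "0.2-0.8"): 0.024,
    ("MESO", "0.8-20"): 0.07,
    ("BATHY", "0.2-0.8"): 0.08,
    ("BATHY", "0.8-20"): 0.125,
}

#: (mean cells/ml, lognormal sd of cells, beta parameters for cultivability)
DEFAULT_STATION_MODEL = {
    "PHOTIC": (8e5, 0.4, (1.2, 399.0), 12),
    "MESO": (1.2e5, 0.4, (2.0, 131.0), 4),
    "BATHY": (5e4, 0.4, (1.3, 99.0), 7),
}

_SAMPLE_LAYER_TO_ISOLATE = {"SRF": "PHOTIC", "DCM": "PHOTIC", "MESO": "MESO", "BATHY": "BATHY"}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_taxa: int = 300
    lognormal_meanlog: float = 0.0
    lognormal_sdlog: float = 2.0
    #: per-stratum lognormal noise on top of the shared base abundances
    stratum_sdlog: float = 0.5
    #: planted culturable cell fraction per (layer, size_fraction)
    culturable_fraction: Mapping[Stratum, float] = field(
        default_factory=lambda: dict(DEFAULT_CULTURABLE_FRACTIONS)
    )
    #: fraction of taxa that are culturable at all
    culturable_taxa_fraction: float = 0.2
    n_samples_per_stratum: int = 3
    reads_per_sample: int = 50_000
    reads_jitter: float = 0.1
    region_length: int = 373
    copiotroph_bias: float = 1.0  # isolate draw weight = abundance^beta
    isolate_count: int = 200
    #: guarantee every culturable taxon at least one isolate when possible
    ensure_coverage: bool = True
    nonmatch_fraction: float = 0.11  # isolates mutated so they cannot match
    #: operon copy numbers: culturable genera drawn from these choices,
    #: everything else single-copy
    copy_number_choices: Sequence[float] = (3.0, 3.5, 4.0)
    copy_number_other: float = 1.0
    dataset_name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        for frac in (
            self.culturable_taxa_fraction,
            self.nonmatch_fraction,
            self.reads_jitter,
            *self.culturable_fraction.values(),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")

    @property
    def strata(self) -> list[Stratum]:
        return list(self.culturable_fraction)


@dataclass
class Community:
    asv_records: list[ASVRecord]
    #: full-length 16S reference per taxon (flank + primer + region + primer + flank)
    full_references: dict[str, str]
    genus_of: dict[str, str]
    culturable: set[str]
    #: per-stratum relative abundance vectors (cells), in asv_records order
    abundances: dict[Stratum, np.ndarray]
    copy_numbers: pd.Series  # genus -> operon copy number


@dataclass
class SyntheticTruth:
    """Everything needed to compute expected downstream statistics."""

    config: SimConfig
    culturable_taxa: set[str]
    #: planted culturable cell fraction per stratum
    planted_cell_fraction: dict[Stratum, float]
    #: read-scale expectation of pct_reads for the matchable taxa (copy-number weighted)
    expected_pct_reads: dict[Stratum, float]
    #: same but on the cell scale (copy numbers ignored)
    matchable_cell_fraction: dict[Stratum, float]
    isolate_taxon: dict[str, str]
    nonmatch_isolates: set[str]
    copy_numbers: pd.Series
    station_cultivability: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    community: Community
    table: AbundanceTable
    sample_meta: pd.DataFrame
    isolates: list[IsolateRecord]
    stations: list[StationCounts]
    truth: SyntheticTruth


# -- sequence helpers --------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _concrete_primer(rng: np.random.Generator, primer: str) -> str:
    """One unambiguous realisation of a degenerate primer."""
    return "".join(rng.choice(sorted(IUPAC_EXPANSION[c])) for c in primer)


# -- generator stages --------------------------------------------------------


def simulate_community(config: SimConfig, rng: np.random.Generator | None = None) -> Community:
    """Draw the taxa: sequences, genera, culturable set, per-stratum abundances."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_taxa

    # distinct ASV sequences; collision retry is belt-and-braces at 373 nt
    seqs: list[str] = []
    seen: set[str] = set()
    for _ in range(n):
        for attempt in range(100):
            s = _random_dna(rng, config.region_length)
            if s not in seen:
                break
        else:
            raise RuntimeError("could not draw distinct ASV sequences")
        seen.add(s)
        seqs.append(s)

    width = len(str(n))
    taxon_ids = [f"asv{str(i + 1).zfill(width)}" for i in range(n)]

    n_cult = max(1, round(config.culturable_taxa_fraction * n))
    cult_idx = set(rng.choice(n, size=n_cult, replace=False).tolist())
    culturable = {taxon_ids[i] for i in sorted(cult_idx)}

    genus_of: dict[str, str] = {}
    cn: dict[str, float] = {}
    for i, tid in enumerate(taxon_ids):
        if i in cult_idx:
            genus = CULTURABLE_GENERA[i % len(CULTURABLE_GENERA)]
            genus_of[tid] = genus
            if genus not in cn:
                cn[genus] = float(rng.choice(config.copy_number_choices))
        else:
            genus = f"Uncultured{str(i + 1).zfill(width)}"
            genus_of[tid] = genus
            cn[genus] = config.copy_number_other

    tax_strings = {
        tid: f"Bacteria;;;;;{genus_of[tid]}" for tid in taxon_ids
    }
    records = [ASVRecord(t, s, tax_strings[t]) for t, s in zip(taxon_ids, seqs)]

    full_refs = {}
    for tid, s in zip(taxon_ids, seqs):
        fwd = _concrete_primer(rng, FORWARD_515FY)
        rev = _concrete_primer(rng, REVERSE_926R)
        left = _random_dna(rng, int(rng.integers(30, 90)))
        right = _random_dna(rng, int(rng.integers(30, 90)))
        full_refs[tid] = left + fwd + s + reverse_complement(rev) + right

    base = rng.lognormal(config.lognormal_meanlog, config.lognormal_sdlog, size=n)
    cult_mask = np.array([i in cult_idx for i in range(n)])
    abundances: dict[Stratum, np.ndarray] = {}
    for stratum in config.strata:
        f = config.culturable_fraction[stratum]
        w = base * rng.lognormal(0.0, config.stratum_sdlog, size=n)
        s_c = w[cult_mask].sum()
        s_u = w[~cult_mask].sum()
        if s_c == 0 or s_u == 0:
            raise RuntimeError("degenerate abundance split between culturable and rest")
        # rescale culturable mass so its cell-scale relative abundance is
        # exactly f (reads are inflated later by operon copy numbers)
        w = w.copy()
        w[cult_mask] *= f * s_u / ((1.0 - f) * s_c) if f < 1.0 else 1.0
        if f >= 1.0:
            w[~cult_mask] = 0.0
        abundances[stratum] = w / w.sum()

    return Community(
        asv_records=records,
        full_references=full_refs,
        genus_of=genus_of,
        culturable=culturable,
        abundances=abundances,
        copy_numbers=pd.Series(cn, name="copy_number"),
    )


def simulate_counts(
    community: Community,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Multinomial read counts per sample, copy-number inflated."""
    rng = rng or np.random.default_rng(config.seed + 1)
    taxon_ids = [r.asv_id for r in community.asv_records]
    cn_per_taxon = np.array(
        [community.copy_numbers[community.genus_of[t]] for t in taxon_ids]
    )

    rows, meta_rows, index = [], [], []
    for stratum in config.strata:
        layer, size_fraction = stratum
        p = community.abundances[stratum] * cn_per_taxon
        p = p / p.sum()
        for j in range(config.n_samples_per_stratum):
            jit = int(config.reads_per_sample * config.reads_jitter)
            reads = int(config.reads_per_sample + (rng.integers(-jit, jit + 1) if jit else 0))
            rows.append(rng.multinomial(reads, p))
            sid = f"{layer}_{size_fraction}_s{j + 1:02d}"
            index.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "dataset": config.dataset_name,
                    "layer": layer,
                    "size_fraction": size_fraction,
                    "station_id": f"st{j + 1:02d}",
                }
            )
    table = AbundanceTable(
        pd.DataFrame(np.array(rows, dtype=np.int64), index=index, columns=taxon_ids)
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta


def simulate_isolates(
    community: Community,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[IsolateRecord], dict[str, str], set[str]]:
    """Draw the culture collection from the culturable taxa.

    Isolates are allocated over the isolate layers present in the config's
    strata and drawn with probability proportional to abundance^beta. With
    ``ensure_coverage`` each culturable taxon receives at least one isolate
    (quota permitting). A ``nonmatch_fraction`` of isolates get substitutions
    inside the amplicon region so they can never match.
    Returns (records, isolate->taxon map, mutated isolate ids).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    taxon_ids = [r.asv_id for r in community.asv_records]
    pos_of = {t: i for i, t in enumerate(taxon_ids)}
    cult = sorted(community.culturable)
    if not cult and config.isolate_count > 0:
        raise ValueError("no culturable taxa to draw isolates from")

    iso_layers = sorted({_SAMPLE_LAYER_TO_ISOLATE[l] for l, _ in config.strata})
    # abundance vector per isolate layer: mean over that layer's strata
    layer_abund: dict[str, np.ndarray] = {}
    for iso_layer in iso_layers:
        vecs = [
            community.abundances[s]
            for s in config.strata
            if _SAMPLE_LAYER_TO_ISOLATE[s[0]] == iso_layer
        ]
        layer_abund[iso_layer] = np.mean(vecs, axis=0)

    # source taxa: coverage pass first, then copiotroph-biased draws
    chosen: list[tuple[str, str]] = []  # (taxon, isolate layer)
    if config.ensure_coverage:
        for i, t in enumerate(cult[: config.isolate_count]):
            chosen.append((t, iso_layers[i % len(iso_layers)]))
    while len(chosen) < config.isolate_count:
        iso_layer = iso_layers[len(chosen) % len(iso_layers)]
        w = np.array(
            [layer_abund[iso_layer][pos_of[t]] ** config.copiotroph_bias for t in cult]
        )
        t = cult[int(rng.choice(len(cult), p=w / w.sum()))]
        chosen.append((t, iso_layer))

    n_iso = len(chosen)
    n_mut = round(config.nonmatch_fraction * n_iso)
    mutated_idx = set(rng.choice(n_iso, size=n_mut, replace=False).tolist()) if n_mut else set()

    stations_per_layer = {
        l: [f"{l.lower()}_st{k + 1:02d}" for k in range(DEFAULT_STATION_MODEL[l][3])]
        for l in iso_layers
    }
    records: list[IsolateRecord] = []
    iso_taxon: dict[str, str] = {}
    mutated_ids: set[str] = set()
    for i, (taxon, iso_layer) in enumerate(chosen):
        iso_id = f"iso{i + 1:04d}"
        full = community.full_references[taxon]
        # partial Sanger read: trim random flank amounts, keep the region
        region = community.asv_records[pos_of[taxon]].sequence
        start_of_region = full.index(region)
        lead = int(rng.integers(0, start_of_region + 1))
        tail = int(rng.integers(0, len(full) - (start_of_region + len(region)) + 1))
        seq = full[lead : len(full) - tail]
        if i in mutated_idx:
            seq = _mutate_region(seq, region, rng)
            mutated_ids.add(iso_id)
        records.append(
            IsolateRecord(
                isolate_id=iso_id,
                sequence=seq,
                station_id=str(rng.choice(stations_per_layer[iso_layer])),
                layer=iso_layer,
                genus=community.genus_of[taxon],
                medium=str(rng.choice(["Marine Agar 2216", "Zobell"])),
            )
        )
        iso_taxon[iso_id] = taxon
    return records, iso_taxon, mutated_ids


def _mutate_region(seq: str, region: str, rng: np.random.Generator) -> str:
    """Substitute 1-3 bases inside the embedded amplicon region."""
    pos0 = seq.index(region)
    out = list(seq)
    n_sub = int(rng.integers(1, 4))
    offsets = rng.choice(len(region), size=min(n_sub, len(region)), replace=False)
    for off in offsets:
        i = pos0 + int(off)
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def simulate_station_counts(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[StationCounts], dict[str, float]]:
    """Per-station cells/ml (cytometry) and cfu/ml (plates).

    Cells are lognormal per layer; cultivability is a per-layer beta draw
    (photic mean ~0.3%, deeper layers ~1.3-1.5%), and cfu = cells x
    cultivability. Returns the stations and the drawn cultivability truth.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    stations: list[StationCounts] = []
    truth: dict[str, float] = {}
    for layer, (mean_cells, sd, (a, b), n_st) in DEFAULT_STATION_MODEL.items():
        for k in range(n_st):
            sid = f"{layer.lower()}_st{k + 1:02d}"
            cells = float(rng.lognormal(math.log(mean_cells), sd))
            cultivability = float(rng.beta(a, b))
            stations.append(
                StationCounts(sid, layer, cfu_per_ml=cells * cultivability, cells_per_ml=cells)
            )
            truth[sid] = cultivability
    return stations, truth


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Run every generator stage and assemble the ground truth."""
    rng = np.random.default_rng(config.seed)
    community = simulate_community(config, rng)
    table, meta = simulate_counts(community, config, rng)
    isolates, iso_taxon, mutated = simulate_isolates(community, config, rng)
    stations, cultivability_truth = simulate_station_counts(config, rng)

    taxon_ids = [r.asv_id for r in community.asv_records]
    cn_per_taxon = np.array(
        [community.copy_numbers[community.genus_of[t]] for t in taxon_ids]
    )
    matchable = {
        t for i, t in iso_taxon.items() if i not in mutated
    }
    match_mask = np.array([t in matchable for t in taxon_ids])

    planted_cell, expected_reads, matchable_cell = {}, {}, {}
    cult_mask = np.array([t in community.culturable for t in taxon_ids])
    for stratum, w in community.abundances.items():
        planted_cell[stratum] = float(w[cult_mask].sum())
        matchable_cell[stratum] = float(w[match_mask].sum())
        wr = w * cn_per_taxon
        expected_reads[stratum] = 100.0 * float(wr[match_mask].sum() / wr.sum())

    truth = SyntheticTruth(
        config=config,
        culturable_taxa=set(community.culturable),
        planted_cell_fraction=planted_cell,
        expected_pct_reads=expected_reads,
        matchable_cell_fraction=matchable_cell,
        isolate_taxon=iso_taxon,
        nonmatch_isolates=mutated,
        copy_numbers=community.copy_numbers,
        station_cultivability=cultivability_truth,
    )
    return SyntheticStudy(community, table, meta, isolates, stations, truth)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write every standard-format input the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(
        [(r.asv_id, r.sequence) for r in study.community.asv_records], out / "asvs.fasta"
    )
    seqio.write_fasta(
        [(i.isolate_id, i.sequence) for i in study.isolates], out / "isolates.fasta"
    )
    seqio.write_count_table(study.table, out / "counts.tsv")
    study.sample_meta.to_csv(out / "samples.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "isolate_id": i.isolate_id,
                "station_id": i.station_id,
                "layer": i.layer,
                "genus": i.genus,
                "medium": i.medium,
            }
            for i in study.isolates
        ]
    ).to_csv(out / "isolates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "station_id": s.station_id,
                "layer": s.layer,
                "cfu_per_ml": s.cfu_per_ml,
                "cells_per_ml": s.cells_per_ml,
            }
            for s in study.stations
        ]
    ).to_csv(out / "stations.tsv", sep="\t", index=False)
    study.community.copy_numbers.rename_axis("genus").to_csv(
        out / "copy_numbers.tsv", sep="\t"
    )


def recovery_config(
    target_fraction: float,
    n_samples: int = 10,
    reads_per_sample: int = 50_000,
    seed: int = 0,
    copy_number_choices: Sequence[float] = (1.0,),
) -> SimConfig:
    """Single-stratum config used for planted-read-fraction recovery checks."""
    return SimConfig(
        n_taxa=300,
        culturable_fraction={("BATHY", "0.2-0.8"): target_fraction},
        n_samples_per_stratum=n_samples,
        reads_per_sample=reads_per_sample,
        nonmatch_fraction=0.0,
        copy_number_choices=copy_number_choices,
        copy_number_other=1.0,
        isolate_count=120,
        seed=seed,
    )
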