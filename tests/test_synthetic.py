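import math

import numpy as np
import pandas as pd
import pytest

from culturematch.matching import build_asv_index, match_isolates
from culturematch.region import extract_regions
from culturematch.synthetic import (
    SimConfig,
    simulate_community,
    simulate_station_counts,
    simulate_study,
)


def tiny_cfg(**kw):
    base = dict(
        seed=1, n_taxa=60, n_samples_per_stratum=1, reads_per_sample=3000,
        isolate_count=30,
        culturable_fraction={("BATHY", "0.2-0.8"): 0.1, ("SRF", "0.2-0.8"): 0.01},
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_study(self):
        a = simulate_study(tiny_cfg())
        b = simulate_study(tiny_cfg())
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)
        assert [i.sequence for i in a.isolates] == [i.sequence for i in b.isolates]
        assert a.truth.expected_pct_reads == b.truth.expected_pct_reads
        assert [(s.station_id, s.cfu_per_ml) for s in a.stations] == [
            (s.station_id, s.cfu_per_ml) for s in b.stations
        ]

    def test_different_seed_differs(self):
        a = simulate_study(tiny_cfg())
        b = simulate_study(tiny_cfg(seed=2))
        assert not a.table.counts.equals(b.table.counts)


class TestCommunity:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_taxa=5)
        with pytest.raises(ValueError):
            SimConfig(nonmatch_fraction=1.5)

    def test_asv_sequences_distinct_and_planted_fraction_exact(self):
        cfg = tiny_cfg()
        com = simulate_community(cfg)
        seqs = [r.sequence for r in com.asv_records]
        assert len(set(seqs)) == len(seqs)
        mask = np.array([r.asv_id in com.culturable for r in com.asv_records])
        for stratum, f in cfg.culturable_fraction.items():
            assert com.abundances[stratum][mask].sum() == pytest.approx(f)
            assert com.abundances[stratum].sum() == pytest.approx(1.0)

    def test_full_references_contain_primer_flanked_region(self):
        com = simulate_community(tiny_cfg())
        for rec in com.asv_records[:5]:
            assert rec.sequence in com.full_references[rec.asv_id]
            assert len(com.full_references[rec.asv_id]) > len(rec.sequence) + 39

    def test_lognormal_shape_abundant_head_and_rare_tail(self):
        # direct-simulation oracle: at n=100, sdlog=2 a stratum typically has
        # a >1% head and >=20 taxa under 0.1% relative abundance
        cfg = SimConfig(
            seed=9, n_taxa=100, lognormal_sdlog=2.0,
            culturable_fraction={("BATHY", "0.2-0.8"): 0.1},
        )
        com = simulate_community(cfg)
        w = com.abundances[("BATHY", "0.2-0.8")]
        assert (w > 0.01).sum() >= 1
        assert (w < 0.001).sum() >= 20

    def test_near_uniform_limit_at_tiny_sdlog(self):
        # plant f at the culturable taxa share so the rescaling factor is ~1
        # and the degenerate lognormal limit is visible across all taxa
        cfg = tiny_cfg(lognormal_sdlog=0.01, stratum_sdlog=0.01,
                       culturable_taxa_fraction=0.2,
                       culturable_fraction={("BATHY", "0.2-0.8"): 0.2})
        com = simulate_community(cfg)
        w = com.abundances[("BATHY", "0.2-0.8")]
        assert w.max() / w.min() < 1.5


class TestCounts:
    def test_rows_sum_to_reads_within_jitter(self):
        cfg = tiny_cfg(reads_jitter=0.1)
        st = simulate_study(cfg)
        sums = st.table.row_sums()
        assert ((sums - 3000).abs() <= 300).all()

    def test_no_jitter_rows_sum_exactly(self):
        st = simulate_study(tiny_cfg(reads_jitter=0.0))
        assert (st.table.row_sums() == 3000).all()

    def test_copy_number_inflation_of_read_share(self):
        # culturable taxa carry copy number 10, others 1: at cell fraction f
        # the expected read share is 10f/(10f + (1-f))
        f = 0.1
        cfg = tiny_cfg(
            copy_number_choices=(10.0,), reads_per_sample=20000,
            n_samples_per_stratum=8, nonmatch_fraction=0.0,
            culturable_fraction={("BATHY", "0.2-0.8"): f},
        )
        st = simulate_study(cfg)
        expected = 100 * 10 * f / (10 * f + (1 - f))
        assert st.truth.expected_pct_reads[("BATHY", "0.2-0.8")] == pytest.approx(
            expected, rel=1e-6
        )
        cult_cols = sorted(st.truth.culturable_taxa)
        share = (
            100.0
            * st.table.counts[cult_cols].sum(axis=1)
            / st.table.counts.sum(axis=1)
        )
        se = share.std(ddof=1) / math.sqrt(len(share))
        assert abs(share.mean() - expected) < 3 * se + 0.2

    def test_single_copy_read_share_equals_cell_fraction(self):
        f = 0.25
        cfg = tiny_cfg(
            copy_number_choices=(1.0,), reads_per_sample=20000,
            n_samples_per_stratum=8, nonmatch_fraction=0.0,
            culturable_fraction={("BATHY", "0.2-0.8"): f},
        )
        st = simulate_study(cfg)
        cult_cols = sorted(st.truth.culturable_taxa)
        share = (
            100.0
            * st.table.counts[cult_cols].sum(axis=1)
            / st.table.counts.sum(axis=1)
        )
        se = share.std(ddof=1) / math.sqrt(len(share))
        assert abs(share.mean() - 100 * f) < 3 * se + 0.2


class TestIsolates:
    def test_every_clean_isolate_matches_its_source_taxon(self):
        st = simulate_study(tiny_cfg(nonmatch_fraction=0.0))
        regions = extract_regions(st.isolates)
        match = match_isolates(regions, build_asv_index(st.community.asv_records))
        for iso_id, taxon in st.truth.isolate_taxon.items():
            assert (iso_id, taxon) in match.pairs

    def test_nonmatch_fraction_one_empties_the_match_set(self):
        st = simulate_study(tiny_cfg(nonmatch_fraction=1.0))
        regions = extract_regions(st.isolates)
        match = match_isolates(regions, build_asv_index(st.community.asv_records))
        assert match.pairs == set()

    def test_coverage_gives_every_culturable_taxon_an_isolate(self):
        st = simulate_study(tiny_cfg(nonmatch_fraction=0.0))
        sources = set(st.truth.isolate_taxon.values())
        assert st.truth.culturable_taxa <= sources

    def test_isolates_only_from_culturable_taxa(self):
        st = simulate_study(tiny_cfg())
        assert set(st.truth.isolate_taxon.values()) <= st.truth.culturable_taxa


class TestStations:
    def test_reproducible_and_positive(self):
        a, ta = simulate_station_counts(SimConfig(seed=11))
        b, tb = simulate_station_counts(SimConfig(seed=11))
        assert [(s.station_id, s.cells_per_ml) for s in a] == [
            (s.station_id, s.cells_per_ml) for s in b
        ]
        assert all(s.cfu_per_ml >= 0 and s.cells_per_ml > 0 for s in a)

    def test_truth_records_drawn_cultivability(self):
        stations, truth = simulate_station_counts(SimConfig(seed=12))
        for s in stations:
            assert 100 * s.cfu_per_ml / s.cells_per_ml == pytest.approx(
                100 * truth[s.station_id]
            )
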