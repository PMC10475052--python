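import numpy as np
import pandas as pd
import pytest

from culturematch.matching import MatchSet
from culturematch.recruitment import (
    add_corrected_percentages,
    copy_number_correct,
    filter_taxa,
    format_percent,
    pooled_recruitment,
    recruitment_per_sample,
    stratum_means,
    unmatched_isolate_fraction,
)
from culturematch.region import RegionExtract
from culturematch.seqio import AbundanceTable


def ms(*asv_ids_per_isolate):
    pairs = set()
    for iso, asvs in asv_ids_per_isolate:
        for a in asvs:
            pairs.add((iso, a))
    return MatchSet(pairs=pairs)


def table(rows, samples, asvs):
    return AbundanceTable(pd.DataFrame(rows, index=samples, columns=asvs))


class TestRecruitmentPerSample:
    toy = table([[50, 30, 20]], ["s1"], ["A", "B", "C"])

    def test_no_matches_gives_zero(self):
        out = recruitment_per_sample(self.toy, ms())
        assert out.loc["s1", "pct_asvs"] == 0.0
        assert out.loc["s1", "pct_reads"] == 0.0

    def test_all_matched_gives_hundred(self):
        out = recruitment_per_sample(self.toy, ms(("i1", ["A", "B", "C"])))
        assert out.loc["s1", "pct_asvs"] == 100.0
        assert out.loc["s1", "pct_reads"] == 100.0

    def test_hand_computed_percentages(self):
        out = recruitment_per_sample(self.toy, ms(("i1", ["A"])))
        assert out.loc["s1", "pct_asvs"] == pytest.approx(100 / 3)
        assert out.loc["s1", "pct_reads"] == pytest.approx(50.0)

    def test_presence_requires_positive_count(self):
        t = table([[50, 30, 0]], ["s1"], ["A", "B", "C"])
        out = recruitment_per_sample(t, ms(("i1", ["A", "C"])))
        # C is matched but absent: 1 of 2 present ASVs matched
        assert out.loc["s1", "n_asvs_present"] == 2
        assert out.loc["s1", "pct_asvs"] == pytest.approx(50.0)

    def test_union_semantics_no_double_counting(self):
        out = recruitment_per_sample(self.toy, ms(("i1", ["A"]), ("i2", ["A"])))
        assert out.loc["s1", "pct_reads"] == pytest.approx(50.0)

    def test_zero_read_sample_is_a_bug_here(self):
        t = table([[0, 0]], ["s1"], ["A", "B"])
        with pytest.raises(ValueError, match="s1"):
            recruitment_per_sample(t, ms())

    def test_union_subadditivity_on_random_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            n_asv = int(rng.integers(4, 12))
            counts = rng.integers(0, 50, size=(3, n_asv))
            counts[:, 0] += 1
            asvs = [f"a{j}" for j in range(n_asv)]
            t = table(counts, ["s0", "s1", "s2"], asvs)
            s1 = set(rng.choice(asvs, size=2, replace=False))
            s2 = set(rng.choice(asvs, size=3, replace=False))
            p1 = recruitment_per_sample(t, ms(("i", list(s1))))["pct_reads"]
            p2 = recruitment_per_sample(t, ms(("i", list(s2))))["pct_reads"]
            pu = recruitment_per_sample(t, ms(("i", list(s1 | s2))))["pct_reads"]
            assert ((pu >= p1 - 1e-12) & (pu >= p2 - 1e-12)).all()
            assert (pu <= p1 + p2 + 1e-12).all()


class TestFilterTaxa:
    taxonomy = {
        "A": "Archaea;Crenarchaeota;;;;",
        "B": "Bacteria;Cyanobacteria;;;;",
        "C": "Bacteria;Proteobacteria;;;;Alteromonas",
    }

    def test_empty_exclusion_is_identity(self):
        t = table([[5, 5, 5]], ["s1"], ["A", "B", "C"])
        out = filter_taxa(t, self.taxonomy, [])
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_domain_and_phylum_exclusion(self):
        t = table([[5, 5, 5]], ["s1"], ["A", "B", "C"])
        out = filter_taxa(t, self.taxonomy, ["domain:Archaea", "phylum:Cyanobacteria"])
        assert out.asv_ids == ["C"]

    def test_emptied_samples_dropped_with_warning(self):
        t = table([[5, 0], [0, 3]], ["s1", "s2"], ["A", "C"])
        with pytest.warns(UserWarning, match="emptied"):
            out = filter_taxa(t, self.taxonomy, ["domain:Archaea"])
        assert out.sample_ids == ["s2"]

    def test_pct_reads_never_decreases_when_no_matched_asv_excluded(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            counts = rng.integers(1, 50, size=(2, 6))
            asvs = [f"a{j}" for j in range(6)]
            tax = {a: ("Archaea;;;;;" if rng.random() < 0.3 else "Bacteria;;;;;") for a in asvs}
            t = table(counts, ["s0", "s1"], asvs)
            matched = [a for a in asvs if tax[a].startswith("Bacteria")][:2]
            if not matched:
                continue
            before = recruitment_per_sample(t, ms(("i", matched)))["pct_reads"]
            filtered = filter_taxa(t, tax, ["domain:Archaea"])
            after = recruitment_per_sample(filtered, ms(("i", matched)))["pct_reads"]
            assert (after >= before - 1e-12).all()


class TestCopyNumberCorrection:
    @pytest.mark.parametrize(
        "raw,expected",
        [(1.6, "0.5"), (4.8, "1.4"), (8.5, "2.4"), (27.9, "8"), (0.0, "0")],
    )
    def test_published_worked_examples(self, raw, expected):
        assert format_percent(copy_number_correct(raw, 3.5)) == expected

    def test_linearity(self):
        a, b, m = 3.7, 9.1, 3.5
        assert copy_number_correct(a + b, m) == pytest.approx(
            copy_number_correct(a, m) + copy_number_correct(b, m)
        )

    def test_median_below_one_rejected(self):
        with pytest.raises(ValueError):
            copy_number_correct(10.0, 0.5)

    def test_corrected_column(self):
        t = table([[50, 50]], ["s1"], ["A", "B"])
        summ = recruitment_per_sample(t, ms(("i", ["A"])))
        out = add_corrected_percentages(summ, 2.0)
        assert out.loc["s1", "pct_reads_corrected"] == pytest.approx(25.0)


class TestStratumMeans:
    meta = pd.DataFrame(
        {
            "dataset": ["d", "d", "d", "d"],
            "layer": ["SRF", "SRF", "BATHY", "BATHY"],
            "size_fraction": ["0.2-0.8"] * 4,
            "station_id": ["st1", "st2", "st3", "st4"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )

    def summary(self, values):
        return pd.DataFrame(
            {"pct_reads": values},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )

    def test_mean_of_two_samples(self):
        out = stratum_means(self.summary([10, 30, 1, 1]), self.meta, ["layer"])
        assert out.loc["SRF", "pct_reads_mean"] == pytest.approx(20.0)

    def test_single_sample_stratum_reports_sd_absent(self):
        meta = self.meta.iloc[:3]
        out = stratum_means(self.summary([10, 30, 5, 0]).iloc[:3], meta, ["layer"])
        assert np.isnan(out.loc["BATHY", "pct_reads_sd"])

    def test_strata_partition_samples(self):
        out = stratum_means(self.summary([1, 2, 3, 4]), self.meta, ["layer", "size_fraction"])
        assert out["n_samples"].sum() == 4

    def test_missing_metadata_is_error(self):
        with pytest.raises(ValueError, match="s4"):
            stratum_means(self.summary([1, 2, 3, 4]), self.meta.iloc[:3], ["layer"])

    def test_planted_depth_gradient_recovered(self, small_study):
        """End-to-end on the shared synthetic study: deeper layers recruit more."""
        from culturematch.matching import build_asv_index, match_isolates
        from culturematch.rarefy import rarefy_permuted
        from culturematch.region import extract_regions

        st = small_study
        regions = extract_regions(st.isolates)
        match = match_isolates(regions, build_asv_index(st.community.asv_records))
        rare = rarefy_permuted(st.table, n_permutations=50, seed=1)
        summ = recruitment_per_sample(rare.table, match)
        strat = stratum_means(summ, st.sample_meta, ["layer"])
        means = strat["pct_reads_mean"]
        assert means["SRF"] < means["MESO"] < means["BATHY"]


class TestUnmatchedIsolates:
    def regions(self, ids, too_short=()):
        return [
            RegionExtract(i, "ACGT" * 50, True, True, "PLUS", too_short=i in too_short)
            for i in ids
        ]

    def test_all_matched_is_zero(self):
        regs = self.regions(["i1", "i2"])
        overall, _ = unmatched_isolate_fraction(regs, ms(("i1", ["A"]), ("i2", ["B"])))
        assert overall == 0.0

    def test_none_matched_is_hundred(self):
        regs = self.regions(["i1", "i2"])
        overall, _ = unmatched_isolate_fraction(regs, ms())
        assert overall == 100.0

    def test_too_short_excluded_from_denominator(self):
        regs = self.regions(["i1", "i2", "i3"], too_short=("i3",))
        overall, _ = unmatched_isolate_fraction(regs, ms(("i1", ["A"])))
        assert overall == pytest.approx(50.0)

    def test_per_stratum_breakdown(self):
        regs = self.regions(["i1", "i2", "i3", "i4"])
        overall, per = unmatched_isolate_fraction(
            regs,
            ms(("i1", ["A"]), ("i3", ["B"])),
            strata={"i1": "PHOTIC", "i2": "PHOTIC", "i3": "BATHY", "i4": "BATHY"},
        )
        assert overall == pytest.approx(50.0)
        per = per.set_index("stratum")
        assert per.loc["PHOTIC", "pct_unmatched"] == pytest.approx(50.0)

    def test_planted_nonmatch_fraction_recovered_exactly(self):
        """Mutated isolates are the only unmatched ones in a clean study."""
        from culturematch.matching import build_asv_index, match_isolates
        from culturematch.region import extract_regions
        from culturematch.synthetic import SimConfig, simulate_study

        cfg = SimConfig(
            seed=23, n_taxa=80, n_samples_per_stratum=1, reads_per_sample=2000,
            isolate_count=40, nonmatch_fraction=0.25,
        )
        st = simulate_study(cfg)
        regions = extract_regions(st.isolates)
        match = match_isolates(regions, build_asv_index(st.community.asv_records))
        overall, _ = unmatched_isolate_fraction(regions, match)
        assert overall == pytest.approx(100.0 * len(st.truth.nonmatch_isolates) / 40)
        assert len(st.truth.nonmatch_isolates) == round(0.25 * 40)


class TestPooled:
    def test_pooled_percentages(self):
        t = table([[10, 0, 0], [0, 10, 0]], ["s1", "s2"], ["A", "B", "C"])
        out = pooled_recruitment(t, ms(("i", ["A"])))
        assert out["pooled_pct_asvs"] == pytest.approx(50.0)  # C absent everywhere
        assert out["pooled_pct_reads"] == pytest.approx(50.0)
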