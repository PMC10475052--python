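"""Full pipeline on a synthetic ocean study: simulate, match, rarefy, summarise.

Generates a community with known culturable fractions per depth layer and
size fraction, runs region extraction, exact-containment matching and
permutation rarefaction, and prints per-stratum recruitment percentages.
"""

from culturematch.matching import build_asv_index, match_isolates
from culturematch.rarefy import rarefy_permuted
from culturematch.recruitment import (
    add_corrected_percentages,
    recruitment_per_sample,
    stratum_means,
    unmatched_isolate_fraction,
)
from culturematch.region import extract_regions
from culturematch.seqio import median_copy_number
from culturematch.synthetic import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=42))
print(f"community: {len(study.community.asv_records)} ASVs, "
      f"{len(study.isolates)} isolates, {len(study.table.sample_ids)} samples")

regions = extract_regions(study.isolates)
match = match_isolates(regions, build_asv_index(study.community.asv_records))
print(f"matching: {len(match.pairs)} isolate-ASV pairs at 100% identity, "
      f"{len(match.matched_asvs)} distinct ASVs recruited")

rarefied = rarefy_permuted(study.table, n_permutations=200, seed=42)
summary = recruitment_per_sample(rarefied.table, match)
# the correction divides by the median copy number of the ISOLATED genera
isolated_genera = sorted({iso.genus for iso in study.isolates if iso.genus})
med = median_copy_number(study.community.copy_numbers[isolated_genera])
print(f"median rRNA operon copy number of isolated genera: {med}")
summary = add_corrected_percentages(summary, med)

strat = stratum_means(summary, study.sample_meta, ["layer", "size_fraction"])
cols = ["pct_asvs_mean", "pct_reads_mean", "pct_reads_corrected_mean"]
print("\nper-stratum recruitment (mean over samples):")
print(strat[cols].round(1))

unmatched, _ = unmatched_isolate_fraction(regions, match)
print(f"\nisolates matching no ASV: {unmatched:.1f}%")
print("\npct_reads rises with depth and particle size: the planted culturable")
print("taxa carry more of the community in deep and particle-attached strata,")
print("and the corrected column divides out the rRNA operon copy-number bias.")
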