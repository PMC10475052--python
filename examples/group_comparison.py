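"""Nonparametric comparison of recruitment percentages between strata.

Kruskal-Wallis tests whether any depth layer differs in the fraction of
reads recruited by isolates; Holm-adjusted pairwise rank-sum tests say
which pairs differ.
"""

from culturematch.matching import build_asv_index, match_isolates
from culturematch.rarefy import rarefy_permuted
from culturematch.recruitment import recruitment_per_sample
from culturematch.region import extract_regions
from culturematch.stats import kruskal_wallis, pairwise_wilcoxon
from culturematch.synthetic import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=5, n_samples_per_stratum=6))
match = match_isolates(
    extract_regions(study.isolates), build_asv_index(study.community.asv_records)
)
rarefied = rarefy_permuted(study.table, n_permutations=100, seed=5)
summary = recruitment_per_sample(rarefied.table, match)

layers = study.sample_meta.loc[summary.index, "layer"]
groups = {lay: summary.loc[layers == lay, "pct_reads"].tolist() for lay in layers.unique()}

omnibus = kruskal_wallis(groups)
print(f"Kruskal-Wallis: H={omnibus.statistic:.2f}, df={omnibus.df}, "
      f"p={omnibus.p_value:.2e} ({'significant' if omnibus.significant else 'ns'} at 0.05)")

posthoc = pairwise_wilcoxon(groups, adjust_method="holm")
print("\npost hoc pairwise rank-sum tests (Holm-adjusted):")
print(posthoc.round(4).to_string(index=False))
print("\nthe planted depth gradient makes the omnibus strongly significant;")
print("adjusted p-values control the family-wise error over the six pairs.")
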