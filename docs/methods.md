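# Methods

## Problem and pipeline

A culture collection of marine heterotrophic bacteria (isolates with partial
16S rRNA sequences, 300–900 nt, possibly containing IUPAC ambiguity codes)
is compared with 16S amplicon datasets: ASV representative sequences plus an
ASV × sample integer count table with per-sample metadata (dataset, depth
layer SRF/DCM/MESO/BATHY, plankton size fraction, station). The pipeline is:

1. **Region extraction** — locate the amplicon primer sites on the isolate
   sequence and cut out the span strictly between them.
2. **Matching** — find every (isolate, ASV) pair where the ASV occurs
   verbatim inside the isolate's region.
3. **Rarefaction** — subsample every sample to the lowest sampling effort.
4. **Recruitment** — per-sample percentages of ASVs and reads matched,
   stratum means, copy-number correction, unmatched-isolate fractions.
5. **Classification** — biosphere classes from mean relative abundance;
   genus occurrence categories over stations.
6. **Cultivability** — cfu/ml over cells/ml per station, per-layer summary.
7. **Statistics** — Kruskal–Wallis omnibus plus Holm-adjusted pairwise
   rank-sum tests.

## Region extraction

Primers default to 515F-Y (`GTGYCAGCMGCCGCGGTAA`) and 926R
(`CCGYCAATTYMTTTRAGTTT`); both are degenerate IUPAC strings. A window
position matches a primer position iff every base the window code could
stand for is allowed by the primer code (an `N` in the sequence matches
anything). Extraction scans the plus strand for the forward primer, then the
reverse complement (orientation MINUS); the reverse primer is searched as
its reverse complement downstream of the forward site. Primer-annealing
spans are excluded from the region because amplicon reads are primer-trimmed
before denoising, so ASVs carry no primer sequence. Fallbacks: forward found
but reverse absent → region runs to the sequence end; neither found → the
whole (oriented) sequence with both flags false, because Sanger reads
obtained with other primers may start inside V4 — the containment rule in
the matcher remains the binding constraint. Regions shorter than
`min_length` (default 100 nt, about a quarter of the 373 nt V4–V5 span) are
flagged `too_short` and excluded from matching and from unmatched-isolate
denominators. Extraction uses 0 mismatches; a separate diagnostic
(`min_primer_mismatches`) reports the best achievable mismatch count per
primer and sequence, which answers whether the amplicon primers could in
principle have captured an organism that was never observed in the TAGs.

When no forward-primer site exists on either strand the orientation is
reported as PLUS (it is undefined); strand symmetry — extract(rc(s)) equals
extract(s) — holds whenever a primer site exists and is asserted for such
sequences in the tests.

## Matching

Match semantics: 100% identity with 100% ASV coverage and no gaps, i.e. the
ASV string is a contiguous substring of the isolate region. The direction is
fixed — the ASV inside the region, never the reverse — so an isolate region
shorter than an ASV can never match it (such isolates are reported). All
hits per isolate are kept; the matched-ASV set is a union, so an ASV hit by
several isolates counts once.

The index seeds on the first k = 31 bases of each ASV and verifies every
candidate in full, so its semantics are exactly those of a naive O(n·m)
scan; ASVs shorter than k go to a brute-force list. Correctness is defined
by the naive scan, which the tests and the acceptance script run as an
independent oracle on hundreds of random instances with planted containments
and single-substitution decoys.

Ambiguity policy: STRICT (default) — an ambiguity code in the isolate region
never matches, so a stray `N` cannot create a false positive; EXPAND — a
code matches any base in its expansion. STRICT ⊆ EXPAND by construction.

The multi-hit report ranks each isolate's hits by mean relative abundance of
the matched ASV (ties broken by ASV id) and reports the dataset-level read
share counting all hits minus counting only top hits, both on union sets —
the quantity that says how much multi-hit isolates could inflate
recruitment.

## Rarefaction

Single draws are multivariate hypergeometric (reads are physical draws from
a finite pool, so sampling is without replacement; a multinomial would
overdisperse). `rarefy_permuted` averages `n_permutations` (default 1000)
independent draws per sample at a common depth (default: the minimum
retained row sum) and rounds half-even; unrounded means are kept for
downstream ranking. Samples shallower than an explicit depth are dropped
with a record of what was dropped. Reproducibility: one master seed, with
the per-sample substream derived as `default_rng([seed, sample_position])`,
so results do not depend on evaluation order. Zeros stay zero; each single
draw sums exactly to depth; rounded rows can deviate from depth by at most
half an ASV count each.

Isolate accumulation curves first dereplicate isolates at 100% identity
(identical region strings share an isolate-OTU named after the
lexicographically smallest member) and then average cumulative richness over
random station orderings; the curve is exact at its endpoints (richness of
one sample; total richness at all samples). The permutation method is used
throughout rather than the analytic expectation, with the exact endpoints as
internal checks.

## Recruitment and copy-number correction

An ASV is "present" in a sample iff its rarefied count is > 0. `pct_asvs`
uses per-sample richness as the denominator (each sample contributes one
point to stratum distributions); pooled dataset-level variants are emitted
separately and labeled as such. Stratum summaries are unweighted means and
sample standard deviations over samples; a stratum with one sample reports
sd as absent, never zero. Taxon filtering removes ASVs carrying excluded
rank-qualified labels (e.g. `domain:Archaea`, `phylum:Cyanobacteria`) before
the percentages, for sensitivity analyses without phototrophs/Archaea.

The correction divides read percentages by the **median rRNA operon copy
number of the isolated genera** (midpoint rule for even counts; the
canonical value is 3.5). Reporting rounds to one decimal and collapses
trailing zeros (8.0 → "8"). The correction is linear and exact only to first
order: if culturable taxa at cell fraction f carry c copies against a
single-copy background, the observed read share is 100·cf/(cf+1−f), and
dividing by c yields 100·f/(1+(c−1)f) — an *under*-estimate whose residual
bias relative to the uncorrected inflation is exactly f/(1−f). The
single-divisor correction therefore removes ≥80% of the inflation bias only
where the culturable cell fraction is ≤ 1/6 ≈ 17% — comfortably the regime
of the default study conditions (0.4–12.5% per stratum) — and degrades to
nothing as f → 1/2. A per-genus correction mode would remove the remaining
bias but is deliberately out of scope for the headline statistic, which
follows the single-median definition.

## Classification

Biosphere classes on mean relative abundance x̄(a) (per-sample relative
abundances averaged unweighted over samples): ABUNDANT iff x̄ > 1%, RARE iff
x̄ < 0.01%, MID otherwise. Both boundary values close into MID because the
verbal definitions are strict on both sides of MID's neighbours. Rank tables
sort by unrounded mean with lexicographic tie-breaks, making the output a
deterministic permutation of the ASV set.

Occurrence categories per genus on the fraction of stations with ≥1 isolate
of that genus (station universe = distinct stations among all isolates):
UBIQUITOUS > 0.80, WIDESPREAD ≥ 0.50, REGIONAL > 0.25, else LOCAL. The mixed
strict/inclusive boundaries reproduce the usual verbal categories; the
policy is a frozen dataclass users can replace.

## Cultivability

`pct_cultivable = 100 · cfu_per_ml / cells_per_ml` with cells from flow
cytometry of heterotrophic prokaryotes (phototrophs excluded upstream — the
plating media never target them). Values above 100% warn but are returned
(replicate plating can pathologically exceed cytometry). Layer summaries
report mean, min, max. Group significance is delegated to the stats module's
nonparametric route for every comparison in the package, including
cultivability, where a parametric ANOVA would be the traditional alternative
— one consistent route rather than two.

## Statistics

The omnibus is the tie-corrected Kruskal–Wallis H (scipy implementation)
with a χ² approximation on k−1 df, used regardless of sample size; an
explicit permutation mode exists for tiny inputs and is validated against
exhaustive enumeration in the tests. All-identical data return H = 0, p = 1
rather than an error. Pairwise comparisons are two-sided rank-sum tests:
exact enumeration when a group has fewer than 2 observations or the pooled
size is ≤ 8, otherwise the normal approximation with tie and continuity
correction; the route taken is recorded per pair. Multiplicity control is
Holm by default (bonferroni and none available) — the R default for the
pairwise-Wilcoxon family, which is the most likely match to common practice.

Known property: the χ² approximation is slightly conservative at moderate
sizes — at 4 groups × 10 observations its true size at α = 0.05 is ≈ 0.043
(confirmed independently with R's `kruskal.test`), not 0.05. The
`type_one_error_sim` harness measures exactly this, so empirical rates just
above 0.04 at that design are the method behaving as documented, not a bug.

## Synthetic generator

The generator emulates the structure of global marine amplicon + culture
studies; its defaults are the study conditions used by the tests.

* **Rank abundance**: taxon abundances are lognormal(meanlog 0, sdlog 2;
  n_taxa 300) — the standard long-tailed marine shape with a few taxa above
  1% and a substantial tail below 0.01%. Per stratum the shared base
  abundances are jittered by lognormal(0, 0.5) noise and renormalised.
* **Planted culturability**: a global 20% of taxa are culturable, assigned
  to genera commonly recovered on marine rich media; per stratum their
  abundance mass is rescaled so the culturable *cell* fraction equals a
  configured target exactly. Defaults rise from 0.4–0.5% (photic
  free-living) to 8% (bathypelagic free-living) and 12.5% (deep particles) —
  the corrected, cell-scale equivalents of field observations, so that under
  copy-number inflation the *observed* read percentages land in the familiar
  1.5–33% range.
* **Copy numbers**: culturable genera draw from {3, 3.5, 4} operon copies
  (median 3.5), everything else is single-copy; read counts per sample are
  multinomial with probabilities ∝ abundance × copy number at 50 000 reads
  (±10% jitter), so sequencing over-represents the culturable fraction and
  the correction is testable against the planted cell-scale truth.
* **Isolates**: 200 isolates drawn from culturable taxa with probability ∝
  abundance^β (β = 1, the copiotroph bias; coverage mode guarantees every
  culturable taxon at least one isolate). Each isolate sequence embeds its
  taxon's full reference (random flanks + concrete primer realisations +
  region), randomly truncated like a partial Sanger read but always
  retaining the region; a nonmatch fraction (default 11%, matching typical
  unmatched-isolate rates) receives 1–3 substitutions inside the region so
  it can never match. ASV sequences are random distinct 373 nt strings —
  the matcher is exact, so base-composition realism adds nothing.
* **Stations**: cells/ml lognormal per layer (8×10⁵ photic, 1.2×10⁵
  mesopelagic, 5×10⁴ bathypelagic, sdlog 0.4); cultivability per station is
  a Beta draw with layer means ≈ 0.3% (photic) and ≈ 1.3–1.5% (deep), and
  cfu = cells × cultivability.

The truth object records the culturable set, planted cell fractions, the
expected read-scale pct_reads (copy-number weighted share of taxa with ≥1
clean isolate), the isolate→taxon map, the mutated isolates and the drawn
cultivabilities — enough to compute every expected downstream statistic
without re-running the generator.

What the generator does **not** emulate: sequencing error and chimeras
(ASVs are taken as correctly denoised), within-taxon 16S polymorphism,
phylogenetic structure among sequences, compositional correlation between
taxa beyond the shared lognormal base, and live/dead or VBNC distinctions.
Passing tests therefore demonstrate the pipeline's arithmetic and its
recovery of planted structure, not robustness to denoising artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately compact sizes chosen to
keep Monte-Carlo error well below the assertion tolerances: 500 random
matcher instances up to 500 ASVs × 100 regions; 20 000 rarefaction
permutations for the hypergeometric-convergence check; recovery at 10
samples × 50 000 reads for planted fractions f ∈ {0.05, 0.25, 0.5} with 1000
rarefaction permutations; the default 8-stratum study at 3 samples per
stratum for the bias-reduction measurement; 10 000 null replicates for the
type-I-error harness. Monte-Carlo assertions use 3× the relevant standard
error. Seeds are explicit everywhere; identical seeds give bit-identical
output, including across the per-sample rarefaction substreams.

Tie-breaking is lexicographic wherever an order is needed (rank tables,
multi-hit ranking, OTU naming). Rounding of rarefied means is half-even to
avoid systematic upward bias. Readers reject malformed input (duplicate ids,
non-integer or negative counts, unknown vocabulary) with messages naming the
offending record, and never repair it.

## Limitations

* The 100% identity / 100% coverage rule is maximally strict: a single
  polymorphism between an isolate's ribotype and the environmental ASV
  breaks the match, so recruitment percentages are lower bounds.
* The single-median copy-number correction under-corrects at high culturable
  fractions (residual bias f/(1−f) of the original inflation; see above).
* pct_asvs depends on rarefaction depth through per-sample richness;
  comparisons should use tables rarefied together.
* The occurrence categories treat stations as exchangeable units and ignore
  how many isolates per station support a genus.
* The χ² omnibus is conservative at small-to-moderate group sizes; use the
  permutation mode when exact size matters.
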