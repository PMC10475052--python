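"""Locate the 515F-Y / 926R primer sites and cut out the V4-V5 region.

Isolate 16S fragments were sequenced with other primers, so they are
comparable with amplicon ASVs only over the span the amplicon primers
delimit. This script builds three illustrative isolates: one with both
primer sites, one on the reverse strand, and one with no primer sites.
"""

import numpy as np

from culturematch.region import extract_common_region, min_primer_mismatches, reverse_complement
from culturematch.region import FORWARD_515FY, REVERSE_926R
from culturematch.seqio import IsolateRecord

rng = np.random.default_rng(0)
dna = lambda n: "".join(rng.choice(list("ACGT"), size=n))

fwd_site = "GTGTCAGCAGCCGCGGTAA"                      # one realisation of 515F-Y
rev_site = reverse_complement("CCGTCAATTCATTTGAGTTT")  # one realisation of 926R, rc'd
v4v5 = dna(373)

isolates = [
    IsolateRecord("iso_plus", dna(40) + fwd_site + v4v5 + rev_site + dna(40)),
    IsolateRecord("iso_minus", reverse_complement(dna(25) + fwd_site + v4v5 + rev_site)),
    IsolateRecord("iso_noprimer", dna(500)),
]

for iso in isolates:
    res = extract_common_region(iso)
    print(f"{iso.isolate_id:>13}: fwd={res.fwd_found} rev={res.rev_found} "
          f"strand={res.orientation} region={len(res.region_sequence)} nt "
          f"too_short={res.too_short}")

print("\nthe two primer-bearing isolates yield the same 373 nt region;",
      "the primer-free one falls back to its whole sequence.")
mm = min_primer_mismatches(isolates[2].sequence, FORWARD_515FY)
print(f"diagnostic: best achievable forward-primer match on the primer-free "
      f"isolate is {mm} mismatches — random DNA, so the primer would not anneal.")
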