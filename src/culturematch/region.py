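"""Degenerate-primer location and extraction of the V4-V5 common region.

Isolate 16S fragments were Sanger-sequenced with primers different from the
amplicon primers, so isolates and ASVs are only comparable over the span the
amplicon primer pair delimits. The default pair is 515F-Y / 926R; primer
annealing sites are excluded from the extracted region, matching
primer-trimmed amplicon reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .seqio import IsolateRecord

FORWARD_515FY = "GTGYCAGCMGCCGCGGTAA"
REVERSE_926R = "CCGYCAATTYMTTTRAGTTT"

#: IUPAC code -> set of unambiguous bases it stands for
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    forward: str = FORWARD_515FY
    reverse: str = REVERSE_926R
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p or set(p) - set(IUPAC_EXPANSION):
                raise ValueError(f"{name} primer is not a non-empty IUPAC string: {p!r}")


@dataclass(frozen=True)
class RegionExtract:
    """Outcome of primer-delimited region extraction for one isolate."""

    isolate_id: str
    region_sequence: str
    fwd_found: bool
    rev_found: bool
    orientation: str  # PLUS or MINUS
    too_short: bool = False


def iupac_match_count(window: str, primer: str) -> int:
    """Mismatches between a sequence window and a degenerate primer.

    Position i matches when the window base is compatible with the primer
    code: an N in the window matches anything; any other window code matches
    iff everything it could stand for is allowed by the primer code.
    """
    if len(window) != len(primer):
        raise ValueError(
            f"window length {len(window)} != primer length {len(primer)}"
        )
    mismatches = 0
    for w, p in zip(window, primer):
        if w == "N":
            continue
        if not IUPAC_EXPANSION[w] <= IUPAC_EXPANSION[p]:
            mismatches += 1
    return mismatches


def find_primer(seq: str, primer: str, max_mismatches: int = 0) -> Optional[int]:
    """Leftmost plus-strand position where the primer anneals, or None."""
    m = len(primer)
    for i in range(len(seq) - m + 1):
        if iupac_match_count(seq[i : i + m], primer) <= max_mismatches:
            return i
    return None


def min_primer_mismatches(seq: str, primer: str) -> Optional[int]:
    """Diagnostic: smallest achievable mismatch count over both strands.

    Answers whether the amplicon primers could in principle capture an
    organism whose partial 16S sequence never yields a 0-mismatch site.
    Returns None when the sequence is shorter than the primer.
    """
    best: Optional[int] = None
    for s in (seq, reverse_complement(seq)):
        m = len(primer)
        for i in range(len(s) - m + 1):
            c = iupac_match_count(s[i : i + m], primer)
            if best is None or c < best:
                best = c
                if best == 0:
                    return 0
    return best


def extract_common_region(
    isolate: IsolateRecord,
    primers: PrimerPair = PrimerPair(),
    min_length: int = 100,
) -> RegionExtract:
    """Extract the span strictly between the primer annealing sites.

    The forward primer is searched on the plus strand, then on the reverse
    complement (orientation MINUS). The reverse primer is searched as its
    reverse complement downstream of the forward site. Fallbacks: forward
    found but reverse absent -> region runs to the sequence end; neither
    found -> the whole (oriented) sequence with both flags false. Regions
    shorter than ``min_length`` are flagged ``too_short`` and should be
    excluded from matching.
    """
    seq = isolate.sequence
    orientation = "PLUS"
    fpos = find_primer(seq, primers.forward, primers.max_mismatches)
    if fpos is None:
        rc = reverse_complement(seq)
        fpos_rc = find_primer(rc, primers.forward, primers.max_mismatches)
        if fpos_rc is not None:
            seq, fpos, orientation = rc, fpos_rc, "MINUS"

    rev_found = False
    if fpos is None:
        region = seq
        fwd_found = False
    else:
        fwd_found = True
        start = fpos + len(primers.forward)
        rc_rev = reverse_complement(primers.reverse)
        rpos = find_primer(seq[start:], rc_rev, primers.max_mismatches)
        if rpos is None:
            region = seq[start:]
        else:
            region = seq[start : start + rpos]
            rev_found = True

    return RegionExtract(
        isolate_id=isolate.isolate_id,
        region_sequence=region,
        fwd_found=fwd_found,
        rev_found=rev_found,
        orientation=orientation,
        too_short=len(region) < min_length,
    )


def extract_regions(
    isolates: Iterable[IsolateRecord],
    primers: PrimerPair = PrimerPair(),
    min_length: int = 100,
) -> list[RegionExtract]:
    """Extract the common region for every isolate in a collection."""
    return [extract_common_region(iso, primers, min_length) for iso in isolates]
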