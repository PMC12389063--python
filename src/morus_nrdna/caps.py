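"""In-silico ITS-CAPS: PCR, degenerate restriction digestion, banding calls.

The assay amplifies the ITS span plus short 18S/26S flanks with
mulberry-specific primers, digests the amplicon with BstEII (G^GTNACC) and
MstI (TGC^GCA, blunt) and reads the species call off the banding pattern:
an amplicon uncut by both enzymes is M. notabilis; a ~449 bp BstEII band
without a ~602-604 bp MstI band is M. alba; the converse is the
nigra group (M. nigra / M. serrata / M. celtidifolia / M. rubra); both
together are the signature of an accession heterogeneous for the 13 bp
ITS1 insertion.  Both recognition motifs are palindromic under IUPAC
complement, so scanning the plus strand finds every double-strand cut.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

FORWARD_PRIMER = "GTAACAAGGTTTCCGTAGGTG"
REVERSE_PRIMER = "TAAACTCAGCGGGTAGCC"

_COMPLEMENT = str.maketrans("ACGTNRYKMSW", "TGCANYRMKSW")

IUPAC_MATCH = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
}

BandingLabel = Literal[
    "M. alba", "M. notabilis", "nigra_group", "heterogeneous_indel", "unresolved"
]


class AmpliconError(ValueError):
    """No unique amplicon for the primer pair on the template."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: IUPAC recognition motif and cut offset.

    ``cut_offset`` is the number of motif bases left of the cut on the
    scanned strand, so a site starting at 1-based position m cuts after
    position m + cut_offset - 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 < self.cut_offset < len(self.recognition):
            raise ValueError("cut offset must fall inside the motif")


BSTEII = Enzyme("BstEII", "GGTNACC", 1)
MSTI = Enzyme("MstI", "TGCGCA", 3)


def _find_exact_or_mismatch(
    template: str, probe: str, max_mismatch: int
) -> list[int]:
    """0-based start positions where probe matches with <= max_mismatch."""
    if max_mismatch == 0:
        hits, start = [], template.find(probe)
        while start != -1:
            hits.append(start)
            start = template.find(probe, start + 1)
        return hits
    hits = []
    k = len(probe)
    for start in range(len(template) - k + 1):
        mism = 0
        for a, b in zip(template[start : start + k], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(start)
    return hits


def insilico_pcr(
    template: str,
    primers: PrimerPair | None = None,
    max_mismatch: int = 0,
) -> str:
    """Extract the unique amplicon delimited by the primer pair.

    The forward primer is located on the plus strand and the reverse
    primer as its reverse complement downstream; the amplicon runs from
    the forward-primer start through the reverse site end, inclusive.
    """
    if not template:
        raise ValueError("empty template")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    primers = primers or PrimerPair()
    template = template.upper()
    fwd_hits = _find_exact_or_mismatch(template, primers.forward, max_mismatch)
    rev_site = reverse_complement(primers.reverse)
    rev_hits = _find_exact_or_mismatch(template, rev_site, max_mismatch)
    products = [
        template[f : r + len(rev_site)]
        for f in fwd_hits
        for r in rev_hits
        if r > f + len(primers.forward) - 1
    ]
    if not products:
        raise AmpliconError("no amplicon: primer site missing")
    if len(products) > 1:
        raise AmpliconError(
            f"ambiguous amplification: {len(products)} candidate products"
        )
    return products[0]


def _motif_regex(motif: str):
    """Overlap-tolerant regex for an IUPAC motif (lookahead per position)."""
    classes = {
        base: (base if len(chars) == 1 else "[" + "".join(sorted(chars)) + "]")
        for base, chars in IUPAC_MATCH.items()
    }
    return re.compile("(?=" + "".join(classes[b] for b in motif.upper()) + ")")


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted cut positions (bases left of each cut) on the plus strand."""
    pattern = _motif_regex(enzyme.recognition)
    return [
        m.start() + enzyme.cut_offset for m in pattern.finditer(seq.upper())
    ]


def digest(amplicon: str, enzyme: Enzyme) -> Counter:
    """Fragment-length multiset from cutting the amplicon with one enzyme."""
    cuts = find_sites(amplicon, enzyme)
    bounds = [0, *cuts, len(amplicon)]
    return Counter(b - a for a, b in zip(bounds, bounds[1:]))


def _as_counter(fragments) -> Counter:
    return fragments if isinstance(fragments, Counter) else Counter(fragments)


def classify_banding(
    bste2_fragments,
    mst1_fragments,
    tol: int = 5,
) -> tuple[BandingLabel, dict]:
    """Species call from BstEII and MstI fragment multisets.

    The classifier keys only on the robust bands: the undigested amplicon,
    the ~449 bp BstEII band and the ~602-604 bp MstI band; small fragments
    (91/100 bp) are often too faint on a gel to score.  Fragment inputs may
    be unions over both alleles of a heterozygous accession.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    bste2 = _as_counter(bste2_fragments)
    mst1 = _as_counter(mst1_fragments)
    if not bste2 or not mst1:
        raise ValueError("both digestion results are required")

    evidence: dict = {}
    if len(bste2) == 1 and len(mst1) == 1:
        (b_len,), (m_len,) = list(bste2), list(mst1)
        if bste2[b_len] == 1 and mst1[m_len] == 1 and abs(b_len - m_len) <= tol:
            evidence["undigested"] = b_len
            return "M. notabilis", evidence

    band_449 = [f for f in bste2 if abs(f - 449) <= tol]
    band_603 = [f for f in mst1 if 602 - tol <= f <= 604 + tol]
    if band_449:
        evidence["bste2_449"] = band_449
    if band_603:
        evidence["mst1_603"] = band_603
    if band_449 and band_603:
        return "heterogeneous_indel", evidence
    if band_449:
        return "M. alba", evidence
    if band_603:
        return "nigra_group", evidence
    return "unresolved", evidence


@dataclass(frozen=True)
class AmpliconDigest:
    """Amplicon with per-enzyme cut positions and fragment multisets."""

    template_id: str
    amplicon_length: int
    cut_positions: dict
    fragments: dict

    def __post_init__(self) -> None:
        for name, frags in self.fragments.items():
            total = sum(length * count for length, count in frags.items())
            if total != self.amplicon_length:
                raise ValueError(
                    f"{self.template_id}/{name}: fragments sum to {total}, "
                    f"not {self.amplicon_length}"
                )
            if sum(frags.values()) != len(self.cut_positions[name]) + 1:
                raise ValueError(
                    f"{self.template_id}/{name}: fragment count must be cuts+1"
                )


def digest_template(
    template_id: str,
    template: str,
    primers: PrimerPair | None = None,
    enzymes: Sequence[Enzyme] = (BSTEII, MSTI),
    max_mismatch: int = 0,
) -> AmpliconDigest:
    """PCR the template and digest the amplicon with each enzyme."""
    amplicon = insilico_pcr(template, primers, max_mismatch)
    cuts = {e.name: find_sites(amplicon, e) for e in enzymes}
    frags = {e.name: digest(amplicon, e) for e in enzymes}
    return AmpliconDigest(template_id, len(amplicon), cuts, frags)


def _format_fragments(frags: Counter) -> str:
    return "/".join(
        str(length) for length in sorted(frags.elements())
    )


def write_digest_report(
    digests: Iterable[AmpliconDigest], path: str | Path, tol: int = 5
) -> None:
    """Tab-delimited per-template summary mirroring the assay's band table."""
    with open(path, "w") as fh:
        fh.write("template_id\tamplicon_bp\tBstEII\tMstI\tcall\n")
        for d in digests:
            call, _ = classify_banding(
                d.fragments["BstEII"], d.fragments["MstI"], tol=tol
            )
            fh.write(
                f"{d.template_id}\t{d.amplicon_length}\t"
                f"{_format_fragments(d.fragments['BstEII'])}\t"
                f"{_format_fragments(d.fragments['MstI'])}\t{call}\n"
            )
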