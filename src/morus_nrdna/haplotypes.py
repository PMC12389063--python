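"""IUPAC-coded SNP haplotypes and exact-match collapsing.

Each accession's SNP genotypes over a shared locus panel are written as one
string: reference base where no variant was called, alternative base for a
homogeneous call, and the two-base IUPAC ambiguity code (R=A/G, Y=C/T,
K=G/T, M=A/C, S=G/C, W=A/T) for a heterogeneous call.  Identical strings
are collapsed into haplotype groups ordered by decreasing size.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .variants import AccessionProfile, classify_zygosity

IUPAC_PAIRS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}
HAPLOTYPE_ALPHABET = frozenset("ACGTRYKMSW")


class PanelError(ValueError):
    """A profile SNP is missing from the locus panel."""


def iupac_code(bases: Iterable[str]) -> str:
    """Single-letter code for a set of one or two nucleotides."""
    base_set = frozenset(b.upper() for b in bases)
    if not base_set <= set("ACGT"):
        raise ValueError(f"not nucleotides: {sorted(base_set)}")
    if len(base_set) == 1:
        return next(iter(base_set))
    if len(base_set) == 2:
        return IUPAC_PAIRS[base_set]
    raise ValueError(
        f"only biallelic ambiguity codes are supported, got {sorted(base_set)}"
    )


@dataclass(frozen=True)
class SnpLocusPanel:
    """Ordered panel of biallelic SNP loci: (1-based position, ref base)."""

    loci: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.loci]
        if positions != sorted(set(positions)):
            raise ValueError("panel positions must be strictly increasing")
        for pos, ref in self.loci:
            if len(ref) != 1 or ref.upper() not in "ACGT":
                raise ValueError(f"panel ref at {pos} must be one nucleotide")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def index_of(self) -> dict[int, int]:
        return {pos: i for i, (pos, _) in enumerate(self.loci)}

    @property
    def reference_string(self) -> str:
        return "".join(ref for _, ref in self.loci)


def panel_from_profiles(profiles: Iterable[AccessionProfile]) -> SnpLocusPanel:
    """Union of SNP loci observed across a cohort, sorted by position."""
    loci: dict[int, str] = {}
    for profile in profiles:
        for rec in profile.variants:
            if not rec.is_snp:
                continue
            if classify_zygosity(rec) == "absent":
                continue
            prev = loci.setdefault(rec.pos, rec.ref_allele)
            if prev != rec.ref_allele:
                raise ValueError(
                    f"conflicting reference bases at position {rec.pos}"
                )
    return SnpLocusPanel(tuple(sorted(loci.items())))


def profile_to_snp_sequence(
    profile: AccessionProfile, panel: SnpLocusPanel
) -> str:
    """IUPAC haplotype string of one accession over the panel loci.

    InDel records are ignored (the panel is SNP-only); a SNP at a position
    absent from the panel raises :class:`PanelError`.
    """
    index_of = panel.index_of
    chars = list(panel.reference_string)
    for rec in profile.variants:
        if not rec.is_snp:
            continue
        zyg = classify_zygosity(rec)
        if zyg == "absent":
            continue
        if rec.pos not in index_of:
            raise PanelError(
                f"{profile.accession_id}: SNP at {rec.pos} not in panel"
            )
        i = index_of[rec.pos]
        if zyg == "homogeneous":
            chars[i] = rec.alt_allele.upper()
        else:
            chars[i] = iupac_code({rec.ref_allele, rec.alt_allele})
    return "".join(chars)


@dataclass(frozen=True)
class HaplotypeGroup:
    """A unique haplotype string and the accessions carrying it."""

    sequence: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a haplotype group needs at least one member")
        if not set(self.sequence) <= HAPLOTYPE_ALPHABET:
            raise ValueError("haplotype contains non-IUPAC characters")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> str:
        return self.members[0]


def collapse(
    seqs: Sequence[tuple[str, str]]
) -> list[HaplotypeGroup]:
    """Collapse (accession_id, haplotype) pairs into unique groups.

    Groups partition the input by exact string equality and are ordered by
    size descending, ties broken by first occurrence in the input.
    """
    lengths = {len(s) for _, s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"haplotype strings differ in length: {sorted(lengths)}")
    groups: "OrderedDict[str, list[str]]" = OrderedDict()
    for accession_id, seq in seqs:
        groups.setdefault(seq, []).append(accession_id)
    # insertion order of an OrderedDict is first-occurrence order
    ordered = sorted(
        enumerate(groups.items()), key=lambda t: (-len(t[1][1]), t[0])
    )
    return [HaplotypeGroup(seq, tuple(members)) for _, (seq, members) in ordered]


def cohort_haplotypes(
    profiles: Sequence[AccessionProfile], panel: SnpLocusPanel | None = None
) -> tuple[SnpLocusPanel, list[tuple[str, str]]]:
    """Panel plus (accession_id, haplotype) pairs for a whole cohort."""
    if panel is None:
        panel = panel_from_profiles(profiles)
    pairs = [
        (p.accession_id, profile_to_snp_sequence(p, panel)) for p in profiles
    ]
    return panel, pairs


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n{seq}\n")


def write_group_fasta(groups: Iterable[HaplotypeGroup], path: str | Path) -> None:
    """FASTA of group representatives, headers ``<representative>|size=N``."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f">{g.representative}|size={g.size}\n{g.sequence}\n")


def write_phylip(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Relaxed-PHYLIP alignment writer for tree-software interchange."""
    if not pairs:
        raise ValueError("nothing to write")
    length = len(pairs[0][1])
    with open(path, "w") as fh:
        fh.write(f" {len(pairs)} {length}\n")
        for name, seq in pairs:
            fh.write(f"{name}  {seq}\n")
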