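"""Synthetic Morus nrDNA study generator.

Builds, from a seed, a complete desk-scale analogue of the 542-accession
study: a 5814 bp reference whose ITS carries the CAPS assay geometry
(primer sites flanked by 41 bp of 18S and 37 bp of 26S, BstEII sites at
amplicon positions 91 and 540, no MstI site, and the read-counting flank
context around the position-1862 insertion locus), six species variant
profiles whose per-region and per-zygosity locus counts reproduce the
packaged target tallies, a cohort realising the nine repeated haplotype groups
(457, 21, 13, 13, 6, 4, 2, 2, 2) plus 22 singletons, insertion-locus reads
with a chosen allele status per accession, and per-species ITS templates
whose in-silico digestion reproduces the packaged assay fragment table.

Everything outside the constrained loci is uniform-random background,
resampled until no unintended primer, enzyme or read-flank motif occurs
anywhere (including under any single planned allele substitution).
Identical seeds give identical sequences and cohorts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .caps import (
    BSTEII,
    FORWARD_PRIMER,
    MSTI,
    REVERSE_PRIMER,
    digest,
    insilico_pcr,
    reverse_complement,
)
from .regions import RegionMap, default_region_map
from .variants import (
    AccessionProfile,
    FilterAnnotations,
    SpeciesRegionTable,
    VariantRecord,
    tally_profiles,
)

# ---------------------------------------------------------------------------
# fixed geometry (1-based nrDNA coordinates; amplicon position = nrDNA - 1767)

AMP_OFFSET = 1767          # amplicon position 1 == nrDNA 1768
INS13 = "CGTGCGCAATGCG"
INS16 = "CGACGTACACAATGCG"
INSERTION_POS = 1862       # insertion anchored after this base (ITS1)

_RC_REV = reverse_complement(REVERSE_PRIMER)

# (literal, 1-based start) segments stamped into the reference
_FIXED_SEGMENTS = (
    (FORWARD_PRIMER, 1768),       # 41 bp of 18S precede the ITS in the amplicon
    ("TCGAAACC", 1847),           # upstream flank of the read-count patterns
    ("GGTAA", 1858),              # 5' part of the first BstEII site
    ("CCCCAACCCC", 1863),         # downstream flank; completes GGTAACC
    ("GGTCACC", 2307),            # second BstEII site (ITS2)
    (_RC_REV, 2439),              # reverse-primer binding site (26S)
)

# motifs that may occur nowhere except at whitelisted spans
_FORBIDDEN = (
    "GGTAACC", "GGTCACC", "GGTGACC", "GGTTACC",   # BstEII (GGTNACC)
    "TGCGCA",                                     # MstI
    "TCGAAACC", "CCCCAACCCC",                     # forward-orientation flanks
    "GGTTTCGA", "GGGGTTGGGG",                     # reverse-orientation flanks
    FORWARD_PRIMER, _RC_REV,
)

_WHITELIST = frozenset(
    {
        (FORWARD_PRIMER, 1768),
        ("TCGAAACC", 1847),
        ("GGTAACC", 1858),
        ("CCCCAACCCC", 1863),
        ("GGTCACC", 2307),
        (_RC_REV, 2439),
    }
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

ALBA = "M. alba"
NIGRA = "M. nigra"
SERRATA = "M. serrata"
RUBRA = "M. rubra"
CELTIDIFOLIA = "M. celtidifolia"
NOTABILIS = "M. notabilis"
SIX_SPECIES = (NIGRA, SERRATA, RUBRA, CELTIDIFOLIA, NOTABILIS, ALBA)


class GenerationError(RuntimeError):
    """Constraint satisfaction failed after bounded retries."""


# ---------------------------------------------------------------------------
# SNP locus pools: 20 in 18S + 66 in ITS + 72 in 26S = 158 distinct loci

def _its_slot_positions() -> list[int]:
    """66 ITS SNP slots (nrDNA), spaced >= 7 bp from every variable or
    reserved position so no enzyme/flank-length window spans two edits."""
    amp = [42, 57, 64, 71, 78, 106]
    amp += [189 + 7 * k for k in range(49)]      # 189..525
    amp += [544]                                  # inside GGTCACC; notabilis-only
    amp += [583 + 7 * k for k in range(10)]       # 583..646
    return [AMP_OFFSET + a for a in amp]


SNP_POOL = {
    "18S": [100 + 80 * k for k in range(20)],
    "ITS": _its_slot_positions(),
    "26S": [2470 + 45 * k for k in range(72)],
}
KILLER_ITS_INDEX = 55  # pool index of nrDNA 2311, disables the ITS2 BstEII site


def _snp_id(region: str, index: int) -> str:
    return f"S{region}_{index:02d}"


def _ids(region: str, indices: Iterable[int]) -> list[str]:
    return [_snp_id(region, i) for i in indices]


# per-species SNP locus subsets of the shared pools (target per-region counts)
SPECIES_SNPS: dict[str, list[str]] = {
    ALBA: _ids("18S", range(6))
    + _ids("ITS", [0, 1, 20, 52, 53, 56, 57])
    + _ids("26S", range(60, 70)),
    NIGRA: _ids("18S", range(7, 13))
    + _ids("ITS", range(33, 50))
    + _ids("26S", [*range(55, 72), 0, 1, 2]),
    SERRATA: _ids("18S", range(11, 19))
    + _ids("ITS", range(33, 52))
    + _ids("26S", range(10, 27)),
    RUBRA: _ids("18S", [19, *range(0, 7)])
    + _ids("ITS", range(6, 22))
    + _ids("26S", range(32, 55)),
    CELTIDIFOLIA: _ids("18S", range(13, 19))
    + _ids("ITS", [*range(0, 6), 52, 53, 54, *range(56, 66)])
    + _ids("26S", range(30, 47)),
    NOTABILIS: _ids("18S", range(11))
    + _ids("ITS", [*range(0, 33), KILLER_ITS_INDEX])
    + _ids("26S", range(32)),
}

# loci heterogeneous in >= 1 accession of the species (target zygosity splits);
# for M. alba every locus is heterogeneous somewhere in the clade.
SPECIES_HET_SNPS: dict[str, list[str]] = {
    ALBA: list(SPECIES_SNPS[ALBA]),
    NIGRA: _ids("ITS", range(33, 39)),
    SERRATA: _ids("ITS", range(33, 36)),
    RUBRA: _ids("ITS", range(6, 22)) + _ids("18S", [19]),
    CELTIDIFOLIA: _ids("ITS", [52, 53, 54, 56, 57, 58]),
    NOTABILIS: _ids("ITS", [2]) + _ids("18S", [9, 10]) + _ids("26S", [30, 31]),
}

# ---------------------------------------------------------------------------
# InDel loci: 15 distinct positions; the position-1862 locus has two alleles

# key -> (op, nrDNA position, payload)
#   op "ins": insert payload after position; op "del": delete payload bases
#   starting at position (VCF anchor = position - 1)
INDEL_OPS: dict[str, tuple[str, int, object]] = {
    "I0:13": ("ins", INSERTION_POS, INS13),
    "I0:16": ("ins", INSERTION_POS, INS16),
    "I1": ("del", 1817, 1),
    "I2": ("ins", 1885, 1),
    "I3": ("ins", 1893, 1),
    "I5": ("ins", 1901, 1),
    "I6": ("del", 1909, 1),
    "I7": ("ins", 1917, 1),
    "I8": ("ins", 1925, 1),
    "I9": ("del", 1933, 2),
    "I12": ("ins", 1941, 1),
    "I13": ("del", 1949, 1),
    "I4": ("del", 2327, 1),
    "I10": ("ins", 2335, 1),
    "I11": ("ins", 2343, 1),
    "I14": ("ins", 3000, 1),
}

# per-species InDel zygosity (target region counts and zygosity splits)
SPECIES_INDELS: dict[str, dict[str, str]] = {
    ALBA: {"I0:13": "het", "I2": "het", "I4": "het"},
    NIGRA: {
        "I0:13": "hom", "I1": "hom", "I2": "hom", "I3": "hom", "I4": "hom",
        "I14": "hom", "I5": "het", "I6": "het",
    },
    SERRATA: {
        "I0:13": "hom", "I2": "hom", "I3": "hom", "I4": "hom",
        "I5": "hom", "I6": "hom",
    },
    RUBRA: {
        "I0:13": "hom", "I2": "hom", "I3": "hom", "I4": "hom",
        "I5": "hom", "I6": "hom",
    },
    CELTIDIFOLIA: {
        "I0:13": "hom", "I2": "hom", "I3": "hom",
        "I7": "hom", "I8": "hom", "I9": "hom",
    },
    NOTABILIS: {
        "I0:16": "hom", "I2": "hom", "I3": "hom", "I10": "hom",
        "I11": "hom", "I12": "hom", "I13": "hom", "I14": "het",
    },
}

# expected assay outcome per template: (amplicon bp, BstEII, MstI multisets)
ASSAY_EXPECTED: dict[str, tuple[int, Counter, Counter]] = {
    ALBA: (689, Counter({91: 1, 149: 1, 449: 1}), Counter({689: 1})),
    ALBA + "+13bp": (702, Counter({149: 1, 553: 1}), Counter({100: 1, 602: 1})),
    CELTIDIFOLIA: (704, Counter({149: 1, 555: 1}), Counter({100: 1, 604: 1})),
    RUBRA: (703, Counter({148: 1, 555: 1}), Counter({100: 1, 603: 1})),
    NOTABILIS: (709, Counter({709: 1}), Counter({709: 1})),
    SERRATA: (703, Counter({148: 1, 555: 1}), Counter({100: 1, 603: 1})),
    NIGRA: (702, Counter({148: 1, 554: 1}), Counter({99: 1, 603: 1})),
}

NOTABILIS_ITS_SPAN = 631


# ---------------------------------------------------------------------------
# cohort composition

@dataclass(frozen=True)
class HaplotypeDef:
    """One distinct cohort haplotype: zygosity per carried locus."""

    hap_id: str
    size: int
    snps: tuple[tuple[str, str], ...]      # (snp_id, 'hom'|'het')
    indels: tuple[tuple[str, str], ...]    # (indel key, 'hom'|'het')
    members: tuple[tuple[str, str, int], ...]  # (fine species, taxon, count)


def _hd(hap_id, size, snps, indels, members) -> HaplotypeDef:
    total = sum(n for _, _, n in members)
    if total != size:
        raise ValueError(f"{hap_id}: members sum to {total}, not {size}")
    return HaplotypeDef(
        hap_id, size, tuple(snps.items()), tuple(indels.items()),
        tuple((fine, taxon, n) for fine, taxon, n in members),
    )


def _alba_alias(i: int) -> str:
    """a1..a23 -> pooled locus ids for the M. alba clade panel."""
    order = (
        _ids("18S", range(6))
        + _ids("ITS", [0, 1, 20, 52, 53, 56, 57])
        + _ids("26S", range(60, 70))
    )
    return order[i - 1]


def default_composition() -> list[HaplotypeDef]:
    """The packaged 542-accession composition: nine repeated haplotype
    groups (457, 21, 13, 13, 6, 4, 2, 2, 2) plus 22 singletons, 31 distinct
    haplotypes over six species clades."""
    a = _alba_alias
    notab_backbone = {
        s: "hom"
        for s in SPECIES_SNPS[NOTABILIS]
        if s not in SPECIES_HET_SNPS[NOTABILIS]
    }
    notab_indels = {
        k: "hom" for k, z in SPECIES_INDELS[NOTABILIS].items() if z == "hom"
    }
    celt_het = SPECIES_HET_SNPS[CELTIDIFOLIA]
    celt_hom = [s for s in SPECIES_SNPS[CELTIDIFOLIA] if s not in celt_het]
    nigra_het = SPECIES_HET_SNPS[NIGRA]
    nigra_hom = [s for s in SPECIES_SNPS[NIGRA] if s not in nigra_het]
    rubra_het = SPECIES_HET_SNPS[RUBRA]
    rubra_hom = [s for s in SPECIES_SNPS[RUBRA] if s not in rubra_het]
    serr_het = SPECIES_HET_SNPS[SERRATA]
    serr_hom = [s for s in SPECIES_SNPS[SERRATA] if s not in serr_het]

    defs = [
        # --- M. alba clade: seven repeated groups + 9 singletons (514 acc.)
        _hd("g_ref", 457, {}, {}, [
            ("M. alba", ALBA, 448), ("M. bombycis", ALBA, 4),
            ("M. mizuho", ALBA, 2), ("M. rotundiloba", ALBA, 1),
            ("M. rubra", RUBRA, 1), ("M. serrata", SERRATA, 1),
        ]),
        _hd("g21", 21, {a(7): "het"}, {"I2": "het"}, [
            ("M. alba", ALBA, 13), ("M. bombycis", ALBA, 4),
            ("M. latifolia", ALBA, 3), ("M. australis", ALBA, 1),
        ]),
        _hd("g13a", 13,
            {a(1): "hom", a(2): "hom", a(8): "hom", a(14): "hom"}, {}, [
                ("M. alba", ALBA, 7), ("M. cathayana", ALBA, 3),
                ("M. macroura", ALBA, 2), ("M. liboensis", ALBA, 1),
            ]),
        _hd("g6", 6,
            {a(1): "het", a(2): "het", a(8): "het", a(14): "het"},
            {"I4": "het"}, [
                ("M. alba", ALBA, 2), ("M. cathayana", ALBA, 2),
                ("M. macroura", ALBA, 1), ("M. wittiorum", ALBA, 1),
            ]),
        _hd("g4", 4,
            {a(i): "het" for i in (3, 4, 5, 9, 10, 11, 15, 16, 17, 18, 19, 20)},
            {"I0:13": "het"}, [
                ("M. australis", ALBA, 3), ("M. alba", ALBA, 1),
            ]),
        _hd("g2w", 2,
            {a(i): "het" for i in (3, 4, 9, 10, 15, 16, 17, 18, 19, 20, 21, 22)},
            {}, [("M. wittiorum", ALBA, 2)]),
        _hd("g2m", 2,
            {a(6): "het", a(21): "het", a(22): "het", a(23): "het"},
            {}, [("M. mongolica", ALBA, 2)]),
        _hd("s_a1", 1, {a(12): "het"}, {}, [("M. mongolica", ALBA, 1)]),
        _hd("s_a2", 1, {a(13): "het"}, {}, [("M. mongolica", ALBA, 1)]),
        _hd("s_a3", 1, {a(12): "het", a(13): "het"}, {},
            [("M. australis", ALBA, 1)]),
        _hd("s_a4", 1, {a(7): "het", a(12): "het"}, {}, [("M. alba", ALBA, 1)]),
        _hd("s_a5", 1, {a(7): "het", a(13): "het"}, {}, [("M. alba", ALBA, 1)]),
        _hd("s_a6", 1, {a(1): "het"}, {}, [("M. alba", ALBA, 1)]),
        _hd("s_a7", 1, {a(2): "het"}, {}, [("M. alba", ALBA, 1)]),
        _hd("s_a8", 1, {a(14): "het"}, {}, [("M. alba", ALBA, 1)]),
        # the Yunsang-6 analogue: SNP profile like M. alba, 13 bp insertion fixed
        _hd("s_a9", 1, {a(10): "het"}, {"I0:13": "hom"},
            [("M. macroura", ALBA, 1)]),
        # --- M. notabilis clade (16 accessions, 3 haplotypes)
        _hd("g13n", 13,
            {**notab_backbone, _snp_id("ITS", 2): "het"}, notab_indels,
            [("M. notabilis", NOTABILIS, 13)]),
        _hd("s_n14", 1, dict(notab_backbone), notab_indels,
            [("M. notabilis", NOTABILIS, 1)]),
        _hd("g2y", 2,
            {**notab_backbone,
             **{s: "het" for s in
                _ids("18S", [9, 10]) + _ids("26S", [30, 31])}},
            {**notab_indels, "I14": "het"},
            [("M. notabilis", NOTABILIS, 2)]),
    ]
    # --- wild singletons: zygosity-pattern variants of one species profile
    for i in range(5):
        snps = {s: "hom" for s in celt_hom}
        snps.update(
            {s: ("het" if j < 6 - i else "hom") for j, s in enumerate(celt_het)}
        )
        defs.append(
            _hd(f"s_c{i + 1}", 1, snps, dict(SPECIES_INDELS[CELTIDIFOLIA]),
                [("M. celtidifolia", CELTIDIFOLIA, 1)])
        )
    for i in range(3):
        snps = {s: "hom" for s in nigra_hom}
        snps.update(
            {s: ("het" if j < 6 - i else "hom") for j, s in enumerate(nigra_het)}
        )
        defs.append(
            _hd(f"s_g{i + 1}", 1, snps, dict(SPECIES_INDELS[NIGRA]),
                [("M. nigra", NIGRA, 1)])
        )
    for i in range(3):
        snps = {s: "hom" for s in rubra_hom}
        snps.update(
            {s: ("het" if j < 17 - i else "hom") for j, s in enumerate(rubra_het)}
        )
        defs.append(
            _hd(f"s_r{i + 1}", 1, snps, dict(SPECIES_INDELS[RUBRA]),
                [("M. rubra", RUBRA, 1)])
        )
    snps = {s: "hom" for s in serr_hom}
    snps.update({s: "het" for s in serr_het})
    defs.append(
        _hd("s_s1", 1, snps, dict(SPECIES_INDELS[SERRATA]),
            [("M. serrata", SERRATA, 1)])
    )
    assert sum(d.size for d in defs) == 542
    assert len(defs) == 31
    return defs


# ---------------------------------------------------------------------------
# reference construction

@dataclass(frozen=True)
class RealizedVariant:
    """A planned allele realized against the reference: VCF-style triple."""

    locus_id: str
    pos: int          # 1-based anchor
    ref: str
    alt: str


@dataclass
class ReferenceBuild:
    """Seeded reference sequence plus every realized variant allele."""

    seed: int
    sequence: str
    region_map: RegionMap
    snps: dict[str, RealizedVariant]
    indels: dict[str, RealizedVariant]

    def variant(self, key: str) -> RealizedVariant:
        return self.snps[key] if key in self.snps else self.indels[key]


def _scan_hits(seq: str, literals=_FORBIDDEN) -> list[tuple[str, int]]:
    """(literal, 1-based start) occurrences of every forbidden literal."""
    hits = []
    for lit in literals:
        start = seq.find(lit)
        while start != -1:
            hits.append((lit, start + 1))
            start = seq.find(lit, start + 1)
    return hits


def motif_audit(seq: str, allowed=_WHITELIST) -> list[tuple[str, int]]:
    """Forbidden-motif occurrences outside the allowed (literal, start) set."""
    return [hit for hit in _scan_hits(seq) if hit not in allowed]


def _edit_ok(seq: str, pos: int, ref: str, alt: str) -> bool:
    """True when substituting ref->alt at 1-based pos creates no forbidden
    motif.  Hits downstream of the edit are compared against the whitelist
    after undoing the length shift; the position-1862 insertions additionally
    allow their internal MstI site and the shifted downstream flank."""
    margin = max(len(lit) for lit in _FORBIDDEN) + 1
    start = max(0, pos - 1 - margin)
    end = min(len(seq), pos - 1 + len(ref) + margin)
    segment = seq[start : pos - 1] + alt + seq[pos - 1 + len(ref) : end]
    delta = len(alt) - len(ref)
    dynamic = set()
    if pos == INSERTION_POS and len(alt) > len(ref):
        ins = alt[len(ref):]
        if ins == INS13:
            dynamic.add(("TGCGCA", INSERTION_POS + 3))  # inside the insertion
        dynamic.add(("CCCCAACCCC", 1863 + delta))
    for lit, seg_start in _scan_hits(segment):
        abs_start = start + seg_start
        if abs_start < pos:
            if (lit, abs_start) in _WHITELIST:
                continue
        else:
            if (lit, abs_start - delta) in _WHITELIST or (lit, abs_start) in dynamic:
                continue
        return False
    return True


def _alt_candidates(ref_base: str) -> list[str]:
    others = [b for b in "ACGT" if b != ref_base]
    return [_TRANSITION[ref_base]] + [
        b for b in others if b != _TRANSITION[ref_base]
    ]


def build_reference(
    seed: int = 1,
    region_map: RegionMap | None = None,
    max_attempts: int = 20,
) -> ReferenceBuild:
    """Generate the constrained reference and realize every planned allele.

    Deterministic for a fixed seed; raises :class:`GenerationError` if the
    constraints cannot be satisfied within ``max_attempts`` background
    resamplings (never observed in practice).
    """
    region_map = region_map or default_region_map()
    n = region_map.total_length
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed) % (2**31), attempt])
        seq = _sample_background(rng, n)
        try:
            build = _realize(seed, seq, region_map, rng)
        except GenerationError:
            continue
        _audit_build(build)
        return build
    raise GenerationError(
        f"could not satisfy reference constraints after {max_attempts} attempts"
    )


def _sample_background(rng, n: int) -> str:
    bases = np.array(list("ACGT"))
    arr = rng.choice(bases, size=n)
    for lit, start in _FIXED_SEGMENTS:
        arr[start - 1 : start - 1 + len(lit)] = list(lit)
    fixed = np.zeros(n, dtype=bool)
    for lit, start in _FIXED_SEGMENTS:
        fixed[start - 1 : start - 1 + len(lit)] = True
    for _ in range(500):
        seq = "".join(arr)
        bad = [h for h in _scan_hits(seq) if h not in _WHITELIST]
        if not bad:
            return seq
        lit, start = bad[0]
        span = [
            i for i in range(start - 1, start - 1 + len(lit)) if not fixed[i]
        ]
        if not span:  # forbidden motif made of fixed bases only: impossible
            raise GenerationError(f"immutable forbidden motif {lit}@{start}")
        i = span[int(rng.integers(len(span)))]
        current = arr[i]
        arr[i] = rng.choice([b for b in "ACGT" if b != current])
    raise GenerationError("background repair did not converge")


def _realize(seed, seq, region_map, rng) -> ReferenceBuild:
    snps: dict[str, RealizedVariant] = {}
    for region, positions in SNP_POOL.items():
        for index, pos in enumerate(positions):
            ref_base = seq[pos - 1]
            for alt in _alt_candidates(ref_base):
                if _edit_ok(seq, pos, ref_base, alt):
                    snps[_snp_id(region, index)] = RealizedVariant(
                        _snp_id(region, index), pos, ref_base, alt
                    )
                    break
            else:
                raise GenerationError(f"no safe alt allele at {pos}")
    killer = snps[_snp_id("ITS", KILLER_ITS_INDEX)]
    # the killer substitution must actually disable GGTNACC (position 2311
    # is the invariant A of the motif, so any substitution does)
    assert killer.pos == 2311 and killer.ref == "A"

    indels: dict[str, RealizedVariant] = {}
    for key, (op, pos, payload) in INDEL_OPS.items():
        if op == "ins":
            ins_seq = payload if isinstance(payload, str) else None
            anchor = pos
            ref = seq[anchor - 1]
            if ins_seq is not None:
                alt = ref + ins_seq
                if not _edit_ok(seq, anchor, ref, alt):
                    raise GenerationError(f"insertion context unsafe at {anchor}")
            else:
                for base in "ACGT":
                    alt = ref + base
                    if _edit_ok(seq, anchor, ref, alt):
                        break
                else:
                    raise GenerationError(f"no safe insertion base at {anchor}")
            indels[key] = RealizedVariant(key, anchor, ref, alt)
        else:  # deletion of `payload` bases starting at pos
            length = int(payload)
            anchor = pos - 1
            ref = seq[anchor - 1 : anchor - 1 + length + 1]
            alt = ref[0]
            if not _edit_ok(seq, anchor, ref, alt):
                raise GenerationError(f"deletion context unsafe at {anchor}")
            indels[key] = RealizedVariant(key, anchor, ref, alt)
    return ReferenceBuild(int(seed), seq, region_map, snps, indels)


# ---------------------------------------------------------------------------
# species profiles and templates

@dataclass(frozen=True)
class SpeciesVariantProfile:
    """A species' variant loci with species-level zygosity labels."""

    species: str
    snp_ids: tuple[str, ...]
    het_snp_ids: frozenset[str]
    indels: tuple[tuple[str, str], ...]  # (indel key, 'hom'|'het')


def default_species_profiles() -> dict[str, SpeciesVariantProfile]:
    """The six packaged species profiles reproducing the packaged target tallies."""
    return {
        sp: SpeciesVariantProfile(
            sp,
            tuple(SPECIES_SNPS[sp]),
            frozenset(SPECIES_HET_SNPS[sp]),
            tuple(SPECIES_INDELS[sp].items()),
        )
        for sp in SIX_SPECIES
    }


def _apply_variants(seq: str, variants: Sequence[RealizedVariant]) -> str:
    """Apply non-overlapping variants (any order) to a sequence."""
    out = seq
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        start = v.pos - 1
        if out[start : start + len(v.ref)] != v.ref:
            raise ValueError(f"reference mismatch applying {v.locus_id}@{v.pos}")
        out = out[:start] + v.alt + out[start + len(v.ref):]
    return out


def shifted_position(pos: int, variants: Sequence[RealizedVariant]) -> int:
    """Position of reference base ``pos`` after applying ``variants``."""
    shift = 0
    for v in variants:
        if v.pos + len(v.ref) - 1 <= pos:
            shift += len(v.alt) - len(v.ref)
    return pos + shift


def _template_variants(
    build: ReferenceBuild, profile: SpeciesVariantProfile
) -> list[RealizedVariant]:
    """Homogeneous ITS-region variants applied to build a species template."""
    its_start, its_end = build.region_map.its_span()
    chosen = []
    for snp_id in profile.snp_ids:
        if snp_id in profile.het_snp_ids:
            continue
        v = build.snps[snp_id]
        if its_start <= v.pos <= its_end:
            chosen.append(v)
    for key, zyg in profile.indels:
        if zyg != "hom":
            continue
        v = build.indels[key]
        if its_start <= v.pos <= its_end:
            chosen.append(v)
    return chosen


def build_its_templates(
    build: ReferenceBuild,
    profiles: Mapping[str, SpeciesVariantProfile] | None = None,
) -> dict[str, str]:
    """Per-species full-length templates for the CAPS assay, audited
    against the expected amplicon/fragment table.

    Includes the reference-allele M. alba template and the 13 bp-insertion
    allele ("M. alba+13bp") carried by part of the clade.
    """
    profiles = profiles or default_species_profiles()
    templates: dict[str, str] = {}
    for sp, profile in profiles.items():
        templates[sp] = _apply_variants(
            build.sequence, _template_variants(build, profile)
        )
    templates[ALBA + "+13bp"] = _apply_variants(
        build.sequence, [build.indels["I0:13"]]
    )
    _audit_templates(templates)
    return templates


def measure_its_span(
    build: ReferenceBuild, profile: SpeciesVariantProfile
) -> int:
    """ITS length (18S/26S boundary to boundary) of the species template."""
    variants = _template_variants(build, profile)
    its_start, its_end = build.region_map.its_span()
    return shifted_position(its_end, variants) - shifted_position(
        its_start - 1, variants
    )


def _audit_templates(templates: Mapping[str, str]) -> None:
    for name, (amp_len, bste2, mst1) in ASSAY_EXPECTED.items():
        amplicon = insilico_pcr(templates[name])
        if len(amplicon) != amp_len:
            raise GenerationError(
                f"{name}: amplicon {len(amplicon)} != expected {amp_len}"
            )
        got_b, got_m = digest(amplicon, BSTEII), digest(amplicon, MSTI)
        if got_b != bste2 or got_m != mst1:
            raise GenerationError(
                f"{name}: digestion {dict(got_b)}/{dict(got_m)} != expected"
            )


def _audit_build(build: ReferenceBuild) -> None:
    if len(build.sequence) != build.region_map.total_length:
        raise GenerationError("reference length mismatch")
    bad = motif_audit(build.sequence)
    if bad:
        raise GenerationError(f"forbidden motifs remain: {bad[:3]}")
    templates = build_its_templates(build)
    profiles = default_species_profiles()
    span = measure_its_span(build, profiles[NOTABILIS])
    if span != NOTABILIS_ITS_SPAN:
        raise GenerationError(f"M. notabilis ITS span {span} != 631")
    del templates


# ---------------------------------------------------------------------------
# cohort simulation

_PASSING = FilterAnnotations(
    QD=25.0, MQ=60.0, FS=2.0, SOR=1.0, QUAL=900.0,
    MQRankSum=0.0, ReadPosRankSum=0.0,
)


@dataclass
class CohortSim:
    """A simulated cohort: accession profiles plus ground truth."""

    build: ReferenceBuild
    profiles: list[AccessionProfile]
    metadata: "object"  # pandas DataFrame: accession_id, species, taxon, hap
    haplotype_defs: list[HaplotypeDef]
    insertion_status: dict[str, str]

    def tally(self) -> SpeciesRegionTable:
        return tally_profiles(self.profiles, self.build.region_map)


def simulate_cohort(
    build: ReferenceBuild,
    composition: Sequence[HaplotypeDef] | None = None,
) -> CohortSim:
    """Realize the composition into per-accession variant profiles.

    Accessions are numbered deterministically in composition order.  The
    default insertion-read status is 'mixed' for every accession except
    the three M. nigra accessions, which are pure-insertion.
    """
    import pandas as pd

    composition = list(composition or default_composition())
    profiles: list[AccessionProfile] = []
    meta_rows = []
    counter = 0
    for hap in composition:
        records = []
        for snp_id, zyg in hap.snps:
            v = build.snps[snp_id]
            observed = (
                (v.alt, v.alt) if zyg == "hom" else (v.ref, v.alt)
            )
            records.append(
                VariantRecord(v.pos, v.ref, v.alt, observed, _PASSING)
            )
        for key, zyg in hap.indels:
            v = build.indels[key]
            observed = (
                (v.alt, v.alt) if zyg == "hom" else (v.ref, v.alt)
            )
            records.append(
                VariantRecord(v.pos, v.ref, v.alt, observed, _PASSING)
            )
        for fine_species, taxon, count in hap.members:
            for _ in range(count):
                counter += 1
                acc = f"ACC{counter:04d}"
                profiles.append(AccessionProfile(acc, taxon, list(records)))
                meta_rows.append(
                    {
                        "accession_id": acc,
                        "species": fine_species,
                        "taxon": taxon,
                        "haplotype_id": hap.hap_id,
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    status = {
        row["accession_id"]: (
            "ins_only" if row["taxon"] == NIGRA and row["haplotype_id"] != "g_ref"
            else "mixed"
        )
        for row in meta_rows
    }
    return CohortSim(build, profiles, metadata, composition, status)


# ---------------------------------------------------------------------------
# insertion-locus reads

def simulate_insertion_reads(
    build: ReferenceBuild,
    status: Literal["ins_only", "ref_only", "mixed"],
    depth: int = 60,
    read_length: int = 150,
    seed: int = 0,
    insertion: str = INS13,
) -> list[str]:
    """Reads from the position-1862 locus realizing the requested status.

    Reads are windows of the reference (or insertion-bearing) allele
    template covering the diagnostic flanks, half of them reverse
    complemented; the pattern-based tally recovers ``status`` exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if status == "mixed" and depth < 2:
        raise ValueError("mixed status needs depth >= 2")
    span = 26 + len(insertion)  # TCGAAACC start .. shifted flank end
    if read_length < span:
        raise ValueError(
            f"read length {read_length} cannot contain the {span} bp "
            "diagnostic span"
        )
    rng = np.random.default_rng([int(seed) % (2**31), 17])
    local_start = 1600  # nrDNA coordinate of local template base 1
    local = build.sequence[local_start - 1 : 2150]
    cut = INSERTION_POS - local_start + 1
    ins_local = local[:cut] + insertion + local[cut:]
    flank_lo = 1847 - local_start  # 0-based local index of pattern start

    if status == "ins_only":
        n_ins, n_ref = depth, 0
    elif status == "ref_only":
        n_ins, n_ref = 0, depth
    else:
        n_ins = depth // 2
        n_ref = depth - n_ins
    reads = []
    for template, count, ins_len in (
        (ins_local, n_ins, len(insertion)),
        (local, n_ref, 0),
    ):
        if not count:
            continue
        cover_end = flank_lo + 26 + ins_len  # one past the diagnostic span
        low = max(0, cover_end - read_length)
        high = min(flank_lo, len(template) - read_length)
        starts = rng.integers(low, high + 1, size=count)
        flips = rng.random(count) < 0.5
        for start, flip in zip(starts, flips):
            read = template[start : start + read_length]
            reads.append(reverse_complement(read) if flip else read)
    return reads


def simulate_cohort_reads(
    cohort: CohortSim,
    depth: int = 60,
    read_length: int = 150,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Per-accession insertion-locus reads for the whole cohort.

    M. notabilis accessions carry the 16 bp insertion allele; all others
    the 13 bp allele.  Per-accession seeds derive deterministically from
    ``seed``.
    """
    taxon_of = dict(
        zip(cohort.metadata["accession_id"], cohort.metadata["taxon"])
    )
    reads = {}
    for i, (acc, status) in enumerate(sorted(cohort.insertion_status.items())):
        ins = INS16 if taxon_of[acc] == NOTABILIS else INS13
        reads[acc] = simulate_insertion_reads(
            cohort.build, status, depth=depth, read_length=read_length,
            seed=(int(seed) * 100003 + i) % (2**31), insertion=ins,
        )
    return reads


# ---------------------------------------------------------------------------
# writers

def write_reference_fasta(build: ReferenceBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(">nrDNA synthetic Morus nrDNA reference\n")
        seq = build.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_metadata(cohort: CohortSim, path: str | Path) -> None:
    cohort.metadata.to_csv(path, sep="\t", index=False)


def write_cohort_vcf(cohort: CohortSim, path: str | Path) -> None:
    """Multi-sample VCF 4.2 of the cohort (plain text, biallelic rows
    merged per position into multi-allelic records where needed)."""
    samples = [p.accession_id for p in cohort.profiles]
    # (pos, ref) -> {alt: {accession: zygosity}}
    sites: dict[tuple[int, str], dict[str, dict[str, str]]] = {}
    for p in cohort.profiles:
        for rec in p.variants:
            alts = sites.setdefault((rec.pos, rec.ref_allele), {})
            carriers = alts.setdefault(rec.alt_allele, {})
            seen = set(rec.observed_alleles)
            carriers[p.accession_id] = (
                "hom" if seen == {rec.alt_allele} else "het"
            )
    ann = _PASSING
    info = (
        f"QD={ann.QD};MQ={ann.MQ};FS={ann.FS};SOR={ann.SOR};"
        f"MQRankSum={ann.MQRankSum};ReadPosRankSum={ann.ReadPosRankSum}"
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID=nrDNA,length={cohort.build.region_map.total_length}>\n"
        )
        for key in ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum"):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (pos, ref), alts in sorted(sites.items()):
            alt_list = sorted(alts)
            gts = []
            for acc in samples:
                code = "0/0"
                for k, alt in enumerate(alt_list, start=1):
                    zyg = alts[alt].get(acc)
                    if zyg == "hom":
                        code = f"{k}/{k}"
                    elif zyg == "het":
                        code = f"0/{k}"
                gts.append(code)
            fh.write(
                f"nrDNA\t{pos}\t.\t{ref}\t{','.join(alt_list)}\t"
                f"{ann.QUAL:.1f}\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_templates_fasta(templates: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in templates.items():
            fh.write(f">{name.replace(' ', '_')}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_reads_fastq(
    reads: Mapping[str, list[str]], directory: str | Path, gzip_out: bool = True
) -> list[Path]:
    """One FASTQ (optionally gzipped) per accession under ``directory``."""
    import gzip as _gzip

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for acc, seqs in reads.items():
        path = directory / (f"{acc}.fastq.gz" if gzip_out else f"{acc}.fastq")
        opener = _gzip.open if gzip_out else open
        with opener(path, "wt") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f"@{acc}.{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths.append(path)
    return paths
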