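"""Variant records, hard filtering, zygosity and per-species region tallies.

A variant call against the nrDNA reference is kept only if it survives the
GATK-style hard filters (SNPs: QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
QUAL < 30.0, MQRankSum < -12.5, ReadPosRankSum < -8.0; InDels relax the
strand-bias bounds to FS > 200.0 and SOR > 10.0).  Each surviving call is
classified from its genotype observation:

* homogeneous  — only the alternative allele is seen in the accession's
  rDNA copies (a 1/1-like call);
* heterogeneous — reference and alternative alleles co-occur (0/1-like),
  the signature of incomplete concerted evolution;
* absent       — only the reference allele (0/0), i.e. not a variant of
  this accession.

Tallies aggregate accessions into species counts of distinct variant loci
per subregion (18S / pooled ITS / 26S) and per zygosity class.  At species
level a locus is heterogeneous if heterogeneous in at least one member
accession, otherwise homogeneous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .regions import RegionMap

Zygosity = Literal["homogeneous", "heterogeneous", "absent"]

# (attribute, comparator, threshold) per variant class; a record fails when
# the inequality holds.  Missing annotations never trigger their criterion.
_SNP_CRITERIA = (
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("SOR", ">", 3.0),
    ("QUAL", "<", 30.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)
_INDEL_CRITERIA = (
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 200.0),
    ("SOR", ">", 10.0),
    ("QUAL", "<", 30.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclass(frozen=True)
class FilterAnnotations:
    """Site annotations evaluated by the hard filters; any may be absent."""

    QD: float | None = None
    MQ: float | None = None
    FS: float | None = None
    SOR: float | None = None
    QUAL: float | None = None
    MQRankSum: float | None = None
    ReadPosRankSum: float | None = None

    def __post_init__(self) -> None:
        if self.FS is not None and self.FS < 0:
            raise ValueError("FS is a phred-scaled probability, must be >= 0")
        if self.QUAL is not None and self.QUAL < 0:
            raise ValueError("QUAL must be >= 0")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP or InDel call with its genotype observation.

    ``observed_alleles`` is the multiset of alleles seen in the accession,
    each element either the ref or the alt string.
    """

    pos: int
    ref_allele: str
    alt_allele: str
    observed_alleles: tuple[str, ...]
    annotations: FilterAnnotations = field(default_factory=FilterAnnotations)
    allele_depths: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.observed_alleles:
            raise ValueError("observed_alleles must be non-empty")
        bad = set(self.observed_alleles) - {self.ref_allele, self.alt_allele}
        if bad:
            raise ValueError(f"observed alleles {bad} are neither ref nor alt")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def kind(self) -> str:
        return "SNP" if self.is_snp else "InDel"

    @property
    def locus(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class AccessionProfile:
    """An accession's species label and its variant calls."""

    accession_id: str
    species: str
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        loci = [v.locus for v in self.variants]
        if len(set(loci)) != len(loci):
            raise ValueError(
                f"{self.accession_id}: duplicate variant loci in profile"
            )


def apply_hard_filters(
    rec: VariantRecord, kind: str | None = None
) -> tuple[bool, list[str]]:
    """Evaluate the hard-filter expressions for ``rec``.

    Returns ``(passed, failed_criteria)``; a record fails when any listed
    inequality holds for its class.  Annotations that are absent cannot
    trigger their criterion.
    """
    if kind is None:
        kind = rec.kind
    if kind not in ("SNP", "InDel"):
        raise ValueError(f"unknown variant kind {kind!r}")
    if kind != rec.kind:
        raise ValueError(f"record at {rec.pos} is a {rec.kind}, not a {kind}")
    criteria = _SNP_CRITERIA if kind == "SNP" else _INDEL_CRITERIA
    failed = []
    for name, op, threshold in criteria:
        value = getattr(rec.annotations, name)
        if value is None:
            continue
        if (op == "<" and value < threshold) or (op == ">" and value > threshold):
            failed.append(name)
    return (not failed, failed)


def classify_zygosity(rec: VariantRecord) -> Zygosity:
    """Homogeneous (alt only), heterogeneous (ref+alt) or absent (ref only)."""
    seen = set(rec.observed_alleles)
    if seen == {rec.alt_allele}:
        return "homogeneous"
    if seen == {rec.ref_allele}:
        return "absent"
    return "heterogeneous"


def decompose_multiallelic(
    pos: int,
    ref: str,
    alts: Sequence[str],
    observed_indices: Sequence[int],
    annotations: FilterAnnotations | None = None,
) -> list[VariantRecord]:
    """Split a multi-allelic site into biallelic ref/alt records.

    ``observed_indices`` are VCF-style allele indices (0 = ref, k = alts[k-1])
    for the accession's genotype.  One record is produced per alt allele the
    accession carries; alleles from other alts count as reference evidence
    for that record.
    """
    records = []
    for k, alt in enumerate(alts, start=1):
        if k not in observed_indices:
            continue
        observed = tuple(
            alt if idx == k else ref for idx in observed_indices if idx >= 0
        )
        records.append(
            VariantRecord(
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                observed_alleles=observed,
                annotations=annotations or FilterAnnotations(),
            )
        )
    return records


_T2_COLUMNS = [
    "accessions",
    "snp_18S",
    "snp_ITS",
    "snp_26S",
    "indel_18S",
    "indel_ITS",
    "indel_26S",
]
_T3_COLUMNS = [
    "homogeneous_snps",
    "heterogeneous_snps",
    "homogeneous_indels",
    "heterogeneous_indels",
]


@dataclass
class SpeciesRegionTable:
    """Per-species distinct-locus counts by region and by zygosity class."""

    region_counts: pd.DataFrame   # index species, columns _T2_COLUMNS
    zygosity_counts: pd.DataFrame  # index species, columns _T3_COLUMNS

    def __post_init__(self) -> None:
        rc, zc = self.region_counts, self.zygosity_counts
        if (rc[_T2_COLUMNS[1:]] < 0).any().any() or (zc < 0).any().any():
            raise ValueError("counts must be non-negative")
        snp_tot = rc[["snp_18S", "snp_ITS", "snp_26S"]].sum(axis=1)
        indel_tot = rc[["indel_18S", "indel_ITS", "indel_26S"]].sum(axis=1)
        if not (
            zc["homogeneous_snps"] + zc["heterogeneous_snps"]
        ).equals(snp_tot.reindex(zc.index)):
            raise ValueError("zygosity SNP split does not sum to region total")
        if not (
            zc["homogeneous_indels"] + zc["heterogeneous_indels"]
        ).equals(indel_tot.reindex(zc.index)):
            raise ValueError("zygosity InDel split does not sum to region total")

    def write(self, table2_path: str | Path, table3_path: str | Path) -> None:
        self.region_counts.to_csv(table2_path, sep="\t", index_label="species")
        self.zygosity_counts.to_csv(table3_path, sep="\t", index_label="species")


def tally_profiles(
    profiles: Iterable[AccessionProfile], region_map: RegionMap
) -> SpeciesRegionTable:
    """Tally distinct variant loci per species, region and zygosity class.

    A locus (pos, ref, alt) counts once per species when observed in at
    least one member accession; 'absent' observations are ignored.
    """
    # species -> locus -> set of zygosities observed across accessions
    per_species: dict[str, dict[tuple, set[str]]] = {}
    carriers: dict[str, set[str]] = {}
    for profile in profiles:
        loci = per_species.setdefault(profile.species, {})
        carriers.setdefault(profile.species, set())
        has_variant = False
        for rec in profile.variants:
            zyg = classify_zygosity(rec)
            if zyg == "absent":
                continue
            region_map.pooled_region(rec.pos)  # raises on out-of-range pos
            loci.setdefault(rec.locus, set()).add(zyg)
            has_variant = True
        if has_variant:
            carriers[profile.species].add(profile.accession_id)

    species = sorted(per_species)
    rc = pd.DataFrame(0, index=species, columns=_T2_COLUMNS, dtype=int)
    zc = pd.DataFrame(0, index=species, columns=_T3_COLUMNS, dtype=int)
    for sp in species:
        rc.loc[sp, "accessions"] = len(carriers[sp])
        for (pos, ref, alt), zygs in per_species[sp].items():
            kind = "snp" if len(ref) == 1 and len(alt) == 1 else "indel"
            region = region_map.pooled_region(pos)
            rc.loc[sp, f"{kind}_{region}"] += 1
            zyg = (
                "heterogeneous" if "heterogeneous" in zygs else "homogeneous"
            )
            zc.loc[sp, f"{zyg}_{kind}s"] += 1
    return SpeciesRegionTable(rc, zc)


def read_species_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-delimited accession metadata (accession_id, species, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "accession_id" not in df.columns or "species" not in df.columns:
        raise ValueError("metadata needs 'accession_id' and 'species' columns")
    return df


def read_vcf_profiles(
    vcf_path: str | Path,
    metadata: pd.DataFrame | Mapping[str, str],
    apply_filters: bool = True,
) -> list[AccessionProfile]:
    """Build accession profiles from a multi-sample VCF.

    ``metadata`` maps accession id to species label (a mapping, or a frame
    with accession_id/species columns).  Multi-allelic records are
    decomposed; records failing the hard filters are dropped when
    ``apply_filters`` is set.  Genotypes: 1/1-like calls are homogeneous,
    0/1-like heterogeneous, 0/0 absent (not recorded).
    """
    from cyvcf2 import VCF

    if isinstance(metadata, pd.DataFrame):
        species_of = dict(zip(metadata["accession_id"], metadata["species"]))
    else:
        species_of = dict(metadata)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in species_of]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]} ...")
    variants: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    for v in vcf:
        ann = FilterAnnotations(
            QD=_info_float(v, "QD"),
            MQ=_info_float(v, "MQ"),
            FS=_info_float(v, "FS"),
            SOR=_info_float(v, "SOR"),
            QUAL=float(v.QUAL) if v.QUAL is not None else None,
            MQRankSum=_info_float(v, "MQRankSum"),
            ReadPosRankSum=_info_float(v, "ReadPosRankSum"),
        )
        for sample, gt in zip(samples, v.genotypes):
            alleles = [idx for idx in gt[:-1] if isinstance(idx, int)]
            if not alleles or all(idx <= 0 for idx in alleles):
                continue
            for rec in decompose_multiallelic(
                v.POS, v.REF, v.ALT, alleles, ann
            ):
                if apply_filters and not apply_hard_filters(rec)[0]:
                    continue
                variants[sample].append(rec)
    return [
        AccessionProfile(s, species_of[s], variants[s]) for s in samples
    ]


def _info_float(variant, key: str) -> float | None:
    value = variant.INFO.get(key)
    return None if value is None else float(value)
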