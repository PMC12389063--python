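"""The synthetic study generator: determinism, audits and round trips."""

from collections import Counter

import pandas as pd
import pytest

from morus_nrdna import simulate as sim
from morus_nrdna.simulate import (
    ALBA,
    CELTIDIFOLIA,
    NIGRA,
    NOTABILIS,
    RUBRA,
    SERRATA,
    motif_audit,
)

# packaged target per-species tallies the generator must reproduce
EXPECTED_REGION_COUNTS = {
    # species: (accessions, snp 18S/ITS/26S, indel 18S/ITS/26S)
    NIGRA: (3, 6, 17, 20, 0, 7, 1),
    SERRATA: (1, 8, 19, 17, 0, 6, 0),
    RUBRA: (3, 8, 16, 23, 0, 6, 0),
    CELTIDIFOLIA: (5, 6, 19, 17, 0, 6, 0),
    NOTABILIS: (16, 11, 34, 32, 0, 7, 1),
    ALBA: (57, 6, 7, 10, 0, 3, 0),
}
EXPECTED_ZYGOSITY = {
    # species: (hom SNPs, het SNPs, hom InDels, het InDels)
    NIGRA: (37, 6, 6, 2),
    SERRATA: (41, 3, 6, 0),
    RUBRA: (30, 17, 6, 0),
    CELTIDIFOLIA: (36, 6, 6, 0),
    NOTABILIS: (72, 5, 7, 1),
    ALBA: (0, 23, 0, 3),
}


class TestReference:
    def test_length_and_determinism(self, build):
        assert len(build.sequence) == 5814
        again = sim.build_reference(seed=1)
        assert again.sequence == build.sequence
        assert again.snps == build.snps
        assert again.indels == build.indels

    def test_different_seed_different_background(self, build):
        other = sim.build_reference(seed=2)
        assert other.sequence != build.sequence
        # constrained loci identical across seeds
        assert other.snps.keys() == build.snps.keys()
        assert all(
            other.snps[k].pos == build.snps[k].pos for k in build.snps
        )

    def test_motif_audit_passes(self, build):
        assert motif_audit(build.sequence) == []

    def test_insertion_flank_context(self, build):
        seq = build.sequence
        assert seq[1846:1854] == "TCGAAACC"
        assert seq[1862:1872] == "CCCCAACCCC"

    def test_seed_stability_across_small_seeds(self):
        for seed in (3, 17):
            b = sim.build_reference(seed=seed)
            assert motif_audit(b.sequence) == []
            sim.build_its_templates(b)  # raises if any assay cell deviates


class TestSpeciesProfiles:
    def test_snp_counts_by_region(self, build, species_profiles):
        rmap = build.region_map
        for sp, profile in species_profiles.items():
            per_region = Counter(
                rmap.pooled_region(build.snps[s].pos) for s in profile.snp_ids
            )
            _, s18, sits, s26, *_ = EXPECTED_REGION_COUNTS[sp]
            assert (per_region["18S"], per_region["ITS"], per_region["26S"]) \
                == (s18, sits, s26)
            hom, het, *_ = EXPECTED_ZYGOSITY[sp]
            assert len(profile.het_snp_ids) == het
            assert len(profile.snp_ids) - len(profile.het_snp_ids) == hom

    def test_snp_loci_inside_their_regions(self, build, species_profiles):
        rmap = build.region_map
        for profile in species_profiles.values():
            for s in profile.snp_ids:
                assert 1 <= build.snps[s].pos <= rmap.total_length

    def test_insertion_alleles(self, build, species_profiles):
        v13 = build.indels["I0:13"]
        v16 = build.indels["I0:16"]
        assert v13.pos == v16.pos == 1862
        assert v13.alt[1:] == sim.INS13 and v16.alt[1:] == sim.INS16
        assert dict(species_profiles[NOTABILIS].indels)["I0:16"] == "hom"
        for sp in (NIGRA, SERRATA, RUBRA, CELTIDIFOLIA):
            assert dict(species_profiles[sp].indels)["I0:13"] == "hom"
        assert dict(species_profiles[ALBA].indels)["I0:13"] == "het"

    def test_global_panel_sizes(self, build, species_profiles):
        all_snps = {s for p in species_profiles.values() for s in p.snp_ids}
        assert len(all_snps) == 158
        indel_positions = {
            build.indels[k].pos
            for p in species_profiles.values()
            for k, _ in p.indels
        }
        assert len(indel_positions) == 15


class TestCohort:
    def test_size_and_composition(self, cohort):
        assert len(cohort.profiles) == 542
        md = cohort.metadata
        assert len(md) == 542
        assert md["accession_id"].is_unique
        by_hap = md.groupby("haplotype_id").size().sort_values(ascending=False)
        assert list(by_hap)[:9] == [457, 21, 13, 13, 6, 4, 2, 2, 2]
        assert list(by_hap)[9:] == [1] * 22
        assert md["taxon"].value_counts()[ALBA] == 512

    def test_fine_species_counts(self, cohort):
        counts = cohort.metadata["species"].value_counts()
        assert counts["M. alba"] == 476  # varieties folded into M. alba
        assert counts["M. notabilis"] == 16
        assert counts["M. nigra"] == 3
        assert counts["M. rubra"] == 4
        assert counts["M. serrata"] == 2
        assert counts["M. celtidifolia"] == 5
        assert counts.sum() == 542

    def test_tally_round_trip_reproduces_target_tables(self, cohort):
        """Profiling the simulated cohort recovers every packaged target
        per-species count exactly."""
        table = cohort.tally()
        for sp, expected in EXPECTED_REGION_COUNTS.items():
            assert tuple(table.region_counts.loc[sp]) == expected, sp
        for sp, expected in EXPECTED_ZYGOSITY.items():
            assert tuple(table.zygosity_counts.loc[sp]) == expected, sp

    def test_haplotype_determinism(self, build):
        a = sim.simulate_cohort(build)
        b = sim.simulate_cohort(build)
        assert a.metadata.equals(b.metadata)
        assert [
            [v.locus for v in p.variants] for p in a.profiles
        ] == [[v.locus for v in p.variants] for p in b.profiles]

    def test_insertion_status_assignment(self, cohort):
        statuses = Counter(cohort.insertion_status.values())
        assert statuses == {"mixed": 539, "ins_only": 3}
        taxon_of = dict(
            zip(cohort.metadata["accession_id"], cohort.metadata["taxon"])
        )
        pure = [
            acc for acc, s in cohort.insertion_status.items()
            if s == "ins_only"
        ]
        assert all(taxon_of[acc] == NIGRA for acc in pure)


class TestOutputs:
    def test_vcf_is_well_formed(self, cohort, tmp_path):
        path = tmp_path / "cohort.vcf"
        sim.write_cohort_vcf(cohort, path)
        lines = path.read_text().splitlines()
        header = [l for l in lines if l.startswith("#CHROM")]
        assert len(header) == 1
        assert len(header[0].split("\t")) == 9 + 542
        body = [l for l in lines if not l.startswith("#")]
        # 158 SNP rows + 15 InDel rows (the two 1862 insertion alleles
        # share one multi-allelic row)
        assert len(body) == 158 + 15
        multi = [l for l in body if l.split("\t")[1] == "1862"]
        assert len(multi) == 1 and "," in multi[0].split("\t")[4]

    def test_templates_fasta_round_trip(self, templates, tmp_path):
        from Bio import SeqIO

        path = tmp_path / "templates.fasta"
        sim.write_templates_fasta(templates, path)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert records["M._notabilis"] == templates["M. notabilis"]
        assert len(records) == len(templates)

    def test_cohort_reads_deterministic(self, cohort):
        a = sim.simulate_cohort_reads(cohort, depth=4, seed=5)
        b = sim.simulate_cohort_reads(cohort, depth=4, seed=5)
        assert a == b
        c = sim.simulate_cohort_reads(cohort, depth=4, seed=6)
        assert a != c
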