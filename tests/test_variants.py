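"""Hard filters, zygosity classification and species/region tallies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morus_nrdna.regions import default_region_map
from morus_nrdna.variants import (
    AccessionProfile,
    FilterAnnotations,
    VariantRecord,
    apply_hard_filters,
    classify_zygosity,
    decompose_multiallelic,
    tally_profiles,
)

PASSING = FilterAnnotations(
    QD=20.0, MQ=60.0, FS=1.0, SOR=1.0, QUAL=500.0,
    MQRankSum=0.0, ReadPosRankSum=0.0,
)


def snp(pos=100, ref="T", alt="C", observed=None, ann=PASSING):
    return VariantRecord(pos, ref, alt, observed or (alt, alt), ann)


def indel(pos=1900, ref="CG", alt="C", observed=None, ann=PASSING):
    return VariantRecord(pos, ref, alt, observed or (alt, alt), ann)


class TestHardFilters:
    def test_passing_record(self):
        assert apply_hard_filters(snp()) == (True, [])

    @pytest.mark.parametrize(
        "field, value, should_fail",
        [
            ("QD", 1.9, True), ("QD", 2.0, False),
            ("MQ", 39.9, True), ("MQ", 40.0, False),
            ("FS", 60.1, True), ("FS", 60.0, False),
            ("SOR", 3.1, True), ("SOR", 3.0, False),
            ("QUAL", 29.9, True), ("QUAL", 30.0, False),
            ("MQRankSum", -12.6, True), ("MQRankSum", -12.5, False),
            ("ReadPosRankSum", -8.1, True), ("ReadPosRankSum", -8.0, False),
        ],
    )
    def test_snp_thresholds(self, field, value, should_fail):
        ann = FilterAnnotations(**{**vars(PASSING), field: value})
        passed, failed = apply_hard_filters(snp(ann=ann))
        assert passed is not should_fail
        assert (field in failed) is should_fail

    def test_indel_strand_bias_thresholds_are_relaxed(self):
        # FS=150 fails a SNP but passes an InDel (threshold 200)
        ann = FilterAnnotations(**{**vars(PASSING), "FS": 150.0})
        assert apply_hard_filters(indel(ann=ann)) == (True, [])
        assert apply_hard_filters(snp(ann=ann))[0] is False
        ann = FilterAnnotations(**{**vars(PASSING), "SOR": 8.0})
        assert apply_hard_filters(indel(ann=ann))[0] is True
        assert apply_hard_filters(snp(ann=ann))[0] is False

    def test_missing_annotations_never_fail(self):
        ann = FilterAnnotations(QUAL=50.0)
        assert apply_hard_filters(snp(ann=ann)) == (True, [])
        assert apply_hard_filters(snp(ann=FilterAnnotations())) == (True, [])

    def test_all_violations_reported(self):
        ann = FilterAnnotations(QD=1.0, MQ=10.0, FS=100.0, SOR=5.0, QUAL=10.0)
        _, failed = apply_hard_filters(snp(ann=ann))
        assert failed == ["QD", "MQ", "FS", "SOR", "QUAL"]

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_hard_filters(snp(), kind="InDel")

    @settings(max_examples=200, deadline=None)
    @given(
        base=st.fixed_dictionaries(
            {
                "QD": st.floats(0, 40),
                "MQ": st.floats(0, 70),
                "FS": st.floats(0, 300),
                "SOR": st.floats(0, 12),
                "QUAL": st.floats(0, 1000),
                "MQRankSum": st.floats(-20, 20),
                "ReadPosRankSum": st.floats(-20, 20),
            }
        ),
        field=st.sampled_from(
            ["QD", "MQ", "FS", "SOR", "QUAL", "MQRankSum", "ReadPosRankSum"]
        ),
        delta=st.floats(0.1, 50),
    )
    def test_filter_monotone_in_each_annotation(self, base, field, delta):
        """Worsening one annotation never turns a failing record passing."""
        worse_direction = 1 if field in ("FS", "SOR") else -1
        rec = snp(ann=FilterAnnotations(**base))
        worse = dict(base)
        worse[field] = max(0.0, base[field] + worse_direction * delta) \
            if field in ("FS", "SOR", "QD", "MQ", "QUAL") \
            else base[field] + worse_direction * delta
        rec_worse = snp(ann=FilterAnnotations(**worse))
        if not apply_hard_filters(rec)[0]:
            assert not apply_hard_filters(rec_worse)[0]


class TestZygosity:
    def test_alt_only_is_homogeneous(self):
        assert classify_zygosity(snp(observed=("C", "C"))) == "homogeneous"

    def test_ref_plus_alt_is_heterogeneous(self):
        assert classify_zygosity(snp(observed=("T", "C"))) == "heterogeneous"

    def test_ref_only_is_absent(self):
        assert classify_zygosity(snp(observed=("T", "T"))) == "absent"

    def test_multiallelic_decomposition(self):
        recs = decompose_multiallelic(
            1862, "A", ["ACGTGCGCAATGCG", "ACGACGTACACAATGCG"], [0, 1]
        )
        assert len(recs) == 1
        assert recs[0].alt_allele == "ACGTGCGCAATGCG"
        assert classify_zygosity(recs[0]) == "heterogeneous"
        recs = decompose_multiallelic(1862, "A", ["AC", "AG"], [2, 2])
        assert len(recs) == 1
        assert recs[0].alt_allele == "AG"
        assert classify_zygosity(recs[0]) == "homogeneous"


class TestTally:
    def make_profiles(self):
        rmap = default_region_map()
        # two accessions of one species sharing a locus with mixed zygosity,
        # plus a private InDel in the 26S
        a = AccessionProfile("a1", "sp1", [
            snp(pos=100, observed=("C", "C")),
            snp(pos=1900, ref="A", alt="G", observed=("A", "G")),
        ])
        b = AccessionProfile("a2", "sp1", [
            snp(pos=100, observed=("T", "C")),
            indel(pos=3000, observed=("C", "C")),
        ])
        c = AccessionProfile("a3", "sp2", [])
        return [a, b, c], rmap

    def test_hand_counted_tally(self):
        profiles, rmap = self.make_profiles()
        table = tally_profiles(profiles, rmap)
        rc = table.region_counts
        assert rc.loc["sp1", "accessions"] == 2
        assert rc.loc["sp1", "snp_18S"] == 1
        assert rc.loc["sp1", "snp_ITS"] == 1
        assert rc.loc["sp1", "indel_26S"] == 1
        assert rc.loc["sp2"].sum() == 0
        zc = table.zygosity_counts
        # the shared 18S locus is heterogeneous in a2 => heterogeneous
        assert zc.loc["sp1", "heterogeneous_snps"] == 2
        assert zc.loc["sp1", "homogeneous_snps"] == 0
        assert zc.loc["sp1", "homogeneous_indels"] == 1

    def test_empty_cohort_gives_empty_table(self):
        table = tally_profiles([], default_region_map())
        assert table.region_counts.empty

    def test_out_of_range_variant_raises(self):
        from morus_nrdna.regions import CoordinateError

        bad = AccessionProfile("x", "sp", [snp(pos=6000)])
        with pytest.raises(CoordinateError):
            tally_profiles([bad], default_region_map())

    def test_duplicate_loci_rejected(self):
        with pytest.raises(ValueError):
            AccessionProfile("x", "sp", [snp(pos=5), snp(pos=5)])


class TestVcfRoundTrip:
    def test_cohort_vcf_round_trip(self, cohort, tmp_path):
        """Writing the cohort VCF and re-reading it reproduces the tally."""
        from morus_nrdna.simulate import write_cohort_vcf, write_metadata
        from morus_nrdna.variants import read_vcf_profiles

        vcf = tmp_path / "cohort.vcf"
        meta = tmp_path / "metadata.tsv"
        write_cohort_vcf(cohort, vcf)
        write_metadata(cohort, meta)
        import pandas as pd

        md = pd.read_csv(meta, sep="\t")
        species_of = dict(zip(md["accession_id"], md["taxon"]))
        profiles = read_vcf_profiles(vcf, species_of)
        table = tally_profiles(profiles, cohort.build.region_map)
        direct = cohort.tally()
        assert table.region_counts.equals(direct.region_counts)
        assert table.zygosity_counts.equals(direct.zygosity_counts)
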