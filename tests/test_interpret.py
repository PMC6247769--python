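"""Impact classes, clonality rule, SV adjustment and biallelic calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmakit.interpret import (
    call_biallelic,
    classify_clonality,
    classify_impact,
    cna_burden,
    collect_gene_hits,
    gene_alteration_summary,
    sv_median_adjustment,
)
from plasmakit.types import (
    CnaSegment,
    GeneHit,
    GeneStatus,
    SampleMeta,
    SomaticVariant,
    StructuralVariant,
)

TP53 = ("chr17", 7_668_402, 7_687_550)


def _mut(effect, vaf=0.2, gene="TP53", pos=7_670_000, hotspot=None):
    depth = 800
    alt = int(round(vaf * depth))
    return SomaticVariant(
        chrom=TP53[0], pos=pos, ref="CA" if effect == "frameshift" else "A",
        alt="C" if effect == "frameshift" else "T",
        gene=gene, effect=effect,
        cfdna_ref_depth=depth - alt, cfdna_alt_depth=alt,
        hotspot=(effect == "hotspot_missense") if hotspot is None else hotspot,
    )


def _sv(region="exonic_span", fraction=0.1, gene="TP53"):
    return StructuralVariant(
        chrom1=TP53[0], pos1=7_670_100, chrom2=TP53[0], pos2=7_680_000,
        sv_type="deletion", genes_disrupted=[(gene, region)],
        supporting_fraction=fraction,
    )


def _seg(call, r, baf=0.5, chrom="chr17", start=7_000_000, end=8_500_000):
    return CnaSegment(chrom=chrom, start=start, end=end, coverage_ratio=r,
                      baf=baf, n_snps=50, cn_call=call)


class TestImpact:
    def test_frameshift_is_high_impact(self):
        assert classify_impact(_mut("frameshift")) == "high_impact_mutation"

    def test_hotspot_missense(self):
        assert classify_impact(_mut("hotspot_missense")) == "hotspot_mutation"

    def test_nonhotspot_missense_is_vus(self):
        assert classify_impact(_mut("missense_nonhotspot")) == "vus_mutation"

    def test_silent_classes_are_not_hits(self):
        assert classify_impact(_mut("synonymous")) is None
        assert classify_impact(_mut("intronic")) is None

    def test_exon_spanning_sv_is_high_impact(self):
        assert classify_impact(_sv("exonic_span")) == "high_impact_sv"

    def test_single_intron_sv_is_vus(self):
        assert classify_impact(_sv("single_intron")) == "vus_sv"

    def test_unannotated_sv_warns(self):
        sv = _sv()
        sv.genes_disrupted = []
        with pytest.warns(UserWarning):
            assert classify_impact(sv) == "unclassified"


class TestSvAdjustment:
    def test_ratio_of_medians(self):
        muts = [_mut("missense_nonhotspot", vaf=v, pos=7_670_000 + i)
                for i, v in enumerate((0.25, 0.30, 0.35))]
        svs = [_sv(fraction=f) for f in (0.10, 0.15, 0.20)]
        factor = sv_median_adjustment(muts, svs)
        assert factor == pytest.approx(2.0)
        # the median SV fraction maps exactly onto the median mutation VAF
        assert sorted(sv.adjusted_fraction for sv in svs)[1] == pytest.approx(0.30)
        # mutation VAFs are untouched
        assert [m.vaf for m in muts] == pytest.approx([0.25, 0.30, 0.35])

    def test_equal_medians_give_unit_factor(self):
        assert sv_median_adjustment(
            [_mut("missense_nonhotspot", vaf=0.2)], [_sv(fraction=0.2)]
        ) == pytest.approx(1.0)

    def test_adjusted_fraction_capped_at_one(self):
        svs = [_sv(fraction=0.6)]
        sv_median_adjustment([_mut("missense_nonhotspot", vaf=0.4)], svs)
        # factor 0.4/0.6 < 1; force a big factor instead
        svs = [_sv(fraction=0.6), _sv(fraction=0.1)]
        sv_median_adjustment([_mut("missense_nonhotspot", vaf=0.7)], svs)
        assert svs[0].adjusted_fraction == 1.0

    def test_no_mutations_warns_and_keeps_scale(self):
        svs = [_sv(fraction=0.3)]
        with pytest.warns(UserWarning):
            factor = sv_median_adjustment([], svs)
        assert factor == 1.0
        assert svs[0].adjusted_fraction == pytest.approx(0.3)


class TestClonality:
    @pytest.mark.parametrize(
        "fraction,tf,expected",
        [
            (0.05, 0.4, "subclonal"),
            (0.2, 0.4, "clonal"),
            (0.1, 0.4, "clonal"),  # exactly tf/4: strict < keeps it clonal
        ],
    )
    def test_quarter_rule(self, fraction, tf, expected):
        assert classify_clonality(fraction, tf) == expected

    def test_no_tumor_fraction_gives_na(self):
        assert classify_clonality(0.2, 0.0) == "NA"

    @given(
        fraction=st.floats(0.001, 1.0),
        tf=st.floats(0.01, 1.0),
        scale=st.floats(0.1, 0.99),
    )
    @settings(deadline=None)
    def test_scale_free(self, fraction, tf, scale):
        assert classify_clonality(fraction, tf) == classify_clonality(
            fraction * scale, tf * scale
        )


class TestBiallelic:
    def test_homozygous_deletion_alone_is_biallelic(self):
        seg = _seg("homozygous_deletion", r=0.7)
        hits = collect_gene_hits("TP53", [], [], [seg], tf=0.5)
        status = call_biallelic("TP53", hits, [seg])
        assert status.zygosity_call == "biallelic"
        assert not status.residual_breakpoint

    def test_clonal_high_impact_plus_loh_is_biallelic(self):
        seg = _seg("deletion_LOH", r=0.75, baf=0.67)
        hits = collect_gene_hits("TP53", [_mut("frameshift", vaf=0.3)], [], [seg], tf=0.5)
        assert call_biallelic("TP53", hits, [seg]).zygosity_call == "biallelic"

    def test_single_clonal_hit_without_second_event_is_monoallelic(self):
        # the exon-spanning deletion without any observable second hit
        svs = [_sv("exonic_span", fraction=0.25)]
        hits = collect_gene_hits("TP53", [], svs, [], tf=0.5)
        assert call_biallelic("TP53", hits, []).zygosity_call == "monoallelic"

    def test_two_clonal_mutations_are_biallelic(self):
        muts = [_mut("frameshift", vaf=0.25), _mut("truncating", vaf=0.22, pos=7_671_000)]
        hits = collect_gene_hits("TP53", muts, [], [], tf=0.5)
        assert call_biallelic("TP53", hits, []).zygosity_call == "biallelic"

    def test_subclonal_hit_does_not_count(self):
        hits = collect_gene_hits("TP53", [_mut("frameshift", vaf=0.05)], [], [], tf=0.6)
        assert call_biallelic("TP53", hits, []).zygosity_call == "wild_type"

    def test_residual_breakpoint_inside_homdel(self):
        seg = _seg("homozygous_deletion", r=0.7)
        hits = collect_gene_hits("TP53", [], [_sv(fraction=0.2)], [seg], tf=0.5)
        status = call_biallelic("TP53", hits, [seg])
        assert status.zygosity_call == "biallelic"
        assert status.residual_breakpoint

    def test_homdel_with_clonal_mutation_is_conflict(self):
        seg = _seg("homozygous_deletion", r=0.7)
        hits = collect_gene_hits("TP53", [_mut("frameshift", vaf=0.3)], [], [seg], tf=0.5)
        status = call_biallelic("TP53", hits, [seg])
        assert status.conflict and status.zygosity_call == "no_call"

    def test_msi_samples_flagged_for_exclusion(self):
        hits = collect_gene_hits("TP53", [_mut("frameshift", vaf=0.3)], [], [], tf=0.5)
        assert call_biallelic("TP53", hits, [], msi_flag=True).msi_excluded

    @given(
        classes=st.lists(
            st.sampled_from(
                ["high_impact_mutation", "hotspot_mutation", "high_impact_sv",
                 "vus_mutation", "vus_sv", "loh"]
            ),
            max_size=5,
        ),
        clonalities=st.lists(st.sampled_from(["clonal", "subclonal"]), min_size=5, max_size=5),
    )
    @settings(deadline=None)
    def test_biallelic_requires_two_events_or_homdel(self, classes, clonalities):
        hits = [GeneHit(None, cls, clon) for cls, clon in zip(classes, clonalities)]
        status = call_biallelic("TP53", hits, [])
        if status.zygosity_call == "biallelic":
            inactivating = sum(
                1 for h in hits
                if (h.hit_class in ("high_impact_mutation", "hotspot_mutation",
                                    "high_impact_sv") and h.clonality == "clonal")
                or h.hit_class in ("loh", "homozygous_deletion")
            )
            assert inactivating >= 2


class TestGeneSummary:
    def _meta(self, patient, sample, line="mCRPC1"):
        return SampleMeta(patient_id=patient, sample_id=sample, stage_line=line)

    def _status(self, gene="AR", classes=()):
        return {gene: GeneStatus(gene=gene, hits=[GeneHit(None, c, "clonal") for c in classes])}

    def test_no_alterations(self):
        samples = [(self._meta("p1", "s1"), self._status())]
        table = gene_alteration_summary(samples, "AR")
        assert table["frac_any"].iloc[0] == 0.0

    def test_planted_amplification_fraction(self):
        samples = [
            (self._meta(f"p{i}", f"s{i}"),
             self._status(classes=("amplification",) if i < 5 else ()))
            for i in range(10)
        ]
        table = gene_alteration_summary(samples, "AR")
        assert table["frac_amplification"].iloc[0] == pytest.approx(0.5)

    def test_patient_counted_once_under_any(self):
        samples = [
            (self._meta("p1", "s1"), self._status(classes=("amplification",))),
            (self._meta("p1", "s2"), self._status(classes=("high_impact_sv",))),
        ]
        table = gene_alteration_summary(samples, "AR")
        assert table["n_any"].iloc[0] == 1
        assert table["n_patients"].iloc[0] == 1


def test_cna_burden_fraction():
    segs = [
        _seg("neutral", 1.0, chrom="chr1", start=0, end=70_000_000),
        _seg("gain", 1.2, chrom="chr1", start=70_000_000, end=100_000_000),
    ]
    assert cna_burden(segs) == pytest.approx(0.3)
    assert cna_burden([]) == 0.0
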