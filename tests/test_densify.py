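"""Local->global projections and densification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcr.core import Call, GenomicLocus, genotype_index, n_genotypes
from svcr.densify import (
    densify_at_locus,
    densify_stream,
    localize_fields,
    project_lad_to_ad,
    project_lgt_to_gt,
    project_lpl_to_pl,
)
from svcr.combine import merge
from svcr.gvcf import import_gvcf
from svcr.refblocks import split_fixed_period

from conftest import make_cohort


class TestProjections:
    def test_worked_example_ad(self):
        """LAD [0,14,16] with LA [0,1,3] at a 5-allele site -> [0,14,0,16,0]."""
        assert project_lad_to_ad((0, 14, 16), (0, 1, 3), 5) == (0, 14, 0, 16, 0)

    def test_identity_la_is_noop(self):
        assert project_lad_to_ad((1, 2, 3), (0, 1, 2), 3) == (1, 2, 3)
        lpl = tuple(range(n_genotypes(3, 2)))
        assert project_lpl_to_pl(lpl, (0, 1, 2), 3) == lpl

    def test_ref_only_observation(self):
        assert project_lad_to_ad((5,), (0,), 4) == (5, 0, 0, 0)
        assert project_lpl_to_pl((0,), (0,), 2) == (0, None, None)

    def test_pl_projection_populates_local_genotypes_only(self):
        la = (0, 1, 3)
        lpl = tuple(10 * i for i in range(n_genotypes(3, 2)))
        pl = project_lpl_to_pl(lpl, la, 5)
        assert len(pl) == 15
        assert sum(x is not None for x in pl) == 6
        # spot-check the placement: local (1,2) -> global (1,3)
        assert pl[genotype_index(1, 3)] == lpl[genotype_index(1, 2)]
        assert pl[genotype_index(0, 0)] == lpl[0]

    def test_pl_projection_with_sentinel_fill(self):
        pl = project_lpl_to_pl((0,), (0,), 2, fill=999)
        assert pl == (0, 999, 999)

    def test_gt_projection_follows_la(self):
        assert str(project_lgt_to_gt(Call.parse("1/2"), (0, 1, 3))) == "1/3"
        assert str(project_lgt_to_gt(Call.parse("0/0"), (0, 4))) == "0/0"
        assert str(project_lgt_to_gt(Call.parse("0|1"), (0, 4))) == "0|4"

    def test_length_mismatches_rejected(self):
        with pytest.raises(ValueError, match="LAD"):
            project_lad_to_ad((1, 2), (0, 1, 2), 3)
        with pytest.raises(ValueError, match="LPL"):
            project_lpl_to_pl((1, 2), (0, 1, 2), 3)
        with pytest.raises(ValueError, match="outside LA"):
            project_lgt_to_gt(Call.parse("0/3"), (0, 1))

    def test_read_conservation(self):
        lad = (3, 9, 2)
        ad = project_lad_to_ad(lad, (0, 2, 5), 7)
        assert sum(ad) == sum(lad)


@settings(max_examples=200, derandomize=True)
@given(st.data())
def test_projection_length_law(data):
    """Projected PL has G(n_global) entries of which exactly G(n_local) are
    populated, for random injective LA maps."""
    n_global = data.draw(st.integers(1, 30))
    n_local = data.draw(st.integers(1, min(3, n_global)))
    nonzero = data.draw(
        st.lists(st.integers(1, n_global - 1), unique=True,
                 min_size=n_local - 1, max_size=n_local - 1)
        if n_global > 1 else st.just([])
    )
    la = tuple([0] + nonzero)
    lpl = tuple(range(n_genotypes(n_local, 2)))
    pl = project_lpl_to_pl(lpl, la, n_global)
    assert len(pl) == n_global * (n_global + 1) // 2
    assert sum(x is not None for x in pl) == n_local * (n_local + 1) // 2


@settings(max_examples=150, derandomize=True)
@given(st.data())
def test_localize_then_project_is_identity(data):
    """Round trip dense -> local -> dense for random genotypes."""
    n_global = data.draw(st.integers(1, 6))
    j = data.draw(st.integers(0, n_global - 1))
    k = data.draw(st.integers(0, n_global - 1))
    gt = Call((min(j, k), max(j, k)))
    ad = tuple(data.draw(st.integers(0, 40)) for _ in range(n_global))
    pl = tuple(data.draw(st.integers(0, 99))
               for _ in range(n_genotypes(n_global, 2)))
    g = localize_fields(gt, ad, pl)
    assert project_lgt_to_gt(g.lgt, g.la) == gt
    back_ad = project_lad_to_ad(g.lad, g.la, n_global)
    for i in range(n_global):
        if i in g.la:
            assert back_ad[i] == ad[i]
        else:
            assert back_ad[i] == 0
    back_pl = project_lpl_to_pl(g.lpl, g.la, n_global)
    for a in range(n_global):
        for b in range(a, n_global):
            if a in g.la and b in g.la:
                assert back_pl[genotype_index(a, b)] == pl[genotype_index(a, b)]


class TestDensification:
    def test_point_query_fills_hom_ref_from_block(self, cohort4):
        ds = merge(cohort4.import_all())
        # find a locus where some sample relies on a block
        for site in ds.variant_matrix:
            absent = [s for s in ds.samples if s not in site.entries]
            if absent:
                row = densify_at_locus(ds, site.locus)
                for s in absent:
                    call = row.calls[s]
                    if call is not None:
                        assert call.from_block and str(call.gt) == "0/0"
                        assert call.ad is None and call.pl is None
                return
        pytest.fail("no locus with a block-filled sample in fixture")

    def test_point_query_outside_coverage_is_missing(self):
        from svcr.gvcf import GvcfRecord

        ds = import_gvcf(
            [GvcfRecord("chr1", 100, "A", ("T",), fmt={"GT": "0/1"})], "S1"
        )
        row = densify_at_locus(ds, GenomicLocus("chr1", 50))
        assert row.calls["S1"] is None

    def test_unknown_contig_rejected(self, cohort4):
        ds = cohort4.import_all()[0]
        with pytest.raises(KeyError, match="contig"):
            densify_at_locus(ds, GenomicLocus("chrZ", 5))

    def test_stream_equals_point_query_at_every_site(self, cohort4):
        ds = merge(cohort4.import_all())
        for row in densify_stream(ds):
            point = densify_at_locus(ds, row.locus)
            assert point.calls == row.calls
            assert point.alleles == row.alleles

    def test_no_variants_yields_empty_stream(self):
        from svcr.core import SvcrDataset

        assert list(densify_stream(SvcrDataset(["S1"], ["chr1"]))) == []

    def test_composition_identity_on_fresh_import(self, cohort4):
        """With identity LA, projections reproduce the GVCF's GT/AD/PL."""
        sg = cohort4.samples[0]
        ds = import_gvcf(sg.records, sg.sample_id, "retain", [cohort4.model.contig])
        variant_recs = [r for r in sg.records if not r.is_reference_row()]
        rows = list(densify_stream(ds))
        assert len(rows) == len(variant_recs)
        for rec, row in zip(variant_recs, rows):
            call = row.calls[sg.sample_id]
            assert call.gt == rec.gt
            assert call.ad == rec.ad
            assert tuple(call.pl) == rec.pl

    def test_partitioned_region_stream_is_self_contained(self, cohort4):
        """After fixed-period splitting at K, one K-partition densifies
        identically with and without looking outside the partition."""
        k = 5000
        ds = split_fixed_period(merge(cohort4.import_all()), k)
        region = ("chr1", k + 1, 2 * k)
        full = [
            r for r in densify_stream(ds)
            if region[1] <= r.locus.position <= region[2]
        ]
        partitioned = list(
            densify_stream(ds, region=region, assume_partitioned=True)
        )
        assert [r.locus for r in partitioned] == [r.locus for r in full]
        for a, b in zip(full, partitioned):
            assert a.calls == b.calls
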