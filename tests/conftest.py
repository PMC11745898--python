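"""Shared fixtures: small synthetic cohorts and an independent dense-join oracle.

The oracle builds, directly from GVCF records and the simulated reference
sequence, the per-base / per-sample truth that densification of a merged
dataset must reproduce.  It shares no code with the merge or densify paths:
allele harmonization here is done on allele *strings* extended with reference
sequence, so the comparison is independent of any allele index order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from svcr.gvcf import NON_REF, GvcfRecord, import_gvcf
from svcr.simulate import CohortModel, CohortPool, SampleGvcf, build_pool, simulate_sample


@dataclass
class SmallCohort:
    model: CohortModel
    pool: CohortPool
    samples: list[SampleGvcf]

    def import_all(self, policy: str = "drop"):
        return [
            import_gvcf(sg.records, sg.sample_id, policy, [self.model.contig])
            for sg in self.samples
        ]


def make_cohort(n_samples: int, k: int = 100, genome_length: int = 30_000,
                seed: int = 7) -> SmallCohort:
    model = CohortModel(
        n_samples=n_samples,
        k_variants_per_sample=k,
        genome_length=genome_length,
        seed=seed,
    )
    pool = build_pool(model)
    samples = [simulate_sample(model, pool, i) for i in range(n_samples)]
    return SmallCohort(model, pool, samples)


@pytest.fixture(scope="session")
def cohort4() -> SmallCohort:
    return make_cohort(4)


@pytest.fixture(scope="session")
def cohort8() -> SmallCohort:
    return make_cohort(8, k=150, genome_length=100_000, seed=13)


# ---------------------------------------------------------------------------
# Brute-force dense join, straight from GVCF records


@dataclass
class TruthCall:
    """A sample's truth at one variant locus, in allele-string terms."""

    gt_alleles: tuple[str, ...]  # called allele sequences ("<ref>" for ref)
    ad: dict[str, int]  # allele string -> depth (sample's own alleles only)
    dp: object
    gq: object
    hom_ref_block: bool = False


def _extend(allele: str, ref: str, longest_ref: str) -> str:
    if allele.startswith("<") or allele == "*":
        return allele
    return allele + longest_ref[len(ref):]


def brute_force_join(cohort: SmallCohort) -> dict[int, dict[str, TruthCall | None]]:
    """Per-base truth at every union variant locus, computed record by record.

    <NON_REF> is ignored (the merge inputs are imported under the drop
    policy).  Allele identity is the extended allele string, so the result is
    independent of any index assignment.
    """
    per_sample_variants: dict[str, dict[int, GvcfRecord]] = {}
    per_sample_cover: dict[str, dict[int, tuple]] = {}
    for sg in cohort.samples:
        variants: dict[int, GvcfRecord] = {}
        cover: dict[int, tuple] = {}
        for rec in sg.records:
            if rec.is_reference_row():
                end = rec.end if rec.end is not None else rec.pos + len(rec.ref) - 1
                for pos in range(rec.pos, end + 1):
                    cover[pos] = (rec.dp, rec.gq)
            else:
                variants[rec.pos] = rec
        per_sample_variants[sg.sample_id] = variants
        per_sample_cover[sg.sample_id] = cover

    union_loci = sorted(
        {pos for v in per_sample_variants.values() for pos in v}
    )
    out: dict[int, dict[str, TruthCall | None]] = {}
    for pos in union_loci:
        longest_ref = max(
            (per_sample_variants[s][pos].ref
             for s in per_sample_variants if pos in per_sample_variants[s]),
            key=len,
        )
        row: dict[str, TruthCall | None] = {}
        for sg in cohort.samples:
            s = sg.sample_id
            rec = per_sample_variants[s].get(pos)
            if rec is not None:
                alleles = [rec.ref] + [a for a in rec.alts]
                extended = [_extend(a, rec.ref, longest_ref) for a in alleles]
                gt = rec.gt
                gt_strings = tuple(
                    extended[a] for a in gt.alleles if a is not None
                )
                ad = {}
                if rec.ad is not None:
                    for a_str, depth in zip(extended, rec.ad):
                        if a_str != NON_REF:
                            ad[a_str] = depth
                row[s] = TruthCall(gt_strings, ad, rec.dp, rec.gq)
            elif pos in per_sample_cover[s]:
                dp, gq = per_sample_cover[s][pos]
                row[s] = TruthCall((longest_ref, longest_ref), {}, dp, gq,
                                   hom_ref_block=True)
            else:
                row[s] = None
        out[pos] = row
    return out


def assert_dense_rows_match_truth(rows, truth, samples) -> None:
    """Compare a densified row stream with the brute-force truth."""
    by_pos = {row.locus.position: row for row in rows}
    assert sorted(by_pos) == sorted(truth), "variant locus sets differ"
    for pos, expected in truth.items():
        row = by_pos[pos]
        strings = row.alleles.alleles
        for s in samples:
            want = expected[s]
            got = row.calls[s]
            if want is None:
                assert got is None, f"{s}@{pos}: expected missing"
                continue
            assert got is not None, f"{s}@{pos}: unexpectedly missing"
            if want.hom_ref_block:
                assert got.from_block and got.gt.is_hom_ref(), f"{s}@{pos}"
                assert (got.dp, got.gq) == (want.dp, want.gq), f"{s}@{pos}"
                continue
            got_gt = tuple(
                strings[a] for a in got.gt.alleles if a is not None
            )
            assert sorted(got_gt) == sorted(want.gt_alleles), f"{s}@{pos}: GT"
            assert (got.dp, got.gq) == (want.dp, want.gq), f"{s}@{pos}: DP/GQ"
            if want.ad:
                assert got.ad is not None
                for a_str, depth in zip(strings, got.ad):
                    assert depth == want.ad.get(a_str, 0), (
                        f"{s}@{pos}: AD for {a_str}"
                    )
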