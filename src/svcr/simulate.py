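"""Synthetic GVCF cohorts with realistic sharing structure, and scaling fits.

The generator emulates GATK-style whole-genome GVCFs: per-sample nonreference
records are drawn from a shared site pool with a skewed allele-frequency
spectrum, interleaved with GQ-banded reference blocks tiling the rest of the
genome.  Frequencies follow a log-uniform (density proportional to 1/f) law,
the simplest spectrum under which the number of distinct variant sites in a
cohort grows sub-linearly with sample count: common variants saturate early
while rare variants keep contributing singletons.  A diploid sample carries a
variant of frequency f with probability 1-(1-f)^2 and is heterozygous or
homozygous by Hardy-Weinberg proportions.

Sample streams derive child seeds from one root seed by sample index, so a
cohort is extensible: adding sample N+1 leaves samples 1..N byte-identical —
mirroring incremental N+K combining.

The measured quantities are record counts: a dense matrix holds
samples x sites genotype records, while the sparse representation stores only
each sample's own variant genotypes plus its reference blocks.  Fitting
log10(measure) against log10(N) over a cohort sweep yields the scaling
exponent: ~1 for sparse storage, 1 + (site exponent) for the dense matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .combine import merge
from .core import SvcrDataset
from .gvcf import NON_REF, GvcfRecord, import_gvcf

__all__ = [
    "CohortModel",
    "CohortPool",
    "PoolVariant",
    "SampleGvcf",
    "CohortStats",
    "ScalingFit",
    "build_pool",
    "simulate_cohort",
    "count_stats",
    "fit_loglog",
    "scaling_sweep",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CohortModel:
    """Study conditions for a synthetic cohort.

    ``k_variants_per_sample`` is the expected number of nonreference genotype
    records per sample (genome-scale callers produce 3-6 million; the
    desk-scale default is 500 on a 100 kb toy genome).  ``site_pool_size``
    of None sizes the pool so the expected per-sample record count equals K
    exactly under the frequency law.  ``block_gq_bands`` are (GQ, mean span)
    pairs for reference-block tiling; ``indel_fraction`` and
    ``max_alts_per_locus`` control how often multiallelic and
    length-discordant sites arise (they exercise allele unification).
    """

    n_samples: int
    k_variants_per_sample: int = 500
    site_pool_size: Optional[int] = None
    freq_min: float = 1e-4
    freq_max: float = 0.5
    genome_length: int = 100_000
    contig: str = "chr1"
    indel_fraction: float = 0.15
    max_alts_per_locus: int = 4
    block_gq_bands: tuple[tuple[int, int], ...] = ((15, 150), (30, 400), (50, 1200))
    mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.k_variants_per_sample < 1:
            raise ValueError("counts must be positive")
        if not (0.0 < self.freq_min <= self.freq_max <= 1.0):
            raise ValueError("frequencies must satisfy 0 < min <= max <= 1")
        if self.genome_length < 100:
            raise ValueError("genome_length too small")


@dataclass(frozen=True)
class PoolVariant:
    pos: int
    ref: str
    alt: str
    freq: float


@dataclass
class CohortPool:
    """The shared site pool: loci, their variants, and the reference sequence."""

    genome: str
    loci: list[list[PoolVariant]]  # sorted by position; >= 1 variant per locus
    expected_records_per_sample: float

    @property
    def n_variants(self) -> int:
        return sum(len(v) for v in self.loci)


@dataclass
class SampleGvcf:
    sample_id: str
    records: list[GvcfRecord]


def _draw_freq(rng: np.random.Generator, model: CohortModel) -> float:
    lo, hi = math.log(model.freq_min), math.log(model.freq_max)
    return float(math.exp(rng.uniform(lo, hi)))


_N_ALT_P = np.array([0.90, 0.06, 0.025, 0.015])


def _draw_locus_variants(
    rng: np.random.Generator, model: CohortModel, pos: int, genome: str
) -> list[PoolVariant]:
    n_alts = int(rng.choice(4, p=_N_ALT_P)) + 1
    n_alts = min(n_alts, model.max_alts_per_locus)
    variants: list[PoolVariant] = []
    seen: set[tuple[str, str]] = set()
    base = genome[pos - 1]
    for _ in range(n_alts):
        f = _draw_freq(rng, model)
        if rng.random() < model.indel_fraction:
            length = int(rng.integers(1, 7))
            if rng.random() < 0.5:  # deletion
                ref = genome[pos - 1 : pos + length]
                alt = ref[0]
            else:  # insertion
                ref = base
                alt = base + "".join(
                    _BASES[i] for i in rng.integers(0, 4, size=length)
                )
        else:  # SNV
            ref = base
            alt = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
        if (ref, alt) in seen:
            continue
        seen.add((ref, alt))
        variants.append(PoolVariant(pos, ref, alt, f))
    return variants


def build_pool(model: CohortModel) -> CohortPool:
    """Draw the shared reference genome and variant pool (deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(0,)))
    genome = "".join(
        _BASES[i] for i in rng.integers(0, 4, size=model.genome_length)
    )
    margin = 10
    candidates = rng.permutation(np.arange(2, model.genome_length - margin))

    loci: list[list[PoolVariant]] = []
    expected = 0.0
    target = float(model.k_variants_per_sample)
    for idx, pos in enumerate(candidates):
        if model.site_pool_size is None:
            if expected >= target:
                break
        elif len(loci) >= model.site_pool_size:
            break
        variants = _draw_locus_variants(rng, model, int(pos), genome)
        loci.append(variants)
        q_absent = 1.0
        for v in variants:
            q_absent *= (1.0 - v.freq) ** 2
        expected += 1.0 - q_absent
    loci.sort(key=lambda vs: vs[0].pos)
    return CohortPool(genome, loci, expected)


def _pl_for_call(
    called: tuple[int, int], n_alleles: int, q1: int, q2: int
) -> list[int]:
    from .core import genotype_index, n_genotypes

    pl = [0] * n_genotypes(n_alleles, 2)
    cj, ck = called
    for k in range(n_alleles):
        for j in range(k + 1):
            if (j, k) == called:
                continue
            shares = j in (cj, ck) or k in (cj, ck)
            pl[genotype_index(j, k)] = q1 if shares else q2
    return pl


def _variant_record(
    rng: np.random.Generator,
    model: CohortModel,
    pool: CohortPool,
    carried: list[tuple[PoolVariant, bool]],
) -> tuple[GvcfRecord, int]:
    """Build one nonreference row; returns (record, footprint end position)."""
    carried = carried[:2]  # a diploid carries at most two alternates
    pos = carried[0][0].pos
    longest_ref = max((v.ref for v, _ in carried), key=len)
    alts = []
    for v, _ in carried:
        suffix = longest_ref[len(v.ref):]
        alts.append(v.alt + suffix)
    alleles = [longest_ref] + alts + [NON_REF]
    n = len(alleles)

    dp = max(4, int(rng.poisson(model.mean_depth)))
    ad = [0] * n
    if len(carried) == 2:
        gt = "1/2"
        called = (1, 2)
        ad[1] = dp // 2
        ad[2] = dp - ad[1]
    else:
        hom = carried[0][1]
        if hom:
            gt, called = "1/1", (1, 1)
            ad[1] = dp
        else:
            gt, called = "0/1", (0, 1)
            ad[0] = int(rng.binomial(dp, 0.5))
            ad[1] = dp - ad[0]
    q1 = int(rng.integers(20, 61))
    q2 = q1 + int(rng.integers(30, 200))
    pl = _pl_for_call(called, n, q1, q2)
    gq = min(q1, 99)

    rec = GvcfRecord(
        contig=model.contig,
        pos=pos,
        ref=longest_ref,
        alts=tuple(alleles[1:]),
        qual=str(q1),
        fmt={
            "GT": gt,
            "AD": ",".join(str(x) for x in ad),
            "DP": str(dp),
            "GQ": str(gq),
            "PL": ",".join(str(x) for x in pl),
        },
    )
    return rec, pos + len(longest_ref) - 1


def _tile_blocks(
    rng: np.random.Generator,
    model: CohortModel,
    genome: str,
    start: int,
    end: int,
) -> list[GvcfRecord]:
    out = []
    bands = model.block_gq_bands
    cur = start
    while cur <= end:
        gq, mean_len = bands[int(rng.integers(0, len(bands)))]
        span = min(end - cur + 1, max(1, int(rng.geometric(1.0 / mean_len))))
        dp = max(1, int(rng.poisson(model.mean_depth)))
        out.append(
            GvcfRecord(
                contig=model.contig,
                pos=cur,
                ref=genome[cur - 1],
                alts=(NON_REF,),
                info={"END": str(cur + span - 1)},
                fmt={"GT": "0/0", "DP": str(dp), "GQ": str(gq)},
            )
        )
        cur += span
    return out


def simulate_sample(
    model: CohortModel, pool: CohortPool, index: int
) -> SampleGvcf:
    """Generate one sample's GVCF stream; deterministic in (seed, index)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(model.seed, spawn_key=(1, index))
    )
    flat = [(li, v) for li, vs in enumerate(pool.loci) for v in vs]
    freqs = np.array([v.freq for _, v in flat])
    p_carry = 2 * freqs - freqs**2
    u = rng.uniform(size=len(flat))
    u_hom = rng.uniform(size=len(flat))

    per_locus: dict[int, list[tuple[PoolVariant, bool]]] = {}
    for i, (li, v) in enumerate(flat):
        if u[i] < p_carry[i]:
            p_hom = v.freq**2 / p_carry[i]
            per_locus.setdefault(li, []).append((v, bool(u_hom[i] < p_hom)))

    records: list[GvcfRecord] = []
    cursor = 1
    for li in sorted(per_locus, key=lambda li: pool.loci[li][0].pos):
        carried = per_locus[li]
        pos = carried[0][0].pos
        if pos < cursor:
            continue  # footprint of the previous record swallowed this locus
        if pos > cursor:
            records.extend(_tile_blocks(rng, model, pool.genome, cursor, pos - 1))
        rec, foot_end = _variant_record(rng, model, pool, carried)
        records.append(rec)
        cursor = foot_end + 1
    if cursor <= model.genome_length:
        records.extend(
            _tile_blocks(rng, model, pool.genome, cursor, model.genome_length)
        )
    return SampleGvcf(f"S{index:04d}", records)


def simulate_cohort(model: CohortModel) -> list[SampleGvcf]:
    """Generate the cohort's single-sample GVCF streams (deterministic)."""
    pool = build_pool(model)
    return [simulate_sample(model, pool, i) for i in range(model.n_samples)]


# ---------------------------------------------------------------------------
# Measurement


@dataclass
class CohortStats:
    n_samples: int
    n_variant_sites: int
    n_genotype_records: int  # dense: samples x sites
    n_svcr_records: int  # stored variant genotypes + reference blocks
    bytes_svcr_vcf: Optional[int] = None
    bytes_dense_pvcf: Optional[int] = None


def count_stats(ds: SvcrDataset, with_bytes: bool = False) -> CohortStats:
    """Size measures of a dataset in dense and sparse terms."""
    n_sites = len(ds.variant_matrix)
    stats = CohortStats(
        n_samples=len(ds.samples),
        n_variant_sites=n_sites,
        n_genotype_records=n_sites * len(ds.samples),
        n_svcr_records=ds.n_variant_genotypes() + ds.n_reference_blocks(),
    )
    if with_bytes:
        from .vcfio import encoded_size, export_dense_pvcf, write_svcr_vcf

        stats.bytes_svcr_vcf = encoded_size(write_svcr_vcf, ds)
        stats.bytes_dense_pvcf = encoded_size(export_dense_pvcf, ds)
    return stats


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares line log10(measure) = a + b*log10(n)."""

    a: float
    b: float
    r2: float


def fit_loglog(points: Sequence[tuple[float, float]]) -> ScalingFit:
    if len(points) < 3:
        raise ValueError("need at least 3 points for a scaling fit")
    n = np.array([p[0] for p in points], dtype=float)
    m = np.array([p[1] for p in points], dtype=float)
    if np.any(n <= 0) or np.any(m <= 0):
        raise ValueError("scaling fits require positive values")
    x, y = np.log10(n), np.log10(m)
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ScalingFit(float(a), float(b), r2)


def scaling_sweep(
    model: CohortModel,
    n_values: Sequence[int],
    with_bytes: bool = False,
) -> list[CohortStats]:
    """Measure cohort sizes at each N by incremental N+K combining.

    One cohort of max(n_values) samples is generated; the dataset at each
    checkpoint merges the previous checkpoint with the next batch of
    single-sample imports, exactly the incremental workflow the
    representation exists for.
    """
    n_values = sorted(n_values)
    if n_values[-1] > model.n_samples:
        model = CohortModel(**{**model.__dict__, "n_samples": n_values[-1]})
    pool = build_pool(model)
    out: list[CohortStats] = []
    current: Optional[SvcrDataset] = None
    done = 0
    for n in n_values:
        batch = [
            import_gvcf(
                sg.records, sg.sample_id, non_ref_policy="drop", contigs=[model.contig]
            )
            for sg in (simulate_sample(model, pool, i) for i in range(done, n))
        ]
        inputs = ([current] if current is not None else []) + batch
        current = merge(inputs) if len(inputs) > 1 else inputs[0]
        done = n
        out.append(count_stats(current, with_bytes=with_bytes))
    return out
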