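"""Resolving the sparse representation into dense, globally indexed rows.

Local fields store only the alleles a sample observed; densification projects
them onto the site's full allele list (AD entries for unobserved alleles are
0 — zero informative reads — while PL entries for genotypes touching an
unobserved allele are missing by default) and fills homozygous-reference
calls from overlapping reference blocks.  A point query searches backwards at
most ``max_ref_block_length - 1`` bases for covering blocks; the streaming
variant keeps one active block per sample while sweeping the merged record
stream, which per-sample disjointness makes unambiguous.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Union

from .core import (
    AlleleList,
    Call,
    GenomicLocus,
    ReferenceBlock,
    SvcrDataset,
    VariantGenotype,
    genotype_index,
    n_genotypes,
)

MISSING = None  # fill value for PL entries of genotypes touching non-local alleles


@dataclass
class DenseCall:
    gt: Optional[Call]
    ad: Optional[tuple[int, ...]] = None
    pl: Optional[tuple[Optional[int], ...]] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    from_block: bool = False


@dataclass
class DenseRow:
    """One locus with a resolved (or missing) record for every sample."""

    locus: GenomicLocus
    alleles: AlleleList
    calls: dict[str, Optional[DenseCall]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Field projections


def project_lad_to_ad(
    lad: Sequence[int], la: Sequence[int], n_global: int
) -> tuple[int, ...]:
    """LR-numbered depths -> R-numbered depths; unobserved alleles get 0."""
    if len(lad) != len(la):
        raise ValueError(f"LAD length {len(lad)} != LA length {len(la)}")
    ad = [0] * n_global
    for depth, g in zip(lad, la):
        ad[g] = depth
    return tuple(ad)


def project_lpl_to_pl(
    lpl: Sequence[int],
    la: Sequence[int],
    n_global: int,
    ploidy: int = 2,
    fill: Union[None, int] = MISSING,
) -> tuple[Optional[int], ...]:
    """LG-numbered likelihoods -> G-numbered; non-local genotypes get ``fill``."""
    n_local = len(la)
    if len(lpl) != n_genotypes(n_local, ploidy):
        raise ValueError(
            f"LPL length {len(lpl)} != {n_genotypes(n_local, ploidy)} local genotypes"
        )
    pl: list[Optional[int]] = [fill] * n_genotypes(n_global, ploidy)
    if ploidy == 1:
        for i, g in enumerate(la):
            pl[g] = lpl[i]
        return tuple(pl)
    for k in range(n_local):
        for j in range(k + 1):
            gj, gk = la[j], la[k]
            if gj > gk:
                gj, gk = gk, gj
            pl[genotype_index(gj, gk)] = lpl[genotype_index(j, k)]
    return tuple(pl)


def project_lgt_to_gt(lgt: Call, la: Sequence[int]) -> Call:
    """Replace local allele indices by global ones; phase is preserved."""
    for a in lgt.alleles:
        if a is not None and (a < 0 or a >= len(la)):
            raise ValueError(f"LGT index {a} outside LA of length {len(la)}")
    return Call(
        tuple(None if a is None else la[a] for a in lgt.alleles), lgt.phased
    )


def localize_fields(
    gt: Call,
    ad: Optional[Sequence[int]],
    pl: Optional[Sequence[int]],
) -> VariantGenotype:
    """Inverse of the projections: build a locally indexed genotype from
    global GT/AD/PL.  Local alleles are the called alleles plus the reference,
    in ascending global order."""
    from .core import local_allele_map

    la = local_allele_map(a for a in gt.alleles if a is not None)
    global_to_local = {g: i for i, g in enumerate(la)}
    lgt = Call(
        tuple(None if a is None else global_to_local[a] for a in gt.alleles),
        gt.phased,
    )
    lad = tuple(ad[g] for g in la) if ad is not None else None
    lpl = None
    if pl is not None:
        if gt.ploidy == 1:
            lpl = tuple(pl[g] for g in la)
        else:
            lpl = tuple(
                pl[genotype_index(min(la[j], la[k]), max(la[j], la[k]))]
                for k in range(len(la))
                for j in range(k + 1)
            )
    return VariantGenotype(la=la, lgt=lgt, lad=lad, lpl=lpl)


def _project_entry(g: VariantGenotype, n_global: int,
                   fill: Union[None, int] = MISSING) -> DenseCall:
    return DenseCall(
        gt=project_lgt_to_gt(g.lgt, g.la) if g.lgt is not None else None,
        ad=project_lad_to_ad(g.lad, g.la, n_global) if g.lad is not None else None,
        pl=project_lpl_to_pl(g.lpl, g.la, n_global, g.ploidy, fill)
        if g.lpl is not None
        else None,
        dp=g.dp,
        gq=g.gq,
    )


def _block_call(block: ReferenceBlock, ploidy: int) -> DenseCall:
    # Blocks carry only LEN/DP/GQ; AD/PL stay missing, the call is hom-ref.
    return DenseCall(
        gt=Call((0,) * ploidy),
        dp=block.dp,
        gq=block.gq,
        from_block=True,
    )


# ---------------------------------------------------------------------------
# Point query


def densify_at_locus(
    ds: SvcrDataset,
    locus: GenomicLocus,
    fill: Union[None, int] = MISSING,
    block_ploidy: int = 2,
) -> DenseRow:
    """Resolve one locus for every sample.

    Samples without a variant record are looked up in reference rows whose
    start lies within the preceding ``max_ref_block_length - 1`` bases; a
    covering block yields a hom-ref call with the block's DP/GQ, otherwise
    the sample is missing at this locus.
    """
    key = ds.locus_key(locus)  # raises on unknown contig

    site = None
    vkeys = [ds.locus_key(s.locus) for s in ds.variant_matrix]
    idx = bisect.bisect_left(vkeys, key)
    if idx < len(ds.variant_matrix) and vkeys[idx] == key:
        site = ds.variant_matrix[idx]

    alleles = site.alleles if site is not None else AlleleList("N")
    row = DenseRow(locus, alleles)

    lo_key = (key[0], max(1, locus.position - max(ds.max_ref_block_length, 1) + 1))
    rkeys = [ds.locus_key(loc) for loc, _ in ds.reference_matrix]
    start = bisect.bisect_left(rkeys, lo_key)
    stop = bisect.bisect_right(rkeys, key)

    for sample in ds.samples:
        if site is not None and sample in site.entries:
            row.calls[sample] = _project_entry(
                site.entries[sample], alleles.n_alleles, fill
            )
            continue
        found = None
        for i in range(start, stop):
            block = ds.reference_matrix[i][1].get(sample)
            if block is not None and block.covers(locus):
                found = block
                break
        row.calls[sample] = _block_call(found, block_ploidy) if found else None
    return row


# ---------------------------------------------------------------------------
# Streaming


def densify_stream(
    ds: SvcrDataset,
    region: Optional[tuple[str, int, int]] = None,
    fill: Union[None, int] = MISSING,
    block_ploidy: int = 2,
    assume_partitioned: bool = False,
) -> Iterator[DenseRow]:
    """Yield a dense row at every variant site, in locus order.

    A single forward pass over the merged stream of reference-block starts and
    variant sites; per sample at most one block is active at a time.  With a
    ``region`` (contig, start, end), rows are emitted only inside it; by
    default the scan still begins at the start of the dataset so blocks
    entering the region from before it are honored.  Set
    ``assume_partitioned=True`` to begin the scan at the region itself, valid
    when blocks never cross the region boundary (e.g. after fixed-period
    splitting with the same period).
    """
    ref_rows = ds.reference_matrix
    sites = ds.variant_matrix
    lo = hi = None
    if region is not None:
        contig, rstart, rend = region
        lo = (ds.contig_rank(contig), rstart)
        hi = (ds.contig_rank(contig), rend)

    active: dict[str, ReferenceBlock] = {}
    i = j = 0
    while i < len(ref_rows) or j < len(sites):
        take_block = j >= len(sites) or (
            i < len(ref_rows)
            and ds.locus_key(ref_rows[i][0]) <= ds.locus_key(sites[j].locus)
        )
        if take_block:
            locus, blocks = ref_rows[i]
            i += 1
            if assume_partitioned and lo is not None and ds.locus_key(locus) < lo:
                continue
            if hi is not None and ds.locus_key(locus) > hi:
                if j >= len(sites) or ds.locus_key(sites[j].locus) > hi:
                    break
            for sample, block in blocks.items():
                active[sample] = block
            continue

        site = sites[j]
        j += 1
        skey = ds.locus_key(site.locus)
        if lo is not None and (skey < lo or skey > hi):
            if skey > hi:
                break
            continue
        alleles = site.alleles
        row = DenseRow(site.locus, alleles)
        for sample in ds.samples:
            if sample in site.entries:
                row.calls[sample] = _project_entry(
                    site.entries[sample], alleles.n_alleles, fill
                )
            else:
                block = active.get(sample)
                if block is not None and block.covers(site.locus):
                    row.calls[sample] = _block_call(block, block_ploidy)
                else:
                    row.calls[sample] = None
        yield row
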