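"""Incremental N+K combining of sparse datasets.

Merging is a locus-keyed outer join: reference blocks are copied verbatim at
their start loci (they affect no other row), while variant sites sharing a
locus have their allele lists unified — the merged reference is the longest
input reference, shorter inputs' non-symbolic alleles are right-extended with
the missing reference suffix, and alternates are ordered by first appearance.
Per-sample genotypes are then *remapped*: only the LA array changes; LGT, LAD
and LPL are expressed over local indices and are invariant under the
translation.  Because every input record appears exactly once in the output,
the stored record count of a merge is the sum of its inputs' — the structural
source of linear scaling in samples.

No genotype adjustment of any kind is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core import (
    AlleleList,
    GenomicLocus,
    SvcrDataset,
    VariantGenotype,
    VariantSite,
    is_symbolic,
)

__all__ = [
    "unify_alleles",
    "remap_genotype",
    "merge",
    "MergePlan",
    "plan_hierarchical",
    "execute_plan",
    "subset_samples",
    "prune_alleles",
    "trim_alleles",
]


class MergeError(ValueError):
    pass


def unify_alleles(
    site_alleles: Sequence[AlleleList],
) -> tuple[AlleleList, list[tuple[int, ...]]]:
    """Unify the allele lists of one locus across inputs.

    Returns the merged list and, per input, a translation tuple mapping old
    global allele index -> merged global index.  All inputs must carry
    reference alleles that are prefixes of the longest one (same reference
    genome); symbolic alleles are matched by exact string and never extended.
    """
    merged_ref = max((al.ref for al in site_alleles), key=len)
    for al in site_alleles:
        if not merged_ref.startswith(al.ref):
            raise MergeError(
                f"inputs disagree on the reference sequence: {al.ref!r} is not "
                f"a prefix of {merged_ref!r}"
            )

    merged_alts: list[str] = []
    index_of: dict[str, int] = {}
    translations: list[tuple[int, ...]] = []
    for al in site_alleles:
        suffix = merged_ref[len(al.ref):]
        tr = [0]
        for alt in al.alts:
            extended = alt if is_symbolic(alt) else alt + suffix
            if extended not in index_of:
                index_of[extended] = len(merged_alts) + 1
                merged_alts.append(extended)
            tr.append(index_of[extended])
        translations.append(tuple(tr))
    return AlleleList(merged_ref, tuple(merged_alts)), translations


def remap_genotype(g: VariantGenotype, translation: Sequence[int]) -> VariantGenotype:
    """Rewrite LA through an allele translation; all local fields unchanged."""
    for x in g.la:
        if x < 0 or x >= len(translation):
            raise MergeError(f"LA element {x} outside translation domain")
    return VariantGenotype(
        la=tuple(translation[x] for x in g.la),
        lgt=g.lgt,
        lad=g.lad,
        lpl=g.lpl,
        dp=g.dp,
        gq=g.gq,
        gvcf_info=g.gvcf_info,
        extra=g.extra,
    )


def _merge_contigs(inputs: Sequence[SvcrDataset]) -> list[str]:
    # Ordered union; relative order of shared contigs must agree.
    merged: list[str] = []
    for ds in inputs:
        pos = -1
        for c in ds.contigs:
            if c in merged:
                at = merged.index(c)
                if at < pos:
                    raise MergeError("inputs disagree on contig order")
                pos = at
            else:
                pos += 1
                merged.insert(pos, c)
    return merged


def merge(inputs: Sequence[SvcrDataset]) -> SvcrDataset:
    """Losslessly merge datasets with pairwise-disjoint sample sets."""
    if not inputs:
        raise MergeError("merge requires at least one input")
    samples: list[str] = []
    for ds in inputs:
        for s in ds.samples:
            if s in samples:
                raise MergeError(f"duplicate sample id {s!r}")
            samples.append(s)

    out = SvcrDataset(samples, _merge_contigs(inputs))
    out.max_ref_block_length = max(ds.max_ref_block_length for ds in inputs)

    # Reference matrix: outer join on locus, blocks preserved verbatim.
    ref_join: dict[tuple[int, int], tuple[GenomicLocus, dict]] = {}
    for ds in inputs:
        for locus, row in ds.reference_matrix:
            key = out.locus_key(locus)
            if key not in ref_join:
                ref_join[key] = (locus, {})
            ref_join[key][1].update(row)
    out.reference_matrix = [ref_join[k] for k in sorted(ref_join)]

    # Variant matrix: outer join with allele unification per shared locus.
    var_join: dict[tuple[int, int], list[VariantSite]] = {}
    for ds in inputs:
        for site in ds.variant_matrix:
            var_join.setdefault(out.locus_key(site.locus), []).append(site)
    for key in sorted(var_join):
        group = var_join[key]
        if len(group) == 1:
            # Single contributor: identity translation, entries copied.
            src = group[0]
            out.variant_matrix.append(
                VariantSite(src.locus, src.alleles, dict(src.entries))
            )
            continue
        merged_alleles, translations = unify_alleles([s.alleles for s in group])
        entries: dict[str, VariantGenotype] = {}
        for src, tr in zip(group, translations):
            identity = tr == tuple(range(len(tr)))
            for sample, g in src.entries.items():
                entries[sample] = g if identity else remap_genotype(g, tr)
        out.variant_matrix.append(VariantSite(group[0].locus, merged_alleles, entries))
    return out


# ---------------------------------------------------------------------------
# Hierarchical combining


@dataclass
class MergePlan:
    """A bottom-up tree of merge tasks.

    ``leaf`` holds an input index; internal nodes hold <= fanout children.
    Executing the tree yields the same dataset as one flat merge because
    merging is associative up to allele order (comparisons are made on
    densified matrices).
    """

    leaf: Optional[int] = None
    children: tuple["MergePlan", ...] = ()

    def n_merge_tasks(self) -> int:
        if self.leaf is not None:
            return 0
        return 1 + sum(c.n_merge_tasks() for c in self.children)

    def tasks_per_level(self) -> list[int]:
        """Merge-task counts from the leaf-most level upward."""
        if self.leaf is not None:
            return []
        below = [c.tasks_per_level() for c in self.children]
        depth = max((len(b) for b in below), default=0)
        levels = [sum(b[i] for b in below if len(b) > i) for i in range(depth)]
        levels.append(1)
        return levels


def plan_hierarchical(n_inputs: int, fanout: int) -> MergePlan:
    """Balanced bottom-up plan: repeatedly group consecutive runs of ``fanout``."""
    if n_inputs < 1:
        raise ValueError("need at least one input")
    if fanout < 2:
        raise ValueError("fanout must be >= 2")
    level: list[MergePlan] = [MergePlan(leaf=i) for i in range(n_inputs)]
    while len(level) > 1:
        level = [
            MergePlan(children=tuple(level[i : i + fanout]))
            for i in range(0, len(level), fanout)
        ]
    node = level[0]
    if node.leaf is not None:  # single input: zero merges
        return node
    return node


def execute_plan(plan: MergePlan, inputs: Sequence[SvcrDataset]) -> SvcrDataset:
    """Run the merge tree; tasks share no mutable state and could run in any
    dependency-respecting order."""
    if plan.leaf is not None:
        return inputs[plan.leaf]
    return merge([execute_plan(c, inputs) for c in plan.children])


# ---------------------------------------------------------------------------
# Subsetting and allele maintenance


def subset_samples(ds: SvcrDataset, keep: Sequence[str]) -> SvcrDataset:
    """Restrict to ``keep`` (in the given order); global alleles are NOT
    pruned — use :func:`prune_alleles` afterwards."""
    keep_set = set(keep)
    missing = keep_set - set(ds.samples)
    if missing:
        raise KeyError(f"unknown samples: {sorted(missing)}")
    out = SvcrDataset(list(keep), list(ds.contigs),
                      max_ref_block_length=ds.max_ref_block_length)
    for locus, row in ds.reference_matrix:
        sub = {s: b for s, b in row.items() if s in keep_set}
        if sub:
            out.reference_matrix.append((locus, sub))
    for site in ds.variant_matrix:
        sub_e = {s: g for s, g in site.entries.items() if s in keep_set}
        if sub_e:
            out.variant_matrix.append(VariantSite(site.locus, site.alleles, sub_e))
    return out


def prune_alleles(ds: SvcrDataset) -> SvcrDataset:
    """Drop global alleles observed in no genotype's LA, updating LA maps only.

    This is the operation local indexing makes cheap: LGT/LAD/LPL never
    change, only the per-genotype translation arrays do.
    """
    out = SvcrDataset(list(ds.samples), list(ds.contigs),
                      reference_matrix=ds.reference_matrix,
                      max_ref_block_length=ds.max_ref_block_length)
    for site in ds.variant_matrix:
        observed = {0}
        for g in site.entries.values():
            observed.update(g.la)
        keep = [i for i in range(site.alleles.n_alleles) if i in observed]
        if len(keep) == site.alleles.n_alleles:
            out.variant_matrix.append(site)
            continue
        old_to_new = {old: new for new, old in enumerate(keep)}
        alleles = AlleleList(
            site.alleles.ref,
            tuple(site.alleles.alleles[i] for i in keep[1:]),
        )
        translation = tuple(
            old_to_new.get(i, -1) for i in range(site.alleles.n_alleles)
        )
        entries = {
            s: remap_genotype(g, translation) for s, g in site.entries.items()
        }
        out.variant_matrix.append(VariantSite(site.locus, alleles, entries))
    return out


def trim_alleles(ds: SvcrDataset) -> SvcrDataset:
    """Reverse merge right-extension by trimming shared trailing bases.

    At each site, while every non-symbolic allele (including the reference)
    has length >= 2 and all share their final base, that base is removed.
    Pure indel records always retain a length-1 allele and are therefore
    never trimmed past their original form.
    """
    out = SvcrDataset(list(ds.samples), list(ds.contigs),
                      reference_matrix=ds.reference_matrix,
                      max_ref_block_length=ds.max_ref_block_length)
    for site in ds.variant_matrix:
        concrete = [a for a in site.alleles.alleles if not is_symbolic(a)]
        trim = 0
        while all(len(a) - trim >= 2 for a in concrete) and len(
            {a[len(a) - 1 - trim] for a in concrete}
        ) == 1:
            trim += 1
        if trim == 0:
            out.variant_matrix.append(site)
            continue
        new = tuple(
            a if is_symbolic(a) else a[: len(a) - trim]
            for a in site.alleles.alleles
        )
        out.variant_matrix.append(
            VariantSite(site.locus, AlleleList(new[0], new[1:]), site.entries)
        )
    return out
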