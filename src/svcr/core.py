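"""Core data model for sparse variant-call datasets.

A dataset holds two locus-sorted matrices over a shared sample list: a
reference matrix of run-length encoded homozygous-reference blocks and a
variant matrix of multiallelic sites whose per-sample genotypes are expressed
over *local* allele indices.  Local indexing stores, per genotype, only the
alleles that sample actually observed; the ``LA`` array maps local indices
back to the site's global allele list (reference always global index 0, and
the first element of LA is always 0).

Coordinates are 1-based and intervals are closed, matching VCF POS/END
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "GenomicLocus",
    "Call",
    "AlleleList",
    "ReferenceBlock",
    "VariantGenotype",
    "VariantSite",
    "SvcrDataset",
    "Violation",
    "n_genotypes",
    "genotype_index",
    "expected_length",
    "local_allele_map",
    "validate_dataset",
    "is_symbolic",
]


class GenomicLocus(NamedTuple):
    """A 1-based genomic coordinate."""

    contig: str
    position: int


def is_symbolic(allele: str) -> bool:
    """True for symbolic allele tokens (``<NON_REF>``, ``<DEL>``, ``*``)."""
    return allele.startswith("<") or allele == "*"


@dataclass(frozen=True)
class Call:
    """A genotype call: allele indices plus a phased flag.

    Indices are local when the call sits in a :class:`VariantGenotype`
    (``LGT``) and global after projection (``GT``).  ``None`` encodes a
    missing allele ("."). The phase separator is preserved verbatim through
    every conversion: ``0|1`` stays ``0|1``.
    """

    alleles: tuple[Optional[int], ...]
    phased: bool = False

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)

    @classmethod
    def parse(cls, text: str) -> "Call":
        phased = "|" in text
        parts = text.replace("|", "/").split("/")
        alleles = tuple(None if p in (".", "") else int(p) for p in parts)
        return cls(alleles, phased)

    def is_hom_ref(self) -> bool:
        return all(a == 0 for a in self.alleles)

    def remap(self, mapping: Sequence[int]) -> "Call":
        return Call(
            tuple(None if a is None else mapping[a] for a in self.alleles),
            self.phased,
        )


@dataclass(frozen=True)
class AlleleList:
    """Global alleles at a site: reference first, then ordered alternates."""

    ref: str
    alts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("reference allele must be nonempty")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)


@dataclass
class ReferenceBlock:
    """A per-sample run of homozygous-reference calls.

    Covers the closed interval [start.position, start.position + length - 1]
    on one contig.  ``ref`` is the reference sequence at the start locus (a
    single base for END-tagged caller output).  ``alts`` preserves symbolic
    alternates such as ``<NON_REF>`` when the NON_REF retention policy asks
    for losslessness; ``extra`` holds verbatim FORMAT strings beyond
    GT/DP/GQ, and ``gvcf_info`` the originating INFO payload minus END.
    """

    start: GenomicLocus
    length: int
    dp: Optional[int] = None
    gq: Optional[int] = None
    lgt: Optional[Call] = None
    ref: str = "N"
    alts: tuple[str, ...] = ()
    extra: dict[str, str] = field(default_factory=dict)
    gvcf_info: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def end(self) -> int:
        """Inclusive end position."""
        return self.start.position + self.length - 1

    def covers(self, locus: GenomicLocus) -> bool:
        return (
            locus.contig == self.start.contig
            and self.start.position <= locus.position <= self.end
        )


@dataclass
class VariantGenotype:
    """A locally indexed genotype record.

    ``la`` maps local allele indices to global ones (injective, first element
    0).  ``lad`` is LR-numbered (one depth per local allele including the
    reference); ``lpl`` is LG-numbered (one Phred-scaled likelihood per
    genotype over the local alleles).
    """

    la: tuple[int, ...]
    lgt: Optional[Call] = None
    lad: Optional[tuple[int, ...]] = None
    lpl: Optional[tuple[int, ...]] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    gvcf_info: dict[str, Optional[str]] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def ploidy(self) -> int:
        return self.lgt.ploidy if self.lgt is not None else 2


@dataclass
class VariantSite:
    """A locus, its global allele list, and one optional genotype per sample."""

    locus: GenomicLocus
    alleles: AlleleList
    entries: dict[str, VariantGenotype] = field(default_factory=dict)


@dataclass
class SvcrDataset:
    """A split pair of locus-sorted matrices over a shared sample list.

    ``reference_matrix`` rows are (locus, {sample: block-starting-here});
    ``variant_matrix`` rows are :class:`VariantSite`.  Both are sorted by
    (contig rank, position) with unique loci per matrix.
    ``max_ref_block_length`` is a dataset-level upper bound on block span; it
    bounds the backward search window of point-query densification.
    """

    samples: list[str]
    contigs: list[str]
    reference_matrix: list[tuple[GenomicLocus, dict[str, ReferenceBlock]]] = field(
        default_factory=list
    )
    variant_matrix: list[VariantSite] = field(default_factory=list)
    max_ref_block_length: int = 0

    # -- ordering helpers ---------------------------------------------------

    def contig_rank(self, contig: str) -> int:
        try:
            return self.contigs.index(contig)
        except ValueError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def locus_key(self, locus: GenomicLocus) -> tuple[int, int]:
        return (self.contig_rank(locus.contig), locus.position)

    def n_variant_genotypes(self) -> int:
        return sum(len(s.entries) for s in self.variant_matrix)

    def n_reference_blocks(self) -> int:
        return sum(len(row) for _, row in self.reference_matrix)


# ---------------------------------------------------------------------------
# Index arithmetic


def n_genotypes(n_alleles: int, ploidy: int) -> int:
    """Number of distinct unphased genotypes over ``n_alleles`` alleles.

    Diploid: n(n+1)/2; haploid: n.  Matches the VCF G-number convention.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if ploidy == 2:
        return n_alleles * (n_alleles + 1) // 2
    if ploidy == 1:
        return n_alleles
    raise ValueError(f"unsupported ploidy {ploidy} (only 1 and 2)")


def genotype_index(allele_j: int, allele_k: int) -> int:
    """Position of unordered diploid genotype j/k (j <= k) in VCF PL ordering.

    The VCF specification orders genotypes by increasing k then j, giving
    index k(k+1)/2 + j.
    """
    if allele_j < 0 or allele_k < 0:
        raise ValueError("allele indices must be nonnegative")
    if allele_j > allele_k:
        raise ValueError(
            f"genotype_index requires j <= k, got ({allele_j}, {allele_k}); "
            "canonicalize the pair first"
        )
    return allele_k * (allele_k + 1) // 2 + allele_j


_NUMBER_CODES = {"LA", "LR", "LG", "A", "R", "G", "1"}


def expected_length(
    number_code: str, n_local: int, n_global: int, ploidy: int
) -> int:
    """Expected list length for a FORMAT field with the given Number code.

    Local codes (LA/LR/LG) count over the local allele set; global codes
    (A/R/G) over the site's full allele list.
    """
    if n_local < 1 or n_global < 1:
        raise ValueError("allele counts must be >= 1")
    if number_code == "LA":
        return n_local - 1
    if number_code == "LR":
        return n_local
    if number_code == "LG":
        return n_genotypes(n_local, ploidy)
    if number_code == "A":
        return n_global - 1
    if number_code == "R":
        return n_global
    if number_code == "G":
        return n_genotypes(n_global, ploidy)
    if number_code == "1":
        return 1
    raise ValueError(f"unknown Number code {number_code!r}")


def local_allele_map(called_global_indices: Iterable[int]) -> tuple[int, ...]:
    """Build an LA array for a genotype observing the given global alleles.

    The reference (0) is always first; observed nonreference alleles follow
    in ascending global order.
    """
    observed = sorted({g for g in called_global_indices if g != 0})
    if any(g < 0 for g in observed):
        raise ValueError("global allele indices must be nonnegative")
    return (0, *observed)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    """One broken invariant, as data.  ``rule`` is a stable identifier."""

    rule: str
    message: str
    locus: Optional[GenomicLocus] = None
    sample: Optional[str] = None


def _check_sorted_unique(
    ds: SvcrDataset, loci: Sequence[GenomicLocus], matrix: str, out: list[Violation]
) -> None:
    prev = None
    for locus in loci:
        if locus.contig not in ds.contigs:
            out.append(
                Violation("unknown-contig", f"{matrix}: contig not declared", locus)
            )
            continue
        key = ds.locus_key(locus)
        if prev is not None:
            if key == prev:
                out.append(
                    Violation("duplicate-locus", f"{matrix}: repeated locus", locus)
                )
            elif key < prev:
                out.append(
                    Violation("unsorted", f"{matrix}: rows out of order", locus)
                )
        prev = key


def validate_dataset(ds: SvcrDataset) -> list[Violation]:
    """Check every structural invariant; returns one record per breach."""
    out: list[Violation] = []

    if len(set(ds.samples)) != len(ds.samples):
        out.append(Violation("duplicate-sample", "sample ids not unique"))
    if len(set(ds.contigs)) != len(ds.contigs):
        out.append(Violation("duplicate-contig", "contig names not unique"))
    known = set(ds.samples)

    _check_sorted_unique(ds, [loc for loc, _ in ds.reference_matrix], "reference", out)
    _check_sorted_unique(ds, [s.locus for s in ds.variant_matrix], "variant", out)

    # Reference blocks: row consistency, length bound, per-sample disjointness.
    per_sample_blocks: dict[str, list[ReferenceBlock]] = {}
    for locus, row in ds.reference_matrix:
        for sample, block in row.items():
            if sample not in known:
                out.append(Violation("unknown-sample", "block for undeclared sample",
                                     locus, sample))
            if block.start != locus:
                out.append(Violation("block-start-mismatch",
                                     f"block start {block.start} != row locus",
                                     locus, sample))
            if block.length < 1:
                out.append(Violation("block-length", "block length < 1", locus, sample))
            elif block.length > ds.max_ref_block_length:
                out.append(Violation(
                    "max-ref-block-length",
                    f"block length {block.length} exceeds declared maximum "
                    f"{ds.max_ref_block_length}", locus, sample))
            per_sample_blocks.setdefault(sample, []).append(block)

    for sample, blocks in per_sample_blocks.items():
        by_contig: dict[str, list[ReferenceBlock]] = {}
        for b in blocks:
            by_contig.setdefault(b.start.contig, []).append(b)
        for contig, group in by_contig.items():
            group.sort(key=lambda b: b.start.position)
            for a, b in zip(group, group[1:]):
                if b.start.position <= a.end:
                    out.append(Violation(
                        "block-overlap",
                        f"blocks {a.start.position}-{a.end} and "
                        f"{b.start.position}-{b.end} overlap on {contig}",
                        b.start, sample))

    # Variant genotypes: LA shape, field lengths, LGT range.
    for site in ds.variant_matrix:
        n_global = site.alleles.n_alleles
        for sample, g in site.entries.items():
            if sample not in known:
                out.append(Violation("unknown-sample", "genotype for undeclared sample",
                                     site.locus, sample))
            la = g.la
            if not la or la[0] != 0:
                out.append(Violation("la-first-zero",
                                     f"LA {list(la)} does not start with 0",
                                     site.locus, sample))
            if len(set(la)) != len(la):
                out.append(Violation("la-injective", f"LA {list(la)} has duplicates",
                                     site.locus, sample))
            if any(x < 0 or x >= n_global for x in la):
                out.append(Violation("la-range",
                                     f"LA {list(la)} outside {n_global} global alleles",
                                     site.locus, sample))
            n_local = len(la)
            if g.lad is not None and len(g.lad) != expected_length(
                "LR", n_local, n_global, g.ploidy
            ):
                out.append(Violation("lad-length",
                                     f"LAD length {len(g.lad)} != {n_local}",
                                     site.locus, sample))
            if g.lpl is not None:
                want = expected_length("LG", n_local, n_global, g.ploidy)
                if len(g.lpl) != want:
                    out.append(Violation("lpl-length",
                                         f"LPL length {len(g.lpl)} != {want}",
                                         site.locus, sample))
            if g.lgt is not None and any(
                a is not None and (a < 0 or a >= n_local) for a in g.lgt.alleles
            ):
                out.append(Violation("lgt-range",
                                     f"LGT {g.lgt} indexes outside LA",
                                     site.locus, sample))
    return out
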