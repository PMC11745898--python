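"""Lossless conversion between single-sample GVCFs and sparse datasets.

A GVCF is a single-sample VCF in which runs of homozygous-reference calls are
stored as interval records carrying an END INFO key.  Such a file is already a
single-sample instance of the sparse representation: conversion amounts to
(i) adding an identity LA, (ii) renaming allele-indexed fields with an "L"
prefix, and (iii) replacing END with a LEN span.  Both directions are
implemented here, along with line-level VCF text reading/writing that keeps
field values verbatim (the losslessness contract is defined at the level of
POS/END, alleles, FORMAT values and INFO values).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

from .core import (
    AlleleList,
    Call,
    GenomicLocus,
    ReferenceBlock,
    SvcrDataset,
    VariantGenotype,
    VariantSite,
    genotype_index,
    is_symbolic,
    n_genotypes,
    validate_dataset,
)

NON_REF = "<NON_REF>"

# Reserved gvcf_info keys carrying site columns through the per-sample payload.
RESERVED_ID = "_ID"
RESERVED_QUAL = "_QUAL"
RESERVED_FILTER = "_FILTER"
_RESERVED = (RESERVED_ID, RESERVED_QUAL, RESERVED_FILTER)


class GvcfImportError(ValueError):
    """Raised for malformed or unsorted GVCF input, naming the locus."""


@dataclass
class GvcfRecord:
    """One GVCF data line, values kept as verbatim strings where possible."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...] = ()
    vid: str = "."
    qual: str = "."
    filt: str = "."
    info: dict[str, Optional[str]] = field(default_factory=dict)
    fmt: dict[str, str] = field(default_factory=dict)

    @property
    def locus(self) -> GenomicLocus:
        return GenomicLocus(self.contig, self.pos)

    @property
    def end(self) -> Optional[int]:
        raw = self.info.get("END")
        return int(raw) if raw is not None else None

    # typed FORMAT accessors ------------------------------------------------

    @property
    def gt(self) -> Optional[Call]:
        raw = self.fmt.get("GT")
        return Call.parse(raw) if raw is not None else None

    def _int_list(self, key: str) -> Optional[tuple[int, ...]]:
        raw = self.fmt.get(key)
        if raw is None:
            return None
        return tuple(int(x) for x in raw.split(","))

    @property
    def ad(self) -> Optional[tuple[int, ...]]:
        return self._int_list("AD")

    @property
    def pl(self) -> Optional[tuple[int, ...]]:
        return self._int_list("PL")

    @property
    def dp(self) -> Optional[int]:
        raw = self.fmt.get("DP")
        return int(raw) if raw is not None else None

    @property
    def gq(self) -> Optional[int]:
        raw = self.fmt.get("GQ")
        return int(raw) if raw is not None else None

    def is_reference_row(self) -> bool:
        """True when this row encodes only homozygous-reference calls."""
        if any(not is_symbolic(a) for a in self.alts):
            return False
        gt = self.gt
        return gt is None or gt.is_hom_ref()


# ---------------------------------------------------------------------------
# VCF text layer


def _parse_info(text: str) -> dict[str, Optional[str]]:
    if text == "." or text == "":
        return {}
    out: dict[str, Optional[str]] = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        elif item:
            out[item] = None
    return out


def format_info(info: dict[str, Optional[str]]) -> str:
    if not info:
        return "."
    return ";".join(k if v is None else f"{k}={v}" for k, v in info.items())


def parse_record_line(line: str) -> GvcfRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 8:
        raise GvcfImportError(f"short VCF line: {line!r}")
    chrom, pos, vid, ref, alt, qual, filt, info = parts[:8]
    alts = () if alt == "." else tuple(alt.split(","))
    fmt: dict[str, str] = {}
    if len(parts) >= 10:
        keys = parts[8].split(":")
        values = parts[9].split(":")
        for k, v in zip(keys, values):
            if v != "." and v != "":
                fmt[k] = v
    return GvcfRecord(chrom, int(pos), ref, alts, vid, qual, filt,
                      _parse_info(info), fmt)


_FMT_ORDER = ("GT", "AD", "DP", "GQ", "PL")


def format_record_line(rec: GvcfRecord) -> str:
    alt = ",".join(rec.alts) if rec.alts else "."
    keys = [k for k in _FMT_ORDER if k in rec.fmt]
    keys += [k for k in rec.fmt if k not in _FMT_ORDER]
    fmt_col = ":".join(keys) if keys else "."
    sample_col = ":".join(rec.fmt[k] for k in keys) if keys else "."
    return "\t".join(
        [rec.contig, str(rec.pos), rec.vid, rec.ref, alt, rec.qual, rec.filt,
         format_info(rec.info), fmt_col, sample_col]
    )


def _open_text(path: str, mode: str) -> TextIO:
    if str(path).endswith(".gz"):
        import pysam

        return io.TextIOWrapper(pysam.BGZFile(str(path), mode.rstrip("t") + "b"))
    return open(path, mode)


def read_gvcf(path: str) -> tuple[str, list[str], list[GvcfRecord]]:
    """Read a (possibly bgzipped) GVCF; returns (sample, contigs, records).

    Contig order is taken from header contig lines when present, otherwise
    from first appearance in the records.
    """
    contigs: list[str] = []
    sample = "SAMPLE"
    records: list[GvcfRecord] = []
    with _open_text(path, "rt") as fh:
        for line in fh:
            if line.startswith("##"):
                if line.startswith("##contig=") and "ID=" in line:
                    ident = line.split("ID=", 1)[1]
                    contigs.append(ident.split(",")[0].split(">")[0].strip())
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) >= 10:
                    sample = cols[9]
                continue
            if line.strip():
                records.append(parse_record_line(line))
    if not contigs:
        seen = dict.fromkeys(r.contig for r in records)
        contigs = list(seen)
    return sample, contigs, records


def gvcf_header(sample: str, contigs: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.3"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of reference block">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    return "\n".join(lines) + "\n"


def write_gvcf(
    records: Iterable[GvcfRecord],
    sample: str,
    contigs: Sequence[str],
    sink: Union[str, TextIO],
) -> None:
    own = isinstance(sink, (str, bytes))
    fh = _open_text(sink, "wt") if own else sink
    try:
        fh.write(gvcf_header(sample, contigs))
        for rec in records:
            fh.write(format_record_line(rec) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Import


def _drop_allele(
    alleles: tuple[str, ...],
    drop_global: int,
    gt: Optional[Call],
    ad: Optional[tuple[int, ...]],
    pl: Optional[tuple[int, ...]],
    locus: GenomicLocus,
):
    """Remove one global allele, reindexing GT and the R-/G-numbered arrays."""
    n_old = len(alleles)
    keep = [i for i in range(n_old) if i != drop_global]
    old_to_new = {old: new for new, old in enumerate(keep)}
    if gt is not None:
        for a in gt.alleles:
            if a == drop_global:
                raise GvcfImportError(
                    f"{locus.contig}:{locus.position}: genotype calls the "
                    "allele being dropped"
                )
        gt = Call(
            tuple(None if a is None else old_to_new[a] for a in gt.alleles),
            gt.phased,
        )
    if ad is not None:
        ad = tuple(ad[i] for i in keep)
    if pl is not None:
        new_pl = [0] * n_genotypes(len(keep), 2)
        for nk, ok in enumerate(keep):
            for nj, oj in enumerate(keep[: nk + 1]):
                new_pl[genotype_index(nj, nk)] = pl[genotype_index(oj, ok)]
        pl = tuple(new_pl)
    new_alleles = tuple(alleles[i] for i in keep)
    return new_alleles, gt, ad, pl


def import_gvcf(
    records: Sequence[GvcfRecord],
    sample_id: str,
    non_ref_policy: str = "drop",
    contigs: Optional[Sequence[str]] = None,
) -> SvcrDataset:
    """Convert a sorted single-sample GVCF record stream to a sparse dataset.

    Reference rows become blocks with length END - POS + 1 (or the reference
    allele length when END is absent); variant rows become sites with one
    genotype whose LA is the identity.  Under ``non_ref_policy="drop"`` the
    sample-local <NON_REF> allele is removed with AD/PL/GT reindexed; under
    ``"retain"`` everything is kept for exact round trips.
    """
    if non_ref_policy not in ("drop", "retain"):
        raise ValueError(f"unknown non_ref_policy {non_ref_policy!r}")
    if contigs is None:
        contigs = list(dict.fromkeys(r.contig for r in records))
    ds = SvcrDataset([sample_id], list(contigs))

    prev_key = None
    max_len = 0
    for rec in records:
        locus = rec.locus
        where = f"{locus.contig}:{locus.position}"
        key = ds.locus_key(locus)
        if prev_key is not None and key < prev_key:
            raise GvcfImportError(f"{where}: records not sorted by locus")
        prev_key = key

        gvcf_info = {k: v for k, v in rec.info.items() if k != "END"}
        if rec.vid != ".":
            gvcf_info[RESERVED_ID] = rec.vid
        if rec.qual != ".":
            gvcf_info[RESERVED_QUAL] = rec.qual
        if rec.filt != ".":
            gvcf_info[RESERVED_FILTER] = rec.filt

        if rec.is_reference_row():
            end = rec.end
            if end is None:
                end = rec.pos + len(rec.ref) - 1
            if end < rec.pos:
                raise GvcfImportError(f"{where}: END {end} < POS")
            extra = {
                k: v
                for k, v in rec.fmt.items()
                if k not in ("GT", "DP", "GQ")
            }
            alts = rec.alts
            if non_ref_policy == "drop":
                extra.pop("AD", None)
                extra.pop("PL", None)
                alts = tuple(a for a in alts if a != NON_REF)
            block = ReferenceBlock(
                start=locus,
                length=end - rec.pos + 1,
                dp=rec.dp,
                gq=rec.gq,
                lgt=rec.gt,
                ref=rec.ref,
                alts=alts,
                extra=extra,
                gvcf_info=gvcf_info,
            )
            max_len = max(max_len, block.length)
            ds.reference_matrix.append((locus, {sample_id: block}))
            continue

        alleles = (rec.ref,) + rec.alts
        gt, ad, pl = rec.gt, rec.ad, rec.pl
        ploidy = gt.ploidy if gt is not None else 2
        if ad is not None and len(ad) != len(alleles):
            raise GvcfImportError(
                f"{where}: AD length {len(ad)} != {len(alleles)} alleles"
            )
        if pl is not None and len(pl) != n_genotypes(len(alleles), ploidy):
            raise GvcfImportError(
                f"{where}: PL length {len(pl)} != "
                f"{n_genotypes(len(alleles), ploidy)} genotypes"
            )
        if non_ref_policy == "drop" and NON_REF in alleles:
            alleles, gt, ad, pl = _drop_allele(
                alleles, alleles.index(NON_REF), gt, ad, pl, locus
            )
        genotype = VariantGenotype(
            la=tuple(range(len(alleles))),
            lgt=gt,
            lad=ad,
            lpl=pl,
            dp=rec.dp,
            gq=rec.gq,
            gvcf_info=gvcf_info,
            extra={
                k: v
                for k, v in rec.fmt.items()
                if k not in ("GT", "AD", "PL", "DP", "GQ")
            },
        )
        site = VariantSite(
            locus,
            AlleleList(alleles[0], tuple(alleles[1:])),
            {sample_id: genotype},
        )
        ds.variant_matrix.append(site)

    ds.max_ref_block_length = max_len
    return ds


# ---------------------------------------------------------------------------
# Export


def _site_columns(gvcf_info: dict[str, Optional[str]]):
    info = {k: v for k, v in gvcf_info.items() if k not in _RESERVED}
    vid = gvcf_info.get(RESERVED_ID) or "."
    qual = gvcf_info.get(RESERVED_QUAL) or "."
    filt = gvcf_info.get(RESERVED_FILTER) or "."
    return info, vid, qual, filt


def export_gvcf(ds: SvcrDataset, non_ref_policy: str = "retain") -> list[GvcfRecord]:
    """Reconstruct the GVCF record stream of a single-sample dataset.

    Inverse of :func:`import_gvcf`: blocks become END-tagged reference rows
    and genotypes become variant rows with the identity LA dropped.  A
    genotype whose LA is not the identity cannot be exported losslessly
    (the dataset must be allele-pruned first) and is rejected.
    """
    if len(ds.samples) != 1:
        raise ValueError("export_gvcf requires a single-sample dataset")
    problems = validate_dataset(ds)
    if problems:
        raise ValueError(f"invalid dataset: {problems[0].rule}: {problems[0].message}")
    del non_ref_policy  # both policies export the alleles as stored
    sample = ds.samples[0]

    out: list[GvcfRecord] = []
    ref_rows = [(loc, row[sample]) for loc, row in ds.reference_matrix if sample in row]
    sites = [s for s in ds.variant_matrix if sample in s.entries]
    i = j = 0
    while i < len(ref_rows) or j < len(sites):
        take_block = j >= len(sites) or (
            i < len(ref_rows)
            and ds.locus_key(ref_rows[i][0]) <= ds.locus_key(sites[j].locus)
        )
        if take_block:
            locus, block = ref_rows[i]
            i += 1
            info, vid, qual, filt = _site_columns(block.gvcf_info)
            info = dict(info)
            info["END"] = str(block.end)
            fmt: dict[str, str] = {}
            if block.lgt is not None:
                fmt["GT"] = str(block.lgt)
            if block.dp is not None:
                fmt["DP"] = str(block.dp)
            if block.gq is not None:
                fmt["GQ"] = str(block.gq)
            fmt.update(block.extra)
            out.append(
                GvcfRecord(locus.contig, locus.position, block.ref, block.alts,
                           vid, qual, filt, info, fmt)
            )
        else:
            site = sites[j]
            j += 1
            g = site.entries[sample]
            # The genotype's local order is the original file's allele order:
            # emit alleles through LA.  The LA image must cover the whole site
            # allele list (true after prune_alleles), otherwise dropping the
            # unobserved alleles would be lossy.
            if sorted(g.la) != list(range(site.alleles.n_alleles)):
                raise ValueError(
                    f"{site.locus.contig}:{site.locus.position}: LA does not "
                    "cover the site's alleles; prune alleles before GVCF export"
                )
            ordered = [site.alleles.alleles[gidx] for gidx in g.la]
            info, vid, qual, filt = _site_columns(g.gvcf_info)
            fmt = {}
            if g.lgt is not None:
                fmt["GT"] = str(g.lgt)
            if g.lad is not None:
                fmt["AD"] = ",".join(str(x) for x in g.lad)
            if g.dp is not None:
                fmt["DP"] = str(g.dp)
            if g.gq is not None:
                fmt["GQ"] = str(g.gq)
            if g.lpl is not None:
                fmt["PL"] = ",".join(str(x) for x in g.lpl)
            fmt.update(g.extra)
            out.append(
                GvcfRecord(site.locus.contig, site.locus.position,
                           ordered[0], tuple(ordered[1:]),
                           vid, qual, filt, info, fmt)
            )
    return out
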