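"""Serialization of sparse datasets as SVCR-VCF, plus dense PVCF exports.

SVCR-VCF is ordinary VCF 4.3 text with two extra FORMAT keys: LA (the local
allele map) and LEN (reference-block span).  A reference block is stored at
its start locus with a nonmissing LEN and missing LA/LAD/LPL; a nonreference
genotype has a nonmissing LA and missing LEN.  Rows that exist only because a
block starts there carry ALT=".".  The header declares the longest block span
as ``##MAXIMUM_REFERENCE_BLOCK_LENGTH=<int>``, which bounds the backward
search of point queries.

Local fields are declared with Number="." because VCF 4.3 has no LA/LR/LG
Number codes; the length rules are enforced semantically on read.  Per-sample
INFO payloads (``gvcf_info``) and any non-modeled FORMAT fields ride in a
GINFO FORMAT string (percent-encoded key=value pairs) so that reading back a
written file reproduces the dataset exactly.

Writing the same dataset twice yields identical bytes (fixed key order,
integer formatting).
"""

from __future__ import annotations

import gzip
import urllib.parse
from typing import Optional, TextIO, Union

from .core import (
    AlleleList,
    Call,
    GenomicLocus,
    ReferenceBlock,
    SvcrDataset,
    VariantGenotype,
    VariantSite,
    validate_dataset,
)
from .densify import densify_stream
from .gvcf import _open_text

__all__ = [
    "write_svcr_vcf",
    "read_svcr_vcf",
    "export_hardcalls_pvcf",
    "export_dense_pvcf",
    "SvcrVcfError",
]

MAX_BLOCK_KEY = "MAXIMUM_REFERENCE_BLOCK_LENGTH"


class SvcrVcfError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GINFO payload codec


def _quote(text: str) -> str:
    return urllib.parse.quote(text, safe="")


def encode_payload(payload: dict[str, Optional[str]]) -> str:
    if not payload:
        return "."
    return "|".join(
        _quote(k) if v is None else f"{_quote(k)}={_quote(v)}"
        for k, v in payload.items()
    )


def decode_payload(text: str) -> dict[str, Optional[str]]:
    if text == ".":
        return {}
    out: dict[str, Optional[str]] = {}
    for item in text.split("|"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
        else:
            out[urllib.parse.unquote(item)] = None
    return out


def _block_payload(block: ReferenceBlock, row_ref: str) -> dict[str, Optional[str]]:
    payload: dict[str, Optional[str]] = {}
    if block.ref != row_ref:
        payload["_REF"] = block.ref
    if block.alts:
        payload["_ALT"] = ",".join(block.alts)
    for k, v in block.extra.items():
        payload[f"F.{k}"] = v
    payload.update(block.gvcf_info)
    return payload


def _genotype_payload(g: VariantGenotype) -> dict[str, Optional[str]]:
    payload: dict[str, Optional[str]] = {}
    for k, v in g.extra.items():
        payload[f"F.{k}"] = v
    payload.update(g.gvcf_info)
    return payload


def _split_payload(payload: dict[str, Optional[str]]):
    ref = payload.pop("_REF", None)
    alt = payload.pop("_ALT", None)
    extra = {k[2:]: v for k, v in payload.items() if k.startswith("F.")}
    gvcf_info = {k: v for k, v in payload.items() if not k.startswith("F.")}
    return ref, alt, extra, gvcf_info


# ---------------------------------------------------------------------------
# Writer

_FORMAT_DECLS = [
    ("LGT", "1", "String", "Genotype over local allele indices"),
    ("LA", ".", "Integer", "Local alleles: map from local to global allele index"),
    ("LEN", "1", "Integer", "Reference block span in base pairs"),
    ("LAD", ".", "Integer", "Allelic depths over local alleles (LR-numbered)"),
    ("LPL", ".", "Integer",
     "Phred-scaled genotype likelihoods over local alleles (LG-numbered)"),
    ("DP", "1", "Integer", "Read depth"),
    ("GQ", "1", "Integer", "Genotype quality"),
    ("GINFO", "1", "String", "Per-sample GVCF INFO payload, percent-encoded"),
]


def _header(ds: SvcrDataset, with_ginfo: bool) -> str:
    lines = ["##fileformat=VCFv4.3", f"##{MAX_BLOCK_KEY}={ds.max_ref_block_length}"]
    lines += [f"##contig=<ID={c}>" for c in ds.contigs]
    for key, num, typ, desc in _FORMAT_DECLS:
        if key == "GINFO" and not with_ginfo:
            continue
        lines.append(
            f'##FORMAT=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(ds.samples)
    )
    return "\n".join(lines) + "\n"


def _ints(values) -> str:
    return ",".join(str(v) for v in values)


def _block_field(block: ReferenceBlock, row_ref: str, with_ginfo: bool,
                 block_lgt: str) -> str:
    if block_lgt == "always":
        lgt = str(block.lgt) if block.lgt is not None else "0/0"
    elif block_lgt == "never":
        lgt = "."
    else:  # auto: emit whatever the block carries
        lgt = str(block.lgt) if block.lgt is not None else "."
    parts = [
        lgt,
        ".",  # LA
        str(block.length),
        ".",  # LAD
        ".",  # LPL
        str(block.dp) if block.dp is not None else ".",
        str(block.gq) if block.gq is not None else ".",
    ]
    if with_ginfo:
        parts.append(encode_payload(_block_payload(block, row_ref)))
    return ":".join(parts)


def _genotype_field(g: VariantGenotype, with_ginfo: bool) -> str:
    parts = [
        str(g.lgt) if g.lgt is not None else ".",
        _ints(g.la),
        ".",  # LEN
        _ints(g.lad) if g.lad is not None else ".",
        _ints(g.lpl) if g.lpl is not None else ".",
        str(g.dp) if g.dp is not None else ".",
        str(g.gq) if g.gq is not None else ".",
    ]
    if with_ginfo:
        parts.append(encode_payload(_genotype_payload(g)))
    return ":".join(parts)


def _dataset_has_payload(ds: SvcrDataset) -> bool:
    for _, row in ds.reference_matrix:
        for b in row.values():
            if b.extra or b.gvcf_info or b.alts or len(b.ref) > 1:
                return True
    for site in ds.variant_matrix:
        for g in site.entries.values():
            if g.extra or g.gvcf_info:
                return True
    return False


def write_svcr_vcf(
    ds: SvcrDataset,
    sink: Union[str, TextIO],
    block_lgt: str = "auto",
) -> None:
    """Serialize a dataset as SVCR-VCF (plain text, or bgzip for ``*.gz``).

    ``block_lgt`` controls whether reference-block columns carry an LGT:
    "auto" (default) writes it when the block has one, "always" synthesizes
    0/0, "never" omits it.
    """
    problems = validate_dataset(ds)
    if problems:
        raise SvcrVcfError(
            f"invalid dataset: {problems[0].rule}: {problems[0].message}"
        )
    if block_lgt not in ("auto", "always", "never"):
        raise ValueError(f"unknown block_lgt {block_lgt!r}")
    with_ginfo = _dataset_has_payload(ds)
    fmt_col = "LGT:LA:LEN:LAD:LPL:DP:GQ" + (":GINFO" if with_ginfo else "")

    sites = {ds.locus_key(s.locus): s for s in ds.variant_matrix}
    ref_rows = {ds.locus_key(loc): (loc, row) for loc, row in ds.reference_matrix}
    keys = sorted(set(sites) | set(ref_rows))

    own = isinstance(sink, (str, bytes))
    fh = _open_text(sink, "wt") if own else sink
    try:
        fh.write(_header(ds, with_ginfo))
        for key in keys:
            site = sites.get(key)
            blocks = ref_rows.get(key, (None, {}))[1]
            if site is not None:
                locus = site.locus
                row_ref = site.alleles.ref
                alt = ",".join(site.alleles.alts) if site.alleles.alts else "."
            else:
                locus = ref_rows[key][0]
                row_ref = max(
                    (b.ref for b in blocks.values()), key=len, default="N"
                )
                alt = "."
            cols = [locus.contig, str(locus.position), ".", row_ref, alt,
                    ".", ".", ".", fmt_col]
            for sample in ds.samples:
                if site is not None and sample in site.entries:
                    cols.append(_genotype_field(site.entries[sample], with_ginfo))
                elif sample in blocks:
                    cols.append(_block_field(blocks[sample], row_ref,
                                             with_ginfo, block_lgt))
                else:
                    cols.append(".")
            fh.write("\t".join(cols) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Reader


def read_svcr_vcf(source: Union[str, TextIO]) -> SvcrDataset:
    """Parse an SVCR-VCF back into a dataset, enforcing the encoding rules.

    Rejects genotypes carrying both LA and LEN, any nonmissing sample field
    at a locus strictly inside one of that sample's blocks, and a declared
    maximum block length smaller than an actual block.
    """
    own = isinstance(source, (str, bytes))
    fh = _open_text(source, "rt") if own else source
    try:
        contigs: list[str] = []
        samples: list[str] = []
        declared_max: Optional[int] = None
        has_la = has_len = False
        ds: Optional[SvcrDataset] = None
        ref_rows: dict[tuple[int, int], tuple[GenomicLocus, dict]] = {}
        # (sample, contig) -> positions where the sample has nonmissing fields
        occupied: dict[str, list[GenomicLocus]] = {}

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith(f"##{MAX_BLOCK_KEY}="):
                    declared_max = int(line.split("=", 1)[1])
                elif line.startswith("##contig=") and "ID=" in line:
                    ident = line.split("ID=", 1)[1]
                    contigs.append(ident.split(",")[0].split(">")[0].strip())
                elif line.startswith("##FORMAT=<ID=LA,"):
                    has_la = True
                elif line.startswith("##FORMAT=<ID=LEN,"):
                    has_len = True
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                samples = cols[9:]
                continue
            if not line.strip():
                continue
            if ds is None:
                if not (has_la and has_len):
                    raise SvcrVcfError("header must declare LA and LEN FORMAT fields")
                ds = SvcrDataset(samples, contigs or [])

            parts = line.split("\t")
            contig, pos_s, _vid, ref, alt = parts[:5]
            if not contigs and contig not in ds.contigs:
                ds.contigs.append(contig)
            locus = GenomicLocus(contig, int(pos_s))
            fmt_keys = parts[8].split(":")
            alts = () if alt == "." else tuple(alt.split(","))

            entries: dict[str, VariantGenotype] = {}
            for sample, col in zip(samples, parts[9:]):
                values = col.split(":")
                fields = {
                    k: v for k, v in zip(fmt_keys, values) if v not in (".", "")
                }
                if not fields:
                    continue
                occupied.setdefault(sample, []).append(locus)
                payload = decode_payload(fields.get("GINFO", "."))
                p_ref, p_alt, extra, gvcf_info = _split_payload(payload)
                if "LEN" in fields:
                    if "LA" in fields:
                        raise SvcrVcfError(
                            f"{contig}:{locus.position}: sample {sample} has "
                            "both LEN and LA"
                        )
                    block = ReferenceBlock(
                        start=locus,
                        length=int(fields["LEN"]),
                        dp=int(fields["DP"]) if "DP" in fields else None,
                        gq=int(fields["GQ"]) if "GQ" in fields else None,
                        lgt=Call.parse(fields["LGT"]) if "LGT" in fields else None,
                        ref=p_ref if p_ref is not None else ref,
                        alts=tuple(p_alt.split(",")) if p_alt else (),
                        extra=extra,
                        gvcf_info=gvcf_info,
                    )
                    key = ds.locus_key(locus)
                    if key not in ref_rows:
                        ref_rows[key] = (locus, {})
                    ref_rows[key][1][sample] = block
                elif "LA" in fields:
                    entries[sample] = VariantGenotype(
                        la=tuple(int(x) for x in fields["LA"].split(",")),
                        lgt=Call.parse(fields["LGT"]) if "LGT" in fields else None,
                        lad=tuple(int(x) for x in fields["LAD"].split(","))
                        if "LAD" in fields
                        else None,
                        lpl=tuple(int(x) for x in fields["LPL"].split(","))
                        if "LPL" in fields
                        else None,
                        dp=int(fields["DP"]) if "DP" in fields else None,
                        gq=int(fields["GQ"]) if "GQ" in fields else None,
                        gvcf_info=gvcf_info,
                        extra=extra,
                    )
                else:
                    raise SvcrVcfError(
                        f"{contig}:{locus.position}: sample {sample} has "
                        "nonmissing fields but neither LA nor LEN"
                    )
            if alts:
                ds.variant_matrix.append(
                    VariantSite(locus, AlleleList(ref, alts), entries)
                )
            elif entries:
                raise SvcrVcfError(
                    f"{contig}:{locus.position}: genotype entries at a row "
                    "with no alternate alleles"
                )
        if ds is None:
            ds = SvcrDataset(samples, contigs)
    finally:
        if own:
            fh.close()

    ds.reference_matrix = [ref_rows[k] for k in sorted(ref_rows)]
    actual_max = max(
        (b.length for _, row in ds.reference_matrix for b in row.values()),
        default=0,
    )
    if declared_max is not None and declared_max < actual_max:
        raise SvcrVcfError(
            f"{MAX_BLOCK_KEY}={declared_max} understates actual maximum "
            f"block length {actual_max}"
        )
    ds.max_ref_block_length = declared_max if declared_max is not None else actual_max

    # No sample field may be nonmissing strictly inside one of its blocks.
    for sample, loci in occupied.items():
        blocks = [
            row[sample]
            for _, row in ds.reference_matrix
            if sample in row
        ]
        spans = {
            b.start.contig: [] for b in blocks
        }
        for b in blocks:
            spans[b.start.contig].append((b.start.position, b.end))
        for locus in loci:
            for s, e in spans.get(locus.contig, ()):
                if s < locus.position <= e:
                    raise SvcrVcfError(
                        f"{locus.contig}:{locus.position}: sample {sample} has "
                        f"nonmissing fields inside its block {s}-{e}"
                    )
    return ds


# ---------------------------------------------------------------------------
# Dense exports


def _pvcf_header(ds: SvcrDataset, keys: list[str]) -> str:
    decls = {
        "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "AD": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "PL": '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
              '"Phred-scaled genotype likelihoods">',
    }
    lines = ["##fileformat=VCFv4.3"]
    lines += [f"##contig=<ID={c}>" for c in ds.contigs]
    lines += [decls[k] for k in keys]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(ds.samples)
    )
    return "\n".join(lines) + "\n"


def export_hardcalls_pvcf(
    ds: SvcrDataset, sink: Union[str, TextIO], block_ploidy: int = 2
) -> None:
    """Dense PVCF with GT only: no allele-indexed fields, no reference blocks.

    Hom-ref calls are filled from overlapping blocks; samples covered by
    neither a record nor a block are ``./.``.
    """
    own = isinstance(sink, (str, bytes))
    fh = _open_text(sink, "wt") if own else sink
    missing = "/".join(["."] * block_ploidy)
    try:
        fh.write(_pvcf_header(ds, ["GT"]))
        for row in densify_stream(ds, block_ploidy=block_ploidy):
            cols = [
                row.locus.contig, str(row.locus.position), ".",
                row.alleles.ref, ",".join(row.alleles.alts) or ".",
                ".", ".", ".", "GT",
            ]
            for sample in ds.samples:
                call = row.calls[sample]
                if call is None or call.gt is None:
                    cols.append(missing)
                else:
                    cols.append(str(call.gt))
            fh.write("\t".join(cols) + "\n")
    finally:
        if own:
            fh.close()


def export_dense_pvcf(
    ds: SvcrDataset,
    sink: Union[str, TextIO],
    fill: Union[None, int] = None,
    block_ploidy: int = 2,
) -> None:
    """Fully densified PVCF with GT/AD/DP/GQ/PL.

    Output size is super-linear in samples by design; intended for small
    regions and tests.  ``fill`` replaces PL entries of genotypes touching
    alleles the sample did not observe (default: missing ".").
    """
    own = isinstance(sink, (str, bytes))
    fh = _open_text(sink, "wt") if own else sink
    missing_gt = "/".join(["."] * block_ploidy)

    def fmt_pl(pl):
        return ",".join("." if x is None else str(x) for x in pl)

    try:
        fh.write(_pvcf_header(ds, ["GT", "AD", "DP", "GQ", "PL"]))
        for row in densify_stream(ds, fill=fill, block_ploidy=block_ploidy):
            cols = [
                row.locus.contig, str(row.locus.position), ".",
                row.alleles.ref, ",".join(row.alleles.alts) or ".",
                ".", ".", ".", "GT:AD:DP:GQ:PL",
            ]
            for sample in ds.samples:
                call = row.calls[sample]
                if call is None:
                    cols.append(f"{missing_gt}:.:.:.:.")
                else:
                    cols.append(":".join([
                        str(call.gt) if call.gt is not None else missing_gt,
                        ",".join(str(x) for x in call.ad)
                        if call.ad is not None else ".",
                        str(call.dp) if call.dp is not None else ".",
                        str(call.gq) if call.gq is not None else ".",
                        fmt_pl(call.pl) if call.pl is not None else ".",
                    ]))
            fh.write("\t".join(cols) + "\n")
    finally:
        if own:
            fh.close()


def encoded_size(write_fn, *args, compress: bool = True, **kwargs) -> int:
    """Bytes of an encoding produced by one of this module's writers.

    Renders to memory and (by default) gzip-compresses, mirroring how these
    files are shipped.
    """
    import io as _io

    buf = _io.StringIO()
    write_fn(*args, buf, **kwargs)
    data = buf.getvalue().encode()
    return len(gzip.compress(data, compresslevel=6)) if compress else len(data)
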