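"""Bounding reference-block length.

Long reference blocks make point-query densification expensive: the search
for a covering block must look back as far as the longest block in the
dataset.  Two splitting strategies bound that distance by a parameter K,
trading a few extra blocks for a bounded search window:

* size threshold — blocks longer than K become ceil(L/K) consecutive pieces,
  all but the last exactly K long (the minimum number of new blocks);
* fixed period — blocks are cut at every genome position p with
  (p - 1) mod K == 0, so no block crosses a K-sized partition boundary and
  any partition's dense sub-matrix is realizable from that partition alone.

Both strategies copy DP/GQ/LGT onto every piece and leave per-base coverage
exactly unchanged.
"""

from __future__ import annotations

from typing import Optional

from .core import GenomicLocus, ReferenceBlock, SvcrDataset

__all__ = ["split_size_threshold", "split_fixed_period", "split_block", "coverage_map"]


def _piece(block: ReferenceBlock, start: int, end: int) -> ReferenceBlock:
    # Pieces after the first no longer sit on the original REF base; the
    # sequence there is unknown without a reference genome, hence "N".
    ref = block.ref if start == block.start.position else "N"
    return ReferenceBlock(
        start=GenomicLocus(block.start.contig, start),
        length=end - start + 1,
        dp=block.dp,
        gq=block.gq,
        lgt=block.lgt,
        ref=ref,
        alts=block.alts if start == block.start.position else (),
        extra=dict(block.extra) if start == block.start.position else {},
        gvcf_info=dict(block.gvcf_info) if start == block.start.position else {},
    )


def split_block(
    block: ReferenceBlock, k: int, strategy: str = "size-threshold"
) -> list[ReferenceBlock]:
    """Split one block; returns the (ordered) pieces."""
    if k < 1:
        raise ValueError("k must be >= 1")
    s, e = block.start.position, block.end
    if strategy == "size-threshold":
        if block.length <= k:
            return [block]
        cuts = list(range(s + k, e + 1, k))
    elif strategy == "fixed-period":
        # interior period boundaries: positions p in (s, e] with (p-1) % k == 0
        first = ((s - 1) // k + 1) * k + 1
        cuts = list(range(first, e + 1, k))
        if not cuts:
            return [block]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    starts = [s] + cuts
    ends = [c - 1 for c in cuts] + [e]
    return [_piece(block, a, b) for a, b in zip(starts, ends)]


def _split_dataset(ds: SvcrDataset, k: int, strategy: str) -> SvcrDataset:
    rows: dict[tuple[int, int], tuple[GenomicLocus, dict[str, ReferenceBlock]]] = {}
    max_len = 0
    for locus, row in ds.reference_matrix:
        for sample, block in row.items():
            for piece in split_block(block, k, strategy):
                key = ds.locus_key(piece.start)
                if key not in rows:
                    rows[key] = (piece.start, {})
                rows[key][1][sample] = piece
                max_len = max(max_len, piece.length)
    return SvcrDataset(
        samples=list(ds.samples),
        contigs=list(ds.contigs),
        reference_matrix=[rows[key] for key in sorted(rows)],
        variant_matrix=ds.variant_matrix,
        max_ref_block_length=max_len,
    )


def split_size_threshold(ds: SvcrDataset, k: int) -> SvcrDataset:
    """Split blocks longer than K into ceil(L/K) pieces of span <= K."""
    return _split_dataset(ds, k, "size-threshold")


def split_fixed_period(ds: SvcrDataset, k: int) -> SvcrDataset:
    """Cut blocks at every K-base period boundary (positions 1 mod K)."""
    return _split_dataset(ds, k, "fixed-period")


def coverage_map(
    ds: SvcrDataset, sample: str
) -> dict[tuple[str, int], tuple[Optional[int], Optional[int]]]:
    """Expand a sample's blocks base-by-base: (contig, pos) -> (dp, gq).

    A test oracle for splitting and densification; intended for small
    regions only.  Overlapping blocks are an invariant breach and rejected.
    """
    if sample not in ds.samples:
        raise KeyError(f"unknown sample {sample!r}")
    out: dict[tuple[str, int], tuple[Optional[int], Optional[int]]] = {}
    for _, row in ds.reference_matrix:
        block = row.get(sample)
        if block is None:
            continue
        for pos in range(block.start.position, block.end + 1):
            key = (block.start.contig, pos)
            if key in out:
                raise ValueError(
                    f"overlapping reference blocks for {sample} at "
                    f"{key[0]}:{key[1]}"
                )
            out[key] = (block.dp, block.gq)
    return out
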