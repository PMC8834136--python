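"""Read counting over flattened exonic portions and over genes.

Only primary alignments are counted (SAM FLAG bits 0x100 and 0x800 are
excluded); a read contributes to every portion one of its aligned blocks
overlaps by at least one base, while gene-level counting deduplicates to at
most one count per gene per fragment.  Paired-end mates sharing a query name
are counted once at the template level.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import ExonicPortion, GeneModel


@dataclass
class CountMatrix:
    """Integer counts with row identifiers, sample columns and row metadata."""

    counts: pd.DataFrame  # rows x samples, integer
    meta: pd.DataFrame | None = None  # indexed like counts; novelty/gene map

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate row ids")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def write_count_matrix(cm: CountMatrix, path: str) -> None:
    """Write a tab-delimited count matrix (first column = row id)."""
    out = cm.counts.copy()
    if cm.meta is not None:
        out = pd.concat([cm.meta, out], axis=1)
    out.to_csv(path, sep="\t", index_label="id")


_META_COLS = ("group_id", "gene_ids", "novelty", "chrom", "start", "end", "strand")


def read_count_matrix(path: str) -> CountMatrix:
    """Read a tab-delimited count matrix written by :func:`write_count_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in df.columns if c in _META_COLS]
    meta = df[meta_cols] if meta_cols else None
    counts = df.drop(columns=meta_cols)
    bad = counts.columns[
        ~counts.dtypes.map(lambda d: np.issubdtype(d, np.integer))
    ]
    if len(bad):
        raise ValueError(f"non-integer count column(s): {list(bad)}")
    return CountMatrix(counts=counts, meta=meta)


class _IntervalIndex:
    """Sorted-interval lookup per chromosome (overlap by >= 1 base)."""

    def __init__(self, items: Sequence[tuple[str, int, int, object]]):
        # chrom -> (starts, ends, payloads, max interval length)
        self.by_chrom: dict[str, tuple[list[int], list[int], list[object], int]] = {}
        tmp: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, start, end, payload in items:
            tmp.setdefault(chrom, []).append((start, end, payload))
        for chrom, lst in tmp.items():
            lst.sort(key=lambda t: (t[0], t[1]))
            starts = [s for s, _, _ in lst]
            ends = [e for _, e, _ in lst]
            max_len = max((e - s for s, e, _ in lst), default=0)
            self.by_chrom[chrom] = (starts, ends, [p for _, _, p in lst], max_len)

    def overlapping(self, chrom: str, start: int, end: int) -> list[object]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, payloads, max_len = entry
        out = []
        i = bisect_right(starts, end - 1)  # candidates with start < end
        # walk left while intervals can still reach `start`
        j = i - 1
        while j >= 0 and starts[j] + max_len > start:
            if ends[j] > start:
                out.append(payloads[j])
            j -= 1
        return out[::-1]


def _template_blocks(alignments: Iterable[pysam.AlignedSegment]):
    """Yield (query_name, chrom, blocks) per template, merging mate blocks.

    Secondary (0x100) and supplementary (0x800) records are skipped.
    """
    by_name: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    n_mapped = 0
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        n_mapped += 1
        chrom = aln.reference_name
        blocks = aln.get_blocks()
        key = aln.query_name
        if key in by_name and by_name[key][0] == chrom:
            by_name[key][1].extend(blocks)
        else:
            by_name[key] = (chrom, list(blocks))
    if n_mapped == 0:
        warnings.warn("no mapped primary alignments; counts are all zero")
    for name, (chrom, blocks) in by_name.items():
        yield name, chrom, blocks


def count_bins(
    alignment_path: str,
    portions: Sequence[ExonicPortion],
) -> pd.Series:
    """Count fragments per exonic portion for one SAM/BAM file.

    A fragment contributes +1 to *every* portion overlapped by at least one
    of its aligned blocks (overlap-mode counting: sibling bins compete for
    reads spanning a boundary, which the exon-usage design requires).
    """
    index = _IntervalIndex(
        [
            (p.interval.chrom, p.interval.start, p.interval.end, p.portion_id)
            for p in portions
        ]
    )
    counts = {p.portion_id: 0 for p in portions}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for _, chrom, blocks in _template_blocks(af):
            hit: set[str] = set()
            for bs, be in blocks:
                hit.update(index.overlapping(chrom, bs, be))
            for pid in hit:
                counts[pid] += 1
    return pd.Series(counts, name=alignment_path)


def count_genes(
    alignment_path: str,
    genes: Sequence[GeneModel],
    multigene: bool = True,
) -> pd.Series:
    """Count fragments per gene (union of the gene's exons, one count max).

    A fragment overlapping exons of two distinct genes counts toward both
    unless ``multigene=False``.
    """
    items = []
    for g in genes:
        for ex in g.exons:
            items.append((g.chrom, ex.interval.start, ex.interval.end, g.gene_id))
    index = _IntervalIndex(items)
    counts = {g.gene_id: 0 for g in genes}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        for _, chrom, blocks in _template_blocks(af):
            hit: set[str] = set()
            for bs, be in blocks:
                hit.update(index.overlapping(chrom, bs, be))
            if not multigene and len(hit) > 1:
                continue
            for gid in hit:
                counts[gid] += 1
    return pd.Series(counts, name=alignment_path)


def count_bins_cohort(
    alignment_paths: Mapping[str, str],
    portions: Sequence[ExonicPortion],
) -> CountMatrix:
    """Run :func:`count_bins` over a cohort and assemble a CountMatrix."""
    cols = {
        sample: count_bins(path, portions)
        for sample, path in alignment_paths.items()
    }
    counts = pd.DataFrame(cols).astype(int)
    meta = portion_meta(portions).loc[counts.index]
    return CountMatrix(counts=counts, meta=meta)


def portion_meta(portions: Sequence[ExonicPortion]) -> pd.DataFrame:
    """Per-portion metadata frame (group, genes, novelty, coordinates)."""
    return pd.DataFrame(
        {
            "group_id": [p.group_id for p in portions],
            "gene_ids": ["_".join(sorted(p.source_gene_ids)) for p in portions],
            "novelty": [p.novelty for p in portions],
            "chrom": [p.interval.chrom for p in portions],
            "start": [p.interval.start for p in portions],
            "end": [p.interval.end for p in portions],
            "strand": [p.interval.strand for p in portions],
        },
        index=pd.Index([p.portion_id for p in portions], name="id"),
    )
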