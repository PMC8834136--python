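"""Splice-junction ingestion and novel exonic-region derivation.

SF3B1 hotspot mutations bias the spliceosome toward alternative branch
points, producing cryptic 3' (and more rarely 5') splice sites typically a
few tens of nucleotides away from the canonical site.  This module takes the
splice junctions an aligner reports per sample (STAR ``SJ.out.tab`` format),
filters and merges them across the cohort, and converts each non-canonical
junction end into a *novel exonic region*: the stretch of sequence between
the observed splice site and the boundary of the nearest canonical exon.
Extensions (novel site intronic of the canonical boundary) add sequence to
the transcript; shortenings (novel site inside the exon) remove it.  Both
create new counting-bin boundaries when the annotation is flattened.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import CanonicalExon, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

EVENT_CLASSES = (
    "acceptor_extension",
    "acceptor_shortening",
    "donor_extension",
    "donor_shortening",
)

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}


@dataclass(frozen=True)
class SpliceJunction:
    """One record of a STAR ``SJ.out.tab`` file.

    ``intron_first``/``intron_last`` are the 1-based first and last bases of
    the intron, exactly as STAR prints them.
    """

    chrom: str
    intron_first: int
    intron_last: int
    strand_code: int
    motif_code: int
    annotated_flag: int
    unique_reads: int
    multi_reads: int
    max_overhang: int

    def __post_init__(self) -> None:
        if self.intron_first > self.intron_last:
            raise ValueError("intron_first > intron_last")
        if min(self.unique_reads, self.multi_reads, self.max_overhang) < 0:
            raise ValueError("negative counts")

    @property
    def strand(self) -> str:
        return _STRAND_FROM_CODE[self.strand_code]

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_first, self.intron_last, self.strand)


@dataclass
class MergedJunction:
    """A junction merged across samples with per-sample unique-read support."""

    chrom: str
    intron_first: int
    intron_last: int
    strand: str
    per_sample_unique_reads: dict[str, int] = field(default_factory=dict)
    n_supporting_samples: int = 0

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_first, self.intron_last, self.strand)

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.intron_first}-{self.intron_last}:{self.strand}"

    @property
    def total_unique_reads(self) -> int:
        return sum(self.per_sample_unique_reads.values())


_SIDE_FOR_CLASS = {
    "acceptor_extension": "acceptor",
    "acceptor_shortening": "acceptor",
    "donor_extension": "donor",
    "donor_shortening": "donor",
}


@dataclass
class NovelExonicRegion:
    """A novel exon piece implied by a non-canonical junction end.

    The interval spans the bases between the observed splice site and the
    assigned canonical exon's boundary; its length equals ``distance_nt``.
    """

    interval: GenomicInterval
    gene_id: str
    gene_name: str = ""
    parent_exon_id: str | None = None
    event_class: str = ""
    source_junction: MergedJunction | None = None
    junction_id: str | None = None

    def __post_init__(self) -> None:
        if self.event_class and self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event_class {self.event_class!r}")
        if self.junction_id is None and self.source_junction is not None:
            self.junction_id = self.source_junction.junction_id

    @property
    def splice_side(self) -> str:
        return _SIDE_FOR_CLASS.get(self.event_class, "")

    @property
    def distance_nt(self) -> int:
        return len(self.interval)

    @property
    def region_id(self) -> str:
        return (
            f"{self.gene_id}:{self.event_class}:"
            f"{self.interval.start}-{self.interval.end}"
        )


# ---------------------------------------------------------------------------
# SJ.out.tab I/O
# ---------------------------------------------------------------------------


def read_sj_file(path: str) -> list[SpliceJunction]:
    """Parse a STAR ``SJ.out.tab`` file (9 tab-separated columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                ints = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(SpliceJunction(chrom, *ints))
    return out


def write_sj_file(junctions: Iterable[SpliceJunction], path: str) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom, j.intron_first, j.intron_last, j.strand_code,
                        j.motif_code, j.annotated_flag, j.unique_reads,
                        j.multi_reads, j.max_overhang,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Canonical-boundary bookkeeping
# ---------------------------------------------------------------------------


class _BoundaryIndex:
    """Strand-aware lookup of canonical donor/acceptor exon boundaries.

    In the internal 0-based half-open convention an exon ``[s, e)`` on the
    plus strand has its acceptor (3' splice site) boundary at ``s`` and its
    donor (5' splice site) boundary at ``e``; on the minus strand the roles
    swap.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        # (chrom, strand) -> side -> list of (boundary_pos, exon, gene)
        self.by_side: dict[tuple[str, str], dict[str, list]] = {}
        for g in genes:
            key = (g.chrom, g.strand)
            sides = self.by_side.setdefault(key, {"acceptor": [], "donor": []})
            for ex in g.exons:
                if g.strand == "+":
                    sides["acceptor"].append((ex.interval.start, ex, g))
                    sides["donor"].append((ex.interval.end, ex, g))
                else:
                    sides["acceptor"].append((ex.interval.end, ex, g))
                    sides["donor"].append((ex.interval.start, ex, g))
        for sides in self.by_side.values():
            for lst in sides.values():
                lst.sort(key=lambda t: t[0])

    def boundary_set(self, chrom: str, strand: str, side: str) -> set[int]:
        sides = self.by_side.get((chrom, strand))
        if not sides:
            return set()
        return {pos for pos, _, _ in sides[side]}

    def candidates(self, chrom: str, strand: str, side: str) -> list:
        sides = self.by_side.get((chrom, strand))
        return sides[side] if sides else []


def junction_end_positions(j: SpliceJunction | MergedJunction) -> dict[str, int]:
    """Map splice side -> 0-based position of the adjacent exonic boundary.

    For an intron with 1-based bases ``[intron_first, intron_last]``, the
    upstream exon ends at internal coordinate ``intron_first - 1`` and the
    downstream exon starts at ``intron_last`` (half-open).  On the plus
    strand the upstream side is the donor; on the minus strand the acceptor.
    """
    left = j.intron_first - 1  # end (exclusive) of the left exon
    right = j.intron_last  # start of the right exon
    strand = j.strand if isinstance(j, MergedJunction) else j.strand
    if strand == "+":
        return {"donor": left, "acceptor": right}
    return {"acceptor": left, "donor": right}


# ---------------------------------------------------------------------------
# Filtering and merging
# ---------------------------------------------------------------------------


def filter_and_merge(
    junctions_per_sample: Mapping[str, Sequence[SpliceJunction]],
    annotation: Sequence[GeneModel],
    min_unique_reads: int = 3,
    min_samples: int = 2,
) -> list[MergedJunction]:
    """Merge per-sample junctions and keep plausibly novel, well-supported ones.

    A junction is retained when

    * its strand is defined (STAR strand code 1 or 2),
    * it is unannotated (STAR column 6 == 0),
    * at least ``min_samples`` samples support it with ``min_unique_reads``
      or more uniquely-mapped reads, and
    * at least one of its two ends does **not** coincide with a canonical
      exon boundary of the matching splice side (a safeguard on top of the
      aligner's annotated flag).
    """
    index = _BoundaryIndex(annotation)
    merged: dict[tuple, MergedJunction] = {}
    annotated_keys: set[tuple] = set()
    for sample, jlist in junctions_per_sample.items():
        for j in jlist:
            if j.strand_code == 0:
                continue
            if j.annotated_flag:
                annotated_keys.add(j.key)
            m = merged.get(j.key)
            if m is None:
                m = MergedJunction(j.chrom, j.intron_first, j.intron_last, j.strand)
                merged[j.key] = m
            m.per_sample_unique_reads[sample] = (
                m.per_sample_unique_reads.get(sample, 0) + j.unique_reads
            )

    out = []
    for key, m in sorted(merged.items()):
        if key in annotated_keys:
            continue
        m.n_supporting_samples = sum(
            1 for c in m.per_sample_unique_reads.values() if c >= min_unique_reads
        )
        if m.n_supporting_samples < min_samples:
            continue
        ends = junction_end_positions(m)
        canonical = {
            side: pos in index.boundary_set(m.chrom, m.strand, side)
            for side, pos in ends.items()
        }
        if all(canonical.values()):
            continue
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Novel-region derivation
# ---------------------------------------------------------------------------


def derive_novel_regions(
    merged: Sequence[MergedJunction],
    genes: Sequence[GeneModel],
    max_distance: int = 500,
) -> list[NovelExonicRegion]:
    """Turn non-canonical junction ends into novel exonic regions.

    For each junction end that does not match a canonical boundary, the
    nearest canonical exon (same strand, matching splice side, boundary
    within ``max_distance`` nt) is selected; the emitted region spans the
    bases between the observed splice site and that exon's boundary and
    inherits the exon's gene annotations.  Equidistant ties prefer an exon
    of a gene that owns the junction's other, canonical end; remaining ties
    go to the lexicographically smallest gene id.  Regions with identical
    coordinates and event class are merged, support summed.
    """
    index = _BoundaryIndex(genes)
    regions: dict[tuple, NovelExonicRegion] = {}
    for m in merged:
        ends = junction_end_positions(m)
        canonical_genes: set[str] = set()
        for side, pos in ends.items():
            for bpos, ex, g in index.candidates(m.chrom, m.strand, side):
                if bpos == pos:
                    canonical_genes.add(g.gene_id)
        for side, pos in ends.items():
            cands = index.candidates(m.chrom, m.strand, side)
            if not cands:
                continue
            # an end that matches any canonical boundary of its side is
            # canonical; it must not be reassigned to a different exon
            if any(bpos == pos for bpos, _, _ in cands):
                continue
            best = None
            for bpos, ex, g in cands:
                d = abs(bpos - pos)
                if d == 0 or d > max_distance:
                    continue
                # extension: the novel site lies on the intronic side of the
                # boundary; shortening: strictly inside the exon.  A position
                # beyond the exon's far end is neither and is skipped.
                if ex.interval.start < pos < ex.interval.end:
                    kind = "shortening"
                elif (pos < bpos) == (bpos == ex.interval.start):
                    kind = "extension"
                else:
                    continue
                rank = (d, 0 if g.gene_id in canonical_genes else 1, g.gene_id)
                if best is None or rank < best[0]:
                    best = (rank, bpos, ex, g, kind)
            if best is None:
                logger.debug(
                    "junction %s: no exon %s boundary within %d nt of %d",
                    m.junction_id, side, max_distance, pos,
                )
                continue
            _, bpos, ex, g, kind = best
            lo, hi = min(pos, bpos), max(pos, bpos)
            event_class = f"{side}_{kind}"
            iv = GenomicInterval(m.chrom, lo, hi, m.strand)
            rkey = (iv.chrom, iv.start, iv.end, iv.strand, event_class)
            if rkey in regions:
                prev = regions[rkey].source_junction
                if prev is not None:
                    for s, c in m.per_sample_unique_reads.items():
                        prev.per_sample_unique_reads[s] = (
                            prev.per_sample_unique_reads.get(s, 0) + c
                        )
            else:
                regions[rkey] = NovelExonicRegion(
                    interval=iv,
                    gene_id=g.gene_id,
                    gene_name=g.gene_name,
                    parent_exon_id=ex.exon_id,
                    event_class=event_class,
                    source_junction=m,
                )
    return [regions[k] for k in sorted(regions)]
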