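"""Strand-aware genomic annotation model and exon flattening.

Coordinates are handled in a single internal convention: 0-based, half-open
``[start, end)``, matching Python slicing.  GFF3/GTF files (1-based, fully
closed) are converted at the I/O boundary and nowhere else.

The flattening operation splits the union of a gene group's exons -- canonical
exons plus any novel exonic regions derived from splice-junction evidence --
into maximal non-overlapping "exonic portions".  Portions covering sequence
absent from the canonical annotation are labelled ``novel_acceptor`` or
``novel_donor``; everything else is ``canonical``.  These portions are the
counting bins for differential exon-usage testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import gffutils

if TYPE_CHECKING:  # pragma: no cover
    from .junctions import NovelExonicRegion

NOVELTY_CANONICAL = "canonical"
NOVELTY_ACCEPTOR = "novel_acceptor"
NOVELTY_DONOR = "novel_donor"

#: GFF3 ``source`` field used for features this package writes.
GFF_SOURCE = "aberex"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    # -- GFF3 coordinate conversion (1-based inclusive) --------------------
    @classmethod
    def from_gff3(cls, chrom: str, start1: int, end1: int, strand: str) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1, strand)

    def to_gff3(self) -> tuple[int, int]:
        """Return (start, end) in GFF3 1-based inclusive coordinates."""
        return self.start + 1, self.end


@dataclass
class CanonicalExon:
    """One deduplicated exon of a gene (merged across transcripts)."""

    interval: GenomicInterval
    exon_id: str
    gene_id: str
    gene_name: str = ""
    biotype: str = ""
    transcript_ids: set[str] = field(default_factory=set)


@dataclass
class GeneModel:
    """A gene with its deduplicated exon set."""

    gene_id: str
    gene_name: str
    biotype: str
    strand: str
    exons: list[CanonicalExon]

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for e in self.exons:
            if e.interval.strand != self.strand:
                raise ValueError(f"exon strand mismatch in gene {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.interval.start for e in self.exons),
            max(e.interval.end for e in self.exons),
            self.strand,
        )

    def sorted_exons(self) -> list[CanonicalExon]:
        return sorted(self.exons, key=lambda e: (e.interval.start, e.interval.end))


@dataclass
class ExonicPortion:
    """A flattened non-overlapping counting bin within an aggregate gene group."""

    interval: GenomicInterval
    group_id: str
    bin_number: int
    source_gene_ids: set[str]
    novelty: str = NOVELTY_CANONICAL
    parent_exon_id: str | None = None

    @property
    def portion_id(self) -> str:
        return f"{self.group_id}:{self.bin_number:03d}"


# ---------------------------------------------------------------------------
# Reading annotation
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("gene_type", "gene_biotype", "biotype")


def _attr_first(feature, *keys: str, default: str = "") -> str:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return default


def read_annotation(path: str, biotype_key: str | None = None) -> list[GeneModel]:
    """Read a GFF3 or GTF file into a list of :class:`GeneModel`.

    Exons identical in coordinates within one gene are merged into a single
    :class:`CanonicalExon` carrying the union of transcript ids.  Exons whose
    gene cannot be resolved are skipped (a warning reports how many).

    Parameters
    ----------
    path:
        GFF3 or GTF file with ``gene`` and ``exon`` features.
    biotype_key:
        Attribute name holding the gene biotype.  By default ``gene_type``,
        ``gene_biotype`` and ``biotype`` are tried in that order.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    biotype_keys = (biotype_key,) if biotype_key else _BIOTYPE_KEYS

    gene_meta: dict[str, tuple[str, str, str]] = {}
    for g in db.features_of_type("gene"):
        gid = _attr_first(g, "gene_id", "ID")
        gene_meta[gid] = (
            _attr_first(g, "gene_name", "Name", default=gid),
            _attr_first(g, *biotype_keys),
            g.strand,
        )

    # transcript -> gene resolution for GFF3 Parent chains
    tx_gene: dict[str, str] = {}
    for ttype in ("mRNA", "transcript"):
        for t in db.features_of_type(ttype):
            tid = _attr_first(t, "transcript_id", "ID")
            gid = _attr_first(t, "gene_id", "Parent")
            if tid and gid:
                tx_gene[tid] = gid

    exons: dict[tuple[str, int, int, str], CanonicalExon] = {}
    n_orphans = 0
    for ex in db.features_of_type("exon"):
        gid = _attr_first(ex, "gene_id")
        if not gid:
            parent = _attr_first(ex, "Parent")
            gid = tx_gene.get(parent, "")
        if not gid or gid not in gene_meta:
            n_orphans += 1
            continue
        tid = _attr_first(ex, "transcript_id", "Parent")
        iv = GenomicInterval.from_gff3(ex.seqid, ex.start, ex.end, ex.strand)
        key = (gid, iv.start, iv.end, iv.strand)
        if key in exons:
            if tid:
                exons[key].transcript_ids.add(tid)
        else:
            name, biotype, _ = gene_meta[gid]
            exons[key] = CanonicalExon(
                interval=iv,
                exon_id=_attr_first(ex, "exon_id", "ID", default=f"{gid}:E{iv.start}"),
                gene_id=gid,
                gene_name=name,
                biotype=biotype,
                transcript_ids={tid} if tid else set(),
            )
    if n_orphans:
        warnings.warn(f"skipped {n_orphans} exon(s) without a resolvable gene")

    by_gene: dict[str, list[CanonicalExon]] = {}
    for ex in exons.values():
        by_gene.setdefault(ex.gene_id, []).append(ex)

    genes = []
    for gid, exs in by_gene.items():
        name, biotype, strand = gene_meta[gid]
        exs.sort(key=lambda e: (e.interval.start, e.interval.end))
        genes.append(GeneModel(gid, name, biotype, strand, exs))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def group_overlapping_genes(genes: Sequence[GeneModel]) -> list[list[GeneModel]]:
    """Partition genes into aggregate groups of span-overlapping genes.

    Genes whose spans overlap on the same chromosome *and strand* are merged
    into one counting group (their flattened bins share a group id, joined by
    underscores); genes overlapping across strands stay separate.
    """
    groups: list[list[GeneModel]] = []
    by_cs: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_cs.setdefault((g.chrom, g.strand), []).append(g)
    for (_, _), gl in sorted(by_cs.items()):
        gl.sort(key=lambda g: g.span.start)
        current: list[GeneModel] = []
        current_end = -1
        for g in gl:
            if current and g.span.start < current_end:
                current.append(g)
                current_end = max(current_end, g.span.end)
            else:
                if current:
                    groups.append(current)
                current = [g]
                current_end = g.span.end
        if current:
            groups.append(current)
    return groups


def flatten_exons(
    exons: Sequence[CanonicalExon],
    novel_regions: Sequence["NovelExonicRegion"] = (),
    group_id: str | None = None,
) -> list[ExonicPortion]:
    """Split canonical exons plus novel regions into non-overlapping portions.

    Boundaries are the union of all input start/end positions; each resulting
    portion is labelled ``novel_acceptor``/``novel_donor`` when it lies inside
    a novel region and outside every canonical exon, else ``canonical``.
    Portions are coordinate-sorted and densely numbered from 1.
    """
    if not exons and not novel_regions:
        return []
    ivs = [e.interval for e in exons] + [r.interval for r in novel_regions]
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"flatten_exons requires one chromosome, got {chroms}")
    if len(strands) > 1:
        raise ValueError(f"inconsistent strands in group: {strands}")
    chrom = chroms.pop()
    strand = strands.pop()

    gene_ids = sorted(
        {e.gene_id for e in exons} | {r.gene_id for r in novel_regions if r.gene_id}
    )
    if group_id is None:
        group_id = "_".join(gene_ids) if gene_ids else "group"

    bounds = sorted({iv.start for iv in ivs} | {iv.end for iv in ivs})
    canon = sorted((e.interval.start, e.interval.end, e) for e in exons)

    portions: list[ExonicPortion] = []
    n = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        # candidate cell; keep only if covered by some input interval
        covering_exons = [e for s, t, e in canon if s <= lo and hi <= t]
        covering_novel = [
            r for r in novel_regions
            if r.interval.start <= lo and hi <= r.interval.end
        ]
        if not covering_exons and not covering_novel:
            continue
        if covering_exons:
            novelty = NOVELTY_CANONICAL
            parent = covering_exons[0].exon_id
        else:
            sides = {r.splice_side for r in covering_novel}
            novelty = NOVELTY_ACCEPTOR if sides == {"acceptor"} else (
                NOVELTY_DONOR if sides == {"donor"} else NOVELTY_ACCEPTOR
            )
            parent = covering_novel[0].parent_exon_id
        n += 1
        portions.append(
            ExonicPortion(
                interval=GenomicInterval(chrom, lo, hi, strand),
                group_id=group_id,
                bin_number=n,
                source_gene_ids=set(gene_ids),
                novelty=novelty,
                parent_exon_id=parent,
            )
        )
    return portions


def flatten_annotation(
    genes: Sequence[GeneModel],
    novel_regions: Sequence["NovelExonicRegion"] = (),
) -> list[ExonicPortion]:
    """Flatten a whole annotation: group overlapping genes, then flatten each group."""
    by_group = group_overlapping_genes(genes)
    novel_by_gene: dict[str, list] = {}
    for r in novel_regions:
        novel_by_gene.setdefault(r.gene_id, []).append(r)
    out: list[ExonicPortion] = []
    for group in by_group:
        exons = [e for g in group for e in g.exons]
        regs = [r for g in group for r in novel_by_gene.get(g.gene_id, [])]
        gid = "_".join(sorted(g.gene_id for g in group))
        out.extend(flatten_exons(exons, regs, group_id=gid))
    return out


# ---------------------------------------------------------------------------
# Writing GFF3
# ---------------------------------------------------------------------------


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v)


def write_custom_gff3(
    genes: Sequence[GeneModel],
    novel_regions: Sequence["NovelExonicRegion"],
    path: str,
) -> None:
    """Write canonical gene models plus novel exonic regions as GFF3.

    Novel features are exon lines with ``source`` "aberex" and attributes
    ``novelty``, ``parent_exon`` and ``junction_id``; canonical features are
    written from the in-memory models.
    """
    novel_by_gene: dict[str, list] = {}
    for r in novel_regions:
        novel_by_gene.setdefault(r.gene_id, []).append(r)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.span.to_gff3()
            fh.write(
                "\t".join(
                    [
                        g.chrom, GFF_SOURCE, "gene", str(s1), str(e1), ".",
                        g.strand, ".",
                        _fmt_attrs(
                            {
                                "ID": g.gene_id,
                                "gene_id": g.gene_id,
                                "gene_name": g.gene_name,
                                "gene_type": g.biotype,
                            }
                        ),
                    ]
                )
                + "\n"
            )
            # one synthetic transcript carrying the union exon set, so that
            # standard GFF3 consumers see a valid Parent chain
            tid = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(
                    [
                        g.chrom, GFF_SOURCE, "mRNA", str(s1), str(e1), ".",
                        g.strand, ".",
                        _fmt_attrs(
                            {
                                "ID": tid,
                                "Parent": g.gene_id,
                                "transcript_id": tid,
                                "gene_id": g.gene_id,
                            }
                        ),
                    ]
                )
                + "\n"
            )
            for ex in g.sorted_exons():
                xs, xe = ex.interval.to_gff3()
                fh.write(
                    "\t".join(
                        [
                            g.chrom, GFF_SOURCE, "exon", str(xs), str(xe), ".",
                            g.strand, ".",
                            _fmt_attrs(
                                {
                                    "ID": ex.exon_id,
                                    "Parent": tid,
                                    "exon_id": ex.exon_id,
                                    "gene_id": g.gene_id,
                                    "transcript_id": tid,
                                }
                            ),
                        ]
                    )
                    + "\n"
                )
            for r in sorted(
                novel_by_gene.get(g.gene_id, []), key=lambda r: r.interval.start
            ):
                rs, re_ = r.interval.to_gff3()
                fh.write(
                    "\t".join(
                        [
                            g.chrom, GFF_SOURCE, "exon", str(rs), str(re_), ".",
                            g.strand, ".",
                            _fmt_attrs(
                                {
                                    "ID": r.region_id,
                                    "Parent": tid,
                                    "gene_id": g.gene_id,
                                    "transcript_id": tid,
                                    "novelty": (
                                        NOVELTY_ACCEPTOR
                                        if r.splice_side == "acceptor"
                                        else NOVELTY_DONOR
                                    ),
                                    "event_class": r.event_class,
                                    "parent_exon": r.parent_exon_id or "",
                                    "junction_id": r.junction_id or "",
                                }
                            ),
                        ]
                    )
                    + "\n"
                )


def read_novel_regions_gff3(path: str):
    """Read back the novel exonic regions from a custom GFF3 written by
    :func:`write_custom_gff3` (the round-trip complement)."""
    from .junctions import NovelExonicRegion

    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "exon":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if "novelty" not in attrs:
                continue
            iv = GenomicInterval.from_gff3(f[0], int(f[3]), int(f[4]), f[6])
            out.append(
                NovelExonicRegion(
                    interval=iv,
                    gene_id=attrs.get("gene_id", ""),
                    gene_name=attrs.get("gene_name", ""),
                    parent_exon_id=attrs.get("parent_exon") or None,
                    event_class=attrs.get("event_class", ""),
                    junction_id=attrs.get("junction_id") or None,
                )
            )
    return out
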