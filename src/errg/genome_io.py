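"""Genomic interval primitives, annotation I/O, and interval lookup.

Coordinate convention
---------------------
All coordinates in this package are 0-based, half-open ``[start, end)`` —
the native BED convention. GTF input (1-based, closed) is converted on
read. Overlap means at least one shared base under half-open semantics, so
``[100, 200)`` and ``[200, 300)`` do *not* overlap. Overlap is
strand-agnostic throughout: enhancer-to-gene assignment in this pipeline
never conditions on strand.

Chromosome names are compared as exact strings (``"chr1" != "1"``); an
optional normalization switch can strip or add the ``chr`` prefix at parse
time.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BIOTYPES = frozenset({"protein_coding", "lncRNA", "other"})
STRANDS = frozenset({"+", "-", "."})

GENE_TABLE_COLUMNS = ("gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype")


class ParseError(ValueError):
    """An annotation file violated its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval — the atom of all assignment logic."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:[{self.start},{self.end})")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp shared under half-open semantics; adjacency is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EnhancerRecord:
    interval: GenomicInterval
    enhancer_id: str
    resource: str


@dataclass(frozen=True)
class GeneRecord:
    interval: GenomicInterval
    gene_id: str
    gene_name: str
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"bad biotype {self.biotype!r} for {self.gene_id}")


def normalize_biotype(raw: str) -> str:
    """Map an annotation biotype onto the closed set {protein_coding, lncRNA, other}."""
    return raw if raw in ("protein_coding", "lncRNA") else "other"


def normalize_chrom(name: str, style: str = "none") -> str:
    """Optionally harmonize the ``chr`` prefix. Off ("none") by default."""
    if style == "none":
        return name
    if style == "strip-chr":
        return name[3:] if name.startswith("chr") else name
    if style == "add-chr":
        return name if name.startswith("chr") else "chr" + name
    raise ValueError(f"unknown chromosome style {style!r}")


def _record_id(rec) -> str:
    for attr in ("enhancer_id", "gene_id", "region_id"):
        val = getattr(rec, attr, None)
        if val is not None:
            return val
    return str(rec)


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path: str | Path, resource: str, chrom_style: str = "none") -> list[EnhancerRecord]:
    """Read BED3/BED4 enhancer annotations for one resource.

    Coordinates are taken as 0-based half-open unchanged. Lines starting with
    ``#``, ``track`` or ``browser`` are skipped. A missing 4th column yields
    an auto-generated id ``<resource>:<line-number>``.
    """
    records: list[EnhancerRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = normalize_chrom(fields[0], chrom_style)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            enh_id = fields[3] if len(fields) >= 4 else f"{resource}:{lineno}"
            if enh_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate enhancer id {enh_id!r}")
            seen.add(enh_id)
            records.append(EnhancerRecord(interval, enh_id, resource))
    return records


def _check_unique_gene_ids(genes: Sequence[GeneRecord]) -> None:
    seen: dict[str, int] = {}
    dups = []
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = sorted(gid for gid, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"duplicate gene ids: {', '.join(dups)}")


def read_gene_table(
    path: str | Path, dialect: str = "tsv", chrom_style: str = "none"
) -> list[GeneRecord]:
    """Read a gene annotation in either the 7-column TSV dialect or GTF.

    TSV carries 0-based half-open coordinates directly; GTF gene lines are
    converted from 1-based closed ``[start, end]`` to ``[start-1, end)``.
    Biotypes outside {protein_coding, lncRNA} map to "other".
    """
    if dialect == "tsv":
        genes = _read_gene_tsv(path, chrom_style)
    elif dialect == "gtf":
        genes = _read_gene_gtf(path, chrom_style)
    else:
        raise ParseError(f"unknown gene table dialect {dialect!r}")
    _check_unique_gene_ids(genes)
    return genes


def _read_gene_tsv(path: str | Path, chrom_style: str) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in GENE_TABLE_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in GENE_TABLE_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                interval = GenomicInterval(
                    normalize_chrom(fields[idx["chrom"]], chrom_style),
                    int(fields[idx["start"]]),
                    int(fields[idx["end"]]),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(
                GeneRecord(
                    interval=interval,
                    gene_id=fields[idx["gene_id"]],
                    gene_name=fields[idx["gene_name"]],
                    strand=fields[idx["strand"]],
                    biotype=normalize_biotype(fields[idx["biotype"]]),
                )
            )
    return genes


def _read_gene_gtf(path: str | Path, chrom_style: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene", order_by=None):
        raw_biotype = (
            feat.attributes.get("gene_type") or feat.attributes.get("gene_biotype") or ["other"]
        )[0]
        gene_id = feat.attributes["gene_id"][0]
        gene_name = (feat.attributes.get("gene_name") or [gene_id])[0]
        genes.append(
            GeneRecord(
                interval=GenomicInterval(
                    normalize_chrom(feat.seqid, chrom_style), feat.start - 1, feat.end
                ),
                gene_id=gene_id,
                gene_name=gene_name,
                strand=feat.strand if feat.strand in STRANDS else ".",
                biotype=normalize_biotype(raw_biotype),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes in the 7-column TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.gene_name}\t{g.interval.chrom}\t{g.interval.start}"
                f"\t{g.interval.end}\t{g.strand}\t{g.biotype}\n"
            )


# ---------------------------------------------------------------------------
# interval index


class IntervalIndex:
    """Chromosome-keyed overlap lookup over records carrying an ``.interval``.

    Backed by an interval tree per chromosome; results are returned in a
    deterministic order (interval start, then record id) and match the
    O(n*m) all-pairs definition exactly — the test suite holds it to a
    brute-force oracle.
    """

    def __init__(self, records: Iterable, key: Callable | None = None):
        self._key = key or _record_id
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            iv = rec.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)

    def overlapping(self, query: GenomicInterval) -> list:
        """All records overlapping ``query`` by >=1 bp, sorted (start, id)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda r: (r.interval.start, self._key(r)))
        return hits

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))
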