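"""Identification of eRNA-regulated genes (eRRGs).

The procedure has four steps, each a separate operation here:

1. **eRNA region construction** — an eRNA-transcribing region is the window
   of ``half_width`` bp (default 3 kb) on either side of the midpoint of an
   annotated enhancer, reflecting that eRNA transcription extends beyond
   the ChIP-seq peak itself.
2. **Gene-overlap filtering** — eRNA regions overlapping any known gene
   body (any biotype, either strand) are discarded, so that what remains is
   plausibly intergenic enhancer transcription rather than genic signal.
3. **Contact-domain assignment** — genes whose bodies fall within the
   contact domain of an eRNA region are its candidate targets. Contact
   domains (self-interacting neighborhoods, median length ~185 kb) are
   operationalized as a fixed-length window of ``domain_length`` bp
   (default 185,000) centered on the eRNA midpoint; a gene is assigned on
   >=1 bp overlap with that window.
4. **Multi-resource intersection** — steps 1-3 run once per enhancer
   resource (e.g. Ensembl / FANTOM / Roadmap / ENCODE) and the final eRRG
   set is the intersection of the per-resource gene sets, which suppresses
   resource-specific false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .genome_io import (
    EnhancerRecord,
    GeneRecord,
    GenomicInterval,
    IntervalIndex,
    read_bed,
    read_gene_table,
)

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 3_000
DEFAULT_DOMAIN_LENGTH = 185_000


@dataclass(frozen=True)
class ErnaRegion:
    """A candidate eRNA-transcribing region derived from one enhancer."""

    interval: GenomicInterval
    enhancer_id: str
    resource: str
    midpoint: int

    @property
    def region_id(self) -> str:
        return self.enhancer_id


class ErrgPair(NamedTuple):
    erna_id: str
    resource: str
    gene_id: str


@dataclass
class ErrgAssignment:
    """Result of the full identification: per-resource sets, pairs, final set."""

    per_resource: dict[str, frozenset[str]]
    final: frozenset[str]
    pairs: list[ErrgPair]
    half_width: int
    domain_length: int
    summary: dict = field(default_factory=dict)


def erna_region(enh: EnhancerRecord, half_width: int = DEFAULT_HALF_WIDTH) -> ErnaRegion:
    """Window of +-``half_width`` bp around the enhancer midpoint.

    The midpoint of an even-length enhancer is taken as the floor; the
    window start is clamped at the chromosome origin (chromosome sizes are
    not required, so the end is not clamped).
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    mid = (enh.interval.start + enh.interval.end) // 2
    interval = GenomicInterval(enh.interval.chrom, max(0, mid - half_width), mid + half_width)
    return ErnaRegion(interval, enh.enhancer_id, enh.resource, mid)


def filter_gene_overlapping(
    regions: Sequence[ErnaRegion],
    genes: Sequence[GeneRecord] | IntervalIndex,
) -> list[ErnaRegion]:
    """Drop eRNA regions overlapping any known gene body by >=1 bp.

    All biotypes count as "known genes" and strand is ignored. Input order
    is preserved; the number removed is logged.
    """
    index = genes if isinstance(genes, IntervalIndex) else IntervalIndex(genes)
    kept = [r for r in regions if not index.any_overlap(r.interval)]
    logger.info("filter_gene_overlapping: removed %d of %d regions", len(regions) - len(kept), len(regions))
    return kept


def domain_window(region: ErnaRegion, domain_length: int = DEFAULT_DOMAIN_LENGTH) -> GenomicInterval:
    """Contact-domain window of total length ``domain_length`` centered on the midpoint."""
    if domain_length <= 0:
        raise ValueError(f"domain_length must be > 0, got {domain_length}")
    half = domain_length // 2
    return GenomicInterval(
        region.interval.chrom,
        max(0, region.midpoint - half),
        region.midpoint + (domain_length - half),
    )


def assign_errgs(
    regions: Sequence[ErnaRegion],
    genes: Sequence[GeneRecord] | IntervalIndex,
    domain_length: int = DEFAULT_DOMAIN_LENGTH,
) -> tuple[list[tuple[ErnaRegion, str]], frozenset[str]]:
    """Assign genes overlapping each region's contact-domain window.

    Returns the (region, gene_id) pairs and the deduplicated gene-id set
    for one resource.
    """
    index = genes if isinstance(genes, IntervalIndex) else IntervalIndex(genes)
    pairs: list[tuple[ErnaRegion, str]] = []
    for region in regions:
        window = domain_window(region, domain_length)
        for hit in index.overlapping(window):
            pairs.append((region, hit.gene_id))
    return pairs, frozenset(g for _, g in pairs)


def intersect_resources(per_resource: Mapping[str, frozenset[str] | set[str]]) -> frozenset[str]:
    """Final eRRG set: intersection of the per-resource gene sets."""
    if not per_resource:
        raise ValueError("at least one resource required")
    sets = [frozenset(s) for s in per_resource.values()]
    final = sets[0]
    for s in sets[1:]:
        final &= s
    return final


def biotype_counts(gene_ids: Iterable[str], genes: Sequence[GeneRecord]) -> dict[str, int]:
    by_id = {g.gene_id: g.biotype for g in genes}
    counts = {"protein_coding": 0, "lncRNA": 0, "other": 0}
    for gid in gene_ids:
        counts[by_id[gid]] += 1
    return counts


def identify_errgs(
    enhancers_by_resource: Mapping[str, Sequence[EnhancerRecord]],
    genes: Sequence[GeneRecord],
    half_width: int = DEFAULT_HALF_WIDTH,
    domain_length: int = DEFAULT_DOMAIN_LENGTH,
) -> ErrgAssignment:
    """Run the full four-step identification across resources.

    The summary mirrors the usual reporting structure: per-resource
    enhancer counts, eRNA counts surviving the gene-overlap filter,
    per-resource eRRG counts, and the final set split by biotype.
    """
    if not genes:
        raise ValueError("gene annotation is empty")
    gene_index = IntervalIndex(genes)
    per_resource: dict[str, frozenset[str]] = {}
    all_pairs: list[ErrgPair] = []
    summary: dict = {"resources": {}, "half_width": half_width, "domain_length": domain_length}
    for resource in sorted(enhancers_by_resource):
        enhancers = enhancers_by_resource[resource]
        regions = [erna_region(e, half_width) for e in enhancers]
        kept = filter_gene_overlapping(regions, gene_index)
        if not kept:
            logger.warning("resource %s contributes zero eRNAs after gene-overlap filtering", resource)
        pairs, gene_set = assign_errgs(kept, gene_index, domain_length)
        per_resource[resource] = gene_set
        seen = set()
        for region, gid in pairs:
            key = (region.enhancer_id, resource, gid)
            if key not in seen:  # duplicate enhancer records may repeat a pair
                seen.add(key)
                all_pairs.append(ErrgPair(region.enhancer_id, resource, gid))
        summary["resources"][resource] = {
            "n_enhancers": len(enhancers),
            "n_erna_after_filter": len(kept),
            "n_errgs": len(gene_set),
        }
    final = intersect_resources(per_resource)
    summary["final"] = {"n_errgs": len(final), **biotype_counts(final, genes)}
    return ErrgAssignment(
        per_resource=per_resource,
        final=final,
        pairs=all_pairs,
        half_width=half_width,
        domain_length=domain_length,
        summary=summary,
    )


def identify_errgs_from_files(
    gene_path: str | Path,
    resource_paths: Mapping[str, str | Path],
    half_width: int = DEFAULT_HALF_WIDTH,
    domain_length: int = DEFAULT_DOMAIN_LENGTH,
    gene_dialect: str = "tsv",
    chrom_style: str = "none",
) -> tuple[ErrgAssignment, Sequence[GeneRecord]]:
    """File-level wrapper around :func:`identify_errgs`."""
    genes = read_gene_table(gene_path, dialect=gene_dialect, chrom_style=chrom_style)
    enhancers = {
        resource: read_bed(path, resource, chrom_style=chrom_style)
        for resource, path in resource_paths.items()
    }
    return identify_errgs(enhancers, genes, half_width, domain_length), genes
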