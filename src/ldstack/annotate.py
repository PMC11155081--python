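"""Region-to-gene annotation.

Prioritized regions are extended by a flank (default 5 kb on each end) and
intersected with gene intervals; any overlap of at least 1 bp counts — genes
are tabulated "within" flanked regions, with no nearest-gene fallback.
Regions are 1-based inclusive, gene models 0-based half-open; the conversion
happens here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .formats import GeneInterval, normalize_chrom


@dataclass(frozen=True)
class RegionGeneHit:
    region_id: str        # "chrom:start-end" in 1-based inclusive coordinates
    gene_name: str
    overlap_bp: int       # length of intersection after flanking, >= 1


def annotate_regions(regions: Iterable, genes: Sequence[GeneInterval],
                     flank_bp: int = 5000
                     ) -> tuple[list[RegionGeneHit], list[str]]:
    """Intersect flanked regions with gene intervals.

    ``regions`` may be :class:`~ldstack.cluster.Region` objects or anything
    with ``chrom``/``start_bp``/``end_bp`` attributes. Returns per-region gene
    hits plus the deduplicated, sorted flat gene list (the input one would
    hand to an enrichment service). Genes recurring across regions appear as
    separate hits but once in the flat list.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(normalize_chrom(g.chrom), IntervalTree()).addi(
            g.start, g.end, g.gene_name)

    hits: list[RegionGeneHit] = []
    for r in regions:
        chrom = normalize_chrom(r.chrom)
        tree = trees.get(chrom)
        if tree is None:
            continue
        # flank in 1-based inclusive space (floored at position 1), then
        # convert to 0-based half-open for the interval query
        start1 = max(1, int(r.start_bp) - flank_bp)
        end1 = int(r.end_bp) + flank_bp
        q_start, q_end = start1 - 1, end1
        region_id = f"{chrom}:{r.start_bp}-{r.end_bp}"
        for iv in sorted(tree.overlap(q_start, q_end)):
            overlap = min(iv.end, q_end) - max(iv.begin, q_start)
            if overlap >= 1:
                hits.append(RegionGeneHit(region_id, iv.data, int(overlap)))
    gene_list = sorted({h.gene_name for h in hits})
    return hits, gene_list
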