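"""Base-level detection of narrow coverage drops inside covered exons.

Region-level counts cannot localize short stretches of poor coverage: an
exon may look well covered overall while hiding a run of low-depth bases
where a variant call would silently fail.  The scanner therefore works on
per-base depth profiles.  An exon is *eligible* when its per-base median
depth reaches the eligibility depth (default 100X, i.e. "highly covered");
a *drop* is a maximal run of at least ``min_width`` consecutive bases
(default 10 bp) whose depth is strictly below ``drop_ratio`` times the
exon median (default 0.5).  Runs separated by at least one passing base
are distinct drops.  Boundary-decay ramps outside the exon are never seen:
profiles are clipped to exon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenomicRegion, PerBaseProfile, write_bed, write_track

__all__ = [
    "CoverageDrop",
    "GeneDropSummary",
    "detect_drops",
    "scan_profiles",
    "aggregate_gene_drops",
    "export_drops",
]


@dataclass
class CoverageDrop:
    """A contiguous low-depth interval within an otherwise covered exon."""

    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    region_id: str
    gene: str
    sample: str
    exon_median_depth: float
    drop_median_depth: float

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def ratio(self) -> float:
        return self.drop_median_depth / self.exon_median_depth


@dataclass
class GeneDropSummary:
    gene: str
    n_drops: int
    total_bp: int
    affected_exons: int
    samples_affected: int


def detect_drops(
    profile: PerBaseProfile,
    min_width: int = 10,
    drop_ratio: float = 0.5,
    eligibility_depth: float = 100.0,
) -> list[CoverageDrop]:
    """Scan one per-base profile for coverage drops.

    Returns drops sorted by coordinate; an ineligible exon (median depth
    below ``eligibility_depth``) yields an empty list.  Each reported drop
    is maximal: it cannot be extended by one base on either side while
    keeping every base below the depth criterion.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if not 0 < drop_ratio < 1:
        raise ValueError("drop_ratio must lie in (0, 1)")
    d = profile.depths
    if d.size == 0:
        raise ValueError("empty per-base profile")
    exon_median = float(np.median(d))
    if exon_median < eligibility_depth:
        return []
    cutoff = drop_ratio * exon_median
    low = d < cutoff
    if not low.any():
        return []
    # maximal runs of consecutive low bases
    padded = np.concatenate(([False], low, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    region = profile.region
    drops = []
    for a, b in zip(starts, ends):
        if b - a < min_width:
            continue
        drops.append(
            CoverageDrop(
                chrom=region.chrom,
                start=region.start + int(a),
                end=region.start + int(b),
                region_id=region.region_id,
                gene=region.gene,
                sample=profile.sample,
                exon_median_depth=exon_median,
                drop_median_depth=float(np.median(d[a:b])),
            )
        )
    return drops


def scan_profiles(
    profiles: Iterable[PerBaseProfile],
    min_width: int = 10,
    drop_ratio: float = 0.5,
    eligibility_depth: float = 100.0,
) -> list[CoverageDrop]:
    """Run :func:`detect_drops` over many profiles; result coordinate-sorted."""
    drops: list[CoverageDrop] = []
    for prof in profiles:
        drops.extend(detect_drops(prof, min_width, drop_ratio, eligibility_depth))
    drops.sort(key=lambda dr: (dr.chrom, dr.start, dr.end, dr.sample))
    return drops


def aggregate_gene_drops(drops: Sequence[CoverageDrop]) -> list[GeneDropSummary]:
    """Group drops by gene; summaries sorted by total affected bases, descending."""
    by_gene: dict[str, list[CoverageDrop]] = {}
    for dr in drops:
        by_gene.setdefault(dr.gene, []).append(dr)
    summaries = [
        GeneDropSummary(
            gene=gene,
            n_drops=len(members),
            total_bp=sum(m.width for m in members),
            affected_exons=len({m.region_id for m in members}),
            samples_affected=len({m.sample for m in members}),
        )
        for gene, members in by_gene.items()
    ]
    summaries.sort(key=lambda s: (-s.total_bp, s.gene))
    return summaries


def export_drops(
    drops: Sequence[CoverageDrop],
    summaries: Sequence[GeneDropSummary],
    out_dir: str | Path,
    prefix: str = "drops",
) -> dict[str, Path]:
    """Write the drops BED, the gene-level TSV and the browser track file.

    BED names are ``gene:region_id:sample``; scores ``round(1000*(1-ratio))``
    so deeper drops score higher.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = [
        (
            GenomicRegion(dr.chrom, dr.start, dr.end, dr.region_id, dr.gene),
            f"{dr.gene}:{dr.region_id}:{dr.sample}",
            round(1000 * (1 - dr.ratio)),
        )
        for dr in drops
    ]
    bed_path = out_dir / f"{prefix}.bed"
    write_bed(records, bed_path, autosort=True)
    track_path = out_dir / f"{prefix}.track.bed"
    write_track(records, track_path, "covqc_coverage_drops",
                "narrow coverage drops within covered exons", autosort=True)
    tsv_path = out_dir / f"{prefix}.genes.tsv"
    pd.DataFrame(
        [
            {
                "gene": s.gene,
                "n_drops": s.n_drops,
                "total_bp": s.total_bp,
                "affected_exons": s.affected_exons,
                "samples_affected": s.samples_affected,
            }
            for s in summaries
        ],
        columns=["gene", "n_drops", "total_bp", "affected_exons", "samples_affected"],
    ).to_csv(tsv_path, sep="\t", index=False)
    return {"bed": bed_path, "track": track_path, "genes": tsv_path}
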