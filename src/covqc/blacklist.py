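"""Region blacklisting: exons with unreliable coverage at a given depth.

A region is blacklisted at depth D when its MPC (median percent coverage
across samples) falls strictly below the threshold (default 75%); a region
at exactly the threshold is kept, mirroring the inclusive ">= 75%" quality
rule.  Blacklists are emitted one BED per depth, because blacklisted
regions may harbor false-negative variant calls and must be tracked per
evaluation depth.  Since percent coverage is non-increasing in depth,
blacklists are nested: a region blacklisted at some depth is blacklisted
at every greater depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .coverage import MPCProfile
from .io import GenomicRegion, write_bed, write_track

__all__ = ["BlacklistEntry", "blacklist_regions", "write_blacklists"]


@dataclass
class BlacklistEntry:
    region: GenomicRegion
    depth: int
    mpc: float
    reason: str


def blacklist_regions(
    profile: MPCProfile,
    depths: tuple[int, ...] | None = None,
    threshold: float = 75.0,
) -> dict[int, list[BlacklistEntry]]:
    """Per-depth blacklists: regions with MPC < ``threshold`` at that depth.

    Entries are sorted by (chrom, start); the BED score convention is
    ``round(10 * MPC)`` so a score of 750 marks the rule boundary.
    """
    depths = depths or profile.depths
    missing = [d for d in depths if d not in profile.depths]
    if missing:
        raise KeyError(f"depths {missing} not present in MPC profile")
    out: dict[int, list[BlacklistEntry]] = {}
    for d in depths:
        k = profile.depth_index(d)
        entries = [
            BlacklistEntry(
                region=r,
                depth=d,
                mpc=float(profile.values[i, k]),
                reason=f"MPC {profile.values[i, k]:.2f} < {threshold:g} at {d}X",
            )
            for i, r in enumerate(profile.regions)
            if profile.values[i, k] < threshold
        ]
        entries.sort(key=lambda e: (e.region.chrom, e.region.start))
        out[d] = entries
    return out


def write_blacklists(
    blacklists: dict[int, list[BlacklistEntry]],
    out_dir: str | Path,
    run_type: str = "DNA",
    track: bool = False,
) -> list[Path]:
    """Write one BED per depth (``blacklist.<runtype>.<depth>X.bed``).

    With ``track=True`` an additional combined browser track file is
    written containing all depths' entries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for depth, entries in sorted(blacklists.items()):
        path = out_dir / f"blacklist.{run_type}.{depth}X.bed"
        records = [(e.region, e.region.region_id, round(10 * e.mpc)) for e in entries]
        write_bed(records, path)
        written.append(path)
    if track:
        path = out_dir / f"blacklist.{run_type}.track.bed"
        records = [
            (e.region, f"{e.region.region_id}:{depth}X", round(10 * e.mpc))
            for depth, entries in sorted(blacklists.items())
            for e in entries
        ]
        write_track(records, path, f"covqc_blacklist_{run_type}",
                    "regions with unreliable coverage", autosort=True)
        written.append(path)
    return written
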