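"""Reading and writing coverage-QC file formats.

The central input is the "covdata" table produced by a per-region depth
counter (e.g. mosdepth thresholds output): one row per target region
(typically an exon) with the number of bases covered at or above each of a
set of depth thresholds.  Two dialects are accepted:

* **per-sample** — one TSV per sample; columns ``chrom start end region``
  followed by one column per depth threshold named ``<n>X`` (case
  insensitive, an optional ``_depth``/`` depth`` suffix is tolerated);
* **wide** — one TSV for a whole run with depth columns prefixed by the
  sample name, ``<sample>_<n>X``.

All coordinates are BED-convention 0-based half-open; region length is
``end - start``.  Per-base depth tracks are BED4 run-length encodings
(chrom, start, end, depth); bases absent from the track have depth 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "CovDataTable",
    "PerBaseProfile",
    "CovDataFormatError",
    "CovDataValidationError",
    "parse_gene",
    "read_covdata",
    "write_covdata",
    "read_bed",
    "write_bed",
    "write_track",
    "read_perbase",
]

_DEPTH_COL = re.compile(r"^(\d+)\s*X(?:[ _]?depth)?$", re.IGNORECASE)
_WIDE_COL = re.compile(r"^(.+?)[ _](\d+)\s*X(?:[ _]?depth)?$", re.IGNORECASE)

#: accepted header names for the four mandatory region columns
_REGION_ALIASES = {
    "chrom": {"chrom", "chr", "chromosome", "#chrom"},
    "start": {"start", "region_start", "exon_start"},
    "end": {"end", "region_end", "exon_end"},
    "region_id": {"region", "region_id", "name", "id"},
}


class CovDataFormatError(ValueError):
    """A covdata/BED file does not match the expected layout."""


class CovDataValidationError(ValueError):
    """A covdata table violates an internal invariant (counts vs length)."""


def parse_gene(region_id: str, separator: str = "_") -> str:
    """Gene symbol from a region identifier.

    The gene is the prefix of ``region_id`` before the first ``separator``;
    the whole id if the separator is absent.

    >>> parse_gene("BRCA1_exon24")
    'BRCA1'
    >>> parse_gene("TP53")
    'TP53'
    """
    idx = region_id.find(separator)
    return region_id if idx < 0 else region_id[:idx]


@dataclass(frozen=True)
class GenomicRegion:
    """A target region (exon) in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    region_id: str
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.region_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if not self.gene:
            object.__setattr__(self, "gene", parse_gene(self.region_id))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.region_id)


@dataclass
class PerBaseProfile:
    """Per-base integer depths over one region for one sample."""

    region: GenomicRegion
    depths: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.shape != (self.region.length,):
            raise ValueError(
                f"profile length {self.depths.size} != region length "
                f"{self.region.length} for {self.region.region_id!r}"
            )
        if (self.depths < 0).any():
            raise ValueError("per-base depths must be non-negative")


@dataclass
class CovDataTable:
    """Per-region base counts at each depth threshold, per sample.

    ``counts[i, j, k]`` is the number of bases of region ``i`` covered at
    depth ``>= depths[k]`` in sample ``j``.  Counts are bounded by region
    length and non-increasing along the depth axis.
    """

    regions: list[GenomicRegion]
    samples: list[str]
    depths: tuple[int, ...]
    counts: np.ndarray  # (n_regions, n_samples, n_depths), int64

    def __post_init__(self) -> None:
        self.depths = tuple(int(d) for d in self.depths)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expect = (len(self.regions), len(self.samples), len(self.depths))
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != {expect}")
        if list(self.depths) != sorted(set(self.depths)):
            raise ValueError("depths must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=np.int64)

    def validate(self, lenient: bool = False) -> list[str]:
        """Check count ≤ length and depth monotonicity.

        Returns warning strings under ``lenient``; raises
        :class:`CovDataValidationError` otherwise.
        """
        problems: list[str] = []
        lengths = self.lengths[:, None, None]
        over = np.argwhere(self.counts > lengths)
        for i, j, k in over[:20]:
            problems.append(
                f"count {self.counts[i, j, k]} exceeds length "
                f"{self.regions[i].length} (region {self.regions[i].region_id!r}, "
                f"sample {self.samples[j]!r}, depth {self.depths[k]}X)"
            )
        if self.counts.shape[2] > 1:
            nonmono = np.argwhere(np.diff(self.counts, axis=2) > 0)
            for i, j, k in nonmono[:20]:
                problems.append(
                    f"counts increase from {self.depths[k]}X to "
                    f"{self.depths[k + 1]}X (region "
                    f"{self.regions[i].region_id!r}, sample {self.samples[j]!r})"
                )
        if problems and not lenient:
            raise CovDataValidationError("; ".join(problems))
        return problems

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CovDataTable):
            return NotImplemented
        return (
            self.regions == other.regions
            and self.samples == other.samples
            and self.depths == other.depths
            and np.array_equal(self.counts, other.counts)
        )


def _canon_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical region-column names to actual header names."""
    mapping: dict[str, str] = {}
    lowered = {c.strip().lower(): c for c in columns}
    for canon, aliases in _REGION_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canon] = lowered[alias]
                break
    return mapping


def _detect_dialect(columns: Sequence[str], region_cols: dict[str, str]) -> str:
    extra = [c for c in columns if c not in region_cols.values()]
    if extra and all(_DEPTH_COL.match(c.strip()) for c in extra):
        return "per-sample"
    if extra and all(_WIDE_COL.match(c.strip()) for c in extra):
        return "wide"
    raise CovDataFormatError(
        "cannot detect covdata dialect from columns: " + ", ".join(extra or columns)
    )


def read_covdata(
    path: str | Path | Sequence[str | Path],
    dialect: str = "auto",
    samples: Sequence[str] | None = None,
    gene_separator: str = "_",
    lenient: bool = False,
) -> CovDataTable:
    """Read covdata TSV file(s) into a :class:`CovDataTable`.

    Parameters
    ----------
    path
        A single file, or a sequence of per-sample files whose rows are
        aligned by region key (chrom, start, end, region_id).
    dialect
        ``"per-sample"``, ``"wide"`` or ``"auto"`` (detected per file from
        the header).
    samples
        Sample names for per-sample files; defaults to the file stems.
    lenient
        Demote count/monotonicity violations to warnings.
    """
    paths = [Path(path)] if isinstance(path, (str, Path)) else [Path(p) for p in path]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"covdata file not found: {p}")

    frames: list[tuple[str, pd.DataFrame, dict[int, str]]] = []
    for idx, p in enumerate(paths):
        df = pd.read_csv(p, sep="\t", dtype={0: str})
        region_cols = _canon_columns(df.columns)
        missing = [c for c in ("chrom", "start", "end", "region_id") if c not in region_cols]
        if missing:
            raise CovDataFormatError(
                f"{p}: missing mandatory column(s): {', '.join(missing)}"
            )
        file_dialect = dialect if dialect != "auto" else (
            _detect_dialect(df.columns, region_cols) if len(df.columns) > 4 else "per-sample"
        )
        if file_dialect == "per-sample":
            depth_of: dict[str, int] = {}
            for c in df.columns:
                m = _DEPTH_COL.match(c.strip())
                if m:
                    depth_of[c] = int(m.group(1))
            if not depth_of:
                raise CovDataFormatError(f"{p}: no depth columns (expected e.g. '100X')")
            name = samples[idx] if samples is not None else p.stem
            frames.append((file_dialect, df.rename(columns={v: k for k, v in region_cols.items()}),
                           {"__sample__": name, "__depths__": depth_of}))
        elif file_dialect == "wide":
            if len(paths) > 1:
                raise CovDataFormatError("wide dialect expects a single file")
            frames.append((file_dialect, df.rename(columns={v: k for k, v in region_cols.items()}),
                           {}))
        else:
            raise CovDataFormatError(f"unknown dialect {file_dialect!r}")

    if frames and frames[0][0] == "wide":
        return _assemble_wide(frames[0][1], gene_separator, lenient)
    return _assemble_per_sample(frames, gene_separator, lenient)


def _regions_from_frame(df: pd.DataFrame, gene_separator: str) -> list[GenomicRegion]:
    regions = [
        GenomicRegion(str(c), int(s), int(e), str(r), parse_gene(str(r), gene_separator))
        for c, s, e, r in zip(df["chrom"], df["start"], df["end"], df["region_id"])
    ]
    seen: set[tuple] = set()
    for r in regions:
        if r.key in seen:
            raise CovDataValidationError(f"duplicate region key {r.key}")
        seen.add(r.key)
    return regions


def _assemble_per_sample(frames, gene_separator: str, lenient: bool) -> CovDataTable:
    ref_regions: list[GenomicRegion] | None = None
    all_samples: list[str] = []
    per_sample_counts: list[np.ndarray] = []
    ref_depths: tuple[int, ...] | None = None
    for _, df, meta in frames:
        regions = _regions_from_frame(df, gene_separator)
        if ref_regions is None:
            ref_regions = regions
        elif [r.key for r in regions] != [r.key for r in ref_regions]:
            # align by key; all files must cover the same region set
            order = {r.key: i for i, r in enumerate(ref_regions)}
            if set(r.key for r in regions) != set(order):
                raise CovDataValidationError(
                    f"sample {meta['__sample__']!r}: region set differs from first file"
                )
            df = df.iloc[np.argsort([order[r.key] for r in regions])].reset_index(drop=True)
            regions = _regions_from_frame(df, gene_separator)
        depth_of = meta["__depths__"]
        depths = tuple(sorted(depth_of.values()))
        if ref_depths is None:
            ref_depths = depths
        elif depths != ref_depths:
            raise CovDataFormatError("depth grids differ across per-sample files")
        col_for = {d: c for c, d in depth_of.items()}
        counts = np.column_stack(
            [df[col_for[d]].to_numpy(dtype=np.int64) for d in depths]
        ) if len(df) else np.empty((0, len(depths)), dtype=np.int64)
        all_samples.append(meta["__sample__"])
        per_sample_counts.append(counts)
    assert ref_regions is not None and ref_depths is not None
    counts = (
        np.stack(per_sample_counts, axis=1)
        if per_sample_counts
        else np.empty((0, 0, 0), dtype=np.int64)
    )
    table = CovDataTable(ref_regions, all_samples, ref_depths, counts)
    table.validate(lenient=lenient)
    return table


def _assemble_wide(df: pd.DataFrame, gene_separator: str, lenient: bool) -> CovDataTable:
    regions = _regions_from_frame(df, gene_separator)
    cols: dict[str, dict[int, str]] = {}
    for c in df.columns:
        if c in ("chrom", "start", "end", "region_id"):
            continue
        m = _WIDE_COL.match(c.strip())
        if not m:
            raise CovDataFormatError(f"unparseable wide depth column: {c!r}")
        cols.setdefault(m.group(1), {})[int(m.group(2))] = c
    samples = sorted(cols)
    depth_sets = {tuple(sorted(v)) for v in cols.values()}
    if len(depth_sets) > 1:
        raise CovDataFormatError("samples carry different depth grids in wide file")
    depths = depth_sets.pop() if depth_sets else ()
    counts = np.empty((len(regions), len(samples), len(depths)), dtype=np.int64)
    for j, s in enumerate(samples):
        for k, d in enumerate(depths):
            counts[:, j, k] = df[cols[s][d]].to_numpy(dtype=np.int64)
    table = CovDataTable(regions, samples, depths, counts)
    table.validate(lenient=lenient)
    return table


def write_covdata(
    table: CovDataTable,
    path: str | Path,
    dialect: str = "wide",
    sample: str | None = None,
) -> None:
    """Write a covdata table as TSV (``wide``, or ``per-sample`` for one sample)."""
    path = Path(path)
    base = {
        "chrom": [r.chrom for r in table.regions],
        "start": [r.start for r in table.regions],
        "end": [r.end for r in table.regions],
        "region_id": [r.region_id for r in table.regions],
    }
    df = pd.DataFrame(base)
    if dialect == "wide":
        for j, s in enumerate(table.samples):
            for k, d in enumerate(table.depths):
                df[f"{s}_{d}X"] = table.counts[:, j, k]
    elif dialect == "per-sample":
        if sample is None:
            raise ValueError("per-sample dialect requires sample=")
        j = table.samples.index(sample)
        for k, d in enumerate(table.depths):
            df[f"{d}X"] = table.counts[:, j, k]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and browser tracks

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (track/browser/comment lines skipped).

    Returns columns ``chrom start end`` plus ``name``/``score`` when present.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    width = max(len(r) for r in rows)
    names = ["chrom", "start", "end", "name", "score"][:width]
    df = pd.DataFrame(rows, columns=names + [f"extra{i}" for i in range(width - len(names))])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "score" in df:
        df["score"] = pd.to_numeric(df["score"])
    return df


BedRecord = tuple  # (GenomicRegion, name, score) — score may be None


def _bed_lines(records: Iterable[BedRecord], autosort: bool) -> list[str]:
    recs = list(records)
    keys = [(r[0].chrom, r[0].start) for r in recs]
    if keys != sorted(keys):
        if not autosort:
            raise ValueError("BED records not sorted by (chrom, start); pass autosort=True")
        recs = [r for _, r in sorted(zip(keys, recs), key=lambda t: t[0])]
    lines = []
    for region, name, score in recs:
        cols = [region.chrom, str(region.start), str(region.end), str(name)]
        if score is not None:
            if not 0 <= score <= 1000:
                raise ValueError(f"BED score {score} outside [0, 1000]")
            cols.append(str(int(round(score))))
        lines.append("\t".join(cols))
    return lines


def write_bed(records: Iterable[BedRecord], path: str | Path, autosort: bool = False) -> None:
    """Write (region, name, score) records as a headerless BED file."""
    Path(path).write_text("".join(line + "\n" for line in _bed_lines(records, autosort)))


def write_track(
    records: Iterable[BedRecord],
    path: str | Path,
    track_name: str,
    description: str = "",
    autosort: bool = False,
) -> None:
    """Write a Genome Browser track: a ``track`` declaration line + BED body."""
    header = f'track name="{track_name}" description="{description or track_name}"\n'
    body = "".join(line + "\n" for line in _bed_lines(records, autosort))
    Path(path).write_text(header + body)


# ---------------------------------------------------------------------------
# Per-base depth tracks

def read_perbase(
    path: str | Path,
    targets: Sequence[GenomicRegion],
    sample: str = "",
) -> list[PerBaseProfile]:
    """Materialize per-region depth arrays from a run-length BED4 track.

    The track holds (chrom, start, end, depth) runs; target regions supply
    the windows of interest.  Bases with no run get depth 0.  Overlapping
    runs on one chromosome are a validation error.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
    ) if Path(path).stat().st_size else pd.DataFrame(
        columns=["chrom", "start", "end", "depth"]
    )
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start").reset_index(drop=True)
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise CovDataValidationError(f"overlapping depth runs on {chrom} in {path}")
        by_chrom[str(chrom)] = sub
    profiles = []
    for region in targets:
        depths = np.zeros(region.length, dtype=np.int64)
        sub = by_chrom.get(region.chrom)
        if sub is not None:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            vals = sub["depth"].to_numpy()
            lo = np.searchsorted(ends, region.start, side="right")
            hi = np.searchsorted(starts, region.end, side="left")
            for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
                a = max(s, region.start) - region.start
                b = min(e, region.end) - region.start
                if b > a:
                    depths[a:b] = v
        profiles.append(PerBaseProfile(region, depths, sample))
    return profiles


def write_perbase(profiles: Sequence[PerBaseProfile], path: str | Path) -> None:
    """Run-length encode per-base profiles to a BED4 track (zero runs kept)."""
    lines = []
    for prof in sorted(profiles, key=lambda p: (p.region.chrom, p.region.start)):
        d = prof.depths
        if d.size == 0:
            continue
        change = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [d.size]))
        for a, b in zip(starts, ends):
            lines.append(
                f"{prof.region.chrom}\t{prof.region.start + a}\t"
                f"{prof.region.start + b}\t{d[a]}"
            )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_targets_bed(path: str | Path, gene_separator: str = "_") -> list[GenomicRegion]:
    """Read a target-regions BED into :class:`GenomicRegion` objects."""
    df = read_bed(path)
    regions = []
    for i, row in df.iterrows():
        rid = str(row["name"]) if "name" in df.columns and pd.notna(row.get("name")) else f"region{i}"
        regions.append(
            GenomicRegion(str(row["chrom"]), int(row["start"]), int(row["end"]),
                          rid, parse_gene(rid, gene_separator))
        )
    return regions
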