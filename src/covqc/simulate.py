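"""Synthetic coverage and wet-metric data with known ground truth.

The per-base generator emulates the two broad coverage-profile classes
seen on hybridization-capture panels:

* **high-coverage** — a flat plateau over the exon interior with a gradual
  decay ramp at the exon edges (the within-target tail of the decay beyond
  the exon-intron boundary) plus integer read-depth noise;
* **low-coverage** — the plateau scaled down, irregular, with coverage
  breakoffs starting before the exon boundaries that leave stretches of
  near-zero signal.

On top of these the generator can inject rectangular narrow drops into
high-coverage exons, force chosen regions below the 75% MPC rule at the
deepest evaluation depth, and force chosen samples below the Q1 rule at a
chosen depth — each injection is recorded in the emitted
:class:`GroundTruth` so detector outputs can be compared against what was
planted.  Region-level covdata counts are always derived from the per-base
profiles by direct thresholding, so base-level and region-level views
describe the same world.

The wet-metric generator draws per-sample metric values around per-run
medians (lognormal for positive-valued metrics, normal otherwise) with
optional multiplicative run effects, and paired pre-capture/enriched
library concentrations with a configurable median decrease.  Default
scales mimic a clinical FFPE validation cohort (DNA plateau median
~648X, pre-capture ~48.7 ng/ul falling to ~18.5 ng/ul after enrichment).

All randomness flows through one ``numpy`` generator seeded from the
config; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CovDataTable,
    GenomicRegion,
    PerBaseProfile,
    write_bed,
    write_covdata,
    write_perbase,
)

__all__ = [
    "SimulationConfig",
    "MetricSpec",
    "MetricsConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_perbase",
    "simulate_covdata",
    "simulate_dataset",
    "simulate_metrics",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Coverage-world parameters; defaults describe a DNA-like panel run."""

    n_samples: int = 8
    n_genes: int = 12
    exons_per_gene: int = 4
    exon_length_range: tuple[int, int] = (120, 300)
    depths: tuple[int, ...] = (5, 10, 50, 100, 250, 500)
    high_fraction: float = 0.9  # fraction of exons with the high-coverage profile
    plateau_median: float = 648.0  # X-fold; per-region plateaus are lognormal around this
    plateau_sigma: float = 0.30  # lognormal sigma of per-region plateau
    sample_sigma: float = 0.08  # lognormal sigma of per-sample plateau factor
    boundary_decay: int = 15  # bp of edge ramp inside the exon
    edge_floor: float = 0.5  # ramp starts at this fraction of the plateau
    noise_sd_frac: float = 0.05  # integer noise sd as a fraction of the plateau
    low_scale_range: tuple[float, float] = (0.05, 0.4)
    n_drops: int = 0  # rectangular drops injected into high exons (per dataset)
    drop_width_range: tuple[int, int] = (11, 30)
    drop_ratio_range: tuple[float, float] = (0.05, 0.25)
    force_blacklist: dict[int, int] = field(default_factory=dict)  # depth -> k regions
    force_flagged: dict[int, int] = field(default_factory=dict)  # depth -> k samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.high_fraction <= 1:
            raise ValueError("high_fraction must lie in [0, 1]")
        if self.drop_width_range[0] < 1:
            raise ValueError("drop widths must be >= 1")
        lo, hi = self.exon_length_range
        if self.n_drops and self.drop_width_range[1] > lo - 2 * self.boundary_decay - 4:
            raise ValueError("drop spec infeasible: widths exceed usable exon interior")
        if list(self.depths) != sorted(set(self.depths)):
            raise ValueError("depths must be strictly increasing")


@dataclass
class GroundTruth:
    """What was planted: the reference answer for every detector."""

    depleted_regions: dict[int, list[str]] = field(default_factory=dict)
    flagged_samples: dict[int, list[str]] = field(default_factory=dict)
    drops: list[dict] = field(default_factory=list)
    low_regions: list[str] = field(default_factory=list)
    metric_medians: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SimulatedDataset:
    targets: list[GenomicRegion]
    profiles: dict[str, list[PerBaseProfile]]  # sample -> per-region profiles
    covdata: CovDataTable
    truth: GroundTruth
    config: SimulationConfig


def _layout_regions(cfg: SimulationConfig, rng: np.random.Generator) -> list[GenomicRegion]:
    regions = []
    cursor = 10_000
    for g in range(cfg.n_genes):
        gene = f"GENE{g:03d}"
        for e in range(cfg.exons_per_gene):
            length = int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1))
            rid = f"{gene}_ex{e + 1}"
            regions.append(GenomicRegion("chr1", cursor, cursor + length, rid, gene))
            cursor += length + int(rng.integers(500, 2000))
    return regions


def _high_profile(length: int, plateau: float, cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    base = np.full(length, plateau, dtype=float)
    w = min(cfg.boundary_decay, length // 4)
    if w > 0:
        ramp = np.linspace(cfg.edge_floor * plateau, plateau, w, endpoint=False)
        base[:w] = ramp
        base[-w:] = ramp[::-1]
    noise = rng.normal(0.0, cfg.noise_sd_frac * plateau, size=length)
    return np.maximum(np.rint(base + noise), 0).astype(np.int64)


def _low_profile(length: int, plateau: float, cfg: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    scale = rng.uniform(*cfg.low_scale_range)
    level = scale * plateau
    base = np.full(length, level, dtype=float)
    # breakoffs: near-zero stretches growing inward from the edges
    for edge in (0, 1):
        if rng.random() < 0.8:
            frac = rng.uniform(0.1, 0.4)
            span = max(1, int(frac * length))
            seg = slice(0, span) if edge == 0 else slice(length - span, length)
            base[seg] = rng.uniform(0.0, 0.1) * level
    noise = rng.normal(0.0, 0.2 * level, size=length)
    return np.maximum(np.rint(base + noise), 0).astype(np.int64)


def _forced_split(length: int, low_value: int, high_value: int) -> np.ndarray:
    """Half the bases below the target depth, half far above it."""
    n_low = length // 2 + 1  # strictly more than half below -> p < 75 guaranteed
    arr = np.full(length, high_value, dtype=np.int64)
    mid = (length - n_low) // 2
    arr[mid:mid + n_low] = low_value
    return arr


def simulate_perbase(
    config: SimulationConfig,
) -> tuple[list[GenomicRegion], dict[str, list[PerBaseProfile]], GroundTruth]:
    """Generate per-base depth profiles for every (sample, region).

    Returns the target regions, per-sample profile lists (aligned with the
    region list) and the ground truth of everything injected.
    """
    rng = np.random.default_rng(config.seed)
    regions = _layout_regions(config, rng)
    n_regions = len(regions)
    samples = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    truth = GroundTruth()

    # per-region class and plateau (shared across samples)
    is_high = rng.random(n_regions) < config.high_fraction
    plateaus = config.plateau_median * np.exp(
        config.plateau_sigma * rng.standard_normal(n_regions)
    )

    grid = list(config.depths)
    max_depth = grid[-1]

    # regions forced below the MPC rule at a chosen depth (use the deepest
    # grid depth: percent coverage is monotone in depth, so depletion at a
    # shallower depth necessarily propagates to all deeper ones)
    forced_region_idx: dict[int, list[int]] = {}
    pool = list(range(n_regions))
    for depth, k in sorted(config.force_blacklist.items()):
        chosen = list(rng.choice(pool, size=k, replace=False))
        pool = [i for i in pool if i not in chosen]
        forced_region_idx[depth] = [int(i) for i in chosen]
        truth.depleted_regions[depth] = [regions[i].region_id for i in chosen]
        for i in chosen:
            is_high[i] = True  # handled specially below

    forced_sample_idx: dict[int, list[int]] = {}
    spool = list(range(config.n_samples))
    for depth, k in sorted(config.force_flagged.items()):
        chosen = list(rng.choice(spool, size=k, replace=False))
        spool = [j for j in spool if j not in chosen]
        forced_sample_idx[depth] = [int(j) for j in chosen]
        truth.flagged_samples[depth] = [samples[j] for j in chosen]

    truth.low_regions = [regions[i].region_id for i in range(n_regions) if not is_high[i]]

    # drop injection plan: (region, sample, offset, width, ratio)
    drop_plan: dict[tuple[int, int], list[tuple[int, int, float]]] = {}
    forced_any = {i for idxs in forced_region_idx.values() for i in idxs}
    eligible = [i for i in range(n_regions) if is_high[i] and i not in forced_any]
    for _ in range(config.n_drops):
        if not eligible:
            break
        i = int(rng.choice(eligible))
        j = int(rng.integers(config.n_samples))
        width = int(rng.integers(config.drop_width_range[0], config.drop_width_range[1] + 1))
        ratio = float(rng.uniform(*config.drop_ratio_range))
        margin = min(config.boundary_decay, regions[i].length // 4) + 2
        lo, hi = margin, regions[i].length - margin - width
        if hi <= lo:
            continue
        offset = int(rng.integers(lo, hi))
        key = (i, j)
        # keep drops within one (region, sample) disjoint with >=2 bases gap
        clash = any(not (offset + width + 2 <= o or o + w + 2 <= offset)
                    for o, w, _ in drop_plan.get(key, []))
        if clash:
            continue
        drop_plan.setdefault(key, []).append((offset, width, ratio))
        truth.drops.append(
            {
                "region_id": regions[i].region_id,
                "sample": samples[j],
                "chrom": regions[i].chrom,
                "start": regions[i].start + offset,
                "end": regions[i].start + offset + width,
                "width": width,
                "ratio": ratio,
            }
        )

    # regions a forced-flagged sample depletes (same set for every forced sample
    # at one depth; >25% of regions so Q1 falls below the rule)
    flag_regions: dict[int, list[int]] = {}
    for depth in forced_sample_idx:
        m = max(1, int(np.ceil(0.35 * n_regions)))
        flag_regions[depth] = [int(i) for i in rng.choice(n_regions, size=m, replace=False)]

    profiles: dict[str, list[PerBaseProfile]] = {s: [] for s in samples}
    for j, s in enumerate(samples):
        sample_factor = float(np.exp(config.sample_sigma * rng.standard_normal()))
        for i, region in enumerate(regions):
            forced_depth = next(
                (d for d, idxs in forced_region_idx.items() if i in idxs), None
            )
            flag_depth = next(
                (d for d, js in forced_sample_idx.items()
                 if j in js and i in flag_regions[d]),
                None,
            )
            if forced_depth is not None:
                gpos = grid.index(forced_depth)
                lower = grid[gpos - 1] if gpos else 0
                arr = _forced_split(region.length, (lower + forced_depth) // 2,
                                    2 * max_depth)
            elif flag_depth is not None:
                gpos = grid.index(flag_depth)
                lower = grid[gpos - 1] if gpos else 0
                arr = _forced_split(region.length, (lower + flag_depth) // 2,
                                    2 * max_depth)
            elif is_high[i]:
                plateau = plateaus[i] * sample_factor
                arr = _high_profile(region.length, plateau, config, rng)
                for offset, width, ratio in drop_plan.get((i, j), []):
                    depth_val = max(0, int(round(ratio * plateau)))
                    arr[offset:offset + width] = depth_val
            else:
                arr = _low_profile(region.length, plateaus[i] * sample_factor,
                                   config, rng)
            profiles[s].append(PerBaseProfile(region, arr, s))
    return regions, profiles, truth


def covdata_from_profiles(
    regions: list[GenomicRegion],
    profiles: dict[str, list[PerBaseProfile]],
    depths: tuple[int, ...],
) -> CovDataTable:
    """Threshold per-base profiles into a covdata count table."""
    samples = list(profiles)
    counts = np.empty((len(regions), len(samples), len(depths)), dtype=np.int64)
    for j, s in enumerate(samples):
        for i, prof in enumerate(profiles[s]):
            for k, d in enumerate(depths):
                counts[i, j, k] = int((prof.depths >= d).sum())
    return CovDataTable(regions, samples, tuple(depths), counts)


def simulate_covdata(config: SimulationConfig) -> tuple[CovDataTable, GroundTruth]:
    """Covdata derived by thresholding simulated per-base profiles."""
    regions, profiles, truth = simulate_perbase(config)
    return covdata_from_profiles(regions, profiles, config.depths), truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full consistent world: targets, per-base profiles, covdata, truth."""
    regions, profiles, truth = simulate_perbase(config)
    covdata = covdata_from_profiles(regions, profiles, config.depths)
    return SimulatedDataset(regions, profiles, covdata, truth, config)


# ---------------------------------------------------------------------------
# Wet / sequencing metrics


@dataclass(frozen=True)
class MetricSpec:
    """Distribution of one metric: median, spread, nucleic type, law."""

    name: str
    median: float
    sigma: float  # lognormal sigma, or sd for normal metrics
    nucleic: str = "DNA"
    dist: str = "lognormal"  # or "normal"


#: default wet-metric panel on clinical FFPE validation scales
DEFAULT_DNA_METRICS: tuple[MetricSpec, ...] = (
    MetricSpec("concentration", 17.1, 0.8, "DNA"),
    MetricSpec("a260_280", 1.97, 0.05, "DNA", "normal"),
    MetricSpec("a260_230", 0.67, 0.6, "DNA"),
    MetricSpec("delta_cq", 0.3, 1.5, "DNA", "normal"),
    MetricSpec("fragment_size", 232.0, 0.15, "DNA"),
    MetricSpec("median_insert_size", 113.0, 0.12, "DNA"),
    MetricSpec("coverage_mad", 0.161, 0.25, "DNA"),
)

DEFAULT_RNA_METRICS: tuple[MetricSpec, ...] = (
    MetricSpec("concentration", 66.0, 0.7, "RNA"),
    MetricSpec("a260_280", 1.96, 0.1, "RNA", "normal"),
    MetricSpec("a260_230", 1.36, 0.6, "RNA"),
    MetricSpec("dv200", 63.7, 16.7, "RNA", "normal"),
)


@dataclass(frozen=True)
class MetricsConfig:
    """Wet-metric world: five runs of 16 preparations by default.

    ``run_effects`` maps a metric name to per-run multiplicative shifts of
    its median (length ``n_runs``); absent metrics have no run effect.
    Paired library concentrations fall from ``pre_capture_median`` to
    ``enriched_ratio`` times it after target enrichment.
    """

    n_runs: int = 5
    samples_per_run: int = 16
    nucleic: str = "DNA"
    metrics: tuple[MetricSpec, ...] = DEFAULT_DNA_METRICS
    run_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    pre_capture_median: float = 48.7
    enriched_ratio: float = 0.38  # DNA-like decrease; RNA-like would be ~0.13
    library_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.metrics:
            if m.dist == "lognormal" and m.median <= 0:
                raise ValueError(f"metric {m.name!r}: lognormal median must be > 0")
        for name, eff in self.run_effects.items():
            if len(eff) != self.n_runs:
                raise ValueError(f"run_effects[{name!r}] must have length {self.n_runs}")


def simulate_metrics(config: MetricsConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a long-format metrics table with known per-run medians.

    Includes the paired ``pre_capture`` / ``enriched`` library metrics with
    the configured median decrease.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    rows = []
    sample_no = 0
    for run in range(1, config.n_runs + 1):
        names = [f"{config.nucleic}{sample_no + i + 1:03d}"
                 for i in range(config.samples_per_run)]
        sample_no += config.samples_per_run
        for spec in config.metrics:
            shift = config.run_effects.get(spec.name, (1.0,) * config.n_runs)[run - 1]
            med = spec.median * shift if spec.dist == "lognormal" else spec.median + (shift - 1.0)
            truth.metric_medians.setdefault(spec.name, {})[str(run)] = med
            if spec.dist == "lognormal":
                vals = med * np.exp(spec.sigma * rng.standard_normal(len(names)))
            else:
                vals = med + spec.sigma * rng.standard_normal(len(names))
            for name, v in zip(names, vals):
                rows.append((name, run, spec.nucleic, spec.name, float(v)))
        pre = config.pre_capture_median * np.exp(
            config.library_sigma * rng.standard_normal(len(names))
        )
        enr = pre * config.enriched_ratio * np.exp(
            config.library_sigma * rng.standard_normal(len(names))
        )
        truth.metric_medians.setdefault("pre_capture", {})[str(run)] = config.pre_capture_median
        truth.metric_medians.setdefault("enriched", {})[str(run)] = (
            config.pre_capture_median * config.enriched_ratio
        )
        for name, a, b in zip(names, pre, enr):
            rows.append((name, run, config.nucleic, "pre_capture", float(a)))
            rows.append((name, run, config.nucleic, "enriched", float(b)))
    table = pd.DataFrame(rows, columns=["sample", "run", "nucleic", "metric", "value"])
    return table, truth


# ---------------------------------------------------------------------------
# Disk output


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit a simulated world: target BED, per-sample per-base BEDs,
    wide covdata TSV and the ground-truth manifest (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    targets = out_dir / "targets.bed"
    write_bed([(r, r.region_id, None) for r in dataset.targets], targets)
    paths["targets"] = targets
    covdata = out_dir / "covdata.tsv"
    write_covdata(dataset.covdata, covdata, dialect="wide")
    paths["covdata"] = covdata
    for sample, profs in dataset.profiles.items():
        p = out_dir / f"perbase.{sample}.bed"
        write_perbase(profs, p)
        paths[f"perbase.{sample}"] = p
    manifest = out_dir / "ground_truth.json"
    manifest.write_text(dataset.truth.to_json() + "\n")
    paths["ground_truth"] = manifest
    return paths
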