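"""Seeded generators for every input the MPRA pipeline consumes.

The generators emulate the statistical structure of a barcoded lentiviral
reporter assay: negative-binomially distributed DNA/RNA barcode counts over
replicates with region-specific activity multipliers, REF/ALT effect
injection, planted transcription-factor motifs, epigenomic annotation tracks
whose overlap is informative about activity, and trio cohorts carrying
per-participant sets of noncoding de novo variants (ncDNVs).

All randomness flows from a single seed that is expanded into independent
per-generator substreams, so components can be regenerated in isolation
while a full run stays reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy import special

BASES = np.array(list("ACGT"))

# Substream labels: one child seed per generator, derived from SimConfig.seed.
_STREAMS = ("genome", "truth", "counts", "annotations", "cohort", "motifs")


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults describe a desk-scale assay: a few hundred regions, four
    biological replicates, sequencing depth of two million reads per library
    and a mild negative-binomial overdispersion.  Cohort parameters are
    calibrated so a participant carries a median of 8 ncDNVs
    (interquartile range 6-11).
    """

    seed: int = 0
    # genome / regions
    n_regions: int = 300
    region_length: int = 400
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    # counts
    n_replicates: int = 4
    dna_depth: float = 2e6
    rna_depth: float = 2e6
    # default matches the reported assay reproducibility: with these depths
    # and activity spread, replicate activities correlate at Pearson r ~ 0.95
    nb_dispersion: float = 0.01
    abundance_sigma: float = 0.5
    # activity structure
    active_fraction: float = 0.3
    activity_log2fc_range: tuple[float, float] = (1.0, 3.0)
    variant_effect_fraction: float = 0.1
    variant_effect_log2: float = 1.5
    # annotations
    annotation_count: int = 50
    annotation_informative_count: int = 5
    annotation_weight: float = 3.0
    annotation_base_rate: float = 0.15
    # cohorts: per-participant ncDNV counts ~ NB(size, mean) with integer
    # quartiles (6, 8, 11); parameters leave >=0.03 probability margin at
    # each quartile boundary so finite cohorts reproduce them stably
    chd_cohort_size: int = 200
    control_cohort_size: int = 300
    ncdnv_nb_size: float = 12.0
    ncdnv_nb_mean: float = 8.6
    cohort_effect_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("active_fraction", "variant_effect_fraction",
                     "annotation_base_rate", "cohort_effect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.annotation_informative_count > self.annotation_count:
            raise ValueError("informative annotations cannot exceed total")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.region_length < 171:
            raise ValueError("region_length must be at least 171 bp")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream for one generator component."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}; one of {_STREAMS}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS.index(stream)]
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "activity_log2fc_range" in d:
            d["activity_log2fc_range"] = tuple(d["activity_log2fc_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    region_log2_multiplier: dict[str, float] = field(default_factory=dict)
    # pair_id -> signed log2 effect of ALT relative to REF (0 = null pair)
    pair_effect: dict[str, float] = field(default_factory=dict)
    informative_annotations: dict[str, float] = field(default_factory=dict)
    # (motif_id, region_id, offset, strand)
    planted_motifs: list[tuple[str, str, int, str]] = field(default_factory=list)

    def active_regions(self) -> set[str]:
        return {r for r, m in self.region_log2_multiplier.items() if m > 0}


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome plus non-overlapping test regions.

    Returns ``(genome, regions)`` where genome maps chromosome name to
    sequence and regions is a BED-like frame (chrom, start, end, region_id)
    with 0-based half-open coordinates.
    """
    rng = config.rng("genome")
    genome = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=config.chromosome_length))
        for i in range(config.n_chromosomes)
    }
    L, k = config.region_length, config.n_regions
    per_chrom = np.array_split(np.arange(k), config.n_chromosomes)
    capacity = config.chromosome_length // L
    if any(len(ix) > capacity for ix in per_chrom):
        raise ValueError(
            f"cannot place {k} non-overlapping {L} bp regions on "
            f"{config.n_chromosomes} chromosomes of {config.chromosome_length} bp"
        )
    rows = []
    for ci, ix in enumerate(per_chrom):
        m = len(ix)
        # stars-and-bars: sample gaps, then lay regions left to right
        slack = config.chromosome_length - m * L
        gaps = np.sort(rng.choice(slack + 1, size=m, replace=True))
        starts = gaps + np.arange(m) * L
        for j, rid in enumerate(ix):
            rows.append((f"chr{ci + 1}", int(starts[j]), int(starts[j]) + L,
                         f"region_{rid:05d}"))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    return genome, regions


def assign_truth(regions: pd.DataFrame, config: SimConfig,
                 pair_ids: list[str] | None = None) -> GroundTruth:
    """Draw the hidden state: which regions are active and how strongly,
    which REF/ALT pairs carry an effect, and which annotations are
    informative."""
    rng = config.rng("truth")
    truth = GroundTruth()
    lo, hi = config.activity_log2fc_range
    for rid in regions["region_id"]:
        if rng.random() < config.active_fraction:
            truth.region_log2_multiplier[rid] = float(rng.uniform(lo, hi))
        else:
            truth.region_log2_multiplier[rid] = 0.0
    if pair_ids:
        for pid in pair_ids:
            if rng.random() < config.variant_effect_fraction:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                truth.pair_effect[pid] = sign * config.variant_effect_log2
            else:
                truth.pair_effect[pid] = 0.0
    ids = rng.choice(config.annotation_count,
                     size=config.annotation_informative_count, replace=False)
    for i in sorted(ids):
        truth.informative_annotations[f"track_{i:04d}"] = config.annotation_weight
    return truth


def simulate_counts(designs: pd.DataFrame, truth: GroundTruth,
                    config: SimConfig) -> pd.DataFrame:
    """Barcode-level DNA and RNA counts for every design and replicate.

    ``designs`` needs columns ``design_id`` and ``region_id``; an optional
    ``pair_id``/``role`` pair marks ALT members whose multiplier is the
    region multiplier plus the planted pair effect.

    DNA counts are negative binomial around the design's relative plasmid
    abundance times ``dna_depth``; the RNA mean is the DNA relative
    abundance scaled by ``2**log2_multiplier`` times ``rna_depth``.
    Variance follows mu + alpha * mu**2 with alpha = ``nb_dispersion``.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    missing = set(designs["region_id"]) - set(truth.region_log2_multiplier)
    if missing:
        raise KeyError(f"designs reference unknown regions: {sorted(missing)[:3]}")
    rng = config.rng("counts")
    n = len(designs)
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    rel = abundance / abundance.sum()
    mult = np.array([truth.region_log2_multiplier[r] for r in designs["region_id"]])
    if "pair_id" in designs.columns and "role" in designs.columns:
        is_alt = (designs["role"].to_numpy() == "ALT")
        eff = np.array([truth.pair_effect.get(p, 0.0) for p in designs["pair_id"]])
        mult = mult + np.where(is_alt, eff, 0.0)
    dna_mu = rel * config.dna_depth
    rna_mu = rel * np.exp2(mult) * config.rna_depth
    alpha = config.nb_dispersion
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for material, mu in (("DNA", dna_mu), ("RNA", rna_mu)):
            size = 1.0 / alpha                       # var = mu + alpha*mu^2
            counts = rng.negative_binomial(size, size / (size + mu))
            rows.append(pd.DataFrame({
                "design_id": designs["design_id"].to_numpy(),
                "replicate": rep,
                "material": material,
                "count": counts,
            }))
    return pd.concat(rows, ignore_index=True)


def simulate_annotations(regions: pd.DataFrame, truth: GroundTruth,
                         config: SimConfig) -> dict[str, pd.DataFrame]:
    """Annotation tracks (BED intervals + value column).

    Informative tracks overlap a region with probability
    ``sigmoid(logit(base_rate) + weight * 1[region active])``; uninformative
    tracks use the base rate regardless of activity.  Interval values are
    gamma-distributed and non-negative.
    """
    rng = config.rng("annotations")
    base_logit = special.logit(config.annotation_base_rate)
    active = truth.active_regions()
    is_active = regions["region_id"].isin(active).to_numpy()
    chroms = regions["chrom"].to_numpy()
    starts = regions["start"].to_numpy()
    lengths = (regions["end"] - regions["start"]).to_numpy()
    tracks: dict[str, pd.DataFrame] = {}
    for t in range(config.annotation_count):
        tid = f"track_{t:04d}"
        w = truth.informative_annotations.get(tid, 0.0)
        p = special.expit(base_logit + w * is_active.astype(float))
        hit = rng.random(len(regions)) < p
        span = (lengths // 4 + (rng.random(len(regions))
                                * (lengths - lengths // 4 + 1)).astype(int))
        span = np.minimum(span, lengths)
        off = (rng.random(len(regions)) * (lengths - span + 1)).astype(int)
        value = rng.gamma(4.0, 2.0, size=len(regions))
        frame = pd.DataFrame({
            "chrom": chroms[hit],
            "start": (starts + off)[hit],
            "end": (starts + off + span)[hit],
            "value": value[hit],
        })
        tracks[tid] = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    return tracks


def simulate_cohort(config: SimConfig,
                    regions: pd.DataFrame | None = None,
                    truth: GroundTruth | None = None) -> pd.DataFrame:
    """Trio variant tables for a CHD-like and a control-like cohort.

    Per-participant ncDNV counts are negative binomial with parameters fixed
    so the integer quartiles are (6, 8, 11).  When ``regions``/``truth`` are
    supplied, a fraction ``cohort_effect_fraction`` of CHD-cohort variants is
    relocated into active regions (the high-scoring annotation context);
    otherwise the two cohorts are exchangeable.
    """
    if config.chd_cohort_size <= 0 or config.control_cohort_size <= 0:
        raise ValueError("cohort sizes must be positive")
    rng = config.rng("cohort")
    size = config.ncdnv_nb_size
    p = size / (size + config.ncdnv_nb_mean)
    genome_len = config.n_chromosomes * config.chromosome_length
    active = None
    if regions is not None and truth is not None:
        act = regions[regions["region_id"].isin(truth.active_regions())]
        if len(act):
            active = act.reset_index(drop=True)
    rows = []
    for cohort, n_part in (("CHD", config.chd_cohort_size),
                           ("control", config.control_cohort_size)):
        counts = rng.negative_binomial(size, p, size=n_part)
        for i, k in enumerate(counts):
            pid = f"{cohort}_{i:05d}"
            for _ in range(int(k)):
                enriched = (cohort == "CHD" and active is not None
                            and rng.random() < config.cohort_effect_fraction)
                if enriched:
                    reg = active.iloc[int(rng.integers(len(active)))]
                    chrom = reg["chrom"]
                    pos = int(rng.integers(reg["start"], reg["end"])) + 1
                else:
                    flat = int(rng.integers(genome_len))
                    chrom = f"chr{flat // config.chromosome_length + 1}"
                    pos = flat % config.chromosome_length + 1
                ref, alt = rng.choice(BASES, size=2, replace=False)
                rows.append((chrom, pos, ref, alt, pid, cohort))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "participant_id", "cohort"])
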