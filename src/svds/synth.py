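"""Self-contained synthetic genome, annotation tracks, SV sets and cohort.

The generator emulates the statistical structure the scoring framework
assumes, on a toy multi-chromosome genome:

* *functional elements* (genes with exons, enhancers) covering a configurable
  fraction of the genome;
* continuous annotation tracks, one or more per feature group — conservation-
  and constraint-like, integrated scores, epigenetic signal, 3D-architecture
  and element-density tracks — whose values are heavy-tailed nonnegative
  background (Exponential) plus a Gamma-distributed lift inside functional
  elements, resembling conservation/ChIP signal and making the 90th-percentile
  statistic meaningful;
* *proxy-neutral* SV sets depleted of functional overlap (purifying selection
  removed functional hits), one per origin (human/chimp x DEL/INS);
* a *reference cohort* with allele counts, in which a small functional
  fraction is biased toward singleton status (so singleton-enrichment analyses
  have planted signal to find);
* *pathogenic spike-ins* forced to overlap genes, and per-individual SV sets
  for spike-in ranking experiments;
* *alignable regions* covering most of the genome, with gaps simulating
  unalignable sequence.

All randomness flows from ``config.seed`` through fixed per-subtask streams,
so generating one output never perturbs another.  SV lengths share one
log-normal distribution between neutral and cohort sets, so length is not a
synthetic confounder.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import (
    AnnotationTrack,
    DataError,
    ElementCatalog,
    GenomicInterval,
    SVRecord,
    write_catalog,
    write_sv_table,
    write_track,
)

FEATURE_GROUPS = (
    "integrated_scores",
    "conservation_constraint",
    "population_disease_constraint",
    "epigenetics_regulatory",
    "genome_architecture_3d",
    "gene_element_enrichment",
)

#: (name, feature group, Gamma lift scale inside functional elements)
TRACK_SPECS = (
    ("phylo_conservation", "conservation_constraint", 3.0),
    ("element_constraint", "conservation_constraint", 2.0),
    ("integrated_score", "integrated_scores", 2.5),
    ("popgen_constraint", "population_disease_constraint", 1.5),
    ("chip_activity", "epigenetics_regulatory", 2.0),
    ("dna_accessibility", "epigenetics_regulatory", 1.5),
    ("contact_insulation", "genome_architecture_3d", 1.2),
    ("element_density", "gene_element_enrichment", 1.0),
)

ORIGINS = ("human_DEL", "chimp_DEL", "human_INS", "chimp_INS")

# fixed sub-stream identifiers; every generator derives its RNG from
# SeedSequence([config.seed, stream]) so outputs are mutually independent
_STREAM_GENOME = 0
_STREAM_NEUTRAL = {o: 10 + i for i, o in enumerate(ORIGINS)}
_STREAM_COHORT = {"DEL": 20, "INS": 21, "DUP": 22}
_STREAM_PATHOGENIC = {"DEL": 30, "INS": 31, "DUP": 32}
_STREAM_INDIVIDUALS = 40


@dataclass
class SynthConfig:
    """Study conditions of the synthetic world (see docs/methods.md)."""

    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    n_genes: int = 150
    n_enhancers: int = 250
    functional_fraction: float = 0.45
    n_neutral_svs: int = 2000
    n_cohort_svs: int = 2000
    singleton_fraction: float = 0.30
    neutral_avoidance: float = 0.95
    seed: int = 0
    # SV length model (log-normal, shared by neutral and cohort sets)
    sv_length_median: float = 7000.0
    sv_length_sigma: float = 0.6
    min_sv_length: int = 50
    # pathogenic spike-ins are longer, mirroring clinically curated SVs
    pathogenic_length_median: float = 20000.0
    pathogenic_length_sigma: float = 0.5
    # cohort composition
    cohort_individuals: int = 1000
    cohort_functional_fraction: float = 0.15
    functional_singleton_bias: float = 2.5
    alignable_fraction: float = 0.92
    track_bin_size: int = 200
    max_place_retries: int = 200

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_enhancers",
                     "n_neutral_svs", "n_cohort_svs", "cohort_individuals"):
            if getattr(self, name) < 0 or (name.startswith("n_chrom") and getattr(self, name) == 0):
                raise DataError(f"{name} must be positive")
        for name in ("functional_fraction", "singleton_fraction",
                     "neutral_avoidance", "cohort_functional_fraction",
                     "alignable_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DataError(f"{name} must be in [0, 1]")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}


@dataclass
class SyntheticWorld:
    """The generated genome: tracks, element catalogs and alignable regions."""

    config: SynthConfig
    chrom_sizes: dict[str, int]
    tracks: dict[str, AnnotationTrack]
    catalogs: dict[str, ElementCatalog]  # gene, gene_start, exon, enhancer, functional
    alignable: ElementCatalog

    @property
    def functional(self) -> ElementCatalog:
        return self.catalogs["functional"]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _partition_gaps(free: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Split *free* bases into n nonnegative integer gaps, jointly uniform-ish."""
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    w = rng.random(n)
    gaps = np.floor(w / w.sum() * free).astype(np.int64)
    gaps[-1] += free - gaps.sum()
    return gaps


def _place_nonoverlapping(
    lengths: np.ndarray, chrom_len: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Place intervals of the given lengths without overlap, random order/gaps."""
    lengths = np.asarray(lengths, dtype=np.int64)
    total = int(lengths.sum())
    if total > chrom_len:
        raise DataError("functional elements exceed chromosome length")
    order = rng.permutation(len(lengths))
    gaps = _partition_gaps(chrom_len - total, len(lengths) + 1, rng)
    out = [None] * len(lengths)
    pos = 0
    for slot, idx in enumerate(order):
        pos += int(gaps[slot])
        out[idx] = (pos, pos + int(lengths[idx]))
        pos += int(lengths[idx])
    return out


def _scaled_lengths(
    n: int, target_total: int, rng: np.random.Generator, min_len: int = 200
) -> np.ndarray:
    if n == 0 or target_total <= 0:
        return np.zeros(0, dtype=np.int64)
    raw = np.exp(rng.normal(0.0, 0.5, size=n))
    lengths = np.maximum((raw / raw.sum() * target_total).astype(np.int64), min_len)
    return lengths


def generate_genome(config: SynthConfig) -> SyntheticWorld:
    """Generate tracks, element catalogs and alignable regions for the config."""
    rng = _rng(config, _STREAM_GENOME)
    chrom_sizes = config.chrom_sizes
    chroms = list(chrom_sizes)

    genes: list[tuple[str, int, int]] = []
    enhancers: list[tuple[str, int, int]] = []
    exons: list[tuple[str, int, int]] = []

    genome_len = config.n_chromosomes * config.chrom_length
    functional_total = int(config.functional_fraction * genome_len)
    if functional_total > 0 and (config.n_genes + config.n_enhancers) > 0:
        gene_budget = int(functional_total * 0.8)
        enh_budget = functional_total - gene_budget
        # spread counts round-robin over chromosomes
        for ci, chrom in enumerate(chroms):
            n_g = config.n_genes // config.n_chromosomes + (
                1 if ci < config.n_genes % config.n_chromosomes else 0
            )
            n_e = config.n_enhancers // config.n_chromosomes + (
                1 if ci < config.n_enhancers % config.n_chromosomes else 0
            )
            g_lens = _scaled_lengths(
                n_g, gene_budget // config.n_chromosomes, rng, min_len=1000
            )
            e_lens = _scaled_lengths(
                n_e, enh_budget // config.n_chromosomes, rng, min_len=300
            )
            lengths = np.concatenate([g_lens, e_lens])
            placed = _place_nonoverlapping(lengths, config.chrom_length, rng)
            for (s, e) in placed[:n_g]:
                genes.append((chrom, s, e))
                # exons: short sub-intervals inside the gene
                n_x = int(rng.integers(2, 7))
                x_lens = np.minimum(
                    rng.integers(120, 400, size=n_x), max(1, (e - s) // (n_x + 1))
                )
                for (xs, xe) in _place_nonoverlapping(x_lens, e - s, rng):
                    exons.append((chrom, s + xs, s + xe))
            for (s, e) in placed[n_g:]:
                enhancers.append((chrom, s, e))

    gene_cat = ElementCatalog("gene", genes)
    enhancer_cat = ElementCatalog("enhancer", enhancers)
    exon_cat = ElementCatalog("exon", exons)
    gene_start_cat = ElementCatalog(
        "gene_start", [(c, s, s + 1) for c, s, _ in genes]
    )
    functional_cat = ElementCatalog("functional", genes + enhancers)

    # alignable regions: whole genome minus random unalignable gaps
    alignable_rows: list[tuple[str, int, int]] = []
    gap_total_per_chrom = int((1.0 - config.alignable_fraction) * config.chrom_length)
    for chrom in chroms:
        n_gaps = 8
        gap_lens = _scaled_lengths(n_gaps, gap_total_per_chrom, rng, min_len=500)
        placed = sorted(_place_nonoverlapping(gap_lens, config.chrom_length, rng))
        pos = 0
        for (gs, ge) in placed:
            if gs > pos:
                alignable_rows.append((chrom, pos, gs))
            pos = ge
        if pos < config.chrom_length:
            alignable_rows.append((chrom, pos, config.chrom_length))
    alignable = ElementCatalog("alignable", alignable_rows)

    # per-chromosome functional coverage fraction per track bin, computed once
    bin_size = config.track_bin_size
    coverage: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_bins = config.chrom_length // bin_size
        cov = np.zeros(n_bins)
        arr = functional_cat.chrom_arrays(chrom)
        if arr is not None:
            delta = np.zeros(config.chrom_length + 1, dtype=np.int32)
            for s, e in zip(*arr):
                delta[s] += 1
                delta[min(e, config.chrom_length)] -= 1
            per_base = np.cumsum(delta[:-1]) > 0
            cov = per_base[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        coverage[chrom] = cov

    tracks: dict[str, AnnotationTrack] = {}
    for name, group, lift in TRACK_SPECS:
        rows: list[tuple[str, int, int, float]] = []
        for chrom in chroms:
            cov = coverage[chrom]
            n_bins = cov.size
            values = rng.exponential(1.0, size=n_bins)
            hot = cov > 0
            values[hot] += cov[hot] * rng.gamma(2.0, lift, size=int(hot.sum()))
            edges = np.arange(n_bins + 1, dtype=np.int64) * bin_size
            rows.extend(
                (chrom, int(edges[i]), int(edges[i + 1]), float(np.round(values[i], 6)))
                for i in range(n_bins)
            )
        tracks[name] = AnnotationTrack(name, rows, group=group)

    return SyntheticWorld(
        config=config,
        chrom_sizes=chrom_sizes,
        tracks=tracks,
        catalogs={
            "gene": gene_cat,
            "gene_start": gene_start_cat,
            "exon": exon_cat,
            "enhancer": enhancer_cat,
            "functional": functional_cat,
        },
        alignable=alignable,
    )


def _draw_length(
    rng: np.random.Generator, median: float, sigma: float, min_len: int, max_len: int
) -> int:
    length = int(round(median * np.exp(rng.normal(0.0, sigma))))
    return int(np.clip(length, min_len, max_len))


class _Placer:
    """Caches the alignable interval arrays for repeated weighted placement."""

    def __init__(self, alignable: ElementCatalog) -> None:
        rows = list(alignable.iter_intervals())
        self.chroms = [r[0] for r in rows]
        self.starts = np.array([r[1] for r in rows], dtype=np.int64)
        self.ends = np.array([r[2] for r in rows], dtype=np.int64)
        self.max_length = int((self.ends - self.starts).max()) if rows else 0

    def place(self, rng: np.random.Generator, length: int) -> GenomicInterval:
        caps = self.ends - self.starts - length + 1
        caps[caps < 0] = 0
        total = int(caps.sum())
        if total == 0:
            raise DataError(f"no alignable interval can host an SV of length {length}")
        k = int(rng.choice(len(self.chroms), p=caps / total))
        pos = int(self.starts[k] + rng.integers(0, caps[k]))
        return GenomicInterval(self.chroms[k], pos, pos + length)


def _neutral_like(
    config: SynthConfig,
    world: SyntheticWorld,
    rng: np.random.Generator,
    sv_type: str,
    n: int,
    prefix: str,
    avoidance: float | None = None,
) -> list[SVRecord]:
    """Place n SVs in alignable space, rejecting functional overlap with the
    configured probability (bounded retries)."""
    avoidance = config.neutral_avoidance if avoidance is None else avoidance
    placer = _Placer(world.alignable)
    functional = world.functional
    max_len = min(config.chrom_length // 4, placer.max_length)
    out: list[SVRecord] = []
    for i in range(n):
        avoid = rng.random() < avoidance
        tries = 0
        while True:
            if sv_type == "INS":
                length = 1
            else:
                length = _draw_length(
                    rng, config.sv_length_median, config.sv_length_sigma,
                    config.min_sv_length, max_len,
                )
            iv = placer.place(rng, length)
            if not (avoid and functional.overlaps_any(iv)):
                break
            # length is redrawn with the position: long candidates may not fit
            # between functional elements at all
            tries += 1
            if tries > config.max_place_retries:
                raise DataError(
                    "could not place a functional-avoiding SV after "
                    f"{config.max_place_retries} retries; lower "
                    "functional_fraction or neutral_avoidance"
                )
        out.append(SVRecord(iv, sv_type, f"{prefix}{i}"))
    return out


def generate_neutral_svs(
    config: SynthConfig, world: SyntheticWorld
) -> dict[str, list[SVRecord]]:
    """Proxy-neutral SV sets per origin (human/chimp x DEL/INS).

    Each contains ``n_neutral_svs`` records placed within alignable regions;
    with probability ``neutral_avoidance`` a record refuses to overlap any
    functional element — the depletion signature purifying selection leaves in
    evolutionarily fixed SVs.
    """
    out: dict[str, list[SVRecord]] = {}
    for origin in ORIGINS:
        sv_type = origin.split("_")[1]
        rng = _rng(config, _STREAM_NEUTRAL[origin])
        out[origin] = _neutral_like(
            config, world, rng, sv_type, config.n_neutral_svs, f"{origin}_"
        )
    return out


def _assign_cohort_alleles(
    config: SynthConfig,
    rng: np.random.Generator,
    is_functional: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Allele counts with the configured marginal singleton fraction.

    Functional records are ``functional_singleton_bias`` times more likely to
    be singletons (purifying selection keeps them rare); the baseline is
    solved so the marginal singleton fraction equals ``singleton_fraction``.
    """
    f = config.cohort_functional_fraction
    bias = config.functional_singleton_bias
    s0 = config.singleton_fraction / (1.0 - f + f * bias)
    p_singleton = np.where(is_functional, np.minimum(1.0, s0 * bias), s0)
    singleton = rng.random(is_functional.size) < p_singleton
    # non-singletons: functional variants skew rarer than background ones
    p_geom = np.where(is_functional, 0.2, 0.05)
    ac = np.where(singleton, 1, 1 + rng.geometric(p_geom))
    ac = np.minimum(ac, 2 * config.cohort_individuals)
    af = ac / (2.0 * config.cohort_individuals)
    return ac.astype(int), af


def generate_cohort(
    config: SynthConfig, world: SyntheticWorld
) -> dict[str, list[SVRecord]]:
    """Reference cohort per SV type, with allele counts and frequencies.

    Mostly neutral-like records; ``cohort_functional_fraction`` of them are
    placed overlapping functional elements and biased toward singleton status.
    """
    out: dict[str, list[SVRecord]] = {}
    for sv_type in ("DEL", "INS", "DUP"):
        rng = _rng(config, _STREAM_COHORT[sv_type])
        n = config.n_cohort_svs
        functional_cat = world.functional
        n_func = (
            int(round(config.cohort_functional_fraction * n))
            if len(functional_cat)
            else 0
        )
        records: list[SVRecord] = []
        is_functional = np.zeros(n, dtype=bool)
        is_functional[:n_func] = True
        elements = list(functional_cat.iter_intervals())
        placer = _Placer(world.alignable)
        max_len = min(config.chrom_length // 4, placer.max_length)
        for i in range(n):
            if is_functional[i]:
                chrom, es, ee = elements[int(rng.integers(0, len(elements)))]
                if sv_type == "INS":
                    pos = int(rng.integers(es, ee))
                    iv = GenomicInterval(chrom, pos, pos + 1)
                else:
                    length = _draw_length(
                        rng, config.sv_length_median, config.sv_length_sigma,
                        config.min_sv_length, max_len,
                    )
                    lo = max(0, es - max(0, length - (ee - es)) )
                    start = int(rng.integers(lo, es + 1)) if es >= lo else es
                    end = min(start + length, config.chrom_length)
                    iv = GenomicInterval(chrom, start, max(end, start + 1))
                records.append(SVRecord(iv, sv_type, f"cohort_{sv_type}_{i}"))
            else:
                avoid = rng.random() < config.neutral_avoidance
                tries = 0
                while True:
                    if sv_type == "INS":
                        length = 1
                    else:
                        length = _draw_length(
                            rng, config.sv_length_median, config.sv_length_sigma,
                            config.min_sv_length, max_len,
                        )
                    iv = placer.place(rng, length)
                    if not (avoid and functional_cat.overlaps_any(iv)):
                        break
                    tries += 1
                    if tries > config.max_place_retries:
                        raise DataError(
                            "cohort placement failed; lower functional_fraction"
                        )
                records.append(SVRecord(iv, sv_type, f"cohort_{sv_type}_{i}"))
        ac, af = _assign_cohort_alleles(config, rng, is_functional)
        out[sv_type] = [
            dataclasses.replace(r, allele_count=int(a), allele_frequency=float(q))
            for r, a, q in zip(records, ac, af)
        ]
    return out


def generate_pathogenic_svs(
    config: SynthConfig, world: SyntheticWorld, n: int, sv_type: str = "DEL"
) -> list[SVRecord]:
    """Spike-in "pathogenic" SVs: long events forced to overlap genes."""
    rng = _rng(config, _STREAM_PATHOGENIC[sv_type])
    genes = list(world.catalogs["gene"].iter_intervals())
    if not genes:
        raise DataError("no genes in the synthetic world to anchor pathogenic SVs")
    out: list[SVRecord] = []
    for i in range(n):
        chrom, gs, ge = genes[int(rng.integers(0, len(genes)))]
        if sv_type == "INS":
            pos = int(rng.integers(gs, ge))
            iv = GenomicInterval(chrom, pos, pos + 1)
        else:
            length = _draw_length(
                rng, config.pathogenic_length_median, config.pathogenic_length_sigma,
                config.min_sv_length, config.chrom_length // 2,
            )
            mid = (gs + ge) // 2
            start = max(0, mid - length // 2)
            end = min(config.chrom_length, start + length)
            iv = GenomicInterval(chrom, start, end)
        out.append(SVRecord(iv, sv_type, f"pathogenic_{sv_type}_{i}"))
    return out


def generate_individual_sets(
    config: SynthConfig,
    world: SyntheticWorld,
    n_individuals: int,
    svs_per_individual: int,
    sv_type: str = "DEL",
) -> list[list[SVRecord]]:
    """SV sets of simulated healthy individuals (neutral-like composition)."""
    rng = _rng(config, _STREAM_INDIVIDUALS)
    return [
        _neutral_like(
            config, world, rng, sv_type, svs_per_individual, f"ind{k}_",
        )
        for k in range(n_individuals)
    ]


def write_world(world: SyntheticWorld, outdir: str | Path) -> Path:
    """Write tracks/catalogs/alignable regions as BED plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, track in world.tracks.items():
        rel = f"track_{name}.bed"
        write_track(track, outdir / rel)
        files[f"track:{name}:{track.group}"] = rel
    for name, cat in world.catalogs.items():
        rel = f"catalog_{name}.bed"
        write_catalog(cat, outdir / rel)
        files[f"catalog:{name}"] = rel
    write_catalog(world.alignable, outdir / "alignable.bed")
    files["alignable"] = "alignable.bed"
    manifest = {
        "config": dataclasses.asdict(world.config),
        "chrom_sizes": world.chrom_sizes,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir / "manifest.json"


def load_world(outdir: str | Path) -> SyntheticWorld:
    """Load a world previously written by :func:`write_world`."""
    from .intervals import read_catalog, read_track

    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SynthConfig(**manifest["config"])
    tracks: dict[str, AnnotationTrack] = {}
    catalogs: dict[str, ElementCatalog] = {}
    for key, rel in manifest["files"].items():
        if key.startswith("track:"):
            _, name, group = key.split(":")
            tracks[name] = read_track(outdir / rel, name, group=group)
        elif key.startswith("catalog:"):
            name = key.split(":")[1]
            catalogs[name] = read_catalog(outdir / rel, name)
    alignable = read_catalog(outdir / manifest["files"]["alignable"], "alignable")
    return SyntheticWorld(
        config=config,
        chrom_sizes={k: int(v) for k, v in manifest["chrom_sizes"].items()},
        tracks=tracks,
        catalogs=catalogs,
        alignable=alignable,
    )
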