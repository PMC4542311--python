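"""Synthetic single-cell methylome generator.

Emulates the statistical structure the pipeline assumes, at desk scale:
a small genome tiled with disjoint region-set regions carrying bimodal
baseline methylation, graded treatment effects (a global shift plus
region-set-specific offsets for designated truth sets), sparse Bernoulli
per-CpG coverage with binary calls, and read-level artifacts (PCR
duplicates, bisulfite conversion errors, spike-in oligos).

The default configuration is a deliberately scaled-down world: the genome,
region count, and regions per set are orders of magnitude below a mammalian
genome, and per-CpG coverage is raised (p_cov = 0.5 versus ~5% for a real
single cell) so that the absolute measurement-support thresholds of the
region-set filter (minimum 100 / mean 200 CpG measurements) remain
meaningful.  Effect sizes and error rates are realistic: a global
demethylation of -0.3 mirrors a strong demethylating treatment, set-specific
offsets of +/-0.15, a 5.8% PCR duplicate rate, 1% over- and 2%
under-conversion, and 0.1% spike-in content.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scmethdyn.methcore import MethylomeSample
from scmethdyn.readproc import ReadRecord
from scmethdyn.regionagg import RegionSet, RegionSetMatrix, annotate_cpg_percent


@dataclass
class SimConfig:
    """Parameters of the simulated world.  See the module docstring for the
    reasoning behind the defaults."""

    # genome geometry
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    # region sets
    n_region_sets: int = 50
    regions_per_set: int = 40
    region_length: int = 500
    cpgs_per_region: int = 10  # mean; per-set density varies by cpg_density_spread
    cpg_density_spread: float = 0.6  # per-set factor ~ U(1-s, 1+s) on the mean
    background_cpg_density: float = 0.002  # CpGs per bp between regions
    # baseline methylation: Beta(a, b) per region set (bimodal by default)
    baseline_beta_a: float = 0.5
    baseline_beta_b: float = 0.5
    # treatment effect structure
    global_effect: float = -0.3
    n_positive_sets: int = 10
    n_negative_sets: int = 10
    set_offset: float = 0.15
    effect_scale: str = "linear"  # or "logit"
    # depth model
    p_cov: float = 0.5  # per-CpG coverage probability
    bulk_depth: float | None = None  # mean depth of covered CpGs (None = single cell, depth 1)
    reads_per_covered_cpg: float = 2.0  # aligned_reads ~ Poisson(this * covered CpGs)
    # read-level artifacts
    read_length: int = 100
    noncpg_c_mean: float = 8.0  # Poisson mean of non-CpG cytosines per read
    duplicate_rate: float = 0.058
    over_conversion: float = 0.01
    under_conversion: float = 0.02
    spikein_fraction: float = 0.001  # spike-in reads per genome fragment, per class
    spikein_c_per_read: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_cov",
            "duplicate_rate",
            "over_conversion",
            "under_conversion",
            "spikein_fraction",
            "background_cpg_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_positive_sets + self.n_negative_sets > self.n_region_sets:
            raise ValueError("truth sets exceed total region sets")
        if self.effect_scale not in ("linear", "logit"):
            raise ValueError("effect_scale must be 'linear' or 'logit'")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    positive_sets: list[str]
    negative_sets: list[str]
    baseline_meth: pd.Series  # per set
    global_effect: float
    set_offset: float
    sample_global: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    sample_multiplier: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class Landscape:
    """A simulated genome: region sets, CpG positions, per-CpG set identity."""

    region_sets: list[RegionSet]
    cpg_positions: dict[str, np.ndarray]  # chrom -> sorted positions
    cpg_set_index: dict[str, np.ndarray]  # chrom -> region-set index per CpG (-1 = background)
    chrom_lengths: dict[str, int]

    @property
    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions.values())


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # stream-split by sample id so results are independent of iteration order
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def simulate_landscape(config: SimConfig) -> tuple[Landscape, SimTruth]:
    """Place disjoint region-set regions and lay down CpGs.

    Regions are placed uniformly by rejection sampling (error if they cannot
    fit); each carries ``cpgs_per_region`` CpGs at uniform positions, and
    background CpGs are scattered between regions at the configured density.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng([config.seed, zlib.crc32(b"landscape")])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    n_regions = config.n_region_sets * config.regions_per_set
    total_needed = n_regions * config.region_length
    genome_size = config.n_chroms * config.chrom_length
    if total_needed > 0.8 * genome_size:
        raise ValueError(
            f"cannot fit {n_regions} regions of {config.region_length} bp into "
            f"{genome_size} bp without excessive rejection"
        )

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placements: list[tuple[str, int, int]] = []
    max_attempts = 200 * max(n_regions, 1)
    attempts = 0
    while len(placements) < n_regions:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("rejection sampling failed to place all regions")
        chrom = chroms[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - config.region_length))
        end = start + config.region_length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        placements.append((chrom, start, end))

    # assign placements to sets in order (placements are already random)
    region_sets: list[RegionSet] = []
    set_names = [f"set_{i:03d}" for i in range(config.n_region_sets)]
    cpg_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    cpg_setidx: dict[str, list[int]] = {c: [] for c in chroms}
    spread = config.cpg_density_spread
    density_factor = rng.uniform(1.0 - spread, 1.0 + spread, size=config.n_region_sets)
    for j, name in enumerate(set_names):
        intervals = placements[j * config.regions_per_set : (j + 1) * config.regions_per_set]
        region_sets.append(RegionSet(name=name, intervals=list(intervals)))
        mean_k = config.cpgs_per_region * density_factor[j]
        for chrom, start, end in intervals:
            k = min(max(int(rng.poisson(mean_k)), 1), end - start)
            positions = rng.choice(np.arange(start, end), size=k, replace=False)
            cpg_chrom[chrom].extend(int(p) for p in positions)
            cpg_setidx[chrom].extend([j] * k)

    # background CpGs between regions
    for chrom in chroms:
        n_bg = rng.binomial(config.chrom_length, config.background_cpg_density)
        candidates = rng.integers(0, config.chrom_length, size=n_bg)
        occ = sorted(occupied[chrom])
        if occ:
            starts = np.array([s for s, _ in occ])
            ends = np.array([e for _, e in occ])
            idx = np.searchsorted(starts, candidates, side="right") - 1
            inside = (idx >= 0) & (candidates < ends[np.clip(idx, 0, None)])
            candidates = candidates[~inside]
        existing = set(cpg_chrom[chrom])
        fresh = [int(p) for p in np.unique(candidates) if int(p) not in existing]
        cpg_chrom[chrom].extend(fresh)
        cpg_setidx[chrom].extend([-1] * len(fresh))

    cpg_positions = {}
    cpg_set_index = {}
    for chrom in chroms:
        pos = np.array(cpg_chrom[chrom], dtype=np.int64)
        idx = np.array(cpg_setidx[chrom], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        cpg_positions[chrom] = pos[order]
        cpg_set_index[chrom] = idx[order]

    region_sets = [annotate_cpg_percent(rs, cpg_positions) for rs in region_sets]

    baseline = pd.Series(
        rng.beta(config.baseline_beta_a, config.baseline_beta_b, size=config.n_region_sets),
        index=set_names,
        name="baseline_meth",
    )
    truth = SimTruth(
        positive_sets=set_names[: config.n_positive_sets],
        negative_sets=set_names[
            config.n_positive_sets : config.n_positive_sets + config.n_negative_sets
        ],
        baseline_meth=baseline,
        global_effect=config.global_effect,
        set_offset=config.set_offset,
    )
    landscape = Landscape(
        region_sets=region_sets,
        cpg_positions=cpg_positions,
        cpg_set_index=cpg_set_index,
        chrom_lengths=chrom_lengths,
    )
    return landscape, truth


# ---------------------------------------------------------------------------
# per-CpG methylation probabilities
# ---------------------------------------------------------------------------

def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def true_meth_probability(
    landscape: Landscape,
    truth: SimTruth,
    config: SimConfig,
    multiplier: float,
    background_baseline: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Per-CpG methylation probability for a group at a given effect multiplier.

    clamp(baseline + multiplier * (global_effect + set_offset), 0, 1) on the
    linear scale (or the same shift applied on the logit scale).
    """
    set_names = list(truth.baseline_meth.index)
    offsets = np.zeros(len(set_names))
    for name in truth.positive_sets:
        offsets[set_names.index(name)] = +truth.set_offset
    for name in truth.negative_sets:
        offsets[set_names.index(name)] = -truth.set_offset
    baselines = truth.baseline_meth.to_numpy()

    out = {}
    for chrom, idx in landscape.cpg_set_index.items():
        base = np.where(idx >= 0, baselines[np.clip(idx, 0, None)], background_baseline[chrom])
        shift = multiplier * (
            config.global_effect + np.where(idx >= 0, offsets[np.clip(idx, 0, None)], 0.0)
        )
        if config.effect_scale == "linear":
            out[chrom] = np.clip(base + shift, 0.0, 1.0)
        else:
            out[chrom] = _expit(_logit(base) + shift)
    return out


def _background_baseline(landscape: Landscape, config: SimConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([config.seed, zlib.crc32(b"background")])
    return {
        chrom: rng.beta(
            config.baseline_beta_a, config.baseline_beta_b, size=len(idx)
        )
        for chrom, idx in landscape.cpg_set_index.items()
    }


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def simulate_samples(
    landscape: Landscape,
    config: SimConfig,
    groups: Sequence[tuple[str, int, float]],
    truth: SimTruth,
) -> tuple[list[MethylomeSample], SimTruth]:
    """Draw sparse methylome samples for groups at given effect multipliers.

    ``groups`` is a list of (label, n_samples, effect_multiplier); multiplier
    0 reproduces the untreated baseline, 1 the full endpoint effect, and
    intermediate values graded intermediate states.  Per covered CpG the
    call is Bernoulli(p) at depth 1 (single cell) or binomial at the
    configured bulk depth.  Each sample uses an independent RNG stream keyed
    by (seed, sample id), so results do not depend on iteration order.
    """
    background = _background_baseline(landscape, config)
    samples: list[MethylomeSample] = []
    global_truth = {}
    mult_truth = {}
    for label, n_samples, multiplier in groups:
        probs = true_meth_probability(landscape, truth, config, multiplier, background)
        all_p = np.concatenate([probs[c] for c in sorted(probs)])
        for i in range(n_samples):
            sample_id = f"{label}_{i:02d}"
            rng = _sample_rng(config.seed, sample_id)
            frames = []
            n_covered = 0
            for chrom in sorted(landscape.cpg_positions):
                pos = landscape.cpg_positions[chrom]
                p = probs[chrom]
                covered = rng.random(len(pos)) < config.p_cov
                if not covered.any():
                    continue
                n_cov = int(covered.sum())
                n_covered += n_cov
                if config.bulk_depth is None:
                    total = np.ones(n_cov, dtype=np.int64)
                else:
                    total = 1 + rng.poisson(max(config.bulk_depth - 1.0, 0.0), size=n_cov)
                meth = rng.binomial(total, p[covered])
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos[covered],
                            "meth_count": meth,
                            "total_count": total,
                        }
                    )
                )
            calls = (
                pd.concat(frames, ignore_index=True)
                if frames
                else None
            )
            aligned = int(rng.poisson(config.reads_per_covered_cpg * n_covered))
            samples.append(
                MethylomeSample(
                    sample_id=sample_id,
                    calls=calls,
                    genome_label="synthetic",
                    cell_count=1 if config.bulk_depth is None else "bulk",
                    group=label,
                    aligned_reads=aligned,
                )
            )
            global_truth[sample_id] = float(all_p.mean())
            mult_truth[sample_id] = float(multiplier)
    truth.sample_global = pd.Series(global_truth, name="true_global_meth")
    truth.sample_multiplier = pd.Series(mult_truth, name="effect_multiplier")
    return samples, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    landscape: Landscape,
    meth_probability: dict[str, np.ndarray],
    config: SimConfig,
    n_fragments: int,
    seed: int | None = None,
) -> tuple[list[ReadRecord], int]:
    """Emit aligned-read records with duplicates, conversion errors, spike-ins.

    Genome fragments are placed uniformly; each observes the CpGs in its
    span (true state Bernoulli(p), then conversion errors flip it: a
    methylated C reads unmethylated with the over-conversion rate, an
    unmethylated C reads methylated with the under-conversion rate).
    Non-CpG cytosines per read ~ Poisson(noncpg_c_mean); each converts with
    probability 1 - under_conversion.  Each fragment is followed by an exact
    duplicate with probability ``duplicate_rate``.  Spike-in reads for both
    oligo classes are appended at ``spikein_fraction`` per class.

    Returns (reads, n_duplicates); the number of emitted genome reads equals
    n_fragments + n_duplicates exactly.
    """
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, zlib.crc32(b"reads")]
    )
    chroms = sorted(landscape.chrom_lengths)
    lengths = np.array([landscape.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    reads: list[ReadRecord] = []
    n_duplicates = 0
    for _ in range(n_fragments):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        start = int(rng.integers(0, landscape.chrom_lengths[chrom] - config.read_length))
        end = start + config.read_length
        pos = landscape.cpg_positions[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        obs = []
        for p_idx in range(lo, hi):
            true_m = rng.random() < meth_probability[chrom][p_idx]
            if true_m:
                read_m = rng.random() >= config.over_conversion
            else:
                read_m = rng.random() < config.under_conversion
            obs.append((int(pos[p_idx]), bool(read_m)))
        nct = int(rng.poisson(config.noncpg_c_mean))
        ncc = int(rng.binomial(nct, 1.0 - config.under_conversion)) if nct else 0
        read = ReadRecord(
            chrom=chrom,
            start=start,
            end=end,
            non_cpg_c_total=nct,
            non_cpg_c_converted=ncc,
            cpg_obs=tuple(obs),
            source="genome",
        )
        reads.append(read)
        if rng.random() < config.duplicate_rate:
            reads.append(read)
            n_duplicates += 1
    n_spike = int(round(config.spikein_fraction * n_fragments))
    for source in ("spikein_meth", "spikein_unmeth"):
        for i in range(n_spike):
            nct = int(config.spikein_c_per_read)
            if source == "spikein_meth":
                ncc = int(rng.binomial(nct, config.over_conversion))
            else:
                ncc = int(rng.binomial(nct, 1.0 - config.under_conversion))
            reads.append(
                ReadRecord(
                    chrom=source,
                    start=0,
                    end=60,
                    non_cpg_c_total=nct,
                    non_cpg_c_converted=ncc,
                    cpg_obs=(),
                    source=source,
                )
            )
    return reads, n_duplicates


# ---------------------------------------------------------------------------
# matrix-level simulation (for the state model on its own)
# ---------------------------------------------------------------------------

def simulate_regionset_matrix(
    n_sets: int = 200,
    n_positive: int = 10,
    n_negative: int = 10,
    effect: float = 0.15,
    noise_sd: float = 0.03,
    groups: Sequence[tuple[str, int, float]] = (("control", 8, 0.0), ("treated", 8, 1.0)),
    control_slope: float = -0.5,
    cpg_slope: float = 0.005,
    intercept: float = -0.05,
    n_measurements: int = 500,
    seed: int = 0,
) -> tuple[RegionSetMatrix, pd.Series, SimTruth, pd.Series]:
    """Simulate the aggregated matrix directly, bypassing read/call levels.

    Each set gets a control methylation level ~ U(0.2, 0.8) and a CpG
    percentage ~ U(0.5, 10).  A sample at effect multiplier m has value

        ref_j + m * (intercept + control_slope*ref_j + cpg_slope*cpg_j
                     + offset_j) + noise,    noise ~ N(0, noise_sd),

    where offset_j is +effect for the designated positive truth sets,
    -effect for the negative ones, 0 elsewhere.  The linear component is
    exactly what the per-sample OLS absorbs, so residuals recover the
    offsets.  Returns (matrix, cpg_percents, truth, group labels).
    """
    if n_positive + n_negative > n_sets:
        raise ValueError("truth sets exceed total sets")
    rng = np.random.default_rng([seed, zlib.crc32(b"matrix")])
    set_names = [f"set_{j:03d}" for j in range(n_sets)]
    ref = rng.uniform(0.2, 0.8, size=n_sets)
    cpg = rng.uniform(0.5, 10.0, size=n_sets)
    offsets = np.zeros(n_sets)
    positive = set_names[:n_positive]
    negative = set_names[n_positive : n_positive + n_negative]
    offsets[:n_positive] = +effect
    offsets[n_positive : n_positive + n_negative] = -effect

    rows = {}
    group_labels = {}
    multipliers = {}
    for label, n_samples, mult in groups:
        for i in range(n_samples):
            sample_id = f"{label}_{i:02d}"
            srng = _sample_rng(seed, sample_id)
            noise = srng.normal(0.0, noise_sd, size=n_sets)
            rows[sample_id] = (
                ref
                + mult * (intercept + control_slope * ref + cpg_slope * cpg + offsets)
                + noise
            )
            group_labels[sample_id] = label
            multipliers[sample_id] = float(mult)
    values = pd.DataFrame(rows, index=set_names).T
    values.index.name = "sample_id"
    counts = pd.DataFrame(
        np.full(values.shape, n_measurements, dtype=np.int64),
        index=values.index,
        columns=values.columns,
    )
    matrix = RegionSetMatrix(values=values, n_measurements=counts)
    cpg_percents = pd.Series(cpg, index=set_names, name="cpg_percent")
    truth = SimTruth(
        positive_sets=positive,
        negative_sets=negative,
        baseline_meth=pd.Series(ref, index=set_names, name="baseline_meth"),
        global_effect=intercept,
        set_offset=effect,
        sample_multiplier=pd.Series(multipliers, name="effect_multiplier"),
    )
    return matrix, cpg_percents, truth, pd.Series(group_labels, name="group")
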