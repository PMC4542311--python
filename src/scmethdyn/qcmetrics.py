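"""Quality-control and exploratory analytics.

Saturation curves (cumulative unique CpGs versus aligned reads over random
sample orderings), the mixed-species alignment-ratio check, copy-number
concordance against annotated CN region sets, classical (Torgerson) MDS of
tile matrices, and within-group pairwise-distance variability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from scmethdyn.methcore import MethylomeSample


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

@dataclass
class SaturationCurve:
    """Mean +/- sd of cumulative unique CpG coverage at each accumulation step.

    ``points`` rows: cum_aligned_reads (mean over iterations), mean and sd of
    the cumulative unique CpG count after adding k samples in random order.
    """

    points: pd.DataFrame  # columns: cum_aligned_reads, mean_unique_cpgs, sd_unique_cpgs
    n_iterations: int
    seed: int


def saturation_curve(
    samples: Sequence[MethylomeSample],
    n_iter: int = 10,
    seed: int = 0,
) -> SaturationCurve:
    """Cumulative unique-CpG coverage under random sample orderings.

    Per iteration, samples are shuffled uniformly; at step k the x value is
    the summed aligned-read count of the first k samples and the y value the
    size of the union of their covered positions.  Points aggregate the mean
    and (population) sd over iterations at each step index.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("saturation_curve requires at least one sample")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    position_sets = [s.positions() for s in samples]
    reads = np.array([s.aligned_reads for s in samples], dtype=np.int64)
    k = len(samples)
    ys = np.empty((n_iter, k), dtype=np.int64)
    xs = np.empty((n_iter, k), dtype=np.int64)
    for it in range(n_iter):
        order = rng.permutation(k)
        seen: set = set()
        cum_reads = 0
        for step, idx in enumerate(order):
            seen |= position_sets[idx]
            cum_reads += int(reads[idx])
            ys[it, step] = len(seen)
            xs[it, step] = cum_reads
    points = pd.DataFrame(
        {
            "cum_aligned_reads": xs.mean(axis=0),
            "mean_unique_cpgs": ys.mean(axis=0),
            "sd_unique_cpgs": ys.std(axis=0, ddof=0),
        }
    )
    return SaturationCurve(points=points, n_iterations=n_iter, seed=seed)


def exhaustive_saturation_mean(samples: Sequence[MethylomeSample]) -> np.ndarray:
    """Exact mean cumulative unique-CpG curve over all sample permutations.

    Feasible only for small n (n! orderings); serves as the reference for
    the Monte-Carlo curve.
    """
    position_sets = [s.positions() for s in samples]
    k = len(position_sets)
    totals = np.zeros(k)
    count = 0
    for order in itertools.permutations(range(k)):
        seen: set = set()
        for step, idx in enumerate(order):
            seen |= position_sets[idx]
            totals[step] += len(seen)
        count += 1
    return totals / count


def plot_saturation(curve: SaturationCurve, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    p = curve.points
    ax.errorbar(
        p["cum_aligned_reads"], p["mean_unique_cpgs"], yerr=p["sd_unique_cpgs"],
        fmt="o-", capsize=3,
    )
    ax.set_xlabel("aligned reads (cumulative)")
    ax.set_ylabel("unique CpGs covered")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# alignment-ratio check (mixed-species cell pools)
# ---------------------------------------------------------------------------

@dataclass
class RatioCheck:
    expected_fraction: float
    observed_fraction: float
    fold_tolerance: float
    ok: bool


# effective genome sizes (bp); configurable per call
GENOME_SIZE_HG19 = 3.10e9
GENOME_SIZE_MM10 = 2.73e9


def alignment_ratio_check(
    reads_h: int,
    reads_m: int,
    cells_h: int,
    cells_m: int,
    genome_size_h: float = GENOME_SIZE_HG19,
    genome_size_m: float = GENOME_SIZE_MM10,
    fold_tolerance: float = 2.0,
) -> RatioCheck:
    """Compare observed human-read fraction with the sorted-cell expectation.

    For a well with ``cells_h`` human and ``cells_m`` mouse cells, the
    expected human fraction of aligned reads is proportional to cell count
    times genome size.  The check passes when the observed odds lie within
    ``fold_tolerance``-fold of the expected odds (symmetric band on the odds
    scale); a large deviation indicates cell loss or contamination.
    """
    if cells_h + cells_m < 1:
        raise ValueError("at least one cell must have been sorted")
    if reads_h + reads_m < 1:
        raise ValueError("zero total aligned reads")
    expected = (cells_h * genome_size_h) / (
        cells_h * genome_size_h + cells_m * genome_size_m
    )
    observed = reads_h / (reads_h + reads_m)

    def _odds(f: float) -> float:
        if f >= 1.0:
            return np.inf
        return f / (1.0 - f)

    eo, oo = _odds(expected), _odds(observed)
    if np.isinf(eo) or np.isinf(oo):
        ok = np.isinf(eo) and np.isinf(oo)
    elif eo == 0.0 or oo == 0.0:
        ok = eo == oo
    else:
        ratio = oo / eo
        ok = max(ratio, 1.0 / ratio) <= fold_tolerance
    return RatioCheck(
        expected_fraction=float(expected),
        observed_fraction=float(observed),
        fold_tolerance=fold_tolerance,
        ok=bool(ok),
    )


# ---------------------------------------------------------------------------
# copy-number concordance
# ---------------------------------------------------------------------------

CN_CLASSES = ("deleted", "haploid", "diploid", "polyploid")


@dataclass
class CnConcordance:
    """Per-CN-class raw mean coverage and diploid-normalized coverage.

    ``normalized`` values are NaN when diploid coverage is zero; by
    construction the diploid normalized value is exactly 1.0 otherwise.
    """

    raw: dict[str, float]
    normalized: dict[str, float]


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def cn_concordance(
    read_intervals: Sequence[tuple[str, int, int]],
    cn_regions: Sequence[tuple[str, int, int, str]],
    exclusion_regions: Sequence[tuple[str, int, int]] = (),
) -> CnConcordance:
    """Coverage concordance with annotated copy-number classes.

    CN regions overlapping any exclusion region (ambiguous repeats,
    segmental duplications, ...) are dropped entirely.  Per class, coverage
    is the total aligned bases falling in class regions divided by the total
    region length; values are then normalized by the diploid coverage.
    """
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in exclusion_regions:
        excl_by_chrom.setdefault(chrom, []).append((start, end))

    kept: list[tuple[str, int, int, str]] = []
    for chrom, start, end, label in cn_regions:
        if label not in CN_CLASSES:
            raise ValueError(f"unknown CN class {label!r}; expected one of {CN_CLASSES}")
        if any(_overlaps(start, end, es, ee) for es, ee in excl_by_chrom.get(chrom, ())):
            continue
        kept.append((chrom, start, end, label))

    reads_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in itertools.groupby(
        sorted(read_intervals), key=lambda r: r[0]
    ):
        arr = np.array([(s, e) for _, s, e in group], dtype=np.int64)
        reads_by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    covered = {c: 0.0 for c in CN_CLASSES}
    length = {c: 0 for c in CN_CLASSES}
    for chrom, start, end, label in kept:
        length[label] += end - start
        entry = reads_by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends = entry
        overlap = np.clip(np.minimum(ends, end) - np.maximum(starts, start), 0, None)
        covered[label] += float(overlap.sum())

    raw = {
        c: (covered[c] / length[c]) if length[c] > 0 else float("nan")
        for c in CN_CLASSES
    }
    diploid = raw.get("diploid", float("nan"))
    if not np.isfinite(diploid) or diploid <= 0:
        normalized = {c: float("nan") for c in CN_CLASSES}
    else:
        normalized = {
            c: (raw[c] / diploid if np.isfinite(raw[c]) else float("nan"))
            for c in CN_CLASSES
        }
    return CnConcordance(raw=raw, normalized=normalized)


def read_cn_bed(path) -> list[tuple[str, int, int, str]]:
    """BED4 with a CN class label (deleted/haploid/diploid/polyploid) in column 4."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: CN BED needs 4 columns")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


# ---------------------------------------------------------------------------
# classical MDS and within-group variability
# ---------------------------------------------------------------------------

def pairwise_complete_distances(X: pd.DataFrame) -> np.ndarray:
    """Euclidean distances using pairwise-complete features.

    For each sample pair, the squared distance over the features observed in
    both is rescaled by (total features / shared features) before the square
    root, so sparsely shared pairs stay comparable with densely shared ones.
    """
    values = X.to_numpy(dtype=float)
    n, p = values.shape
    D = np.zeros((n, n))
    mask = np.isfinite(values)
    for i in range(n):
        for j in range(i + 1, n):
            shared = mask[i] & mask[j]
            k = int(shared.sum())
            if k == 0:
                raise ValueError(
                    f"samples {X.index[i]!r} and {X.index[j]!r} share no features"
                )
            d2 = float(((values[i, shared] - values[j, shared]) ** 2).sum())
            D[i, j] = D[j, i] = np.sqrt(d2 * p / k)
    return D


def classical_mds(
    X: pd.DataFrame,
    k: int = 2,
    min_sample_fraction: float = 1.0,
) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a samples x features matrix.

    Features covered in fewer than ``min_sample_fraction`` of samples are
    dropped first (default: complete features only).  The squared-distance
    matrix is double-centered and eigendecomposed; the top-k coordinates are
    returned with a fixed sign convention (largest-magnitude loading of each
    axis positive).  If fewer than k positive eigenvalues exist, the
    available axes are returned with a warning.
    """
    import warnings

    if len(X) < 3:
        raise ValueError("classical_mds needs at least 3 samples")
    frac_covered = np.isfinite(X.to_numpy(dtype=float)).mean(axis=0)
    keep = frac_covered >= min_sample_fraction
    X = X.loc[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no features pass the coverage threshold")
    D = pairwise_complete_distances(X)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-9 * abs(eigvals[0])) if eigvals[0] > 0 else eigvals > 1e-12
    n_axes = int(min(k, positive.sum()))
    if n_axes < k:
        warnings.warn(
            f"only {n_axes} positive eigenvalues; returning {n_axes} axes", stacklevel=2
        )
    if n_axes == 0:
        coords = np.zeros((n, k))
        n_axes = k
    else:
        coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for ax in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, ax]))
        if coords[pivot, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return pd.DataFrame(
        coords, index=X.index, columns=[f"MDS{i + 1}" for i in range(coords.shape[1])]
    )


def within_group_variability(
    X: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Mean pairwise Euclidean distance within each sample group.

    Distances use pairwise-complete features (see
    :func:`pairwise_complete_distances`).  Groups with fewer than two
    samples get NaN.
    """
    groups = pd.Series(groups).reindex(X.index)
    out = {}
    for label, members in groups.groupby(groups):
        ids = list(members.index)
        if len(ids) < 2:
            out[label] = float("nan")
            continue
        D = pairwise_complete_distances(X.loc[ids])
        iu = np.triu_indices(len(ids), k=1)
        out[label] = float(D[iu].mean())
    return pd.Series(out, name="mean_pairwise_distance")
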