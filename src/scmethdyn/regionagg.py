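"""Region-set handling and mean-of-means aggregation.

A region set is a named collection of genomic intervals sharing a biological
definition (binding sites of one factor, one tissue's DNase peaks, ...).
Sparse single-cell methylation calls gain statistical power when summarized
over such sets: per region, the unweighted mean of the covered per-CpG
methylation fractions; per set, the unweighted mean of those region means
("mean of these means").  The result is a samples x region-sets matrix,
subsequently filtered for measurement support (minimum and mean CpG
measurements across samples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from scmethdyn.methcore import MethylomeSample


@dataclass
class RegionSet:
    """Named interval collection with optional CpG-content annotation.

    ``cpg_percent`` is the unweighted mean over regions of
    100 * (CpG dinucleotide starts in [start, end)) / (end - start),
    left None until :func:`annotate_cpg_percent` runs.
    """

    name: str
    intervals: list[tuple[str, int, int]]
    cpg_percent: float | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"{self.name}: empty interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)

    @property
    def n_regions(self) -> int:
        return len(self.intervals)


@dataclass
class RegionSetMatrix:
    """Samples x region-sets aggregation result.

    ``values`` holds methylation fractions (NaN = no covered CpG in any
    region of the set for that sample); ``n_measurements`` the contributing
    covered-CpG measurement counts.  Both share index (sample ids) and
    columns (set names).
    """

    values: pd.DataFrame
    n_measurements: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.n_measurements.index) or not (
            self.values.columns.equals(self.n_measurements.columns)
        ):
            raise ValueError("values and n_measurements must be aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# BED input
# ---------------------------------------------------------------------------

def _read_bed(path) -> list[tuple[str, int, int]]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval {chrom}:{start}-{end}")
            intervals.append((chrom, start, end))
    return intervals


def _stem(path) -> str:
    stem = str(path).rsplit("/", 1)[-1]
    if stem.endswith(".bed"):
        stem = stem[:-4]
    return stem


def load_region_collection(
    paths: Sequence, names: Sequence[str] | None = None
) -> list[RegionSet]:
    """Load one region set per BED file, named by file stem (or ``names``).

    Empty files yield empty sets, which downstream aggregation flags with a
    warning and which are naturally removed by the support filter.
    """
    if names is not None and len(names) != len(paths):
        raise ValueError("names and paths must have equal length")
    sets = []
    for i, path in enumerate(paths):
        name = names[i] if names is not None else _stem(path)
        intervals = _read_bed(path)
        if not intervals:
            warnings.warn(f"region set {name!r} ({path}) is empty", stacklevel=2)
        sets.append(RegionSet(name=name, intervals=intervals))
    return sets


def load_region_manifest(manifest_path) -> list[RegionSet]:
    """Load region sets from a manifest TSV with columns ``name`` and ``path``.

    Relative paths resolve against the manifest's directory.  Extra columns
    (cell type, mark, ...) are allowed and ignored here.
    """
    import os

    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    if not {"name", "path"} <= set(df.columns):
        raise ValueError("manifest needs 'name' and 'path' columns")
    base = os.path.dirname(str(manifest_path))
    paths = [p if os.path.isabs(p) else os.path.join(base, p) for p in df["path"]]
    return load_region_collection(paths, names=list(df["name"]))


# ---------------------------------------------------------------------------
# CpG-content annotation
# ---------------------------------------------------------------------------

def _count_cpgs_positions(positions: np.ndarray, start: int, end: int) -> int:
    lo = np.searchsorted(positions, start, side="left")
    hi = np.searchsorted(positions, end, side="left")
    return int(hi - lo)


def _count_cpgs_sequence(seq: str, start: int, end: int) -> int:
    # CpG starts in [start, end); the G at position `end` may lie outside
    window = seq[start : end + 1].upper()
    count = 0
    idx = window.find("CG")
    while idx != -1 and idx < end - start:
        count += 1
        idx = window.find("CG", idx + 1)
    return count


def annotate_cpg_percent(
    region_set: RegionSet,
    cpg_source: Union[Mapping[str, np.ndarray], Mapping[str, str], str],
) -> RegionSet:
    """Annotate a region set with its mean CpG-dinucleotide percentage.

    ``cpg_source`` is one of: a mapping chrom -> sorted array of CpG start
    positions; a mapping chrom -> sequence string; or a FASTA path (indexed
    with pyfaidx).  A region on a chromosome absent from the source counts
    as 0 CpGs and still enters the unweighted mean.
    """
    if isinstance(cpg_source, str):
        from pyfaidx import Fasta

        fasta = Fasta(cpg_source)
        source: Mapping = {name: str(fasta[name][:]) for name in fasta.keys()}
    else:
        source = cpg_source

    percents = []
    for chrom, start, end in region_set.intervals:
        entry = source.get(chrom)
        if entry is None:
            n = 0
        elif isinstance(entry, str):
            n = _count_cpgs_sequence(entry, start, end)
        else:
            n = _count_cpgs_positions(np.asarray(entry), start, end)
        percents.append(100.0 * n / (end - start))
    mean_pct = float(np.mean(percents)) if percents else float("nan")
    return replace(region_set, cpg_percent=mean_pct)


def cpg_percent_series(sets: Sequence[RegionSet]) -> pd.Series:
    """Per-set CpG percentages as a Series indexed by set name."""
    return pd.Series(
        {s.name: (float("nan") if s.cpg_percent is None else s.cpg_percent) for s in sets},
        name="cpg_percent",
    )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(sample: MethylomeSample, region_set: RegionSet) -> tuple[float, int]:
    """Mean-of-means methylation of one sample over one region set.

    Per region with at least one covered CpG: the unweighted mean of the
    per-CpG methylation fractions.  The set value is the unweighted mean of
    those region means; regions without coverage are skipped, not
    zero-filled.  Returns (value, n) where n is the total number of covered
    CpG measurements; value is NaN when no region is covered.  A CpG inside
    k overlapping regions of the set contributes to each region.
    """
    if not region_set.intervals or sample.n_calls == 0:
        return float("nan"), 0
    calls = sample.calls
    region_means: list[float] = []
    n_measurements = 0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        frac = sub["meth_count"].to_numpy() / sub["total_count"].to_numpy()
        by_chrom[chrom] = (pos, frac)
    for chrom, start, end in region_set.intervals:
        entry = by_chrom.get(chrom)
        if entry is None:
            continue
        pos, frac = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        if hi > lo:
            region_means.append(float(frac[lo:hi].mean()))
            n_measurements += int(hi - lo)
    if not region_means:
        return float("nan"), 0
    return float(np.mean(region_means)), n_measurements


def build_matrix(
    samples: Sequence[MethylomeSample], sets: Sequence[RegionSet]
) -> RegionSetMatrix:
    """Aggregate every sample over every region set."""
    sample_ids = [s.sample_id for s in samples]
    set_names = [rs.name for rs in sets]
    values = np.full((len(samples), len(sets)), np.nan)
    counts = np.zeros((len(samples), len(sets)), dtype=np.int64)
    for i, sample in enumerate(samples):
        for j, rs in enumerate(sets):
            v, n = aggregate(sample, rs)
            values[i, j] = v
            counts[i, j] = n
    return RegionSetMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=set_names),
        n_measurements=pd.DataFrame(counts, index=sample_ids, columns=set_names),
    )


def filter_region_sets(
    matrix: RegionSetMatrix,
    min_measurements: int = 100,
    mean_measurements: int = 200,
) -> RegionSetMatrix:
    """Drop low-support region sets.

    A set is kept iff, across all samples, the minimum number of CpG
    measurements is >= ``min_measurements`` AND the mean is >=
    ``mean_measurements``.  Column order is preserved.
    """
    n = matrix.n_measurements
    keep = (n.min(axis=0) >= min_measurements) & (n.mean(axis=0) >= mean_measurements)
    kept_cols = [c for c in matrix.set_names if keep[c]]
    if not kept_cols:
        warnings.warn("support filter removed every region set", stacklevel=2)
    return RegionSetMatrix(
        values=matrix.values[kept_cols], n_measurements=matrix.n_measurements[kept_cols]
    )


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: RegionSetMatrix, values_path, counts_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="sample_id")
    matrix.n_measurements.to_csv(counts_path, sep="\t", index_label="sample_id")


def read_matrix(values_path, counts_path) -> RegionSetMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="sample_id")
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    return RegionSetMatrix(values=values, n_measurements=counts)
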