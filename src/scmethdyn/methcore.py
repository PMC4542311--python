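"""Per-sample methylome data model.

A methylome sample is a sparse collection of per-CpG methylation calls:
for each covered CpG position, the number of reads observing it methylated
and the total number of observations.  Single cells at ~1x coverage yield
mostly binary calls (total_count == 1); bulk controls carry real depth.

Coordinates are 0-based half-open throughout.  CpG calls are strand-collapsed
to the forward-strand C position; coverage files that report the two strands
separately (positions differing by 1) can be merged at ingestion with
``destrand=True``.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


@dataclass(frozen=True)
class CpGCall:
    """A single CpG methylation observation count.

    ``pos`` is the 0-based forward-strand position of the C.
    """

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise ValueError(f"total_count must be >= 1, got {self.total_count}")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )

    @property
    def fraction(self) -> float:
        return self.meth_count / self.total_count


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series([], dtype=str),
            "pos": pd.Series([], dtype=np.int64),
            "meth_count": pd.Series([], dtype=np.int64),
            "total_count": pd.Series([], dtype=np.int64),
        }
    )


def calls_dataframe(calls: Union[pd.DataFrame, Iterable[CpGCall], None]) -> pd.DataFrame:
    """Normalize calls to a sorted, validated DataFrame unique by (chrom, pos)."""
    if calls is None:
        df = _empty_calls()
    elif isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        rows = list(calls)
        if not rows:
            df = _empty_calls()
        else:
            df = pd.DataFrame(
                {
                    "chrom": [c.chrom for c in rows],
                    "pos": [c.pos for c in rows],
                    "meth_count": [c.meth_count for c in rows],
                    "total_count": [c.total_count for c in rows],
                }
            )
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calls table missing columns: {missing}")
    df = df[CALL_COLUMNS].astype(
        {"chrom": str, "pos": np.int64, "meth_count": np.int64, "total_count": np.int64}
    )
    if len(df):
        if (df["total_count"] < 1).any():
            raise ValueError("calls with total_count < 1 are invalid")
        if (df["meth_count"] < 0).any() or (df["meth_count"] > df["total_count"]).any():
            raise ValueError("meth_count must lie in [0, total_count]")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in calls")
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class MethylomeSample:
    """One sample's sparse methylome plus its sheet metadata.

    ``cell_count`` is an integer for sorted cell pools or the string "bulk"
    for bulk controls.  ``aligned_reads`` is the post-deduplication aligned
    read count from the sample sheet and feeds the saturation x-axis; it is
    unrelated to the number of covered positions.
    """

    sample_id: str
    calls: pd.DataFrame = field(default_factory=_empty_calls)
    genome_label: str = "synthetic"
    cell_count: Union[int, str] = 1
    group: str = ""
    aligned_reads: int = 0

    def __post_init__(self) -> None:
        self.calls = calls_dataframe(self.calls)
        if self.aligned_reads < 0:
            raise ValueError("aligned_reads must be non-negative")

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def positions(self) -> set[tuple[str, int]]:
        """Covered positions as a set of (chrom, pos)."""
        return set(zip(self.calls["chrom"], self.calls["pos"].tolist()))


@dataclass
class TileVector:
    """Genome-anchored fixed tiling of one sample's methylome.

    ``values`` maps (chrom, tile_index) to the count-weighted methylation
    fraction of the CpG calls inside tile [index*size, (index+1)*size);
    only tiles with at least one covered CpG are present.
    """

    tile_size: int
    values: dict[tuple[str, int], float]
    n_cpgs: dict[tuple[str, int], int]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# coverage-file I/O (Bismark-coverage-style dialect)
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_coverage_file(
    path,
    sample_id: str | None = None,
    genome_label: str = "synthetic",
    cell_count: Union[int, str] = 1,
    group: str = "",
    aligned_reads: int = 0,
    destrand: bool = False,
) -> MethylomeSample:
    """Read a Bismark-coverage-style TSV into a :class:`MethylomeSample`.

    Expected columns: chrom, start, end, methylation percent, methylated
    count, unmethylated count.  ``pos`` is taken from the start column and
    ``total_count = meth + unmeth``; a line with total 0 is rejected.  If the
    reported percentage disagrees with the counts by more than 0.5 a warning
    is issued and the counts win.

    With ``destrand=True``, a call whose position immediately follows another
    call (the reverse-strand C of the same CpG) is merged into the lower
    position.
    """
    if sample_id is None:
        stem = str(path).rsplit("/", 1)[-1]
        for suffix in (".gz", ".cov", ".tsv", ".txt", ".bedGraph"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        sample_id = stem
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    totals: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                pct = float(fields[3])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            total = meth + unmeth
            if total < 1:
                raise ValueError(
                    f"{path}:{lineno}: zero total count (meth=0, unmeth=0) is invalid"
                )
            if abs(pct - 100.0 * meth / total) > 0.5:
                warnings.warn(
                    f"{path}:{lineno}: reported percent {pct} disagrees with "
                    f"counts {meth}/{total}; counts win",
                    stacklevel=2,
                )
            chroms.append(chrom)
            poss.append(start)
            meths.append(meth)
            totals.append(total)
    df = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "meth_count": meths, "total_count": totals}
    )
    if destrand and len(df):
        df = _destrand(df)
    return MethylomeSample(
        sample_id=sample_id,
        calls=df,
        genome_label=genome_label,
        cell_count=cell_count,
        group=group,
        aligned_reads=aligned_reads,
    )


def _destrand(df: pd.DataFrame) -> pd.DataFrame:
    """Merge calls at pos+1 into an existing call at pos (opposite strands)."""
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out_frames = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        # a call is the reverse-strand mate if the preceding position exists
        anchor = pos.copy()
        prev = set(pos.tolist())
        for i, p in enumerate(pos):
            if p - 1 in prev:
                anchor[i] = p - 1
        sub = sub.assign(pos=anchor)
        merged = sub.groupby("pos", as_index=False)[["meth_count", "total_count"]].sum()
        merged.insert(0, "chrom", chrom)
        out_frames.append(merged)
    return pd.concat(out_frames, ignore_index=True)


def write_coverage_file(sample: MethylomeSample, path) -> None:
    """Write calls as Bismark-coverage-style TSV (percent with 2 decimals)."""
    with _open_text(path, "wt") as fh:
        for chrom, pos, meth, total in sample.calls.itertuples(index=False):
            pct = 100.0 * meth / total
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct:.2f}\t{meth}\t{total - meth}\n")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def global_methylation(sample: MethylomeSample) -> float:
    """Pooled methylation level: sum(meth_count) / sum(total_count).

    Returns NaN for a sample with zero calls.
    """
    if sample.n_calls == 0:
        return float("nan")
    return float(sample.calls["meth_count"].sum() / sample.calls["total_count"].sum())


def tile_means(sample: MethylomeSample, tile_size: int) -> TileVector:
    """Count-weighted methylation means in fixed genome-anchored tiles.

    Tiles are [k*tile_size, (k+1)*tile_size); tile_index = pos // tile_size,
    so tiles are directly comparable across samples.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if sample.n_calls == 0:
        return TileVector(tile_size=tile_size, values={}, n_cpgs={})
    df = sample.calls
    idx = df["pos"].to_numpy() // tile_size
    grouped = (
        df.assign(tile=idx)
        .groupby(["chrom", "tile"], sort=True)
        .agg(meth=("meth_count", "sum"), total=("total_count", "sum"), n=("pos", "size"))
    )
    values = {
        (chrom, int(tile)): float(row.meth / row.total)
        for (chrom, tile), row in grouped.iterrows()
    }
    n_cpgs = {(chrom, int(tile)): int(row.n) for (chrom, tile), row in grouped.iterrows()}
    return TileVector(tile_size=tile_size, values=values, n_cpgs=n_cpgs)


def tile_matrix(
    samples: Sequence[MethylomeSample], tile_size: int
) -> pd.DataFrame:
    """Samples x tiles matrix of tile means (NaN where a tile is uncovered).

    Columns are (chrom, tile_index) tuples sorted genomically; this is the
    feature matrix consumed by MDS and within-group variability.
    """
    vectors = [tile_means(s, tile_size) for s in samples]
    all_tiles = sorted({t for v in vectors for t in v.values})
    data = np.full((len(samples), len(all_tiles)), np.nan)
    col_index = {t: j for j, t in enumerate(all_tiles)}
    for i, v in enumerate(vectors):
        for t, val in v.values.items():
            data[i, col_index[t]] = val
    return pd.DataFrame(
        data, index=[s.sample_id for s in samples], columns=all_tiles
    )


def write_tile_bedgraph(tiles: TileVector, path) -> None:
    """Export a TileVector as BEDGraph (chrom, start, end, fraction)."""
    with _open_text(path, "wt") as fh:
        for (chrom, idx), val in sorted(tiles.values.items()):
            start = idx * tiles.tile_size
            fh.write(f"{chrom}\t{start}\t{start + tiles.tile_size}\t{val:.6f}\n")


def merge_composite(samples: Sequence[MethylomeSample]) -> MethylomeSample:
    """Merge low-coverage samples into a single composite methylome.

    Per position, methylated and total counts are summed across samples;
    covered positions are the union; aligned read counts are summed.  All
    samples must share a genome label.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("merge_composite requires at least one sample")
    labels = {s.genome_label for s in samples}
    if len(labels) > 1:
        raise ValueError(f"cannot merge samples with mixed genome labels: {sorted(labels)}")
    merged = (
        pd.concat([s.calls for s in samples], ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False)[["meth_count", "total_count"]]
        .sum()
    )
    cell_counts = [s.cell_count for s in samples]
    total_cells: Union[int, str]
    if any(isinstance(c, str) for c in cell_counts):
        total_cells = "bulk"
    else:
        total_cells = int(sum(cell_counts))
    return MethylomeSample(
        sample_id="+".join(s.sample_id for s in samples),
        calls=merged,
        genome_label=samples[0].genome_label,
        cell_count=total_cells,
        group=samples[0].group if len({s.group for s in samples}) == 1 else "composite",
        aligned_reads=int(sum(s.aligned_reads for s in samples)),
    )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, genome_label, cell_count, group, aligned_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "genome_label", "cell_count", "group", "aligned_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_sample_sheet(samples: Sequence[MethylomeSample], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genome_label": s.genome_label,
            "cell_count": s.cell_count,
            "group": s.group,
            "aligned_reads": s.aligned_reads,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
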