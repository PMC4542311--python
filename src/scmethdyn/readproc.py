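"""Read-level processing downstream of bisulfite alignment.

Consumes per-read records (a documented TSV dialect produced from aligner
output) and applies the conversion-evidence filter, PCR-duplicate removal,
collapsing into per-CpG calls, and spike-in conversion-rate estimation.

Bisulfite chemistry converts unmethylated cytosines to thymines.  A genomic
read whose non-CpG cytosines were NOT converted is either an unconverted or
a contaminating fragment; reads with fewer than three converted non-CpG
cytosines are discarded.  Spike-in oligonucleotides of known methylation
state are exempt from that filter — the unmethylated spike-in is precisely
the instrument that measures failed conversion.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from scmethdyn.methcore import calls_dataframe

SOURCES = ("genome", "spikein_meth", "spikein_unmeth")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned bisulfite read with its conversion evidence.

    ``non_cpg_c_total`` counts cytosines outside a CpG context covered by the
    read; ``non_cpg_c_converted`` counts those read as thymine.  ``cpg_obs``
    lists (position, methylated) observations at CpG sites.  ``source`` tags
    genomic reads versus the two spike-in oligo classes.
    """

    chrom: str
    start: int
    end: int
    non_cpg_c_total: int = 0
    non_cpg_c_converted: int = 0
    cpg_obs: tuple[tuple[int, bool], ...] = ()
    source: str = "genome"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read interval empty: [{self.start}, {self.end})")
        if not 0 <= self.non_cpg_c_converted <= self.non_cpg_c_total:
            raise ValueError("non_cpg_c_converted must lie in [0, non_cpg_c_total]")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        object.__setattr__(self, "cpg_obs", tuple((int(p), bool(m)) for p, m in self.cpg_obs))
        for pos, _ in self.cpg_obs:
            if not self.start <= pos < self.end:
                raise ValueError(f"CpG observation at {pos} outside read [{self.start}, {self.end})")


@dataclass
class ConversionRates:
    """Bisulfite conversion error rates estimated from spike-in controls.

    under_conversion: fraction of cytosines on the unmethylated spike-in
    still read as C (conversion failure).  over_conversion: fraction of
    cytosines on the methylated spike-in read as T (conversion of a
    protected base).  A rate is None when its spike-in class contributed
    zero cytosine observations.
    """

    under_conversion: Optional[float]
    over_conversion: Optional[float]
    n_unmeth_c: int = 0
    n_meth_c: int = 0

    @property
    def under_missing(self) -> bool:
        return self.under_conversion is None

    @property
    def over_missing(self) -> bool:
        return self.over_conversion is None


def filter_unconverted_reads(
    reads: Sequence[ReadRecord], min_converted: int = 3
) -> list[ReadRecord]:
    """Drop genomic reads with fewer than ``min_converted`` converted non-CpG Cs.

    Reads with zero non-CpG cytosines cannot demonstrate conversion and are
    discarded.  Spike-in reads are always retained.  Order is preserved.
    """
    if min_converted < 0:
        raise ValueError("min_converted must be >= 0")
    return [
        r
        for r in reads
        if r.source != "genome" or r.non_cpg_c_converted >= min_converted
    ]


def deduplicate_reads(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Remove presumed PCR duplicates keyed on identical (chrom, start, end).

    The first read in input order wins; output preserves input order.
    """
    seen: set[tuple[str, int, int]] = set()
    out: list[ReadRecord] = []
    for r in reads:
        key = (r.chrom, r.start, r.end)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def calls_from_reads(reads: Sequence[ReadRecord]) -> pd.DataFrame:
    """Collapse per-read CpG observations into position-level call counts.

    Returns a calls table (chrom, pos, meth_count, total_count) with one row
    per distinct observed position.  Intended for filtered, deduplicated
    genomic reads; spike-in reads are ignored.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for r in reads:
        if r.source != "genome":
            continue
        for pos, methylated in r.cpg_obs:
            c = counts.setdefault((r.chrom, pos), [0, 0])
            c[0] += int(methylated)
            c[1] += 1
    rows = {
        "chrom": [k[0] for k in counts],
        "pos": [k[1] for k in counts],
        "meth_count": [v[0] for v in counts.values()],
        "total_count": [v[1] for v in counts.values()],
    }
    return calls_dataframe(pd.DataFrame(rows))


def conversion_rates(reads: Sequence[ReadRecord]) -> ConversionRates:
    """Estimate over-/under-conversion from spike-in reads.

    All cytosine observations on the spike-ins are pooled — CpG and non-CpG
    alike — because the oligo methylation state is known by design: every C
    on the methylated spike-in is methylated, every C on the unmethylated
    spike-in is not.  An unmethylated-spike-in C read as C is a conversion
    failure; a methylated-spike-in C read as T is an over-conversion.
    """
    unmeth_total = unmeth_unconverted = 0
    meth_total = meth_converted = 0
    for r in reads:
        if r.source == "spikein_unmeth":
            unmeth_total += r.non_cpg_c_total + len(r.cpg_obs)
            unmeth_unconverted += (r.non_cpg_c_total - r.non_cpg_c_converted) + sum(
                1 for _, m in r.cpg_obs if m
            )
        elif r.source == "spikein_meth":
            meth_total += r.non_cpg_c_total + len(r.cpg_obs)
            meth_converted += r.non_cpg_c_converted + sum(
                1 for _, m in r.cpg_obs if not m
            )
    under = unmeth_unconverted / unmeth_total if unmeth_total else None
    over = meth_converted / meth_total if meth_total else None
    return ConversionRates(
        under_conversion=under,
        over_conversion=over,
        n_unmeth_c=unmeth_total,
        n_meth_c=meth_total,
    )


# ---------------------------------------------------------------------------
# read-record TSV dialect
# ---------------------------------------------------------------------------
# 8 tab-separated columns:
#   chrom  start  end  non_cpg_c_total  non_cpg_c_converted  cpg_positions  cpg_flags  source
# cpg_positions: ';'-joined integers, '.' if none; cpg_flags: ';'-joined 0/1.

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_read_file(path) -> list[ReadRecord]:
    """Parse the 8-column read-record TSV dialect (gzip-transparent)."""
    out: list[ReadRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                nct, ncc = int(fields[3]), int(fields[4])
                if fields[5] == ".":
                    obs: tuple[tuple[int, bool], ...] = ()
                else:
                    positions = [int(x) for x in fields[5].split(";")]
                    flags = [bool(int(x)) for x in fields[6].split(";")]
                    if len(positions) != len(flags):
                        raise ValueError("cpg position/flag count mismatch")
                    obs = tuple(zip(positions, flags))
                rec = ReadRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    non_cpg_c_total=nct,
                    non_cpg_c_converted=ncc,
                    cpg_obs=obs,
                    source=fields[7],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed read record ({exc})") from exc
            out.append(rec)
    return out


def write_read_file(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            if r.cpg_obs:
                positions = ";".join(str(p) for p, _ in r.cpg_obs)
                flags = ";".join(str(int(m)) for _, m in r.cpg_obs)
            else:
                positions, flags = ".", "."
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.non_cpg_c_total}\t"
                f"{r.non_cpg_c_converted}\t{positions}\t{flags}\t{r.source}\n"
            )
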