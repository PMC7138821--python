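"""Assembly summary statistics, adjusted BUSCO gene-space scores, and
k-mer-spectrum genome-size estimation.

The BUSCO adjustment rescales a raw completeness percentage from the full
benchmark universe (1,440 embryophyte genes) to the universe excluding
genes absent from the whole lineage (13 genes missing from all rice
assemblies tested and from maize outgroups): adjusted = raw * 1440 / 1427,
rounded half-up to two decimals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError

BUSCO_UNIVERSE = 1440
LINEAGE_ABSENT = 13


@dataclass
class AssemblyStats:
    name: str
    contig_lengths: list[int]
    gap_count: int
    raw_busco_pct: float | None = None
    adjusted_busco_pct: float | None = None

    @property
    def total_bp(self) -> int:
        return sum(self.contig_lengths)

    @property
    def n50(self) -> int:
        return contig_n50(self.contig_lengths)


@dataclass
class BuscoPanel:
    """Per-assembly missing BUSCO ids plus an outgroup presence table."""

    missing: dict[str, set[str]]               # assembly -> missing gene ids
    outgroup_presence: dict[str, dict[str, bool]]  # gene -> outgroup -> present
    universe: int = BUSCO_UNIVERSE


def contig_n50(lengths: Sequence[int]) -> int:
    """Smallest length L with contigs >= L covering half the assembly."""
    if not len(lengths):
        raise ValidationError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValidationError("non-positive contig length")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def gap_count(sequence: str) -> int:
    """Number of maximal runs of N (case-insensitive)."""
    return len(re.findall(r"[Nn]+", sequence))


def adjusted_busco(raw_pct: float, total: int = BUSCO_UNIVERSE,
                   excluded: int = LINEAGE_ABSENT) -> float:
    """Rescale completeness to the universe minus lineage-absent genes."""
    if not 0 <= raw_pct <= 100:
        raise ValidationError(f"raw percentage {raw_pct} outside [0, 100]")
    if excluded >= total:
        raise ValidationError("excluded must be smaller than the universe")
    val = Decimal(str(raw_pct)) * total / (total - excluded)
    out = float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    if out > 100:
        warnings.warn(f"adjusted score {out} capped at 100", RuntimeWarning)
        out = 100.0
    return out


def universal_missing(panel: BuscoPanel) -> tuple[set[str], set[str]]:
    """Genes missing from every assembly, and the subset also absent from
    every outgroup genome (candidates for lineage-wide absence)."""
    if not panel.missing:
        raise ValidationError("empty BUSCO panel")
    if panel.universe <= 0:
        raise ValidationError("empty BUSCO universe")
    sets = list(panel.missing.values())
    missing_in_all = set.intersection(*sets)
    lineage_absent = {
        g for g in missing_in_all
        if not any(panel.outgroup_presence.get(g, {}).values())
    }
    return missing_in_all, lineage_absent


# ---------------------------------------------------------------------------
# k-mer genome size
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTacgt", "TGCATGCA")


def _canonical_counts(reads: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in reads:
        seq = seq.upper()
        rc = seq.translate(_COMP)[::-1]
        L = len(seq)
        for i in range(L - k + 1):
            fwd = seq[i:i + k]
            if "N" in fwd:
                continue
            rev = rc[L - k - i:L - i]
            kmer = fwd if fwd <= rev else rev
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_depth_histogram(reads: Iterable[str], k: int) -> np.ndarray:
    """hist[d] = number of distinct canonical k-mers observed d times."""
    if not 13 <= k <= 31:
        raise ValidationError(f"k={k} outside the supported range 13..31")
    counts = _canonical_counts(reads, k)
    if not counts:
        raise ValidationError("no k-mers counted")
    return np.bincount(np.fromiter(counts.values(), dtype=np.int64))


def kmer_genome_size(reads: Iterable[str] | Mapping[str, str], k: int = 17,
                     min_depth: int = 2) -> int:
    """Estimate genome size from the k-mer depth spectrum.

    The error peak (low-depth k-mers from sequencing errors) is separated at
    the first local minimum of the histogram; the genome size is the total
    number of k-mer observations above that cutoff divided by the peak
    depth.  The peak depth is measured as the mean depth of the post-cutoff
    spectrum, which coincides with the homozygous-peak position but is
    stable where the raw histogram mode is noisy.
    """
    if isinstance(reads, Mapping):
        reads = list(reads.values())
    hist = kmer_depth_histogram(reads, k)
    # locate the error/signal boundary: first depth where the histogram
    # stops falling
    cutoff = None
    for d in range(1, len(hist) - 1):
        if hist[d] <= hist[d + 1]:
            cutoff = d
            break
    if cutoff is None:
        if min_depth <= 1:
            cutoff = 1  # degenerate low-depth input: whole spectrum is signal
        else:
            raise ValidationError(
                "no local minimum separates the error peak from the coverage "
                "peak; increase coverage or lower min_depth"
            )
    if cutoff > 1:  # an error peak exists; honour the caller's floor too
        cutoff = max(cutoff, min_depth)
    depths = np.arange(len(hist))
    sel = depths >= cutoff
    n_kmers = float((depths[sel] * hist[sel]).sum())
    n_distinct = float(hist[sel].sum())
    if n_distinct == 0:
        raise ValidationError("no k-mers above the error cutoff")
    peak_depth = n_kmers / n_distinct
    return int(round(n_kmers / peak_depth))


# ---------------------------------------------------------------------------
# tabular summaries
# ---------------------------------------------------------------------------


def load_assembly_table() -> pd.DataFrame:
    """Published per-assembly statistics for the 12 rice genomes."""
    with resources.files("panstruct.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def load_te_table() -> pd.DataFrame:
    """Published TE-class percentages for the 16-genome panel."""
    with resources.files("panstruct.data").joinpath("table4.csv").open() as fh:
        return pd.read_csv(fh)


def table_summaries(df: pd.DataFrame, columns: Sequence[str] | None = None,
                    label_col: str | None = None) -> pd.DataFrame:
    """Mean (rounded half-up to 2 decimals), min and max per numeric column,
    with the row label attaining each extreme when *label_col* is given."""
    if columns is None:
        columns = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for col in columns:
        vals = df[col]
        bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
        if len(bad):
            raise ValidationError(f"non-numeric cell {bad.iloc[0]!r} in column {col!r}")
        vals = pd.to_numeric(vals)
        mean = float(Decimal(str(float(vals.mean()))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP))
        row = {"column": col, "mean": mean,
               "min": float(vals.min()), "max": float(vals.max())}
        if label_col is not None:
            row["min_label"] = df.loc[vals.idxmin(), label_col]
            row["max_label"] = df.loc[vals.idxmax(), label_col]
        rows.append(row)
    return pd.DataFrame(rows)


def count_passing(df: pd.DataFrame, column: str, op: str, threshold: float) -> int:
    """Number of rows whose *column* passes the comparison."""
    import operator
    ops = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
           ">=": operator.ge, "==": operator.eq}
    vals = pd.to_numeric(df[column])
    return int(ops[op](vals, threshold).sum())
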