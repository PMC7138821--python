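"""Domain types and file I/O for the pipeline.

All genomic coordinates are 0-based half-open internally.  VCF positions are
converted on read and restored on write.  Missing genotype dosages are stored
as -1 internally and rendered as ``NA`` in the simple matrix dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

MISSING = -1

SV_TYPES = ("INS", "DEL", "DUP_TANDEM")

# VCF SVTYPE spellings normalized to internal type names
_SVTYPE_ALIASES = {
    "INS": "INS",
    "DEL": "DEL",
    "DUP_TANDEM": "DUP_TANDEM",
    "DUP:TANDEM": "DUP_TANDEM",
}

_NUC = set("ACGTNacgtn")


class FormatError(ValueError):
    """Structurally malformed input (ragged rows, bad header, ...)."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with values in {0, 1, 2} or -1 (missing)."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValidationError(
                f"dosage grid {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("duplicate SNP ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} out of range at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.dosages == MISSING).mean(axis=0)


@dataclass
class QMatrix:
    """Per-sample admixture proportions over K ancestral groups.

    Rows lie on the probability simplex (sum to 1 within 1e-6).
    """

    sample_ids: list[str]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValidationError("proportions must be a 2-D array")
        if self.proportions.shape[0] != len(self.sample_ids):
            raise ValidationError("row count does not match sample ids")
        if self.K < 1:  # K = 1 only arises as the degenerate single-ancestry fit
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if ((self.proportions < 0) | (self.proportions > 1)).any():
            raise ValidationError("proportions outside [0, 1]")
        sums = self.proportions.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > 1e-6).any():
            i = int(np.argmax(off))
            raise ValidationError(
                f"row {i} ({self.sample_ids[i]!r}) sums to {sums[i]:.8f}, not 1"
            )

    @property
    def K(self) -> int:
        return self.proportions.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant on a reference contig.

    DEL and DUP_TANDEM span ``[start, end)`` with ``length == end - start``.
    An INS occupies the single anchor base ``[start, start + 1)``; its
    inserted length is carried in ``length``.
    """

    ref_name: str
    start: int
    end: int
    svtype: str
    length: int

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown svtype {self.svtype!r}")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")
        if self.length <= 0:
            raise ValidationError(f"non-positive SV length {self.length}")
        if self.svtype in ("DEL", "DUP_TANDEM") and self.length != self.end - self.start:
            raise ValidationError(
                f"{self.svtype} length {self.length} != span {self.end - self.start}"
            )
        if self.svtype == "INS" and self.end != self.start + 1:
            raise ValidationError("INS must occupy a single anchor base")


class IntervalSet:
    """Sorted disjoint [start, end) intervals per reference name."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivals: dict[str, np.ndarray] = {}
        if intervals:
            for ref, pairs in intervals.items():
                self._ivals[ref] = _normalize(pairs)

    @property
    def refs(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self, ref: str) -> np.ndarray:
        """(k, 2) array of disjoint intervals on *ref* (empty if absent)."""
        return self._ivals.get(ref, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._ivals.values())
        )

    def intersect_bp(self, other: "IntervalSet") -> int:
        """Total bp shared with *other*."""
        total = 0
        for ref in self._ivals:
            a, b = self.intervals(ref), other.intervals(ref)
            if not len(a) or not len(b):
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i, 0], b[j, 0])
                hi = min(a[i, 1], b[j, 1])
                if hi > lo:
                    total += int(hi - lo)
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
        return total

    def union(self, other: "IntervalSet") -> "IntervalSet":
        merged: dict[str, list[tuple[int, int]]] = {}
        for src in (self, other):
            for ref in src._ivals:
                merged.setdefault(ref, []).extend(map(tuple, src.intervals(ref)))
        return IntervalSet(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[r], other._ivals[r]) for r in self._ivals)


def _normalize(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = sorted((int(s), int(e)) for s, e in pairs)
    for s, e in arr:
        if e < s:
            raise ValidationError(f"interval end {e} < start {s}")
        if s < 0:
            raise ValidationError(f"negative interval start {s}")
    out: list[list[int]] = []
    for s, e in arr:
        if s == e:
            continue
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Q files
# ---------------------------------------------------------------------------


def read_q_file(path: str | Path, sample_ids: Sequence[str] | None = None) -> QMatrix:
    """Read a whitespace-delimited .Q file (one row of K fractions per sample).

    Rows within 1e-3 of summing to 1 are renormalized; larger deviations are
    validation errors naming the offending row.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                vals = [float(x) for x in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric entry ({exc})")
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty Q file")
    k = len(rows[0])
    if k < 2:
        raise FormatError(f"{path}: a Q file needs at least 2 columns")
    for lineno, vals in enumerate(rows, 1):
        if len(vals) != k:
            raise FormatError(
                f"{path}: ragged row {lineno}: {len(vals)} columns, expected {k}"
            )
    arr = np.array(rows, dtype=float)
    sums = arr.sum(axis=1)
    off = np.abs(sums - 1.0)
    if (off > 1e-3).any():
        i = int(np.argmax(off))
        raise ValidationError(f"{path}: row {i + 1} sums to {sums[i]:.6f}, not 1")
    arr = arr / sums[:, None]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(rows))]
    return QMatrix(list(sample_ids), arr)


def write_q_file(q: QMatrix, path: str | Path) -> None:
    np.savetxt(path, q.proportions, fmt="%.6f")


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

_DIALECTS = ("simple_matrix", "plink_raw_like")


def read_genotypes(path: str | Path, dialect: str = "simple_matrix") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``simple_matrix``: tab-separated; header ``sample<TAB>snp1<TAB>...``;
    entries 0/1/2/NA.  ``plink_raw_like``: whitespace-separated .raw-style
    layout with FID IID PAT MAT SEX PHENOTYPE leading columns and SNP
    headers; IID is taken as the sample id.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty genotype file")
    if dialect == "simple_matrix":
        header = lines[0].split("\t")
        snp_ids = header[1:]
        n_meta = 1
        split = lambda ln: ln.split("\t")  # noqa: E731
        sample_col = 0
    else:
        header = lines[0].split()
        if len(header) < 7 or header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise FormatError(f"{path}: not a plink-raw-like header")
        snp_ids = header[6:]
        n_meta = 6
        split = lambda ln: ln.split()  # noqa: E731
        sample_col = 1
    sample_ids: list[str] = []
    dosages = np.empty((len(lines) - 1, len(snp_ids)), dtype=np.int16)
    for r, line in enumerate(lines[1:], start=2):
        parts = split(line)
        if len(parts) != n_meta + len(snp_ids):
            raise FormatError(
                f"{path}: line {r}: {len(parts)} fields, expected {n_meta + len(snp_ids)}"
            )
        sample_ids.append(parts[sample_col])
        for c, tok in enumerate(parts[n_meta:]):
            if tok in ("NA", "nan", "."):
                dosages[r - 2, c] = MISSING
            elif tok in ("0", "1", "2"):
                dosages[r - 2, c] = int(tok)
            else:
                raise ValidationError(
                    f"{path}: line {r}: dosage {tok!r} for SNP {snp_ids[c]!r} "
                    "not in {0, 1, 2, NA}"
                )
    return GenotypeMatrix(sample_ids, snp_ids, dosages)


def write_genotypes(g: GenotypeMatrix, path: str | Path, dialect: str = "simple_matrix") -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "simple_matrix":
            fh.write("sample\t" + "\t".join(g.snp_ids) + "\n")
            for sid, row in zip(g.sample_ids, g.dosages):
                toks = ["NA" if d == MISSING else str(int(d)) for d in row]
                fh.write(sid + "\t" + "\t".join(toks) + "\n")
        else:
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(g.snp_ids) + "\n")
            for sid, row in zip(g.sample_ids, g.dosages):
                toks = ["NA" if d == MISSING else str(int(d)) for d in row]
                fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    ("INFO", "SVTYPE", "1", "String", "Type of structural variant"),
    ("INFO", "SVLEN", "1", "Integer", "Length of structural variant"),
    ("INFO", "END", "1", "Integer", "End position of structural variant"),
]


def read_sv_vcf(path: str | Path) -> tuple[list[SVRecord], dict[str, int]]:
    """Parse SVs from a VCF into 0-based half-open records.

    Returns ``(records, drop_counts)``; SVTYPEs other than INS/DEL/tandem DUP
    are dropped and tallied, as are records lacking both SVLEN and END.
    """
    records: list[SVRecord] = []
    drops: dict[str, int] = {"other_svtype": 0, "no_length": 0}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None or _SVTYPE_ALIASES.get(str(svtype)) is None:
                drops["other_svtype"] += 1
                continue
            svtype = _SVTYPE_ALIASES[str(svtype)]
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            start = rec.pos - 1  # VCF 1-based -> half-open
            if svtype == "INS":
                if svlen is None:
                    drops["no_length"] += 1
                    continue
                records.append(SVRecord(rec.chrom, start, start + 1, "INS", abs(int(svlen))))
            else:
                # span from SVLEN when present (htslib rewrites stop from
                # SVLEN for symbolic alleles, so INFO/END is unreliable
                # through the API); otherwise from END via rec.stop
                if svlen is not None:
                    end = start + abs(int(svlen))
                elif int(rec.stop) > start + 1:
                    end = int(rec.stop)
                else:
                    drops["no_length"] += 1
                    continue
                records.append(SVRecord(rec.chrom, start, end, svtype, end - start))
    dropped = sum(drops.values())
    if dropped:
        log.info("read_sv_vcf: dropped %d records (%s)", dropped, drops)
    return records, drops


def write_sv_vcf(records: Sequence[SVRecord], path: str | Path,
                 contig_lengths: Mapping[str, int]) -> None:
    """Write records back out as a minimal VCF (restoring 1-based POS).

    The body is emitted as text: htslib rewrites INFO/END from SVLEN for
    symbolic alleles, which breaks the half-open coordinate convention
    used here.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for _, key, num, typ, desc in _VCF_HEADER_LINES:
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.ref_name, r.start)):
            svtype = "DUP:TANDEM" if r.svtype == "DUP_TANDEM" else r.svtype
            if r.svtype == "INS":
                info = f"SVTYPE={svtype};SVLEN={r.length}"
            else:
                svlen = -r.length if r.svtype == "DEL" else r.length
                info = f"SVTYPE={svtype};SVLEN={svlen};END={r.end}"
            fh.write(f"{r.ref_name}\t{r.start + 1}\t.\tN\t<{svtype}>\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id, validating the nucleotide alphabet."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        bad = set(s) - _NUC
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} contains non-nucleotide symbol(s) "
                f"{sorted(bad)}"
            )
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a >=3-column BED into a normalized IntervalSet."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
            if e < s or s < 0:
                raise ValidationError(f"{path}: line {lineno}: bad interval [{s}, {e})")
            raw.setdefault(parts[0], []).append((s, e))
    return IntervalSet(raw)


def write_bed(ivals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in ivals.refs:
            for s, e in ivals.intervals(ref):
                fh.write(f"{ref}\t{s}\t{e}\n")
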