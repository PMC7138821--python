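"""Pairwise structural-variation quantification between assemblies.

The genome-scale procedure fragments a query assembly into 50-kb
pseudo-reads at 10x redundancy, maps them onto a reference, calls SVs, and
keeps insertions, deletions and tandem duplications up to 25 kb; the
quantity of interest is the total reference sequence affected by SVs per
ordered pair and the fraction of it overlapping transposable elements.
Mapping and calling on real genomes are external; a k-mer anchor-chaining
detector is provided for closed-loop testing on toy genomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .core_io import IntervalSet, SVRecord, ValidationError

log = logging.getLogger(__name__)

MAX_SV_LEN = 25_000
READ_LEN = 50_000
REDUNDANCY = 10


@dataclass
class PseudoRead:
    read_id: str
    contig: str
    start: int
    length: int
    phase: int


@dataclass
class PseudoReadSet:
    source: str
    reads: list[PseudoRead]

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.reads)


@dataclass
class PairwiseSVSummary:
    query: str
    reference: str
    records: list[SVRecord]
    affected_bp: int
    te_overlap_bp: int = 0
    ins_te_flags: dict[int, bool] = field(default_factory=dict)


def fragment(assembly: Mapping[str, str] | Mapping[str, int], source: str = "",
             read_len: int = READ_LEN, redundancy: int = REDUNDANCY) -> PseudoReadSet:
    """Phase-shifted non-overlapping tilings emulating a redundant read set.

    Phase p tiles the contig with windows of *read_len* starting at offset
    ``p * read_len // redundancy``, so every interior base is covered once
    per phase (~redundancy-fold overall).  Terminal partial windows shorter
    than ``read_len / 10`` are dropped; contigs shorter than that are
    emitted whole with a warning.
    """
    if read_len < 1000:
        raise ValidationError("read_len must be >= 1000")
    if redundancy < 1:
        raise ValidationError("redundancy must be >= 1")
    min_keep = read_len // 10
    reads: list[PseudoRead] = []
    for contig, seq in assembly.items():
        L = seq if isinstance(seq, int) else len(seq)
        if L < min_keep:
            warnings.warn(f"contig {contig!r} shorter than read_len/10; emitted whole",
                          RuntimeWarning)
            reads.append(PseudoRead(f"{contig}_p0_r0", contig, 0, L, 0))
            continue
        for p in range(redundancy):
            offset = p * read_len // redundancy
            i = 0
            for s in range(offset, L, read_len):
                length = min(read_len, L - s)
                if length >= min_keep:
                    reads.append(PseudoRead(f"{contig}_p{p}_r{i}", contig, s, length, p))
                    i += 1
    return PseudoReadSet(source, reads)


def filter_svs(records: Sequence[SVRecord],
               max_len: int = MAX_SV_LEN) -> tuple[list[SVRecord], dict[str, int]]:
    """Keep INS/DEL/tandem-DUP records no longer than *max_len* (inclusive)."""
    kept: list[SVRecord] = []
    drops = {"svtype": 0, "length": 0}
    for r in records:
        if r.svtype not in ("INS", "DEL", "DUP_TANDEM"):
            drops["svtype"] += 1
        elif r.length > max_len:
            drops["length"] += 1
        else:
            kept.append(r)
    if drops["svtype"] or drops["length"]:
        log.info("filter_svs: dropped %s", drops)
    return kept, drops


def sv_reference_intervals(records: Sequence[SVRecord]) -> IntervalSet:
    """Merged reference footprints of DEL and tandem-DUP records."""
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if r.svtype in ("DEL", "DUP_TANDEM"):
            by_ref.setdefault(r.ref_name, []).append((r.start, r.end))
    return IntervalSet(by_ref)


def affected_bp(records: Sequence[SVRecord],
                contig_lengths: Mapping[str, int] | None = None) -> int:
    """Total reference bp affected by SVs.

    DEL and tandem-DUP intervals are merged and counted once; each INS adds
    its inserted length.
    """
    if contig_lengths is not None:
        for r in records:
            if r.ref_name not in contig_lengths:
                raise ValidationError(f"record on unknown contig {r.ref_name!r}")
    span = sv_reference_intervals(records).total_bp
    ins = sum(r.length for r in records if r.svtype == "INS")
    return span + ins


def te_fraction(summaries: Sequence[PairwiseSVSummary],
                te_tracks: Mapping[str, IntervalSet]) -> float:
    """Fraction of all affected bp that is TE-related, over all pairs.

    DEL/DUP footprints are intersected with the reference TE track; an INS
    counts as TE only when flagged so by external classification of its
    inserted sequence (unflagged insertions count as non-TE).
    """
    num = den = 0
    for s in summaries:
        if s.reference not in te_tracks:
            raise ValidationError(f"missing TE track for reference {s.reference!r}")
        track = te_tracks[s.reference]
        num += sv_reference_intervals(s.records).intersect_bp(track)
        for i, r in enumerate(s.records):
            if r.svtype == "INS" and s.ins_te_flags.get(i, False):
                num += r.length
        den += affected_bp(s.records)
    if den == 0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# toy-scale SV detection by unique-anchor chaining
# ---------------------------------------------------------------------------


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing chain in both coordinates (patience LIS)."""
    anchors.sort()
    import bisect
    tails: list[int] = []      # query positions of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, q) in enumerate(anchors):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def naive_pair_sv(ref: Mapping[str, str], alt: Mapping[str, str],
                  anchor_k: int = 21, min_len: int = 50,
                  max_ident_frac: float = 0.1) -> list[SVRecord]:
    """Detect INS/DEL/tandem-DUP between two closely related toy genomes.

    Shared k-mers unique in both sequences are chained collinearly; each gap
    between consecutive anchors is classified by its reference-only versus
    query-only extent.  Query-only sequence that aligns (edlib, <=10%
    divergence) to the adjacent upstream reference window is reported as a
    tandem duplication of that window.
    """
    records: list[SVRecord] = []
    for name, rseq in ref.items():
        qseq = alt.get(name)
        if qseq is None:
            raise ValidationError(f"contig {name!r} absent from the query genome")
        rpos = _unique_kmer_positions(rseq, anchor_k)
        qpos = _unique_kmer_positions(qseq, anchor_k)
        anchors = [(rpos[k_], qpos[k_]) for k_ in rpos.keys() & qpos.keys()]
        if not anchors:
            raise ValidationError(f"sequences unrelated at k={anchor_k} on {name!r}")
        chain = _chain(anchors)
        for (r1, q1), (r2, q2) in zip(chain, chain[1:]):
            dr = r2 - r1
            dq = q2 - q1
            delta = dq - dr
            if abs(delta) < min_len:
                continue
            bp = r1 + anchor_k  # first reference base after the left anchor
            if delta < 0:  # reference-only extent -> deletion
                records.append(SVRecord(name, bp, bp - delta, "DEL", -delta))
            else:          # query-only extent -> insertion or tandem dup
                inserted = qseq[q1 + anchor_k:q1 + anchor_k + delta]
                # a tandem duplication's extra copy matches the reference
                # window abutting the breakpoint on either side
                windows = [
                    (rseq[bp:bp + delta], bp, bp + delta),          # downstream
                    (rseq[max(0, bp - delta):bp], bp - delta, bp),  # upstream
                ]
                placed = False
                for wseq, ws, we in windows:
                    if len(wseq) != delta:
                        continue
                    d = edlib.align(inserted, wseq, mode="NW", task="distance")
                    if d["editDistance"] <= max_ident_frac * delta:
                        records.append(SVRecord(name, ws, we, "DUP_TANDEM", delta))
                        placed = True
                        break
                if not placed:
                    records.append(SVRecord(name, bp, bp + 1, "INS", delta))
    return records


def pairwise_matrix(assemblies: Mapping[str, Mapping[str, str]],
                    anchor_k: int = 21, max_len: int = MAX_SV_LEN,
                    group_map: Mapping[str, str] | None = None
                    ) -> tuple[pd.DataFrame, list[PairwiseSVSummary]]:
    """Directional matrix of affected bp over all ordered assembly pairs.

    Entry (query, reference) is the affected reference bp when *query* is
    compared onto *reference*; the diagonal is 0.  With a *group_map*,
    per-group-pair means are attached as a second frame attribute.
    """
    names = list(assemblies)
    if len(names) < 2:
        raise ValidationError("need at least 2 assemblies")
    mat = pd.DataFrame(0, index=names, columns=names, dtype=np.int64)
    summaries: list[PairwiseSVSummary] = []
    for q in names:
        for r in names:
            if q == r:
                continue
            recs = naive_pair_sv(assemblies[r], assemblies[q], anchor_k=anchor_k)
            kept, _ = filter_svs(recs, max_len=max_len)
            bp = affected_bp(kept)
            mat.loc[q, r] = bp
            summaries.append(PairwiseSVSummary(q, r, kept, bp))
    if group_map is not None:
        rows = []
        groups = sorted(set(group_map.values()))
        for ga in groups:
            for gb in groups:
                vals = [mat.loc[q, r] for q in names for r in names
                        if q != r and group_map[q] == ga and group_map[r] == gb]
                if vals:
                    rows.append({"query_group": ga, "ref_group": gb,
                                 "mean_affected_bp": float(np.mean(vals))})
        mat.attrs["group_means"] = pd.DataFrame(rows)
    return mat, summaries
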