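"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure each downstream stage
assumes: structured subpopulations with admixed individuals under a
Balding-Nichols allele-frequency model, ensembles of noisy column-permuted
Q replicates with optional second modes, toy genome pairs with planted
structural variants and a transposable-element track, and uniform shotgun
reads for k-mer analysis.  Every generator is a pure function of its
parameters and an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenotypeMatrix, IntervalSet, QMatrix, SVRecord, ValidationError
from .q_aggregate import RunEnsemble

MAJOR_GROUPS = ("cA", "XI", "GJ")


def _rng(seed: int | None) -> np.random.Generator:
    if seed is None:
        raise ValueError("generators require an explicit integer seed")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


@dataclass
class PopModel:
    """Admixture-model description of a structured genotype panel.

    ``pure_sizes[k]`` samples have ancestry fully in population k;
    ``admixed_specs`` is a list of ``(n, q_vector)`` blocks of samples with
    the given mixing proportions.  ``fst`` controls the Balding-Nichols
    differentiation of per-population allele frequencies around the
    ancestral frequencies.  ``major_group_map`` assigns each population to a
    major variety group (cA / XI / GJ / other).
    """

    K_true: int
    n_snps: int
    fst: float | list[float] = 0.15
    pure_sizes: list[int] | None = None
    admixed_specs: list[tuple[int, list[float]]] = field(default_factory=list)
    ancestral_freqs: np.ndarray | None = None
    major_group_map: list[str] | None = None

    def __post_init__(self) -> None:
        if self.pure_sizes is None:
            self.pure_sizes = [50] * self.K_true
        if len(self.pure_sizes) != self.K_true:
            raise ValidationError("pure_sizes must have K_true entries")
        fst = [self.fst] * self.K_true if np.isscalar(self.fst) else list(self.fst)
        if any(not (0 < f < 1) for f in fst):
            raise ValidationError("fst values must lie in (0, 1)")
        self.fst = fst
        for n, q in self.admixed_specs:
            if len(q) != self.K_true or abs(sum(q) - 1.0) > 1e-6:
                raise ValidationError("admixed mixing proportions must sum to 1 over K_true")
        if self.major_group_map is not None and len(self.major_group_map) != self.K_true:
            raise ValidationError("major_group_map must have K_true entries")

    @property
    def n_samples(self) -> int:
        return sum(self.pure_sizes) + sum(n for n, _ in self.admixed_specs)


def simulate_genotypes(model: PopModel, seed: int) -> tuple[GenotypeMatrix, QMatrix]:
    """Draw a genotype panel and its true ancestry matrix.

    Per-population allele frequencies follow the Balding-Nichols beta model:
    ``f_kj ~ Beta(p_j (1-F_k)/F_k, (1-p_j)(1-F_k)/F_k)`` around the ancestral
    frequency ``p_j``, so that ``Var(f_kj) = F_k p_j (1-p_j)``.  Each dosage
    is Binomial(2, sum_k q_ik f_kj).
    """
    rng = _rng(seed)
    K, m = model.K_true, model.n_snps
    p = model.ancestral_freqs
    if p is None:
        p = rng.uniform(0.1, 0.9, size=m)
    p = np.asarray(p, dtype=float)
    F = np.empty((K, m))
    for k in range(K):
        fk = model.fst[k]
        a = p * (1 - fk) / fk
        b = (1 - p) * (1 - fk) / fk
        F[k] = rng.beta(a, b)
    q_rows: list[np.ndarray] = []
    for k, n in enumerate(model.pure_sizes):
        row = np.zeros(K)
        row[k] = 1.0
        q_rows.extend([row] * n)
    for n, q in model.admixed_specs:
        q_rows.extend([np.asarray(q, dtype=float)] * n)
    Q = np.vstack(q_rows)
    probs = np.clip(Q @ F, 0.0, 1.0)
    dosages = rng.binomial(2, probs).astype(np.int16)
    ids = [f"S{i:04d}" for i in range(len(Q))]
    snps = [f"snp{j}" for j in range(m)]
    return GenotypeMatrix(ids, snps, dosages), QMatrix(ids, Q)


def true_labels(model: PopModel, group_names: list[str] | None = None) -> list[str]:
    """Expected membership label per sample under the 0.65 rules.

    Pure samples carry their group name; admixed blocks carry the
    within-major-group ``-adm`` label when their mixture stays inside one
    major group with total >= 0.65, otherwise ``admixed``.
    """
    if group_names is None:
        group_names = [f"G{k + 1}" for k in range(model.K_true)]
    majors = model.major_group_map or ["other"] * model.K_true
    labels = []
    for k, n in enumerate(model.pure_sizes):
        labels.extend([group_names[k]] * n)
    for n, q in model.admixed_specs:
        q = np.asarray(q)
        if q.max() >= 0.65:
            lab = group_names[int(np.argmax(q))]
        else:
            lab = "admixed"
            for mg in MAJOR_GROUPS:
                s = sum(qk for qk, g in zip(q, majors) if g == mg)
                if s >= 0.65:
                    lab = f"{mg}-adm"
                    break
        labels.extend([lab] * n)
    return labels


# ---------------------------------------------------------------------------
# Q-replicate ensembles
# ---------------------------------------------------------------------------


def _second_mode(true_q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alternative solution at the same K: merge the two closest groups and
    re-split the largest group, mimicking ambiguity over which subgroup a
    given K level resolves."""
    K = true_q.shape[1]
    if K < 3:
        raise ValidationError("a second mode needs K >= 3")
    col_d = np.full((K, K), np.inf)
    for a in range(K):
        for b in range(a + 1, K):
            col_d[a, b] = np.linalg.norm(true_q[:, a] - true_q[:, b])
    a, b = np.unravel_index(np.argmin(col_d), col_d.shape)
    merged = np.delete(true_q, b, axis=1)
    merged[:, a if a < b else a - 1] += true_q[:, b]
    big = int(np.argmax(merged.sum(axis=0)))
    w = np.where(np.arange(merged.shape[0]) % 2 == 0, 0.9, 0.1)
    left = merged[:, big] * w
    right = merged[:, big] * (1 - w)
    out = np.delete(merged, big, axis=1)
    return np.column_stack([out, left, right])


def simulate_run_ensemble(true_q: QMatrix, n_runs: int, noise_sd: float = 0.02,
                          permute: bool = True, modes: int = 1,
                          seed: int = 0, mode2_fraction: float = 0.4) -> RunEnsemble:
    """Replicate ensemble of noisy, column-permuted copies of *true_q*.

    Noise is Dirichlet resampling around each row with concentration
    ``1 / noise_sd**2`` so rows stay on the simplex; ``noise_sd == 0`` means
    exact copies.  With ``modes == 2`` the last ``mode2_fraction`` of runs
    derive from an alternative solution sharing the same K.
    """
    if n_runs < 2:
        raise ValidationError("need n_runs >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = _rng(seed)
    bases = {1: true_q.proportions}
    n_mode2 = int(round(n_runs * mode2_fraction)) if modes == 2 else 0
    if modes == 2:
        bases[2] = _second_mode(true_q.proportions, rng)
    replicates, prov = [], []
    for r in range(n_runs):
        mode = 2 if r >= n_runs - n_mode2 else 1
        base = bases[mode]
        if noise_sd > 0:
            conc = 1.0 / noise_sd**2
            rows = np.vstack([rng.dirichlet((row + 1e-4) * conc) for row in base])
        else:
            rows = base.copy()
        perm = rng.permutation(base.shape[1]) if permute else np.arange(base.shape[1])
        replicates.append(QMatrix(list(true_q.sample_ids), rows[:, perm]))
        prov.append({"run_id": r, "seed": seed, "mode": mode, "permutation": perm.tolist()})
    return RunEnsemble(true_q.K, replicates, prov)


# ---------------------------------------------------------------------------
# toy genomes with planted SVs
# ---------------------------------------------------------------------------


@dataclass
class PlantedSVSet:
    """Ground truth for a simulated genome pair."""

    records: list[SVRecord]
    inserted_seqs: dict[int, str]  # index into records -> inserted/duplicated seq
    te_flags: dict[int, bool]      # index -> event lies in / is a TE sequence


def random_genome(length: int, rng: np.random.Generator, gc: float = 0.44) -> str:
    w = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=w)])


def random_sv_spec(base_len: int, n_events: int, rng_or_seed, min_len: int = 200,
                   max_len: int = 2000, min_gap: int = 2000,
                   types: tuple[str, ...] = ("INS", "DEL", "DUP_TANDEM")) -> list[tuple]:
    """Non-overlapping ``(svtype, position, length)`` events on a base genome."""
    rng = rng_or_seed if isinstance(rng_or_seed, np.random.Generator) else _rng(rng_or_seed)
    spec = []
    slot = base_len // n_events
    if slot < max_len + min_gap:
        raise ValidationError("base genome too short for requested events")
    for i in range(n_events):
        svtype = types[rng.integers(len(types))]
        length = int(rng.integers(min_len, max_len + 1))
        lo = i * slot + min_gap // 2
        hi = (i + 1) * slot - min_gap // 2 - length
        pos = int(rng.integers(lo, hi))
        spec.append((svtype, pos, length))
    return spec


def simulate_toy_genome_pair(base_len: int, sv_spec: list[tuple], seed: int,
                             te_fraction: float = 0.7,
                             ref_name: str = "chr1") -> tuple[dict, dict, PlantedSVSet, IntervalSet]:
    """Reference genome plus an alternative carrying planted SVs.

    ``sv_spec`` lists ``(svtype, ref_position, length)`` with positions on
    the reference; events must not overlap.  Events are applied left to
    right.  DEL removes reference bases; INS adds novel random sequence at
    the position; DUP_TANDEM repeats ``ref[pos:pos+length]`` immediately
    after itself.  A TE interval track covering ``te_fraction`` of the
    planted events (chosen deterministically from the seed) is returned with
    per-event TE flags.
    """
    rng = _rng(seed)
    ref = random_genome(base_len, rng)
    spec = sorted(sv_spec, key=lambda t: t[1])
    last_end = -1
    for svtype, pos, length in spec:
        footprint = length if svtype in ("DEL", "DUP_TANDEM") else 1
        if pos <= last_end:
            raise ValidationError(f"planted events overlap at ref position {pos}")
        if pos + footprint > base_len:
            raise ValidationError(f"event at {pos} exceeds genome length")
        last_end = pos + footprint
    records: list[SVRecord] = []
    inserted: dict[int, str] = {}
    te_flags: dict[int, bool] = {}
    pieces: list[str] = []
    cursor = 0
    for idx, (svtype, pos, length) in enumerate(spec):
        pieces.append(ref[cursor:pos])
        if svtype == "DEL":
            records.append(SVRecord(ref_name, pos, pos + length, "DEL", length))
            cursor = pos + length
        elif svtype == "INS":
            seq = random_genome(length, rng)
            pieces.append(seq)
            records.append(SVRecord(ref_name, pos, pos + 1, "INS", length))
            inserted[idx] = seq
            cursor = pos
        else:  # DUP_TANDEM
            seq = ref[pos:pos + length]
            pieces.append(seq + seq)
            records.append(SVRecord(ref_name, pos, pos + length, "DUP_TANDEM", length))
            inserted[idx] = seq
            cursor = pos + length
        te_flags[idx] = bool(rng.random() < te_fraction)
    pieces.append(ref[cursor:])
    alt = "".join(pieces)
    te_ivals = [
        (r.start, r.end if r.svtype != "INS" else r.start + 1)
        for i, r in enumerate(records) if te_flags[i] and r.svtype != "INS"
    ]
    te_track = IntervalSet({ref_name: te_ivals} if te_ivals else {})
    planted = PlantedSVSet(records, inserted, te_flags)
    return {ref_name: ref}, {ref_name: alt}, planted, te_track


# ---------------------------------------------------------------------------
# shotgun reads
# ---------------------------------------------------------------------------


def simulate_reads(genome: dict[str, str], coverage: float, read_len: int = 1000,
                   error_rate: float = 0.0, seed: int = 0) -> dict[str, str]:
    """Uniformly placed error-prone reads totalling ~coverage x genome bp."""
    if coverage <= 0:
        raise ValidationError("coverage must be > 0")
    rng = _rng(seed)
    reads: dict[str, str] = {}
    alphabet = np.array(list("ACGT"))
    for name, seq in genome.items():
        L = len(seq)
        if read_len > L:
            raise ValidationError(f"read_len {read_len} exceeds contig {name} length {L}")
        n_reads = int(round(coverage * L / read_len))
        starts = rng.integers(0, L - read_len + 1, size=n_reads)
        # start position is encoded in the read id, wgsim-style
        for i, s in enumerate(sorted(starts.tolist())):
            r = seq[s:s + read_len]
            if error_rate > 0:
                arr = np.array(list(r))
                hit = rng.random(read_len) < error_rate
                n_err = int(hit.sum())
                if n_err:
                    arr[hit] = alphabet[(
                        np.searchsorted(alphabet, arr[hit]) + rng.integers(1, 4, n_err)
                    ) % 4]
                    r = "".join(arr)
            reads[f"{name}_{s}_read{i}"] = r
    return reads
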