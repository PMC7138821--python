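"""End-to-end orchestration of the synthetic analysis pipeline.

Chains the stages simulate -> admixture fits -> Q aggregation -> membership
classification -> representative selection -> toy structural-variant
comparison -> genome-size estimate -> published-table summaries, writing
every artifact under one output directory together with a manifest holding
the configuration, the seed and a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture_em, classify_select, genome_stats, q_aggregate, simdata, sv_compare
from .core_io import ValidationError, write_fasta, write_genotypes, write_q_file

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the published analysis protocol
    (K from 5 to 15, 30 runs per K, membership threshold 0.65, 5 principal
    axes, 50-kb pseudo-reads at 10x redundancy, 25-kb SV length cap,
    k-mer size 17)."""

    seed: int = 0
    # simulation
    K_true: int = 3
    n_snps: int = 2000
    pure_size: int = 50
    admixed_specs: list = field(default_factory=list)
    major_group_map: list | None = None
    fst: float = 0.15
    # admixture stage
    k_min: int = 5
    k_max: int = 15
    n_runs: int = 30
    em_tol: float = 1e-4
    em_max_iter: int = 2000
    # aggregation
    cut_threshold: float = 0.1
    # classification / selection
    membership_threshold: float = 0.65
    n_axes: int = 5
    # SV comparison
    read_len: int = 50_000
    redundancy: int = 10
    max_sv_len: int = 25_000
    toy_genome_len: int = 60_000
    toy_n_events: int = 8
    # genome size
    kmer_k: int = 17
    kmer_coverage: float = 20.0

    def validate(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValidationError("need 2 <= k_min <= k_max")
        if not 0 < self.membership_threshold <= 1:
            raise ValidationError("membership threshold must be in (0, 1]")
        if self.n_runs < 2:
            raise ValidationError("n_runs must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        model = simdata.PopModel(
            K_true=config.K_true, n_snps=config.n_snps,
            fst=config.fst, pure_sizes=[config.pure_size] * config.K_true,
            admixed_specs=[(n, list(q)) for n, q in config.admixed_specs],
            major_group_map=config.major_group_map,
        )
        G, true_q = simdata.simulate_genotypes(model, seed=config.seed)
        write_genotypes(G, outdir / "genotypes.tsv")
        write_q_file(true_q, outdir / "true_q.Q")
        artifacts += [outdir / "genotypes.tsv", outdir / "true_q.Q"]

        # --- admixture runs ----------------------------------------------
        stage = "admix"
        ensembles: dict[int, q_aggregate.RunEnsemble] = {}
        manifest_rows = []
        for K in range(config.k_min, config.k_max + 1):
            seeds = [config.seed * 1000 + K * 100 + r for r in range(config.n_runs)]
            fits = admixture_em.multi_start(G, K, seeds, tol=config.em_tol,
                                            max_iter=config.em_max_iter)
            reps, prov = [], []
            for i, f in enumerate(fits):
                qpath = outdir / f"run_K{K}_{i}.Q"
                write_q_file(f.Q, qpath)
                artifacts.append(qpath)
                reps.append(f.Q)
                prov.append({"run_id": i, "seed": f.seed, "K": K})
                manifest_rows.append({"file": qpath.name, "K": K, "seed": f.seed,
                                      "loglik": f.loglik, "converged": f.converged})
            ensembles[K] = q_aggregate.RunEnsemble(K, reps, prov)
        runs_csv = outdir / "runs.csv"
        pd.DataFrame(manifest_rows).to_csv(runs_csv, index=False)
        artifacts.append(runs_csv)

        # --- aggregation --------------------------------------------------
        stage = "aggregate"
        primary: dict[int, q_aggregate.ModeSummary] = {}
        n_modes = {}
        for K, ens in ensembles.items():
            modes = q_aggregate.aggregate_modes(ens, config.cut_threshold)
            primary[K] = modes[0]
            n_modes[K] = len(modes)
            for m in modes:
                p = outdir / f"mode_{m.mode_label}.Q"
                write_q_file(m.averaged, p)
                artifacts.append(p)
        ladder = q_aggregate.ladder_match(list(primary.values()))
        ladder_json = outdir / "ladder.json"
        ladder_json.write_text(json.dumps(
            {"names": {str(k): v for k, v in ladder.names.items()},
             "edges": ladder.edges, "n_modes": n_modes}, indent=1, sort_keys=True))
        artifacts.append(ladder_json)
        log.info("aggregate: modes per K = %s", n_modes)

        # --- classification ----------------------------------------------
        stage = "classify"
        top = primary[config.k_max].averaged
        names = ladder.names[config.k_max]
        majors = {g: "other" for g in names}
        if config.major_group_map and config.k_max == config.K_true:
            # transfer simulated major-group labels through column alignment:
            # aligned[:, p] = top[:, perm[p]] matches truth column p
            perm, _ = q_aggregate.align_columns(true_q, top)
            majors = {names[perm[p]]: config.major_group_map[p]
                      for p in range(len(names))}
        scheme = classify_select.GroupScheme(names, majors)
        calls = classify_select.classify_all(top, scheme, config.membership_threshold)
        calls_csv = outdir / "calls.csv"
        pd.DataFrame([{"sample": c.sample_id, "label": c.label,
                       "max_component": round(c.max_component, 6)} for c in calls]
                     ).to_csv(calls_csv, index=False)
        artifacts.append(calls_csv)

        # --- selection ----------------------------------------------------
        stage = "select"
        D = classify_select.ibs_distance(G)
        coords = classify_select.principal_axes(D, config.n_axes)
        coords_csv = outdir / "coords.csv"
        pd.DataFrame(np.round(coords, 8), index=G.sample_ids,
                     columns=[f"axis{a + 1}" for a in range(coords.shape[1])]
                     ).to_csv(coords_csv)
        artifacts.append(coords_csv)
        available = {sid: True for sid in G.sample_ids}
        reps_rows = []
        for g in sorted({c.label for c in calls}):
            if g == "admixed" or g.endswith("-adm"):
                continue
            rep = classify_select.select_representative(coords, calls, g, available)
            reps_rows.append({"group": g, "representative": rep})
        reps_csv = outdir / "representatives.csv"
        pd.DataFrame(reps_rows).to_csv(reps_csv, index=False)
        artifacts.append(reps_csv)

        # --- toy SV comparison -------------------------------------------
        stage = "svcompare"
        spec = simdata.random_sv_spec(config.toy_genome_len, config.toy_n_events,
                                      config.seed + 7)
        ref, alt, planted, te_track = simdata.simulate_toy_genome_pair(
            config.toy_genome_len, spec, seed=config.seed + 8)
        write_fasta(ref, outdir / "toy_ref.fa")
        write_fasta(alt, outdir / "toy_alt.fa")
        artifacts += [outdir / "toy_ref.fa", outdir / "toy_alt.fa"]
        detected = sv_compare.naive_pair_sv(ref, alt)
        kept, drops = sv_compare.filter_svs(detected, config.max_sv_len)
        flags = {i: planted.te_flags.get(_nearest_planted(r, planted), False)
                 for i, r in enumerate(kept) if r.svtype == "INS"}
        summary = sv_compare.PairwiseSVSummary(
            "toy_alt", "toy_ref", kept, sv_compare.affected_bp(kept), ins_te_flags=flags)
        frac = sv_compare.te_fraction([summary], {"toy_ref": te_track})
        sv_json = outdir / "sv_summary.json"
        sv_json.write_text(json.dumps({
            "n_detected": len(detected), "n_kept": len(kept), "dropped": drops,
            "affected_bp": summary.affected_bp, "te_fraction": round(frac, 4)},
            indent=1, sort_keys=True))
        artifacts.append(sv_json)

        # --- genome size ----------------------------------------------
        stage = "genomesize"
        reads = simdata.simulate_reads(ref, coverage=config.kmer_coverage,
                                       read_len=1000, seed=config.seed + 9)
        est = genome_stats.kmer_genome_size(reads, k=config.kmer_k)
        gs_json = outdir / "genome_size.json"
        gs_json.write_text(json.dumps({
            "estimate_bp": est, "true_bp": len(ref["chr1"]),
            "relative_error": round(est / len(ref["chr1"]) - 1, 6)}, sort_keys=True))
        artifacts.append(gs_json)

        # --- published-table summaries -------------------------------
        stage = "stats"
        t3 = genome_stats.load_assembly_table()
        t4 = genome_stats.load_te_table()
        summ = pd.concat([
            genome_stats.table_summaries(
                t3, ["contig_n50_bp", "n_gaps", "busco_raw_pct", "busco_adjusted_pct"],
                label_col="variety"),
            genome_stats.table_summaries(
                t4, ["total_pct", "ltr_rt_pct", "line_pct", "sine_pct", "dna_te_pct"],
                label_col="variety"),
        ])
        stats_csv = outdir / "stats_summary.csv"
        summ.to_csv(stats_csv, index=False)
        artifacts.append(stats_csv)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _nearest_planted(rec, planted) -> int:
    """Index of the planted event closest to a detected record (TE flag lookup)."""
    best, best_d = -1, None
    for i, p in enumerate(planted.records):
        d = abs(p.start - rec.start)
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best
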