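import numpy as np
import pytest

from panstruct import simdata, sv_compare
from panstruct.core_io import IntervalSet, SVRecord, ValidationError
from panstruct.sv_compare import (PairwiseSVSummary, affected_bp, filter_svs,
                                  fragment, naive_pair_sv, pairwise_matrix,
                                  te_fraction)


class TestFragment:
    def test_coverage_bookkeeping(self):
        prs = fragment({"c": 100_000}, read_len=50_000, redundancy=10)
        assert abs(prs.total_bp - 1_000_000) <= 10 * 50_000

    def test_redundancy_one_plain_split(self):
        prs = fragment({"c": 120_000}, read_len=50_000, redundancy=1)
        starts = sorted(r.start for r in prs.reads)
        assert starts == [0, 50_000, 100_000]
        assert prs.reads[-1].length == 20_000

    @pytest.mark.parametrize("read_len,redundancy", [
        (50_000, 10), (50_000, 5), (10_000, 10), (20_000, 4),
    ])
    def test_interior_coverage_property(self, read_len, redundancy):
        L = 6 * read_len + 1234
        prs = fragment({"c": L}, read_len=read_len, redundancy=redundancy)
        cov = np.zeros(L, dtype=np.int16)
        for r in prs.reads:
            cov[r.start:r.start + r.length] += 1
        interior = cov[read_len:L - read_len]
        assert set(interior.tolist()) <= {redundancy - 1, redundancy}

    def test_short_contig_emitted_whole(self):
        with pytest.warns(RuntimeWarning, match="whole"):
            prs = fragment({"tiny": 2_000}, read_len=50_000, redundancy=10)
        assert len(prs.reads) == 1 and prs.reads[0].length == 2_000


class TestFilter:
    def test_length_boundary_inclusive(self):
        keep = SVRecord("c", 0, 25_000, "DEL", 25_000)
        drop = SVRecord("c", 0, 25_001, "DEL", 25_001)
        kept, drops = filter_svs([keep, drop])
        assert kept == [keep] and drops["length"] == 1

    def test_oversized_deletion_dropped(self):
        kept, _ = filter_svs([SVRecord("c", 0, 30_000, "DEL", 30_000)])
        assert kept == []

    def test_known_composition(self):
        rng = np.random.default_rng(0)
        records, expect_kept = [], 0
        for _ in range(100):
            t = ("INS", "DEL", "DUP_TANDEM")[rng.integers(3)]
            ln = int(rng.integers(100, 40_000))
            s = int(rng.integers(0, 1_000_000))
            if t == "INS":
                records.append(SVRecord("c", s, s + 1, t, ln))
            else:
                records.append(SVRecord("c", s, s + ln, t, ln))
            expect_kept += ln <= 25_000
        kept, drops = filter_svs(records)
        assert len(kept) == expect_kept
        assert drops["length"] == 100 - expect_kept


class TestAffectedBp:
    def test_del_plus_ins(self):
        recs = [SVRecord("c", 1000, 1500, "DEL", 500),
                SVRecord("c", 5000, 5001, "INS", 300)]
        assert affected_bp(recs) == 800

    def test_overlapping_dels_merged(self):
        recs = [SVRecord("c", 0, 100, "DEL", 100),
                SVRecord("c", 50, 150, "DEL", 100)]
        assert affected_bp(recs) == 150

    def test_mask_oracle(self):
        rng = np.random.default_rng(1)
        L = 100_000
        recs = []
        for _ in range(60):
            t = ("INS", "DEL", "DUP_TANDEM")[rng.integers(3)]
            ln = int(rng.integers(10, 3000))
            s = int(rng.integers(0, L - 3000))
            recs.append(SVRecord("c", s, s + 1, t, ln) if t == "INS"
                        else SVRecord("c", s, s + ln, t, ln))
        mask = np.zeros(L, dtype=bool)
        ins_total = 0
        for r in recs:
            if r.svtype == "INS":
                ins_total += r.length
            else:
                mask[r.start:r.end] = True
        assert affected_bp(recs) == int(mask.sum()) + ins_total

    def test_unknown_contig_rejected(self):
        recs = [SVRecord("ghost", 0, 10, "DEL", 10)]
        with pytest.raises(ValidationError, match="ghost"):
            affected_bp(recs, contig_lengths={"c": 1000})


class TestTeFraction:
    def test_no_overlap_no_flags_zero(self):
        recs = [SVRecord("c", 0, 100, "DEL", 100),
                SVRecord("c", 500, 501, "INS", 50)]
        s = PairwiseSVSummary("q", "c", recs, affected_bp(recs))
        assert te_fraction([s], {"c": IntervalSet({"c": [(10_000, 20_000)]})}) == 0.0

    def test_full_overlap_all_flagged_one(self):
        recs = [SVRecord("c", 100, 200, "DEL", 100),
                SVRecord("c", 500, 501, "INS", 50)]
        s = PairwiseSVSummary("q", "c", recs, affected_bp(recs),
                              ins_te_flags={1: True})
        track = IntervalSet({"c": [(0, 1000)]})
        assert te_fraction([s], {"c": track}) == 1.0

    def test_missing_track_error(self):
        recs = [SVRecord("c", 0, 10, "DEL", 10)]
        s = PairwiseSVSummary("q", "c", recs, 10)
        with pytest.raises(ValidationError, match="TE track"):
            te_fraction([s], {})

    def test_generator_ground_truth(self, toy_pair):
        ref, alt, planted, track = toy_pair
        kept, _ = filter_svs(planted.records)
        flags = {i: planted.te_flags[i] for i, r in enumerate(planted.records)
                 if r.svtype == "INS"}
        s = PairwiseSVSummary("alt", "chr1", kept, affected_bp(kept),
                              ins_te_flags=flags)
        frac = te_fraction([s], {"chr1": track})
        truth = (sum(r.length for i, r in enumerate(planted.records)
                     if planted.te_flags[i])
                 / sum(r.length for r in planted.records))
        assert frac == pytest.approx(truth, abs=0.01)


class TestNaivePairSV:
    def test_identical_sequences_no_records(self):
        g = simdata.random_genome(20_000, np.random.default_rng(2))
        assert naive_pair_sv({"c": g}, {"c": g}) == []

    def test_single_deletion_recovered(self):
        ref, alt, _, _ = simdata.simulate_toy_genome_pair(
            50_000, [("DEL", 20_000, 500)], seed=7)
        [rec] = naive_pair_sv(ref, alt)
        assert rec.svtype == "DEL"
        assert abs(rec.start - 20_000) <= 21
        assert abs(rec.length - 500) <= 5

    def test_unrelated_sequences_error(self):
        rng = np.random.default_rng(3)
        a = simdata.random_genome(5_000, rng)
        b = simdata.random_genome(5_000, rng)
        with pytest.raises(ValidationError, match="unrelated"):
            naive_pair_sv({"c": a}, {"c": b})

    def test_planted_recovery_rate(self, toy_pair):
        """>=90% of planted events >=200 bp at >=2 kb spacing recovered with
        the correct type, position and length."""
        ref, alt, planted, _ = toy_pair
        detected = naive_pair_sv(ref, alt)
        recovered = 0
        for p in planted.records:
            recovered += any(
                d.svtype == p.svtype and abs(d.start - p.start) <= 50
                and abs(d.length - p.length) <= 10
                for d in detected)
        assert recovered / len(planted.records) >= 0.9


class TestPairwiseMatrix:
    def test_identical_pair_zero_both_directions(self):
        g = {"c": simdata.random_genome(20_000, np.random.default_rng(4))}
        mat, _ = pairwise_matrix({"a": g, "b": dict(g)}, anchor_k=21)
        assert mat.loc["a", "b"] == 0 and mat.loc["b", "a"] == 0
        assert mat.loc["a", "a"] == 0

    def test_planted_divergence_ordering(self):
        rng = np.random.default_rng(5)
        base = simdata.random_genome(60_000, rng)
        genomes = {"base": {"c": base}}
        for name, n_dels in (("low", 2), ("mid", 5), ("high", 9)):
            seq = base
            offset = 0
            for i in range(n_dels):
                pos = 5_000 + i * 6_000 - offset
                seq = seq[:pos] + seq[pos + 400:]
                offset += 400
            genomes[name] = {"c": seq}
        mat, _ = pairwise_matrix(genomes, anchor_k=21)
        vals = [mat.loc[n, "base"] for n in ("low", "mid", "high")]
        assert vals[0] < vals[1] < vals[2]

    def test_singleton_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_matrix({"only": {"c": "ACGT" * 100}})
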