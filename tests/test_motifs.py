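"""PWM scanning, k-mer weights/classifier, nearest-null mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from primatlas import motifs
from primatlas.motifs import Pwm, reverse_complement


@pytest.fixture(scope="module")
def nfia():
    return motifs.builtin_pwms()["NFIA"]


@pytest.fixture(scope="module")
def pparg():
    return motifs.builtin_pwms()["PPARG"]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def oracle_scan(seq, pwm, threshold):
    """Independent per-window rescan from the log-odds definition."""
    smin, smax = pwm.score_range
    hits = []
    for strand in "+-":
        target = seq if strand == "+" else None
        mat = pwm.log_odds if strand == "+" else pwm.reverse_complement().log_odds
        for off in range(len(seq) - pwm.length + 1):
            window = seq[off : off + pwm.length]
            if any(b not in "ACGT" for b in window):
                continue
            s = sum(mat["ACGT".index(b), j] for j, b in enumerate(window))
            rel = (s - smin) / (smax - smin)
            if rel >= threshold:
                hits.append((off, strand, round(rel, 9)))
    return sorted(hits)


class TestScanPwm:
    def test_consensus_scores_exactly_one(self, pparg):
        seq = "AAAA" + pparg.consensus + "TTTT"
        hits, best = motifs.scan_pwm(seq, pparg, threshold=0.99)
        assert best == pytest.approx(1.0)
        assert any(h.offset == 4 and h.strand == "+" for h in hits)

    def test_minimal_scoring_sequence_is_zero(self, pparg):
        lo = pparg.log_odds
        worst = "".join("ACGT"[j] for j in lo.argmin(axis=0))
        _, best = motifs.scan_pwm(worst, pparg, threshold=1.1)
        rel = [
            h.relative_score
            for h in motifs.scan_pwm(worst, pparg, threshold=-0.1)[0]
            if h.strand == "+"
        ]
        assert min(rel) == pytest.approx(0.0, abs=1e-12)

    def test_short_sequence_no_hits(self, pparg):
        hits, best = motifs.scan_pwm("ACGT", pparg)
        assert hits == [] and best == 0.0

    def test_windows_with_n_skipped(self, pparg):
        seq = "N" * pparg.length
        hits, best = motifs.scan_pwm(seq, pparg)
        assert hits == [] and best == 0.0

    def test_matches_bruteforce_oracle(self, rng, nfia, pparg):
        for pwm in (nfia, pparg):
            for _ in range(20):
                seq = random_seq(rng, 200)
                hits, _ = motifs.scan_pwm(seq, pwm, threshold=0.7)
                got = sorted(
                    (h.offset, h.strand, round(h.relative_score, 9)) for h in hits
                )
                assert got == oracle_scan(seq, pwm, 0.7)

    def test_reverse_complement_invariance(self, rng, pparg):
        for _ in range(10):
            seq = random_seq(rng, 100)
            _, best_f = motifs.scan_pwm(seq, pparg)
            _, best_r = motifs.scan_pwm(reverse_complement(seq), pparg)
            assert best_f == pytest.approx(best_r)

    def test_relative_score_range_exhaustive_short_pwm(self):
        pwm = Pwm.from_consensus("toy", "ACGT")
        smin, smax = pwm.score_range
        lo = pwm.log_odds
        scores = [
            sum(lo["ACGT".index(b), j] for j, b in enumerate(w))
            for w in ("".join(t) for t in itertools.product("ACGT", repeat=4))
        ]
        assert min(scores) == pytest.approx(smin)
        assert max(scores) == pytest.approx(smax)


class TestCooccurrence:
    def test_both_planted_gives_one(self, nfia, pparg, rng):
        seqs = {
            f"s{i}": nfia.consensus + random_seq(rng, 20) + pparg.consensus
            for i in range(10)
        }
        rate, _ = motifs.cooccurrence_rate(seqs, nfia, pparg, threshold=0.95)
        assert rate == 1.0

    def test_b_absent_gives_zero(self, nfia, pparg, rng):
        seqs = {f"s{i}": "A" * 10 + nfia.consensus + "T" * 10 for i in range(5)}
        rate, _ = motifs.cooccurrence_rate(seqs, nfia, pparg, threshold=1.0)
        assert rate == 0.0

    def test_no_a_hits_rejected(self, nfia, pparg):
        with pytest.raises(ValueError):
            motifs.cooccurrence_rate({"s": "A" * 50}, nfia, pparg, threshold=1.0)

    def test_planted_rate_recovered(self, nfia, pparg, rng):
        n = 500
        seqs = {}
        for i in range(n):
            s = random_seq(rng, 60)
            s = nfia.consensus + s
            if rng.random() < 0.8:
                s += pparg.consensus
            seqs[f"s{i}"] = s
        rate, _ = motifs.cooccurrence_rate(seqs, nfia, pparg, threshold=0.95)
        assert rate == pytest.approx(0.8, abs=0.06)


class TestOrthologDelta:
    def test_identical_orthologs_zero(self, nfia, rng):
        seq = random_seq(rng, 100)
        assert motifs.ortholog_motif_delta(seq, seq, nfia)["delta"] == 0.0

    def test_consensus_only_in_first(self, pparg, rng):
        bg = random_seq(rng, 60)
        res = motifs.ortholog_motif_delta(
            bg + pparg.consensus, bg + random_seq(rng, pparg.length), pparg,
            threshold=0.99,
        )
        assert res["sum_a"] >= 1.0 and res["delta"] >= 1.0 - res["sum_b"]


class TestNearestNullMap:
    def make(self, spec_rows, common_rows):
        rows = spec_rows + common_rows
        ids = [f"o{i}" for i in range(len(rows))]
        atlas = pd.DataFrame(rows, columns=["chrom", "start", "end"], index=ids)
        calls = pd.DataFrame(
            {
                "state": ["human_increased"] * len(spec_rows)
                + ["common"] * len(common_rows)
            },
            index=ids,
        )
        return calls, atlas

    def test_nearer_of_two(self):
        calls, atlas = self.make(
            [("chr1", 100, 200)], [("chr1", 300, 400), ("chr1", 1000, 1100)]
        )
        out = motifs.nearest_null_map(calls, atlas)
        assert out.loc["o0", "null_ocr_id"] == "o1"

    def test_equidistant_tie_lower_start(self):
        calls, atlas = self.make(
            [("chr1", 450, 550)], [("chr1", 100, 200), ("chr1", 800, 900)]
        )
        out = motifs.nearest_null_map(calls, atlas)
        assert out.loc["o0", "null_ocr_id"] == "o1"

    def test_chromosome_without_common_unmapped(self):
        calls, atlas = self.make([("chr2", 0, 100)], [("chr1", 0, 100)])
        out = motifs.nearest_null_map(calls, atlas)
        assert out.loc["o0", "null_ocr_id"] is None

    def test_matches_quadratic_oracle(self, rng):
        spec = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 30)]
        common = [("chr1", int(s), int(s) + 100) for s in rng.integers(0, 50_000, 40)]
        calls, atlas = self.make(spec, common)
        out = motifs.nearest_null_map(calls, atlas)
        commons = atlas[calls["state"] == "common"]
        for i in range(30):
            mid = (spec[i][1] + spec[i][2]) // 2
            dists = ((commons["start"] + commons["end"]) // 2 - mid).abs()
            best = dists.min()
            cand = commons[dists == best].sort_values("start")
            assert out.loc[f"o{i}", "null_ocr_id"] == cand.index[0]


class TestKmerWeights:
    def test_identical_sets_zero_weights(self, rng):
        seqs = [random_seq(rng, 50) for _ in range(10)]
        w = motifs.kmer_weights(seqs, list(seqs))
        assert np.allclose(w, 0.0)

    def test_absent_kmer_zero_by_pseudocount_symmetry(self):
        w = motifs.kmer_weights(["ACGTACGTAC"], ["ACGTACGTAC"])
        assert w["AAAAAA"] == 0.0

    def test_covers_all_canonical_kmers(self):
        kmers = motifs.canonical_kmers(6)
        # 4^6 = 4096 total; palindromes (4^3 = 64) counted once
        assert len(kmers) == (4096 - 64) // 2 + 64
        w = motifs.kmer_weights(["ACGTACGTAC"], ["AAAATTTTCC"])
        assert len(w) == len(kmers)
        assert np.isfinite(w).all()

    def test_planted_consensus_kmers_rank_top_decile(self, nfia, rng):
        pos = [
            random_seq(rng, 40) + nfia.consensus.replace("N", "A") + random_seq(rng, 40)
            for _ in range(80)
        ]
        null = [random_seq(rng, 95) for _ in range(80)]
        w = motifs.kmer_weights(pos, null)
        planted = nfia.consensus.replace("N", "A")
        consensus_kmers = {
            min(planted[i : i + 6], reverse_complement(planted[i : i + 6]))
            for i in range(len(planted) - 5)
        }
        cutoff = w.quantile(0.9)
        assert all(w[k] >= cutoff for k in consensus_kmers)


class TestKmerClassifier:
    def test_no_signal_auc_near_half(self, rng):
        pos = [random_seq(rng, 80) for _ in range(40)]
        null = [random_seq(rng, 80) for _ in range(40)]
        auc, _ = motifs.kmer_classify_auc(pos, null, seed=0)
        assert auc == pytest.approx(0.5, abs=0.17)

    def test_planted_consensus_auc_high(self, nfia, rng):
        pos = [
            random_seq(rng, 30) + nfia.consensus.replace("N", "C") + random_seq(rng, 30)
            for _ in range(40)
        ]
        null = [random_seq(rng, 75) for _ in range(40)]
        auc, _ = motifs.kmer_classify_auc(pos, null, seed=0)
        assert auc > 0.9

    def test_label_swap_antisymmetry(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = [random_seq(rng, 60) + "ACGTAC" * 3 for _ in range(30)]
        null = [random_seq(rng, 78) for _ in range(30)]
        auc, detail = motifs.kmer_classify_auc(pos, null, seed=1)
        swapped = roc_auc_score(1 - detail["label"], detail["score"])
        assert auc == pytest.approx(1 - swapped, abs=1e-12)

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError):
            motifs.kmer_classify_auc(
                [random_seq(rng, 30)] * 3, [random_seq(rng, 30)] * 3, folds=5
            )


class TestPfmIo:
    def test_jaspar_style_roundtrip(self, tmp_path):
        p = tmp_path / "toy.pfm"
        p.write_text(
            ">TOY\nA [ 10  0  0 10 ]\nC [ 0 10  0  0 ]\nG [ 0  0 10  0 ]\nT [ 0  0  0  0 ]\n"
        )
        pwm = motifs.read_pfm(p)
        assert pwm.name == "TOY"
        assert pwm.length == 4
        assert pwm.consensus == "ACGA"
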