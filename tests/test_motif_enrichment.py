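import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from itss.cli import default_pwm_path
from itss.motif_enrichment import (
    MotifFormatError,
    MotifModel,
    best_hit,
    exact_enrichment,
    load_pwm,
    pwm_to_logodds,
    scan,
)
from itss.naive import naive_fisher_two_sided, naive_pwm_best, naive_scan_hits
from itss.tracks_io import reverse_complement


@pytest.fixture(scope="module")
def mse():
    return load_pwm(default_pwm_path("mse"))


@pytest.fixture(scope="module")
def urs1():
    return load_pwm(default_pwm_path("urs1"))


class TestLoadPWM:
    def test_bundled_matrices(self, mse, urs1):
        assert mse.length == 12
        assert mse.consensus == "GACACAAAAATA"
        assert urs1.length == 9
        assert urs1.consensus == "TCGGCGGCT"
        assert mse.max_score > mse.min_score

    def test_min_max_are_column_sums(self, mse):
        assert mse.min_score == pytest.approx(mse.weights.min(axis=1).sum())
        assert mse.max_score == pytest.approx(mse.weights.max(axis=1).sum())

    def test_degenerate_motif_rejected(self):
        w = np.zeros((3, 4))  # every column flat → zero score range
        with pytest.raises(MotifFormatError, match="degenerate"):
            MotifModel(name="flat", weights=w)

    def test_zero_column_needs_pseudocount(self):
        counts = np.array([[0, 0, 0, 0], [5, 1, 1, 1]], dtype=float)
        with pytest.raises(MotifFormatError):
            pwm_to_logodds(counts, pseudocount=0.0)
        assert np.all(np.isfinite(pwm_to_logodds(counts, pseudocount=0.25)))

    def test_malformed_file(self, tmp_path):
        p = tmp_path / "bad.jaspar"
        p.write_text(">m bad\nA [ 1 2 ]\nC [ 1 2 ]\n")
        with pytest.raises(MotifFormatError):
            load_pwm(p)

    def test_relative_score_invariant_to_column_shift(self, mse):
        shifted = MotifModel(name="s", weights=mse.weights + 0.7)
        seq = "TT" + mse.consensus + "GG"
        h1 = scan(seq, mse, threshold_frac=0.5)
        h2 = scan(seq, shifted, threshold_frac=0.5)
        assert [(h.offset, h.strand) for h in h1] == [(h.offset, h.strand) for h in h2]
        np.testing.assert_allclose(
            [h.relative for h in h1], [h.relative for h in h2], atol=1e-12
        )


class TestScan:
    def test_consensus_scores_relative_one(self, mse):
        seq = "TTTT" + mse.consensus + "CCCC"
        hits = scan(seq, mse)
        top = max(hits, key=lambda h: h.relative)
        assert top.relative == pytest.approx(1.0, abs=1e-12)
        assert top.offset == 4
        assert top.strand == "+"

    def test_anticonsensus_scores_relative_zero(self, mse):
        anti = "".join(
            "ACGT"[int(np.argmin(col))] for col in mse.weights
        )
        h = best_hit(anti, mse)
        # forward offset 0 is the anti-consensus; reverse strand may do better
        fwd = [x for x in scan(anti, mse, threshold_frac=-np.inf) if x.strand == "+"]
        assert fwd[0].relative == pytest.approx(0.0, abs=1e-12)
        assert h.relative < 1.0

    def test_reverse_complement_hit_on_minus_strand(self, mse):
        seq = "TTTT" + reverse_complement(mse.consensus) + "CCCC"
        hits = scan(seq, mse)
        assert any(
            h.strand == "-" and h.relative == pytest.approx(1.0, abs=1e-12)
            for h in hits
        )

    def test_threshold_is_strict(self, mse):
        seq = "TT" + mse.consensus + "GG"
        [top] = [h for h in scan(seq, mse, threshold_frac=0.99)]
        # a hit whose relative score equals the cutoff is excluded
        assert scan(seq, mse, threshold_frac=top.relative) == []

    def test_short_sequence_warns_and_returns_empty(self, mse):
        with pytest.warns(UserWarning, match="shorter"):
            assert scan("ACGT", mse) == []

    def test_scan_reverse_complement_symmetry(self, mse):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 80))
        fwd = scan(seq, mse, threshold_frac=-np.inf)
        rev = scan(reverse_complement(seq), mse, threshold_frac=-np.inf)
        assert sorted(round(h.score, 9) for h in fwd) == sorted(
            round(h.score, 9) for h in rev
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=12, max_size=40))
    def test_matches_exhaustive_enumeration(self, seq):
        mse = load_pwm(default_pwm_path("mse"))
        got = {(h.offset, h.strand, round(h.score, 9)) for h in scan(seq, mse, 0.5)}
        want = {
            (o, s, round(sc, 9))
            for o, s, sc in naive_scan_hits(seq, mse.weights, 0.5)
        }
        assert got == want

    def test_best_hit_matches_naive(self, mse):
        rng = np.random.default_rng(13)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 60))
            got = best_hit(seq, mse)
            score, off, strand = naive_pwm_best(seq, mse.weights)
            assert got.score == pytest.approx(score, abs=1e-9)
            assert (got.offset, got.strand) == (off, strand)


class TestExactEnrichment:
    def test_hand_enumerated_table(self):
        # [[3,1],[1,3]]: hypergeometric enumeration gives p = 34/70
        res = exact_enrichment(3, 4, 1, 4)
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)
        assert naive_fisher_two_sided(3, 4, 1, 4) == pytest.approx(34 / 70, abs=1e-12)

    def test_equal_proportions_give_one(self):
        assert exact_enrichment(2, 4, 2, 4).p_value == pytest.approx(1.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exact_enrichment(5, 4, 1, 10)
        with pytest.raises(ValueError):
            exact_enrichment(-1, 4, 1, 10)

    @pytest.mark.parametrize(
        "k,n,K,N", [(3, 7, 2, 9), (0, 5, 4, 6), (6, 6, 1, 8), (2, 10, 9, 12)]
    )
    def test_matches_naive_enumeration(self, k, n, K, N):
        res = exact_enrichment(k, n, K, N)
        assert res.p_value == pytest.approx(
            naive_fisher_two_sided(k, n, K, N), abs=1e-12
        )

    def test_agrees_with_permutation_estimate(self):
        """Monte-Carlo draw of tables at fixed margins, 1e5 draws, 3 SE."""
        k, n, K, N = 7, 20, 12, 80
        res = exact_enrichment(k, n, K, N)
        rng = np.random.default_rng(14)
        draws = rng.hypergeometric(k + K, n + N - k - K, n, size=100_000)
        pmf = hypergeom.pmf(np.arange(0, k + K + 1), n + N, k + K, n)
        p_obs = pmf[k]
        p_draw = pmf[draws]
        hits = (p_draw <= p_obs * (1 + 1e-12)).mean()
        se = np.sqrt(hits * (1 - hits) / 100_000)
        assert abs(hits - res.p_value) <= 3 * se + 1e-9

    def test_one_sided_monotonicity(self):
        """More extreme over-representation never raises the one-sided tail."""
        n, N, total = 10, 50, 14
        tails = [
            hypergeom.sf(k - 1, n + N, total, n) for k in range(0, total + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))


class TestPlantedMotifIntegration:
    def test_flags_and_enrichment_on_synthetic_run(self, small_sim, small_run):
        _scan, called, motifs = small_run
        planted = {r.gene_id for r in small_sim.truth.induced}
        flagged = {ic.gene.gene_id for ic in motifs.internal if ic.mse}
        called_planted = {
            ic.gene.gene_id for ic in motifs.internal if ic.gene.gene_id in planted
        }
        # every recovered planted gene carries its planted MSE site
        assert called_planted and called_planted <= flagged
        assert "MSE" in motifs.enrichment
        res = motifs.enrichment["MSE"]
        assert res.fg_total == len(motifs.internal)
        assert 0 <= res.p_value <= 1
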