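import itertools
import math

import numpy as np
import pytest

from asmarbiter.config import EvalConfig
from asmarbiter.reference_free import (
    expected_titration_curve,
    length_stats,
    log_count_correlation,
    mappable_fraction,
    n50,
    n50_cutoff_sweep,
    superior_checklist,
    titration_curve,
)
from asmarbiter.types import UCOSummary


def n50_oracle(lengths):
    """Brute force: largest length L with sum(lengths >= L) >= total/2."""
    total = sum(lengths)
    best = 0
    for cand in sorted(set(lengths)):
        if sum(l for l in lengths if l >= cand) >= total / 2:
            best = max(best, cand)
    return best


class TestLengthStats:
    def test_descending_cumsum_example(self):
        s = length_stats([400, 300, 200, 100], min_len=0)
        assert s.n50_length == 300  # 400+300 = 700 >= 500
        assert s.n50_mbp == pytest.approx(0.001)
        assert s.max_length == 400

    def test_single_sequence(self):
        s = length_stats([500], min_len=0)
        assert s.n50_length == 500 and s.median_length == 500

    def test_min_length_filter(self):
        s = length_stats([50, 150], min_len=100)
        assert s.n_sequences == 1
        with pytest.raises(ValueError):
            length_stats([50, 60], min_len=100)

    def test_n_content_follows_filter(self):
        s = length_stats([50, 150, 300], n_counts=[5, 2, 1], min_len=100)
        assert s.n_content == 3  # the 50 bp sequence's Ns drop out

    def test_n50_matches_brute_force_oracle(self):
        rng = np.random.default_rng(909)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            lengths = rng.integers(1, 5000, size=n).tolist()
            assert n50(lengths) == n50_oracle(lengths)

    def test_n50_order_invariant_and_at_least_median(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(100, 3000, size=50).tolist()
        shuffled = list(lengths)
        rng.shuffle(shuffled)
        assert n50(lengths) == n50(shuffled)
        assert n50(lengths) >= np.median(lengths) - 1e-9


class TestN50Sweep:
    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(17)
        lengths = rng.integers(50, 4000, size=500).tolist()
        sweep = n50_cutoff_sweep(lengths)
        assert (sweep["n50_length"].diff().dropna() >= 0).all()

    def test_all_long_sequences_give_identical_rows(self):
        sweep = n50_cutoff_sweep([800, 900, 1000])
        assert sweep["n50_length"].nunique() == 1
        assert sweep["mbp"].nunique() == 1

    def test_mbp_drop_equals_removed_bases(self):
        lengths = [100] * 50 + [2000] * 5
        sweep = n50_cutoff_sweep(lengths, cutoffs=(100, 200))
        removed = sweep["mbp"].iloc[0] - sweep["mbp"].iloc[1]
        assert removed == pytest.approx(5000 / 1e6)


def test_mappable_fraction():
    assert mappable_fraction(717, 1000) == pytest.approx(71.7)
    assert mappable_fraction(100, 100) == 100.0
    assert mappable_fraction(0, 100) == 0.0
    with pytest.raises(ValueError):
        mappable_fraction(1, 0)
    with pytest.warns(UserWarning, match="denominator"):
        assert mappable_fraction(120, 100) == pytest.approx(120.0)


class TestTitration:
    COUNTS = {"a": 120, "b": 40, "c": 8, "d": 1, "e": 0}

    def test_endpoint_exact_and_monotone(self):
        curve = titration_curve(self.COUNTS, step=10, seed=3)
        total = sum(self.COUNTS.values())
        assert curve.endpoint == (total, 4)  # 'e' has zero reads
        assert curve.sample_points[-1] == curve.endpoint
        uniques = [u for _, u in curve.sample_points]
        assert all(b >= a for a, b in zip(uniques, uniques[1:]))

    def test_deterministic_per_seed(self):
        c1 = titration_curve(self.COUNTS, step=10, seed=5)
        c2 = titration_curve(self.COUNTS, step=10, seed=5)
        c3 = titration_curve(self.COUNTS, step=10, seed=6)
        assert c1 == c2
        assert c3.endpoint == c1.endpoint  # seeds agree at the endpoint

    def test_exhaustive_sampling_detects_everything(self):
        curve = titration_curve({"a": 1, "b": 1}, step=5, seed=0)
        assert curve.endpoint == (2, 2)


class TestExpectedTitration:
    def test_tiny_enumeration_oracle(self):
        # counts {a:2, b:2}, draw m=2 of T=4: P(miss a) = C(2,2)/C(4,2) = 1/6
        (val,) = expected_titration_curve({"a": 2, "b": 2}, [2])
        assert val == pytest.approx(2 * (1 - 1 / 6))

    def test_brute_force_enumeration_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            counts = {f"u{i}": int(rng.integers(1, 4)) for i in range(4)}
            total = sum(counts.values())
            reads = [k for k, v in counts.items() for _ in range(v)]
            for m in (1, 2, total):
                exact = np.mean(
                    [len(set(c)) for c in itertools.combinations(reads, m)]
                )
                (val,) = expected_titration_curve(counts, [m])
                assert val == pytest.approx(exact)

    def test_boundary_values(self):
        counts = {"a": 3, "b": 2}
        assert expected_titration_curve(counts, [0]) == [0.0]
        (full,) = expected_titration_curve(counts, [5])
        assert full == pytest.approx(2.0)
        with pytest.raises(ValueError):
            expected_titration_curve(counts, [6])

    def test_monte_carlo_agrees_within_3_standard_errors(self):
        # canonical toy table: 20 unigenes with counts 1..20 (210 reads)
        counts = {f"u{i:02d}": i for i in range(1, 21)}
        step = 25
        points = None
        draws = []
        for seed in range(100):
            curve = titration_curve(counts, step=step, seed=seed)
            if points is None:
                points = [m for m, _ in curve.sample_points]
            draws.append([u for _, u in curve.sample_points])
        draws = np.array(draws, dtype=float)
        expected = expected_titration_curve(counts, points)
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / math.sqrt(draws.shape[0])
        for m, mu, e, s in zip(points, mean, expected, se):
            assert abs(mu - e) <= max(3 * s, 1e-9), (
                f"at m={m}: MC {mu:.3f} vs exact {e:.3f} (3se={3*s:.3f})"
            )


class TestCorrelations:
    def test_identical_and_scaled_vectors(self):
        a = {"g1": 0, "g2": 1, "g3": 3, "g4": 7}
        rho, r = log_count_correlation(a, a)
        assert rho == pytest.approx(1.0) and r == pytest.approx(1.0)
        b = {k: 2 * v for k, v in a.items()}
        rho, r = log_count_correlation(a, b)
        assert rho == pytest.approx(1.0)  # monotone transform
        # Pearson on log2(x+1) vs the textbook formula
        xa = np.log2(np.array([0, 1, 3, 7]) + 1.0)
        xb = np.log2(np.array([0, 2, 6, 14]) + 1.0)
        expect = np.corrcoef(xa, xb)[0, 1]
        assert r == pytest.approx(float(expect))

    def test_reversed_ranks(self):
        a = {"g1": 1, "g2": 5, "g3": 20}
        b = {"g1": 20, "g2": 5, "g3": 1}
        rho, _ = log_count_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_absent_genes_imputed_and_minimum_size(self):
        a = {"g1": 5, "g2": 2, "g3": 1}
        b = {"g1": 5, "g2": 2}  # g3 imputed as 0 in b
        rho, r = log_count_correlation(a, b)
        assert -1 <= rho <= 1 and -1 <= r <= 1
        with pytest.raises(ValueError):
            log_count_correlation({"g1": 1, "g2": 2}, {"g1": 1, "g2": 2})

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(30)]
        a = {g: int(rng.integers(0, 100)) for g in genes}
        b = {g: int(rng.integers(0, 100)) for g in genes}
        fwd = log_count_correlation(a, b)
        rev = log_count_correlation(
            dict(reversed(list(a.items()))), dict(reversed(list(b.items())))
        )
        assert fwd == pytest.approx(rev)


class TestChecklist:
    UCO = UCOSummary(n_listed=100, frac_bs_high=0.75, frac_cov90=0.8, frac_cov99=0.6)

    def test_all_pass(self):
        rep = superior_checklist(70.0, 28800, 1400, self.UCO, 18000, EvalConfig())
        assert rep.verdict
        assert rep.unigene_ratio == pytest.approx(1.6)

    def test_individual_failures(self):
        cfg = EvalConfig()
        assert not superior_checklist(30.0, 28800, 1400, self.UCO, 18000, cfg).pass_mappable
        assert not superior_checklist(70.0, 18000, 1400, self.UCO, 18000, cfg).pass_unigene_ratio
        assert not superior_checklist(70.0, 28800, 900, self.UCO, 18000, cfg).pass_n50
        low_uco = UCOSummary(100, 0.2, 0.3, 0.1)
        rep = superior_checklist(70.0, 28800, 1400, low_uco, 18000, cfg)
        assert not rep.pass_uco and not rep.verdict

    def test_expected_transcripts_validated(self):
        with pytest.raises(ValueError):
            superior_checklist(70.0, 100, 1400, self.UCO, 0, EvalConfig())
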