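"""K2P distances, TN93 rate-matrix estimation, and the published rate table."""

import math
from itertools import combinations

import numpy as np
import pytest

from mitopop import models_distances as md
from mitopop.errors import EstimationError, SaturationError, TreeSizeError
from mitopop.io_formats import AlignedSequenceSet, load_printed_rate_matrix


def _aln(*rows):
    return AlignedSequenceSet.from_records(
        [(f"s{i+1}", r) for i, r in enumerate(rows)]
    )


class TestCountDifferences:
    def test_single_purine_transition(self):
        d = md.count_differences("AAAA", "GAAA")
        assert (d.P1, d.P2, d.Q) == (0.25, 0.0, 0.0)

    def test_identical(self):
        d = md.count_differences("ACGT", "ACGT")
        assert (d.P1, d.P2, d.Q, d.L) == (0, 0, 0, 4)

    def test_missing_columns_excluded(self):
        # column 3 is missing in one row or the other -> 3 comparable columns
        d = md.count_differences("AC-T", "ACNT")
        assert d.L == 3
        d2 = md.count_differences("A--T", "ACNT")
        assert d2.L == 2

    def test_matches_per_column_tally(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            L = int(rng.integers(1, 60))
            a = "".join(rng.choice(list("ACGT"), L))
            b = "".join(rng.choice(list("ACGT"), L))
            d = md.count_differences(a, b)
            p1 = sum({x, y} == {"A", "G"} for x, y in zip(a, b))
            p2 = sum({x, y} == {"C", "T"} for x, y in zip(a, b))
            q = sum(
                x != y and {x, y} not in ({"A", "G"}, {"C", "T"})
                for x, y in zip(a, b)
            )
            assert d.P1 == pytest.approx(p1 / L, abs=1e-15)
            assert d.P2 == pytest.approx(p2 / L, abs=1e-15)
            assert d.Q == pytest.approx(q / L, abs=1e-15)


class TestK2P:
    def test_zero_differences(self):
        assert md.k2p_distance(md.PairwiseDifference(0, 0, 0, 100)) == 0.0

    def test_pure_transition_closed_form(self):
        d = md.k2p_distance(md.PairwiseDifference(0.1, 0, 0, 100))
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)
        assert d == pytest.approx(0.111572, abs=1e-6)

    def test_pure_transversion_closed_form(self):
        d = md.k2p_distance(md.PairwiseDifference(0, 0, 0.1, 100))
        assert d == pytest.approx(-0.5 * math.log(0.9) - 0.25 * math.log(0.8), abs=1e-9)

    def test_saturation_names_pair(self):
        with pytest.raises(SaturationError, match="x/y"):
            md.k2p_distance(md.PairwiseDifference(0.5, 0.1, 0.0, 10), pair=("x", "y"))

    def test_monotone_in_P_and_Q(self):
        grid = np.linspace(0, 0.2, 21)
        dP = [md.k2p_distance(md.PairwiseDifference(p, 0, 0.05, 100)) for p in grid]
        dQ = [md.k2p_distance(md.PairwiseDifference(0.05, 0, q, 100)) for q in grid]
        assert all(b > a for a, b in zip(dP, dP[1:]))
        assert all(b > a for a, b in zip(dQ, dQ[1:]))

    def test_jc_simulation_recovery(self):
        """K2P estimates of Jukes-Cantor pairs at true distance 0.05 are
        unbiased within 3 SE over 200 replicates."""
        rng = np.random.default_rng(37)
        true_d, L = 0.05, 2000
        p_diff = 0.75 * (1 - math.exp(-4 * true_d / 3))
        estimates = []
        for _ in range(200):
            a = rng.choice(list("ACGT"), L)
            b = a.copy()
            hit = rng.random(L) < p_diff
            for i in np.where(hit)[0]:
                b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
            estimates.append(
                md.k2p_distance(md.count_differences("".join(a), "".join(b)))
            )
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(mean - true_d) < 3 * se


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = md.distance_matrix(_aln("ACGT" * 5, "ACGT" * 5, "ACGT" * 5))
        assert np.all(dm.values == 0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(TreeSizeError):
            md.distance_matrix(_aln("ACGT", "ACGA"))

    def test_elementwise_oracle_equivalence(self):
        # moderately diverged sequences (a few % from a common ancestor),
        # so the K2P correction stays well away from saturation
        rng = np.random.default_rng(41)
        anc = rng.choice(list("ACGT"), 300)
        rows = []
        for _ in range(6):
            seq = anc.copy()
            hit = rng.random(300) < 0.05
            for i in np.where(hit)[0]:
                seq[i] = rng.choice([c for c in "ACGT" if c != anc[i]])
            rows.append("".join(seq))
        dm = md.distance_matrix(_aln(*rows))
        for i, j in combinations(range(6), 2):
            expected = md.k2p_distance(md.count_differences(rows[i], rows[j]))
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-15)
            assert dm.values[j, i] == dm.values[i, j]


class TestPublishedRateTable:
    def test_offdiagonal_sum_is_100(self):
        df = load_printed_rate_matrix()
        total = np.nansum(df.values)
        assert total == pytest.approx(100.0, abs=0.1)

    def test_transversion_entries_proportional_to_target_frequency(self):
        """Transversion rates divided by the published target-base frequency
        collapse to a single constant (the TN93 b factor) within 2%."""
        df = load_printed_rate_matrix()
        freqs = {"A": 30.26, "T": 23.76, "C": 32.48, "G": 13.50}
        ratios = []
        for x in "ATCG":
            for j in "ATCG":
                if x == j or {x, j} in ({"A", "G"}, {"C", "T"}):
                    continue
                ratios.append(df.loc[x, j] / freqs[j])
        spread = (max(ratios) - min(ratios)) / np.mean(ratios)
        assert spread < 0.02


class TestTN93Estimation:
    def test_f81_like_recovery(self):
        """On data where every class shares one rate factor (all
        substitutions drawn from the stationary frequencies), the estimated
        k1, k2 and b agree within 10% at 10,000 sites."""
        rng = np.random.default_rng(43)
        freqs = np.array([0.3026, 0.2376, 0.3248, 0.1350])  # A,T,C,G
        bases = np.array(list("ATCG"))
        L, n = 10000, 10
        anc = rng.choice(bases, size=L, p=freqs)
        rows = []
        for _ in range(n):
            seq = anc.copy()
            hit = rng.random(L) < 0.06
            seq[hit] = rng.choice(bases, size=int(hit.sum()), p=freqs)
            rows.append("".join(seq))
        rm = md.tn93_rate_matrix(_aln(*rows))
        vals = sorted([rm.k1, rm.k2, rm.b])
        assert vals[-1] / vals[0] < 1.10

    def test_transition_bias_structure(self):
        """An alignment evolved with strong transition bias yields k1, k2
        well above b and a matrix whose transversion entries are
        proportional to the target frequency."""
        from mitopop import synthetic_data as syn

        aln, _, _ = syn.make_population(
            syn.SyntheticPopulationSpec(
                n_sequences=8, length=8000, theta=0.02, ts_tv_bias=15.0, seed=47
            )
        )
        rm = md.tn93_rate_matrix(aln)
        assert rm.k1 > rm.b and rm.k2 > rm.b
        assert rm.offdiag_sum == pytest.approx(100.0, abs=1e-9)
        idx = {b: i for i, b in enumerate(md.BASE_ORDER)}
        ratios = [
            rm.r[idx[x], idx[j]] / rm.freqs[j]
            for x in md.BASE_ORDER
            for j in md.BASE_ORDER
            if x != j and {x, j} not in ({"A", "G"}, {"C", "T"})
        ]
        assert max(ratios) - min(ratios) < 1e-9 * max(ratios) + 1e-12

    def test_identical_sequences_rejected(self):
        with pytest.raises(EstimationError):
            md.tn93_rate_matrix(_aln("ACGT" * 10, "ACGT" * 10))

    def test_missing_base_class_rejected(self):
        with pytest.raises(EstimationError):
            md.tn93_rate_matrix(_aln("CTCT" * 10, "TCTC" * 10))

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(53)
        rows = ["".join(rng.choice(list("ACGT"), 500)) for _ in range(4)]
        base = md.tn93_rate_matrix(_aln(*rows))
        perm = md.tn93_rate_matrix(_aln(*rows[::-1]))
        dup = md.tn93_rate_matrix(_aln(*(rows + rows)))
        assert np.allclose(base.r, perm.r)
        assert np.allclose(base.r, dup.r)
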