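import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemadelim.distances import (
    SubstitutionCounts,
    build_distance_matrix,
    count_substitutions,
    k2p_distance,
    p_distance,
    percent_similarity,
    tn93_distance,
)
from nemadelim.errors import SaturationError, UndefinedComparisonError
from nemadelim.seq_io import Alignment
from nemadelim.synthetic_data import SimulationConfig, simulate_locus_set

from conftest import record

# --- independent literal transcriptions of the published closed forms ------
# kept separate from the implementation on purpose: they take raw counts and
# spell out every term of the K2P and TN93 formulas.


def k2p_oracle(ts, tv, n):
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def tn93_oracle(ts_ag, ts_ct, tv, n, gA, gC, gG, gT):
    P1, P2, Q = ts_ag / n, ts_ct / n, tv / n
    gR, gY = gA + gG, gC + gT
    term1 = -(2 * gA * gG / gR) * math.log(1 - gR * P1 / (2 * gA * gG) - Q / (2 * gR))
    term2 = -(2 * gC * gT / gY) * math.log(1 - gY * P2 / (2 * gC * gT) - Q / (2 * gY))
    term3 = -2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(
        1 - Q / (2 * gR * gY)
    )
    return term1 + term2 + term3


def make_counts(ts_ag, ts_ct, tv, n, freqs=(0.25, 0.25, 0.25, 0.25)):
    return SubstitutionCounts(n, ts_ag, ts_ct, tv, freqs)


class TestCountSubstitutions:
    def test_identical(self):
        c = count_substitutions(record("x", "ACGTACGT"), record("y", "ACGTACGT"))
        assert (c.compared_sites, c.differences) == (8, 0)

    def test_classification_by_inspection(self):
        c = count_substitutions(record("x", "AAAACCCC"), record("y", "AGAACTCC"))
        assert c.compared_sites == 8
        assert (c.transitions_AG, c.transitions_CT, c.transversions) == (1, 1, 0)
        assert c.differences == 2

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        c = count_substitutions(record("x", "A-GTNCRT"), record("y", "ACGTACAT"))
        # columns 2 (gap), 5 (N), 7 (R) excluded
        assert c.compared_sites == 5
        assert c.differences == 0

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(4)
        bases = "ACGT"
        x = "".join(rng.choice(list(bases), 300))
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        transversion = {"A": "C", "G": "T", "C": "G", "T": "A"}
        sites = rng.choice(300, size=15, replace=False)
        y = list(x)
        for s in sites[:10]:
            y[s] = transition[y[s]]
        for s in sites[10:]:
            y[s] = transversion[y[s]]
        c = count_substitutions(record("x", x), record("y", "".join(y)))
        assert c.transitions_AG + c.transitions_CT == 10
        assert c.transversions == 5

    def test_zero_compared_sites_raises(self):
        with pytest.raises(UndefinedComparisonError):
            count_substitutions(record("x", "NNNN"), record("y", "ACGT"))

    def test_base_freqs_sum_to_one(self):
        c = count_substitutions(record("x", "AACCGGTT"), record("y", "AACCGGTA"))
        assert math.isclose(sum(c.base_freqs), 1.0)


class TestEstimators:
    def test_percent_similarity_values(self):
        assert percent_similarity(make_counts(0, 0, 0, 343)) == 100.0
        assert percent_similarity(make_counts(1, 1, 0, 10)) == 80.0
        assert round(percent_similarity(make_counts(4, 2, 1, 343)), 1) == 98.0

    def test_similarity_complements_p_distance(self):
        c = make_counts(3, 2, 2, 200)
        assert percent_similarity(c) == 100.0 * (1.0 - p_distance(c))

    def test_k2p_frozen_values(self):
        assert k2p_distance(make_counts(0, 0, 0, 100)) == 0.0
        # P=0.1, Q=0.05 and P=0, Q=0.1 evaluated with the literal closed form
        assert math.isclose(k2p_distance(make_counts(10, 0, 5, 100)), 0.1701811651, abs_tol=5e-9)
        assert math.isclose(k2p_distance(make_counts(0, 0, 10, 100)), 0.1084661457, abs_tol=5e-9)

    def test_k2p_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(make_counts(40, 20, 0, 100))  # 1-2P-Q < 0

    def test_tn93_identical_is_zero(self):
        assert tn93_distance(make_counts(0, 0, 0, 100)) == 0.0

    def test_tn93_reduces_to_k2p_in_symmetric_limit(self):
        # equal base frequencies and P1 == P2
        for ts, tv in ((10, 8), (2, 2), (30, 12)):
            c = make_counts(ts, ts, tv, 1000)
            assert abs(tn93_distance(c) - k2p_distance(c)) <= 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_oracle_agreement_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 1000))
        ts_ag = int(rng.integers(0, n // 10))
        ts_ct = int(rng.integers(0, n // 10))
        tv = int(rng.integers(0, n // 10))
        raw = rng.uniform(0.15, 0.35, size=4)
        freqs = tuple(raw / raw.sum())
        c = make_counts(ts_ag, ts_ct, tv, n, freqs)
        assert abs(k2p_distance(c) - k2p_oracle(ts_ag + ts_ct, tv, n)) <= 1e-9
        assert abs(tn93_distance(c) - tn93_oracle(ts_ag, ts_ct, tv, n, *freqs)) <= 1e-9

    def test_monotone_dominance_on_synthetic_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 500
            ts_ag = int(rng.integers(0, 40))
            ts_ct = int(rng.integers(0, 40))
            tv = int(rng.integers(0, 40))
            raw = rng.uniform(0.2, 0.3, size=4)
            c = make_counts(ts_ag, ts_ct, tv, n, tuple(raw / raw.sum()))
            p = p_distance(c)
            k2p = k2p_distance(c)
            tn93 = tn93_distance(c)
            assert tn93 >= k2p - 1e-12 >= p - 2e-12

    def test_small_divergence_limit(self):
        # planted divergence <= 1% on 500 sites: |K2P - p| <= 5e-4
        for ts, tv in ((5, 0), (3, 2), (0, 5), (2, 1)):
            c = make_counts(ts, 0, tv, 500)
            assert abs(k2p_distance(c) - p_distance(c)) <= 5e-4


class TestBuildDistanceMatrix:
    def test_identical_sequences_similarity_100(self):
        aln = Alignment(locus="L", rows=[record(i, "ACGTACGT") for i in "ABC"])
        m = build_distance_matrix(aln, "similarity_percent")
        assert np.allclose(m.values, 100.0)

    def test_diff_count_mode_matches_counts(self):
        aln = Alignment(locus="L", rows=[record("A", "AAAACCCC"), record("B", "AGAACTCC")])
        m = build_distance_matrix(aln, "diff_count")
        assert m.value("A", "B") == 2.0

    def test_matrix_equals_pairwise_brute_force(self):
        records, _ = simulate_locus_set(
            SimulationConfig(seed=2, n_species=4, populations_per_species=1,
                             isolates_per_population=5)
        )
        aln = Alignment(locus="COI", rows=records["COI"][:20])
        for model, fn in (("p", p_distance), ("K2P", k2p_distance), ("TN93", tn93_distance),
                          ("similarity_percent", percent_similarity)):
            m = build_distance_matrix(aln, model)
            for i, x in enumerate(aln.rows):
                for j, y in enumerate(aln.rows):
                    if i < j:
                        expected = fn(count_substitutions(x, y))
                        assert math.isclose(m.values[i, j], expected, abs_tol=1e-12)

    def test_symmetry_and_diagonal(self, coi_alignment):
        m = build_distance_matrix(coi_alignment, "similarity_percent")
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)
        d = build_distance_matrix(coi_alignment, "K2P")
        assert np.allclose(np.diag(d.values), 0.0)

    def test_saturated_pair_flagged_infinite(self):
        aln = Alignment(locus="L", rows=[record("A", "AG" * 50), record("B", "GA" * 50)])
        m = build_distance_matrix(aln, "K2P")
        assert math.isinf(m.value("A", "B"))
        assert ("A", "B") in m.flagged_pairs

    def test_strict_mode_rejects_ambiguous_records(self):
        aln = Alignment(locus="L", rows=[record("A", "N" * 10 + "A" * 90),
                                         record("B", "A" * 100)])
        with pytest.raises(ValueError, match="ambiguous"):
            build_distance_matrix(aln, "p", strict=True)

    def test_tsv_roundtrip(self, tmp_path, coi_alignment):
        m = build_distance_matrix(coi_alignment, "similarity_percent")
        path = tmp_path / "sim.tsv"
        m.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[1:] == m.labels
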