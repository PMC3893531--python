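import math
from itertools import product

import numpy as np
import pytest

from stacklogo import (Alphabet, LogoError, build_logo,
                       gap_parameters_from_hmm, information_content,
                       letter_heights, letter_score, match_occupancy,
                       max_theoretical_height, read_hmm)
from stacklogo.hmm_io import DM, MD, MI, MM, ProfileHMM
from stacklogo.fixtures import HmmSpec, make_toy_hmm, random_hmm_spec

from conftest import make_msa

# printed reference: DNA column distributions (percent) and their
# information content in bits under a uniform background
DNA_INFO_TABLE = [
    ((100, 0, 0, 0), 2.00),
    ((95, 5, 0, 0), 1.71),
    ((90, 10, 0, 0), 1.53),
    ((85, 5, 5, 5), 1.15),
    ((80, 10, 5, 5), 0.98),
    ((70, 10, 10, 10), 0.64),
    ((50, 50, 0, 0), 1.00),
    ((50, 40, 5, 5), 0.54),
    ((45, 45, 5, 5), 0.53),
    ((50, 30, 10, 10), 0.31),
    ((35, 35, 15, 15), 0.12),
    ((25, 25, 25, 25), 0.00),
]


class TestInformationContent:
    @pytest.mark.parametrize("percents,expected", DNA_INFO_TABLE)
    def test_dna_reference_values(self, percents, expected, uniform4):
        p = np.array(percents) / 100.0
        assert round(information_content(p, uniform4), 2) == expected

    def test_identity_gives_zero(self):
        q = np.array([0.4, 0.3, 0.2, 0.1])
        assert information_content(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_divergence(self, uniform4):
        with pytest.raises(LogoError):
            information_content([0.5, 0.5, 0, 0], [0, 0.5, 0.25, 0.25])

    def test_matches_arbitrary_precision_oracle(self, uniform4):
        """D(p||q) agrees with a 50-digit mpmath evaluation on random pairs."""
        import mpmath
        mpmath.mp.dps = 50
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            expected = float(sum(
                mpmath.mpf(pi) * mpmath.log(mpmath.mpf(pi) / mpmath.mpf(qi), 2)
                for pi, qi in zip(p, q) if pi > 0))
            assert information_content(p, q) == pytest.approx(expected, abs=1e-9)


class TestLetterScore:
    def test_zero_at_background(self):
        assert letter_score(0.25, 0.25) == 0.0

    def test_twofold_enrichment_is_one_bit(self):
        assert letter_score(0.5, 0.25) == pytest.approx(1.0)

    def test_zero_probability_is_minus_infinity(self):
        assert letter_score(0.0, 0.25) == float("-inf")

    def test_zero_background_rejected(self):
        with pytest.raises(LogoError):
            letter_score(0.5, 0.0)


class TestLetterHeights:
    def test_info_all_splits_height_by_probability(self, uniform4):
        stack = letter_heights([0.5, 0.5, 0, 0], uniform4, "info_all", "ACGT")
        assert [a for a, _ in stack] == ["C", "A"]  # tie: A closest to top
        for _, h in stack:
            assert h == pytest.approx(0.5, abs=5e-3)  # D = 1.00 bit split 1:1

    def test_score_mode_keeps_only_positive_scores(self, uniform4):
        stack = letter_heights([0.5, 0.25, 0.25, 0], uniform4, "score", "ACGT")
        assert stack == [("A", pytest.approx(1.0))]

    def test_above_background_split_is_proportional(self, uniform4):
        p = [0.5, 0.3, 0.1, 0.1]
        stack = letter_heights(p, uniform4, "info_above_bg", "ACGT")
        assert [a for a, _ in stack] == ["C", "A"]
        D = information_content(p, uniform4)
        assert round(D, 2) == 0.31
        heights = dict(stack)
        assert heights["A"] == pytest.approx(D * 0.5 / 0.8)
        assert heights["C"] == pytest.approx(D * 0.3 / 0.8)

    def test_above_background_total_equals_info_all_total(self, uniform4):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.dirichlet(np.full(4, 0.5))
            all_h = sum(h for _, h in letter_heights(p, uniform4, "info_all", "ACGT"))
            ab_h = sum(h for _, h in letter_heights(p, uniform4, "info_above_bg", "ACGT"))
            assert ab_h == pytest.approx(all_h, abs=1e-9)

    def test_score_heights_equal_log_odds(self):
        amino = Alphabet.amino()
        q = amino.default_background
        rng = np.random.default_rng(9)
        p = rng.dirichlet(np.ones(20))
        stack = dict(letter_heights(p, q, "score", amino.letters))
        for i, a in enumerate(amino.letters):
            s = math.log2(p[i] / q[i])
            if s > 0:
                assert stack[a] == pytest.approx(s)
            else:
                assert a not in stack

    def test_score_stack_can_invert_information_ordering(self, uniform4):
        """A weakly-enriched many-letter column can out-stack a conserved
        two-letter column in score mode, despite lower information."""
        amino = Alphabet.amino()
        q = amino.default_background
        # conserved: two strongly enriched letters, rest zero
        p_conserved = np.zeros(20)
        p_conserved[amino.letters.index("D")] = 0.7
        p_conserved[amino.letters.index("Q")] = 0.3
        # diffuse: many letters modestly above background
        p_diffuse = q.copy()
        boosted = ["C", "A", "S", "T", "M", "W", "H", "F"]
        for a in boosted:
            p_diffuse[amino.letters.index(a)] *= 3.0
        p_diffuse /= p_diffuse.sum()

        D_cons = information_content(p_conserved, q)
        D_diff = information_content(p_diffuse, q)
        assert D_cons > D_diff
        score_total = lambda p: sum(
            h for _, h in letter_heights(p, q, "score", amino.letters))
        assert score_total(p_diffuse) > score_total(p_conserved)

    def test_stack_sorted_ascending_bottom_to_top(self, uniform4):
        stack = letter_heights([0.4, 0.1, 0.2, 0.3], uniform4, "info_all", "ACGT")
        heights = [h for _, h in stack]
        assert heights == sorted(heights)
        assert stack[-1][0] == "A"  # largest probability on top


class TestMaxTheoreticalHeight:
    def test_uniform_dna_is_two_bits(self, dna):
        assert max_theoretical_height(dna) == pytest.approx(2.0)

    def test_uniform_amino_closed_form(self):
        q = np.full(20, 0.05)
        assert max_theoretical_height(q=q) == pytest.approx(math.log2(20))

    def test_blosum62_background_peaks_near_tryptophan(self, amino):
        h = max_theoretical_height(amino)
        assert h == pytest.approx(6.5, abs=0.4)
        w_idx = amino.letters.index("W")
        assert -np.log2(amino.default_background[w_idx]) == pytest.approx(h)


def occupancy_by_path_enumeration(hmm: ProfileHMM, k: int) -> float:
    """Independent oracle: sum path probabilities over all match/delete
    choices at nodes 1..k, keeping paths whose state at node k is match.
    Insert visits marginalize out (the insert state always returns)."""
    t = hmm.transitions
    total = 0.0
    for states in product("MD", repeat=k):
        prob = 1.0
        prev = "B"
        for j, s in enumerate(states, start=1):
            row = t[j - 1]
            if prev == "B":
                prob *= (row[MM] + row[MI]) if s == "M" else row[MD]
            elif prev == "M":
                prob *= (row[MM] + row[MI]) if s == "M" else row[MD]
            else:
                prob *= row[DM] if s == "M" else row[6]
            prev = s
        if states[-1] == "M":
            total += prob
    return total


class TestGapParameters:
    @pytest.mark.parametrize("eps,length", [(0.0, 1.0), (0.5, 2.0), (0.9, 10.0)])
    def test_geometric_mean_insert_length(self, eps, length):
        spec = HmmSpec(match_p=np.tile([0.25] * 4, (3, 1)),
                       eps=np.array([eps] * 3),
                       m_to_i=np.array([0.1, 0.1, 0.1]),
                       m_to_d=np.array([0.1, 0.1, 0.0]))
        hmm = make_toy_hmm(spec)
        for k in (1, 2, 3):
            _, _, exp_len = gap_parameters_from_hmm(hmm, k)
            assert exp_len == pytest.approx(length)

    def test_saturated_insert_self_transition_rejected(self, toy_profile):
        hmm = toy_profile
        broken = ProfileHMM(
            name="x", alphabet=hmm.alphabet,
            match_emissions=hmm.match_emissions.copy(),
            insert_emissions=hmm.insert_emissions.copy(),
            transitions=hmm.transitions.copy())
        broken.transitions[1, 4] = 1.0  # i->i = 1: infinite expected length
        with pytest.raises(LogoError):
            gap_parameters_from_hmm(broken, 1)

    def test_no_deletions_means_full_occupancy(self):
        spec = HmmSpec(match_p=np.tile([0.25] * 4, (3, 1)),
                       eps=np.zeros(3), m_to_i=np.array([0.3, 0.0, 0.2]),
                       m_to_d=np.zeros(3))
        occ = match_occupancy(make_toy_hmm(spec))
        np.testing.assert_allclose(occ, 1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_occupancy_recursion_matches_path_oracle(self, seed):
        M = 2 + seed % 5  # model lengths 2..6
        hmm = make_toy_hmm(random_hmm_spec(M, 4, seed=seed))
        occ = match_occupancy(hmm)
        for k in range(1, M + 1):
            assert occ[k - 1] == pytest.approx(
                occupancy_by_path_enumeration(hmm, k), abs=1e-9)

    def test_occupancy_matches_pyhmmer(self, data_dir):
        pyhmmer = pytest.importorskip("pyhmmer")
        hmm = read_hmm(data_dir / "toy_dna.hmm")
        with pyhmmer.plan7.HMMFile(str(data_dir / "toy_dna.hmm")) as fh:
            ref = np.asarray(fh.read().match_occupancy())
        mine = match_occupancy(hmm)
        # pyhmmer's vector is [0, occ(1), ..., occ(M-1)]
        np.testing.assert_allclose(mine[: len(ref) - 1], ref[1:], atol=1e-6)

    def test_occupancy_bounds_and_length_floor(self):
        for seed in range(5):
            hmm = make_toy_hmm(random_hmm_spec(5, 4, seed=100 + seed))
            occ = match_occupancy(hmm)
            assert np.all((occ >= 0) & (occ <= 1))
            for k in range(1, 6):
                _, ip, el = gap_parameters_from_hmm(hmm, k)
                assert el >= 1.0
                assert 0.0 <= ip <= 1.0


class TestBuildLogo:
    def test_alignment_logo_skips_empty_columns(self):
        rows = ["AC--GTACGT", "AC--GTACGT"]
        logo = build_logo(make_msa(rows), method="observed", symfrac=0)
        assert len(logo) == 8
        assert [p.source_column for p in logo.positions] == [1, 2, 5, 6, 7, 8, 9, 10]
        assert [p.position for p in logo.positions] == list(range(1, 9))

    def test_profile_logo_reports_map_columns(self, toy_profile):
        logo = build_logo(toy_profile)
        assert [p.source_column for p in logo.positions] == [3, 7, 9]
        assert logo.is_profile
        assert logo.positions[0].expected_insert_length == pytest.approx(1.0)
        assert logo.positions[2].expected_insert_length == pytest.approx(10.0)

    def test_alignment_logo_has_no_insert_rows(self):
        logo = build_logo(make_msa(["ACG", "ACG"]), method="weighted_prior")
        for pos in logo.positions:
            assert pos.insert_probability is None
            assert pos.expected_insert_length is None

    def test_observed_vs_weighted_changes_distributions_not_positions(self):
        rows = ["AG"] * 10 + ["CT"]
        obs = build_logo(make_msa(rows), method="observed", symfrac=0)
        wgt = build_logo(make_msa(rows), method="weighted", symfrac=0)
        assert len(obs) == len(wgt)
        assert not np.allclose(obs.positions[0].full_distribution,
                               wgt.positions[0].full_distribution)

    def test_info_content_bounded_by_max_height(self):
        rng = np.random.default_rng(3)
        from stacklogo.fixtures import ColumnSpec, sample_alignment
        specs = [ColumnSpec(rng.dirichlet(np.full(4, 0.4))) for _ in range(6)]
        msa = sample_alignment(specs, nseq=30, seed=8)
        for mode in ("info_all", "info_above_bg"):
            logo = build_logo(msa, mode=mode, method="observed")
            for pos in logo.positions:
                assert pos.info_content <= logo.max_height + 1e-9
                assert pos.stack_height == pytest.approx(pos.info_content, abs=1e-9)

    def test_empty_source_rejected(self, dna):
        from stacklogo import EmptyInputError
        with pytest.raises(EmptyInputError):
            build_logo(make_msa(["--", "--"]), method="observed", symfrac=0)
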