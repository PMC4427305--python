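"""Codon profile construction and frameshift-correcting alignment."""

import itertools

import numpy as np
import pytest

from nirpipe import simulate
from nirpipe.frameshift import (
    AA_ALPHABET,
    AA_INDEX,
    CodonProfile,
    ProfileError,
    X_INDEX,
    build_codon_profile,
    codon_aa,
    correct_frameshifts,
    score_filter,
    translate,
)


class TestBuildProfile:
    def test_identical_references_maximize_their_residue(self):
        base = "MKVLW" * 4  # 20 columns, the minimum usable profile
        profile = build_codon_profile([base] * 5)
        for col, aa in enumerate(base):
            assert np.argmax(profile.matrix[col, :-1]) == AA_INDEX[aa]

    def test_fifty_fifty_column_scores_equally(self):
        a = "MAVLW" * 4
        g = "MGVLW" * 4
        profile = build_codon_profile([a, a, a, g, g, g])
        assert profile.matrix[1, AA_INDEX["A"]] == pytest.approx(
            profile.matrix[1, AA_INDEX["G"]]
        )

    def test_small_pseudocount_recovers_empirical_frequencies(self):
        refs = ["MAAAA" * 4] * 4 + ["MGAAA" * 4]
        profile = build_codon_profile(refs, pseudocount=1e-9)
        # column 1: 4/5 A, 1/5 G against uniform 1/20 background
        assert profile.matrix[1, AA_INDEX["A"]] == pytest.approx(
            np.log2((4 / 5) / (1 / 20)), abs=1e-4
        )
        assert profile.matrix[1, AA_INDEX["G"]] == pytest.approx(
            np.log2((1 / 5) / (1 / 20)), abs=1e-4
        )

    def test_majority_gap_columns_dropped(self):
        refs = ["M-" + "A" * 20, "M-" + "A" * 20, "MK" + "A" * 20,
                "M-" + "A" * 20, "M-" + "A" * 20]
        profile = build_codon_profile(refs)
        assert len(profile) == 21

    def test_fewer_than_five_references_error(self):
        with pytest.raises(ProfileError, match=">= 5"):
            build_codon_profile(["MKVLW"] * 4)


def brute_force_best_score(read: str, profile: CodonProfile) -> float:
    """Independent oracle: enumerate every alignment path recursively."""
    M = len(profile)
    g, f = profile.gap_penalty, profile.frameshift_penalty
    L = len(read)
    best = [-np.inf]

    def score_codon(j, codon):
        return profile.matrix[j, AA_INDEX.get(codon_aa(codon), X_INDEX)]

    def rec(i, j, acc):
        if i >= L - 2:  # free read tail of <= 2 nt, free trailing columns
            best[0] = max(best[0], acc)
            if i >= L:
                return
        if j < M:
            if i + 3 <= L:
                rec(i + 3, j + 1, acc + score_codon(j, read[i:i + 3]))
            if i + 2 <= L:
                rec(i + 2, j + 1, acc - f)
            if i + 4 <= L:
                quad = read[i:i + 4]
                s = max(
                    score_codon(j, quad[:d] + quad[d + 1:]) for d in range(4)
                )
                rec(i + 4, j + 1, acc + s - f)
            rec(i, j + 1, acc - g)  # delete profile column
        if i + 3 <= L:
            rec(i + 3, j, acc - g)  # extra read codon

    for j0 in range(M + 1):  # free leading profile columns
        rec(0, j0, 0.0)
    return best[0]


class TestDpAgainstBruteForce:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_dp_score_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        refs = ["".join(rng.choice(list(AA_ALPHABET), size=24)) for _ in range(5)]
        profile = build_codon_profile(refs)
        # truncate profile and read so full path enumeration stays tractable
        small = CodonProfile(profile.matrix[:6], profile.background,
                             profile.gap_penalty, profile.frameshift_penalty)
        read = "".join(rng.choice(list("ACGT"), size=17 + seed))
        got = correct_frameshifts("r", read, small, min_length=0)
        expected = brute_force_best_score(read, small)
        assert got.score == pytest.approx(expected, abs=1e-6)


class TestCorrection:
    def test_error_free_read_unchanged(self, pool_nir, nir_profile):
        tid = pool_nir.taxa[0]
        seq = pool_nir.sequences[tid]
        res = correct_frameshifts(tid, seq, nir_profile)
        assert res.frameshifts == 0
        assert res.corrected == seq
        assert res.protein == pool_nir.proteins[tid]

    @pytest.mark.parametrize("pos", [30, 100, 233, 401])
    def test_single_deletion_located_and_repaired(self, pool_nir, nir_profile, pos):
        tid = pool_nir.taxa[1]
        seq = pool_nir.sequences[tid]
        mutated = seq[:pos] + seq[pos + 1:]
        res = correct_frameshifts(tid, mutated, nir_profile)
        assert res.frameshifts == 1
        assert abs(res.positions[0] - pos) <= 3
        assert len(res.corrected) % 3 == 0
        assert "*" not in res.protein[:-1]
        # every residue outside the damaged codon is restored
        diffs = sum(a != b for a, b in zip(res.protein, pool_nir.proteins[tid]))
        assert diffs <= 1

    @pytest.mark.parametrize("pos", [45, 150, 312])
    def test_single_insertion_removed_exactly(self, pool_nir, nir_profile, pos):
        tid = pool_nir.taxa[2]
        seq = pool_nir.sequences[tid]
        mutated = seq[:pos] + "A" + seq[pos:]
        res = correct_frameshifts(tid, mutated, nir_profile)
        assert res.frameshifts == 1
        # the repair must restore the true protein; when the insertion lands
        # next to an equivalent base the DP may drop that one instead, so
        # allow one synonymous nt of ambiguity and a position shift within
        # the repeated motif
        assert res.protein == pool_nir.proteins[tid]
        assert len(res.corrected) == len(seq)
        assert sum(a != b for a, b in zip(res.corrected, seq)) <= 1
        assert abs(res.positions[0] - pos) <= 9

    def test_short_read_rejected(self, nir_profile):
        with pytest.raises(ValueError, match="60"):
            correct_frameshifts("r", "ACGT" * 10, nir_profile)

    def test_corrected_region_always_translates_without_stops(self, pool_nir, nir_profile, rng):
        # random homopolymer-style damage; spot check the no-internal-stop invariant
        for tid in pool_nir.taxa[:4]:
            seq = pool_nir.sequences[tid]
            pos = int(rng.integers(10, len(seq) - 10))
            mutated = seq[:pos] + seq[pos + 1:]
            res = correct_frameshifts(tid, mutated, nir_profile)
            assert "*" not in res.protein[:-1]


class TestScoreFilter:
    def results(self, pool_nir, nir_profile):
        return [
            correct_frameshifts(t, pool_nir.sequences[t], nir_profile)
            for t in pool_nir.taxa
        ]

    def test_minus_infinity_threshold_is_identity(self, pool_nir, nir_profile):
        res = self.results(pool_nir, nir_profile)
        kept, frac = score_filter(res, -np.inf)
        assert len(kept) == len(res) and frac == 1.0

    def test_threshold_above_max_empties(self, pool_nir, nir_profile):
        res = self.results(pool_nir, nir_profile)
        kept, frac = score_filter(res, max(r.score for r in res) + 1)
        assert kept == [] and frac == 0.0

    def test_true_reads_separate_from_shuffled_decoys(self, pool_nir, nir_profile, rng):
        true_scores = [r.score for r in self.results(pool_nir, nir_profile)]
        decoy_scores = []
        for t in pool_nir.taxa:
            s = list(pool_nir.sequences[t])
            rng.shuffle(s)
            decoy_scores.append(correct_frameshifts(t, "".join(s), nir_profile).score)
        threshold = (min(true_scores) + max(decoy_scores)) / 2
        assert min(true_scores) > threshold > max(decoy_scores)


class TestSimulatedIndelRecovery:
    def test_most_single_indel_reads_restored_to_true_protein(self):
        restored = total = 0
        for seed in (1, 2, 3):
            pool = simulate.generate_marker_pool(10, "coding", (0.70, 0.90), seed=seed)
            profile = build_codon_profile([pool.proteins[t] for t in pool.taxa])
            table = simulate.simulate_community(pool, 1, 400, samples=["A"], seed=seed)
            reads, truth = simulate.simulate_reads(
                pool, table, {"A": "ACACACACGT"}, "", sub_rate=0.0,
                hp_indel_rate=0.01, chimera_rate=0.0, seed=seed + 50,
            )
            for r in reads:
                t = truth[r.id]
                if len(t.indel_positions) != 1:
                    continue
                body = r.seq[10:]  # strip MID (no primer used here)
                res = correct_frameshifts(r.id, body, profile)
                want = pool.proteins[t.source]
                got = res.protein
                ok = len(got) == len(want) and all(
                    a == b or a == "X" for a, b in zip(got, want)
                )
                total += 1
                restored += ok
        assert total > 50
        assert restored / total >= 0.90
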