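"""Distances, average-neighbor clustering and functional cutoff calibration."""

import numpy as np
import pytest

from nirpipe import otu
from nirpipe.io import DistanceMatrix


class TestPairwiseDistance:
    def test_identical_sequences_zero(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=120))
        dm = otu.pairwise_distance(["a", "b"], [s, s])
        assert dm.values[0, 1] == 0.0

    def test_single_substitution_in_100bp(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=100))
        t = s[:50] + {"A": "C", "C": "G", "G": "T", "T": "A"}[s[50]] + s[51:]
        dm = otu.pairwise_distance(["a", "b"], [s, t])
        assert dm.values[0, 1] == pytest.approx(0.01)

    def test_internal_3bp_gap_counts_once(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=100))
        t = s[:40] + s[43:]  # 3 consecutive bases removed internally
        dm = otu.pairwise_distance(["a", "b"], [s, t])
        assert dm.values[0, 1] == pytest.approx(1 / 97, abs=1e-9)

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            otu.pairwise_distance(["a", "b"], ["ACGZ", "ACGT"])

    def test_engines_agree_on_divergent_pairs(self, pool_16s):
        ids = pool_16s.ids[:6]
        seqs = [pool_16s.sequences[i] for i in ids]
        d1 = otu.pairwise_distance(ids, seqs, engine="needleman")
        d2 = otu.pairwise_distance(ids, seqs, engine="edlib")
        np.testing.assert_allclose(d1.values, d2.values, atol=0.005)


def brute_force_average_linkage(dm: DistanceMatrix, cutoff: float) -> list[set]:
    """Independent oracle: naive agglomeration on explicit cluster sets."""
    clusters = [{i} for i in range(len(dm.ids))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [dm.values[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best[0] > cutoff:
            break
        d, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return [set(dm.ids[i] for i in c) for c in clusters]


class TestClustering:
    def counts_for(self, ids, abundance=None):
        return {x: {"s1": (abundance or {}).get(x, 1)} for x in ids}

    def test_identical_sequences_one_otu(self, rng):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        asg = otu.cluster_average_neighbor(dm, 0.03, self.counts_for("abc"))
        assert asg.n_otus == 1

    @pytest.mark.parametrize("cutoff,expected", [(0.03, 2), (0.05, 1)])
    def test_cutoff_boundary_inclusive(self, cutoff, expected):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.05], [0.05, 0]]))
        asg = otu.cluster_average_neighbor(dm, cutoff, self.counts_for("ab"))
        assert asg.n_otus == expected

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partition_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        v = rng.uniform(0.01, 0.4, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, v)
        cutoff = float(rng.uniform(0.05, 0.3))
        asg = otu.cluster_average_neighbor(dm, cutoff, self.counts_for(ids))
        got = {}
        for sid, o in asg.assignment.items():
            got.setdefault(o, set()).add(sid)
        assert sorted(got.values(), key=sorted) == sorted(
            brute_force_average_linkage(dm, cutoff), key=sorted
        )

    def test_representative_is_most_abundant_tie_lexicographic(self):
        dm = DistanceMatrix(["b", "a", "z"],
                            np.array([[0, .01, .01], [.01, 0, .01], [.01, .01, 0]]))
        counts = {"b": {"s1": 5}, "a": {"s1": 5}, "z": {"s1": 1}}
        asg = otu.cluster_average_neighbor(dm, 0.03, counts)
        assert asg.representatives["Otu0001"] == "a"

    def test_otu_count_non_increasing_in_cutoff(self, rng):
        n = 12
        v = rng.uniform(0, 0.5, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, v)
        counts = self.counts_for(ids)
        sizes = [
            otu.cluster_average_neighbor(dm, c, counts).n_otus
            for c in np.linspace(0.02, 0.5, 12)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_counts_conserved_per_sample(self, pool_16s):
        ids = pool_16s.ids[:8]
        seqs = [pool_16s.sequences[i] for i in ids]
        counts = {x: {"s1": 3, "s2": 2} for x in ids}
        dm = otu.pairwise_distance(ids, seqs, engine="edlib")
        asg = otu.cluster_average_neighbor(dm, 0.03, counts)
        assert asg.table.data["s1"].sum() == 8 * 3
        assert asg.table.data["s2"].sum() == 8 * 2


class TestDereplicatePrecluster:
    def test_dereplicate_aggregates_by_sequence(self):
        from nirpipe.io import Read

        reads = [Read("r1", "ACGT", sample="A"), Read("r2", "ACGT", sample="B"),
                 Read("r3", "TTTT", sample="A")]
        uniques, counts = otu.dereplicate(reads)
        assert uniques[0] == ("r1", "ACGT", 2)
        assert counts["r1"] == {"A": 1, "B": 1}

    def test_precluster_merges_single_error_into_abundant_seed(self, rng):
        from nirpipe.io import Read

        base = "".join(rng.choice(list("ACGT"), size=200))
        err = base[:100] + ("A" if base[100] != "A" else "C") + base[101:]
        reads = [Read(f"r{i}", base, sample="A") for i in range(10)]
        reads.append(Read("rx", err, sample="A"))
        uniques, counts = otu.dereplicate(reads)
        merged, mcounts, mapping = otu.precluster(uniques, counts, diffs=2)
        assert len(merged) == 1
        assert merged[0][2] == 11
        assert mapping["rx"] == "r0"


class TestCalibration:
    CODON = {"K": ("AAA", "AAG"), "N": ("AAT", "AAC"), "I": ("ATT", "ATC", "ATA"),
             "T": ("ACT", "ACC", "ACA", "ACG")}

    def build(self, protein, picks):
        return "".join(self.CODON[aa][p] for aa, p in zip(protein, picks))

    def test_planted_synonymous_radius_is_recovered(self):
        # two proteins differing at half their residues (nt distance >= 0.25),
        # each with two synonymous variants exactly 10% nt apart
        p1 = "KNIT" * 15
        p2 = "TINK" * 15
        n = len(p1)  # 60 codons, 180 nt
        swap = [1] * 18 + [0] * (n - 18)  # 18 codon third-position changes = 10%
        seqs = {
            "a1": self.build(p1, [0] * n), "a2": self.build(p1, swap),
            "b1": self.build(p2, [0] * n), "b2": self.build(p2, swap),
        }
        ids = list(seqs)
        counts = {x: {"s1": 1} for x in ids}
        res = otu.calibrate_functional_cutoff(ids, [seqs[x] for x in ids], counts)
        assert res.chosen == pytest.approx(0.10)
        chosen_asg = res.assignments[res.chosen]
        assert chosen_asg.n_otus == 2

    def test_single_protein_pool_needs_full_merge(self):
        p = "KNIT" * 15
        n = len(p)
        seqs = {
            "a": self.build(p, [0] * n),
            "b": self.build(p, [1] * 18 + [0] * (n - 18)),      # 0.10 away
            "c": self.build(p, [0] * 18 + [1] * 9 + [0] * (n - 27)),  # 0.05 away
        }
        ids = list(seqs)
        counts = {x: {"s1": 1} for x in ids}
        res = otu.calibrate_functional_cutoff(ids, [seqs[x] for x in ids], counts)
        # all sequences encode one protein: first qualifying cutoff is the one
        # collapsing everything into a single OTU
        assert res.chosen is not None
        assert res.assignments[res.chosen].n_otus == 1

    def test_unique_distant_proteins_choose_grid_floor(self, pool_nir):
        taxa = pool_nir.taxa
        ids = taxa
        seqs = [pool_nir.sequences[t] for t in taxa]
        counts = {t: {"s1": 1} for t in taxa}
        res = otu.calibrate_functional_cutoff(ids, seqs, counts)
        assert res.chosen == pytest.approx(0.05)

    def test_otu_counts_non_increasing_along_grid(self, pool_nir):
        ids = pool_nir.ids
        seqs = [pool_nir.sequences[i] for i in ids]
        counts = {i: {"s1": 1} for i in ids}
        res = otu.calibrate_functional_cutoff(ids, seqs, counts)
        assert all(a >= b for a, b in zip(res.otu_counts, res.otu_counts[1:]))

    def test_internal_stop_representative_errors(self):
        seqs = {"a": "TAATAATAA" * 8, "b": ("AAA" * 24)}
        counts = {x: {"s1": 1} for x in seqs}
        with pytest.raises(ValueError, match="stop"):
            otu.calibrate_functional_cutoff(list(seqs), list(seqs.values()), counts)
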