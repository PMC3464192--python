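import numpy as np
import pytest

from disomut import (
    MutationRecord,
    ProteinRecord,
    blosum85,
    cluster_redundant,
    extract_nes,
    flag_outliers,
    global_align,
    percent_identity,
)


@pytest.fixture(scope="module")
def matrix():
    return blosum85()


def brute_force_best_score(a, b, matrix, gap_open=-11.0, gap_extend=-1.0):
    """Exponential enumeration over all global alignments (oracle).

    A gap run of length L costs gap_open + (L-1) * gap_extend; end gaps are
    penalized like internal ones.
    """
    best = -np.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if last == "A" else gap_open), "A")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if last == "B" else gap_open), "B")

    rec(0, 0, 0.0, None)
    return best


class TestGlobalAlign:
    def test_identical_sequences(self):
        result = global_align("MKTAY", "MKTAY")
        assert result.identity_pct == 100.0
        assert "-" not in result.aligned_a + result.aligned_b

    def test_single_mismatch_identity(self):
        result = global_align("ACDEFGHIK", "ACDEFGHIR")
        assert result.identity_pct == pytest.approx(100 * 8 / 9)

    def test_degapped_strings_equal_inputs(self):
        result = global_align("MKTAYIAK", "MKAK")
        assert result.aligned_a.replace("-", "") == "MKTAYIAK"
        assert result.aligned_b.replace("-", "") == "MKAK"
        assert len(result.aligned_a) == len(result.aligned_b)

    def test_score_matches_exhaustive_enumeration(self, matrix, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(12):
            a = "".join(rng.choice(residues, size=rng.integers(1, 7)))
            b = "".join(rng.choice(residues, size=rng.integers(1, 7)))
            expected = brute_force_best_score(a, b, matrix)
            assert global_align(a, b).score == pytest.approx(expected), (a, b)

    def test_score_and_identity_symmetric(self, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(residues, size=12))
            b = "".join(rng.choice(residues, size=10))
            fwd, rev = global_align(a, b), global_align(b, a)
            assert fwd.score == pytest.approx(rev.score)
            assert fwd.identity_pct == pytest.approx(rev.identity_pct)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MKT")

    def test_blosum85_is_symmetric(self, matrix):
        arr = np.array([[matrix[a, b] for b in "ACDEFG"] for a in "ACDEFG"])
        assert np.array_equal(arr, arr.T)


class TestPercentIdentity:
    def test_double_gap_columns_excluded(self):
        assert percent_identity("A-C-", "A--C") == pytest.approx(100 / 3)

    def test_shorter_denominator_option(self):
        assert percent_identity("ACD-", "ACDE", denominator="shorter") == 100.0


class TestClusterRedundant:
    def test_identical_proteins_cluster_together(self):
        proteins = [ProteinRecord("a", "MKTAYIAKQR"), ProteinRecord("b", "MKTAYIAKQR")]
        clusters = cluster_redundant(proteins, 40.0, seed=0)
        assert clusters.cluster_of["a"] == clusters.cluster_of["b"]

    def test_single_linkage_transitivity(self):
        # A-B 50%, B-C 45%, A-C 10%: one cluster at threshold 40
        # (oracle: union-find over the >= threshold edges)
        proteins = [ProteinRecord(i, "M") for i in "ABC"]
        identities = np.array(
            [[100.0, 50.0, 10.0], [50.0, 100.0, 45.0], [10.0, 45.0, 100.0]]
        )
        clusters = cluster_redundant(proteins, 40.0, seed=0, identities=identities)
        assert len(set(clusters.cluster_of.values())) == 1

    def test_all_below_threshold_gives_singletons(self):
        proteins = [ProteinRecord(i, "M") for i in "ABC"]
        identities = np.full((3, 3), 10.0)
        np.fill_diagonal(identities, 100.0)
        clusters = cluster_redundant(proteins, 40.0, seed=0, identities=identities)
        assert len(set(clusters.cluster_of.values())) == 3

    def test_partition_independent_of_seed_and_order(self):
        proteins = [
            ProteinRecord("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
            ProteinRecord("b", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
            ProteinRecord("c", "GSGSGSGSGSGSGSGSGSGSGSGSGSGSGSGSG"),
        ]

        def partition(assignment):
            groups = {}
            for pid, cluster in assignment.cluster_of.items():
                groups.setdefault(cluster, set()).add(pid)
            return sorted(map(frozenset, groups.values()), key=sorted)

        base = cluster_redundant(proteins, 40.0, seed=0)
        reseeded = cluster_redundant(proteins, 40.0, seed=99)
        reordered = cluster_redundant(proteins[::-1], 40.0, seed=0)
        assert partition(base) == partition(reseeded) == partition(reordered)
        # representatives with the same seed are order-invariant too
        assert sorted(base.representatives.values()) == sorted(
            reordered.representatives.values()
        )

    def test_filter_mutations_counts_discards(self):
        proteins = [ProteinRecord("a", "MKT"), ProteinRecord("b", "MKT")]
        clusters = cluster_redundant(proteins, 40.0, seed=0)
        mutations = [
            MutationRecord("a", 1, "M", "V", "DM"),
            MutationRecord("b", 1, "M", "V", "DM"),
        ]
        kept, discarded = clusters.filter_mutations(mutations)
        assert len(kept) == 1 and discarded == 1


class TestFlagOutliers:
    def make(self, counts):
        out = []
        for pid, n in counts.items():
            out += [MutationRecord(pid, i + 1, "A", "C", "DM") for i in range(n)]
        return out

    def test_top_k_flags_highest_count(self):
        mutations = self.make({"big": 100, "s1": 5, "s2": 4, "s3": 3})
        report = flag_outliers(mutations, "top_k", 1)
        assert report.flagged == ["big"]
        assert report.removed_fraction == pytest.approx(100 / 112)

    def test_count_ge_above_max_is_empty(self):
        mutations = self.make({"a": 3, "b": 2})
        report = flag_outliers(mutations, "count_ge", 10)
        assert report.flagged == [] and report.removed_fraction == 0.0

    def test_k_larger_than_protein_count_errors(self):
        with pytest.raises(ValueError):
            flag_outliers(self.make({"a": 1}), "top_k", 5)

    def test_filter_removes_flagged_mutations(self):
        mutations = self.make({"big": 10, "small": 2})
        report = flag_outliers(mutations, "top_k", 1)
        kept = report.filter_mutations(mutations)
        assert {m.protein_id for m in kept} == {"small"}


class TestExtractNes:
    HUMAN = ProteinRecord("hum", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG")

    def ortholog(self, *changes):
        seq = list(self.HUMAN.sequence)
        for pos, aa in changes:
            seq[pos - 1] = aa
        return "".join(seq)

    def test_single_difference_yields_one_record(self):
        records = extract_nes(self.HUMAN, orthologs={"mouse": self.ortholog((10, "W"))})
        assert records == [MutationRecord("hum", 10, "R", "W", "NES")]

    def test_identity_below_threshold_excluded(self):
        # 4 changes in 50 residues: 92% identity < 95%
        distant = self.ortholog((1, "W"), (10, "W"), (20, "W"), (30, "W"))
        assert extract_nes(self.HUMAN, orthologs={"mouse": distant}) == []

    def test_disease_mutations_filtered_out(self):
        disease = [MutationRecord("hum", 10, "R", "W", "DM")]
        records = extract_nes(
            self.HUMAN,
            orthologs={"mouse": self.ortholog((10, "W"))},
            disease_mutations=disease,
        )
        assert records == []

    def test_duplicates_deduplicated_by_default(self):
        orthologs = {
            "mouse": self.ortholog((10, "W")),
            "rat": self.ortholog((10, "W")),
        }
        assert len(extract_nes(self.HUMAN, orthologs=orthologs)) == 1
        assert (
            len(extract_nes(self.HUMAN, orthologs=orthologs, keep_multiplicity=True))
            == 2
        )

    def test_never_contains_any_disease_mutation(self, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        changes = [
            (int(p) + 1, str(a))
            for p, a in zip(rng.integers(0, 50, size=2), rng.choice(residues, 2))
        ]
        ortholog = self.ortholog(*changes)
        disease = [
            MutationRecord("hum", pos, self.HUMAN.sequence[pos - 1], aa, "DM")
            for pos, aa in changes
            if self.HUMAN.sequence[pos - 1] != aa
        ]
        records = extract_nes(
            self.HUMAN, orthologs={"o": ortholog}, disease_mutations=disease
        )
        keys = {m.key() for m in disease}
        assert all(r.key() not in keys for r in records)

    def test_gapped_human_positions_skipped(self):
        human = ProteinRecord("hum", "MKTAY" * 10)
        aligned_h = human.sequence[:25] + "-" + human.sequence[25:]
        aligned_o = human.sequence[:25] + "W" + human.sequence[25:]
        records = extract_nes(human, ortholog_alignments={"o": (aligned_h, aligned_o)})
        assert records == []  # the only difference sits in a human gap
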