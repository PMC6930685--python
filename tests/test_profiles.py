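import numpy as np
import pandas as pd
import pytest

from rnamut.io_formats import ExonRecord, ExonSet
from rnamut.profiles import (
    all_class_labels,
    class_label,
    collapse_substitution,
    context_profile,
    count_contexts,
    embed_and_score,
    person_grouping_score,
    signature_similarity,
    silhouette_scores,
    strand_asymmetry,
)


class TestCollapse:
    def test_pyrimidine_reference_unchanged(self):
        assert collapse_substitution("C", "T", "ACG") == ("C>T", "ACG", "T", False)
        assert collapse_substitution("T", "A", "GTC") == ("T>A", "GTC", "A", False)

    def test_purine_reference_reverse_complemented(self):
        # G>A at context AGT == C>T at revcomp(AGT) = ACT on the other strand
        assert collapse_substitution("G", "A", "AGT") == ("C>T", "ACT", "T", True)
        assert collapse_substitution("A", "C", "TAG") == ("T>G", "CTA", "G", True)

    def test_strand_involution(self):
        # collapsing a substitution and its complement gives the same class
        for ref, alt, ctx in [("G", "T", "AAGTT"), ("A", "G", "CCACC")]:
            cls, cctx, calt, _ = collapse_substitution(ref, alt, ctx)
            comp = str.maketrans("ACGT", "TGCA")
            rc = ctx.translate(comp)[::-1]
            cls2, cctx2, calt2, _ = collapse_substitution(
                ref.translate(comp), alt.translate(comp), rc
            )
            assert (cls, cctx, calt) == (cls2, cctx2, calt2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            collapse_substitution("C", "C", "ACG")
        with pytest.raises(ValueError):
            collapse_substitution("C", "T", "AAG")  # not centred on ref
        with pytest.raises(ValueError):
            collapse_substitution("C", "T", "ACGT")  # even length


class TestLabels:
    def test_label_format(self):
        assert class_label("ACGTA", "T") == "AC[G>T]TA"
        assert class_label("C", "A") == "[C>A]"

    @pytest.mark.parametrize("flank,n", [(0, 6), (1, 96), (2, 1536)])
    def test_class_counts(self, flank, n):
        labels = all_class_labels(flank)
        assert len(labels) == n
        assert len(set(labels)) == n


class TestCountContexts:
    def test_small_sequence_by_hand(self):
        # sequence ACGT, flank 1: windows ACG (C centre), CGT (G centre -> revcomp ACG)
        counts = count_contexts("ACGT", 1)
        assert counts == {"ACG": 2}

    def test_ambiguous_bases_skipped(self):
        assert count_contexts("ANCGT", 1) == {"ACG": 1}

    def test_total_window_count(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 500))
        counts = count_contexts(seq, 2)
        assert sum(counts.values()) == 500 - 4
        assert all(k[2] in "CT" for k in counts)


class TestContextProfile:
    def test_normalization_by_hand(self):
        # one expressed gene "ACGT" at TPM 10: context ACG occurs twice
        prof = context_profile(
            "s0",
            [("C", "T", "ACG"), ("G", "A", "CGT")],  # both collapse to A[C>T]G
            {"g1": "ACGT"},
            {"g1": 10.0},
            flank=1,
        )
        assert prof.counts["A[C>T]G"] == 2
        assert prof.normalized["A[C>T]G"] == pytest.approx(2 / 20.0)
        # classes whose context never occurs are NaN
        assert np.isnan(prof.normalized["T[C>T]T"])

    def test_expression_threshold(self):
        with pytest.raises(ValueError, match="tpm_min"):
            context_profile("s0", [], {"g1": "ACGT"}, {"g1": 0.5}, flank=1)

    def test_missing_sequence_rejected(self):
        with pytest.raises(KeyError, match="g1"):
            context_profile("s0", [], {}, {"g1": 10.0}, flank=1)

    def test_unusable_contexts_counted(self):
        prof = context_profile(
            "s0", [("C", "T", "NCG")], {"g1": "ACGTACGT"}, {"g1": 5.0}, flank=1
        )
        assert prof.n_unusable == 1
        assert prof.counts.sum() == 0


class TestSilhouette:
    def test_spec_worked_example(self):
        coords = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = ["a", "a", "b", "b"]
        s = silhouette_scores(coords, labels, "a")
        # s for (0,0): a=1, b=(10+sqrt(101))/2=10.025 -> 0.9002
        assert s[0] == pytest.approx(0.900, abs=0.001)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(40, 2))
        labels = ["a"] * 20 + ["b"] * 20
        for g in ("a", "b"):
            s = silhouette_scores(coords, labels, g)
            assert np.all(s >= -1.0) and np.all(s <= 1.0)

    def test_singleton_group_rejected(self):
        coords = np.zeros((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            silhouette_scores(coords, ["a", "b", "b"], "a")

    def test_perfect_separation_approaches_one(self):
        coords = np.array([[0, 0], [0, 0.01], [1e4, 0], [1e4, 0.01]])
        s = silhouette_scores(coords, ["a", "a", "b", "b"], "a")
        assert np.all(s > 0.999)


def _pca2(X):
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt[:2].T


class TestEmbedAndScore:
    def _profiles(self, n_per=10, sep=8.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n_per, 5))
        b = rng.normal(sep, 1, size=(n_per, 5))
        X = np.vstack([a, b])
        idx = [f"s{i}" for i in range(2 * n_per)]
        prof = pd.DataFrame(X, index=idx)
        groups = {s: ("a" if i < n_per else "b") for i, s in enumerate(idx)}
        return prof, groups

    def test_separated_groups_score_high(self):
        prof, groups = self._profiles()
        report = embed_and_score(prof, groups, embedding=_pca2, n_boot=200, seed=0)
        ss = report.groups.set_index("group")["ss"]
        assert ss["a"] > 0.6 and ss["b"] > 0.6
        assert report.random_expectation < 0.3
        lo = report.groups.set_index("group")["ci_low"]
        assert (lo <= ss).all()

    def test_permuted_labels_near_zero(self):
        prof, groups = self._profiles()
        rng = np.random.default_rng(3)
        labels = list(groups.values())
        rng.shuffle(labels)
        shuffled = dict(zip(groups.keys(), labels))
        report = embed_and_score(prof, shuffled, embedding=_pca2, n_boot=100, seed=0)
        assert report.groups["ss"].abs().max() < 0.35

    def test_singleton_group_flagged(self):
        prof, groups = self._profiles(n_per=5)
        groups["s0"] = "lonely"
        report = embed_and_score(prof, groups, embedding=_pca2, n_boot=50, seed=0)
        assert any(f.startswith("singleton_or_total_group") for f in report.flags)

    def test_default_embedding_tsne_runs(self):
        prof, groups = self._profiles(n_per=8, sep=12.0, seed=2)
        report = embed_and_score(prof, groups, n_boot=50, seed=0)
        assert report.coords.shape == (16, 2)
        ss = report.groups.set_index("group")["ss"]
        assert ss["a"] > 0.5 and ss["b"] > 0.5

    def test_bad_embedding_shape_rejected(self):
        prof, groups = self._profiles(n_per=4)
        with pytest.raises(ValueError, match="coordinates"):
            embed_and_score(prof, groups, embedding=lambda X: np.zeros((3, 3)))

    def test_person_grouping_score(self):
        rng = np.random.default_rng(4)
        centres = rng.normal(0, 50, size=(10, 2))
        coords = np.repeat(centres, 3, axis=0) + rng.normal(0, 0.5, size=(30, 2))
        individuals = np.repeat([f"i{k}" for k in range(10)], 3)
        score = person_grouping_score(coords, individuals, n_individuals=20, seed=0)
        assert score > 0.8


class TestStrandAsymmetry:
    def test_template_strand_bookkeeping(self):
        exons = ExonSet(
            [
                ExonRecord("chr1", 0, 100, "plus_gene", "+"),
                ExonRecord("chr1", 200, 300, "minus_gene", "-"),
                ExonRecord("chr1", 400, 500, "f", "+"),
                ExonRecord("chr1", 450, 500, "r", "-"),
            ]
        )
        calls = pd.DataFrame(
            [
                # + gene: template is '-'. C ref: pyrimidine on '+', not template
                {"sample": "s0", "chrom": "chr1", "pos": 10, "ref": "C", "alt": "A"},
                # + gene: G>A flips to C>T, pyrimidine on '-', the template strand
                {"sample": "s0", "chrom": "chr1", "pos": 11, "ref": "G", "alt": "A"},
                # - gene: template is '+'. C ref: pyrimidine on '+' == template
                {"sample": "s0", "chrom": "chr1", "pos": 250, "ref": "C", "alt": "A"},
                # outside any gene
                {"sample": "s0", "chrom": "chr1", "pos": 150, "ref": "C", "alt": "A"},
                # genes on both strands
                {"sample": "s0", "chrom": "chr1", "pos": 470, "ref": "C", "alt": "A"},
            ]
        )
        tally = strand_asymmetry(calls, exons, {"s0": "skin"})
        per = tally.per_sample.set_index("class")
        assert per.loc["C>A", "transcribed"] == 1  # the minus-gene call
        assert per.loc["C>A", "non_transcribed"] == 1
        assert per.loc["C>T", "transcribed"] == 1  # the flipped G>A call
        assert tally.n_excluded_no_gene == 1
        assert tally.n_excluded_ambiguous_strand == 1

    def test_per_tissue_summary(self):
        exons = ExonSet([ExonRecord("chr1", 0, 100, "g", "+")])
        calls = pd.DataFrame(
            [
                {"sample": s, "chrom": "chr1", "pos": 10 + i, "ref": "C", "alt": "T"}
                for s in ("s0", "s1")
                for i in range(3)
            ]
        )
        tally = strand_asymmetry(calls, exons, {"s0": "skin", "s1": "skin"})
        row = tally.per_tissue.set_index(["tissue", "class"]).loc[("skin", "C>T")]
        assert row["mean_non_transcribed"] == 3.0
        assert row["mean_transcribed"] == 0.0


class TestSignatureSimilarity:
    def _profiles(self, n=20, planted=True, seed=0):
        rng = np.random.default_rng(seed)
        contexts = all_class_labels(1)
        marker = pd.Series(rng.normal(10, 2, n), index=[f"s{i}" for i in range(n)])
        base = rng.gamma(2.0, 1.0, size=len(contexts))
        sig = np.zeros(len(contexts))
        ct = [i for i, c in enumerate(contexts) if "[C>T]" in c]
        sig[ct] = 1.0
        rows = []
        order = marker.sort_values().index
        low = set(order[:4])
        for s in marker.index:
            boost = 3.0 if (planted and s in low) else 0.0
            rows.append(base * (1 + boost * sig) * rng.uniform(0.9, 1.1, len(contexts)))
        prof = pd.DataFrame(rows, index=marker.index, columns=contexts)
        signature = pd.Series(sig, index=contexts)
        return prof, marker, signature

    def test_planted_signature_recovered(self):
        prof, marker, signature = self._profiles(planted=True)
        res = signature_similarity(prof, marker, signature, n_perm=200, seed=1)
        assert res.cosine_restricted > 0.8
        assert res.p_all <= 0.02

    def test_null_is_uninformative(self):
        prof, marker, signature = self._profiles(planted=False, seed=5)
        res = signature_similarity(prof, marker, signature, n_perm=200, seed=1)
        assert res.p_all > 0.05

    def test_too_few_samples(self):
        prof, marker, signature = self._profiles(n=8)
        with pytest.raises(ValueError, match="10 samples"):
            signature_similarity(prof, marker, signature)
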