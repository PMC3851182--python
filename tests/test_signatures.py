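import itertools
import math

import numpy as np
import pandas as pd
import pytest

from termscan.annotation import Feature, GenomeAnnotation
from termscan.signatures import (
    ExpressionMatrix,
    MutantSignature,
    SignatureError,
    cosine_cluster,
    fold_changes,
    hypergeometric_enrichment,
    profile_correlation,
    read_expression_matrix,
    readthrough_proxy_genes,
    shared_signature_genes,
    significance_filter,
    write_expression_matrix,
)

from conftest import random_annotation


def small_matrix(values, groups):
    genes = [f"g{i}" for i in range(len(next(iter(values.values()))))]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes),
        groups=pd.Series(groups),
    )


class TestFoldChanges:
    def test_mean_vs_pool(self):
        mat = small_matrix(
            {"m1": [2.0], "m2": [2.0], "w1": [0.0], "w2": [0.0], "w3": [0.0]},
            {"m1": "mut", "m2": "mut", "w1": "wt", "w2": "wt", "w3": "wt"},
        )
        sig = fold_changes(mat, "mut", with_pvalues=False)
        assert sig.M.iloc[0] == pytest.approx(2.0)

    def test_identical_groups_zero(self, rng):
        v = rng.normal(size=5)
        mat = small_matrix(
            {"m1": v, "m2": v, "w1": v, "w2": v},
            {"m1": "mut", "m2": "mut", "w1": "wt", "w2": "wt"},
        )
        sig = fold_changes(mat, "mut", with_pvalues=False)
        np.testing.assert_allclose(sig.M, 0.0, atol=1e-12)

    def test_matches_two_mean_recomputation(self, rng):
        n_genes = 30
        cols = {f"m{i}": rng.normal(size=n_genes) for i in range(3)}
        cols.update({f"w{i}": rng.normal(size=n_genes) for i in range(4)})
        groups = {c: ("mut" if c.startswith("m") else "wt") for c in cols}
        mat = small_matrix(cols, groups)
        sig = fold_changes(mat, "mut")
        for gi in range(n_genes):
            mut_mean = sum(cols[f"m{i}"][gi] for i in range(3)) / 3
            wt_mean = sum(cols[f"w{i}"][gi] for i in range(4)) / 4
            assert sig.M.iloc[gi] == pytest.approx(mut_mean - wt_mean, abs=1e-12)

    def test_unknown_mutant_errors(self):
        mat = small_matrix({"w1": [0.0]}, {"w1": "wt"})
        with pytest.raises(SignatureError):
            fold_changes(mat, "nope")

    def test_round_trip_io(self, tmp_path, rng):
        cols = {f"s{i}": rng.normal(size=8) for i in range(4)}
        mat = small_matrix(cols, {"s0": "wt", "s1": "wt", "s2": "a", "s3": "a"})
        write_expression_matrix(mat, tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = read_expression_matrix(tmp_path / "m.tsv", tmp_path / "s.tsv")
        np.testing.assert_allclose(back.values, mat.values, atol=1e-5)
        assert back.mutants == ["a"]


class TestSignificanceFilter:
    def _sig(self, M, p):
        genes = [f"g{i}" for i in range(len(M))]
        return MutantSignature(
            "m", pd.Series(M, index=genes), pd.Series(p, index=genes)
        )

    def test_filter_contract(self):
        sig = self._sig([1.0, 1.0, 0.5], [0.01, 0.10, 0.001])
        kept = significance_filter(sig)
        # kept: strong and significant; dropped: p too high, |M| below log2(1.7)
        assert list(kept) == ["g0"]
        assert sig.significant.tolist() == [True, False, False]

    def test_fold_change_bound_value(self):
        assert math.log2(1.7) == pytest.approx(0.7655, abs=1e-4)
        sig = self._sig([0.766, 0.765], [0.001, 0.001])
        assert list(significance_filter(sig)) == ["g0"]

    def test_degenerate_bounds_keep_all_nonzero(self, rng):
        M = rng.normal(size=20)
        M[3] = 0.0
        sig = self._sig(M, rng.uniform(0.0, 0.999, size=20))
        kept = significance_filter(sig, p_cut=1.0, fc_cut=1.0)
        assert set(kept) == {f"g{i}" for i in range(20) if M[i] != 0}


def average_linkage_trace(D):
    """Naive average-linkage agglomeration on a distance matrix; returns the
    merge list [(members_a, members_b, height), ...]."""
    clusters = [[i] for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            h = np.mean([D[x][y] for x in a for y in b])
            if best is None or h < best[0] - 1e-12:
                best = (h, i, j)
        h, i, j = best
        merges.append((sorted(clusters[i]), sorted(clusters[j]), h))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


class TestCosineCluster:
    def _sigs(self, vectors):
        genes = [f"g{i}" for i in range(len(vectors[0]))]
        return [
            MutantSignature(f"m{k}", pd.Series(v, index=genes))
            for k, v in enumerate(vectors)
        ]

    def test_identical_signatures_merge_first_at_zero(self):
        sigs = self._sigs([[1, 2, 0], [1, 2, 0], [0, 0, 5]])
        tree = cosine_cluster(sigs, genes=["g0", "g1", "g2"])
        assert tree.distance_matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        a, b = int(tree.linkage[0, 0]), int(tree.linkage[0, 1])
        assert {a, b} == {0, 1}
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_signatures_distance_one(self):
        sigs = self._sigs([[1, 1, 0, 0], [0, 0, 1, 1]])
        tree = cosine_cluster(sigs, genes=[f"g{i}" for i in range(4)])
        assert tree.distance_matrix[0, 1] == pytest.approx(1.0)

    def test_rescaling_invariance(self):
        genes = [f"g{i}" for i in range(3)]
        base = [[1.0, 2.0, 3.0], [3.0, 1.0, 0.5], [-1.0, 2.0, 1.0]]
        t1 = cosine_cluster(self._sigs(base), genes=genes)
        scaled = [list(np.array(base[0]) * 7.3), base[1], base[2]]
        t2 = cosine_cluster(self._sigs(scaled), genes=genes)
        np.testing.assert_allclose(t1.distance_matrix, t2.distance_matrix, atol=1e-12)

    def test_four_signature_average_linkage_trace(self, rng):
        vectors = rng.normal(size=(4, 6))
        genes = [f"g{i}" for i in range(6)]
        sigs = self._sigs(vectors)
        tree = cosine_cluster(sigs, genes=genes)
        merges = average_linkage_trace(tree.distance_matrix)
        # reconstruct member sets from the scipy linkage and compare
        members = {i: [i] for i in range(4)}
        for row_i, (a, b, h, _n) in enumerate(tree.linkage):
            a, b = int(a), int(b)
            got = tuple(sorted([sorted(members[a]), sorted(members[b])]))
            exp_a, exp_b, exp_h = merges[row_i]
            assert got == tuple(sorted([exp_a, exp_b]))
            assert h == pytest.approx(exp_h, abs=1e-10)
            members[4 + row_i] = members[a] + members[b]

    def test_zero_norm_errors_with_name(self):
        sigs = self._sigs([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(SignatureError, match="m0"):
            cosine_cluster(sigs, genes=["g0", "g1"])

    def test_newick_contains_all_labels(self):
        sigs = self._sigs([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        tree = cosine_cluster(sigs, genes=["g0", "g1", "g2"])
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for lbl in ("m0", "m1", "m2"):
            assert lbl in nwk


def brute_force_hypergeom(N, K, n, k):
    """P[X >= k] by direct combinatorial counting."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometricEnrichment:
    def test_category_equals_universe_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        hits = {f"g{i}" for i in range(4)}
        assert hypergeometric_enrichment(hits, universe, universe) == pytest.approx(1.0)

    def test_direct_combinatorial_value(self):
        universe = {f"g{i}" for i in range(10)}
        category = {f"g{i}" for i in range(5)}
        hits = {f"g{i}" for i in range(4)}  # all hits in the category
        p = hypergeometric_enrichment(hits, category, universe)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(40):
            N = int(rng.integers(2, 21))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            universe = {f"g{i}" for i in range(N)}
            category = set(rng.choice(sorted(universe), size=K, replace=False))
            hits = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(hits & category)
            p = hypergeometric_enrichment(hits, category, universe)
            assert p == pytest.approx(brute_force_hypergeom(N, K, n, k), abs=1e-12)

    def test_monotone_in_overlap(self):
        N, K, n = 50, 12, 10
        universe = {f"g{i}" for i in range(N)}
        category = {f"g{i}" for i in range(K)}
        ps = []
        for k in range(0, n + 1):
            hits = {f"g{i}" for i in range(k)} | {
                f"g{K + i}" for i in range(n - k)
            }
            ps.append(hypergeometric_enrichment(hits, category, universe))
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_empty_universe_errors(self):
        with pytest.raises(SignatureError):
            hypergeometric_enrichment(set(), set(), set())


class TestProfileCorrelation:
    def _sig(self, name, values):
        return MutantSignature(
            name, pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        )

    def test_proportional_and_antiproportional(self):
        a = self._sig("a", [1.0, 2.0, 3.0, -1.0])
        assert profile_correlation(a, self._sig("b", [2.0, 4.0, 6.0, -2.0]))[0] == pytest.approx(1.0)
        assert profile_correlation(a, self._sig("c", [-1.0, -2.0, -3.0, 1.0]))[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, n = profile_correlation(self._sig("a", x), self._sig("b", y))
        assert n == 50
        exp = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(exp, abs=1e-12)

    def test_too_few_shared_genes_errors(self):
        with pytest.raises(SignatureError):
            profile_correlation(self._sig("a", [1.0, 2.0]), self._sig("b", [1.0, 2.0]))

    def test_zero_variance_errors(self):
        a = self._sig("a", [1.0, 1.0, 1.0])
        b = self._sig("b", [1.0, 2.0, 3.0])
        with pytest.raises(SignatureError):
            profile_correlation(a, b)


class TestProxyGenes:
    def test_mapped_within_bound(self):
        sno = Feature("snR1", "chrI", 900, 1000, "+", "snoRNA")
        orf = Feature("ORF1", "chrI", 1500, 2200, "+", "ORF")
        ann = GenomeAnnotation([sno, orf])
        assert readthrough_proxy_genes(ann) == {"snR1": ("ORF1", 500)}

    def test_beyond_bound_is_none(self):
        sno = Feature("snR1", "chrI", 900, 1000, "+", "snoRNA")
        orf = Feature("ORF1", "chrI", 3500, 4200, "+", "ORF")
        ann = GenomeAnnotation([sno, orf])
        assert readthrough_proxy_genes(ann) == {"snR1": None}

    def test_matches_exhaustive_pair_scan(self, rng):
        for _ in range(15):
            ann = random_annotation(rng, 15, chrom_length=8000)
            # recast half as snoRNAs, half as ORFs
            feats = [
                Feature(
                    f.id, f.chrom, f.start, f.end, f.strand,
                    "snoRNA" if i % 2 else "ORF",
                )
                for i, f in enumerate(ann.features)
            ]
            ann2 = GenomeAnnotation(feats, ann.chrom_lengths)
            got = readthrough_proxy_genes(ann2, max_distance=2000)
            for sno in ann2.by_class("snoRNA"):
                anchor = sno.end if sno.strand == "+" else sno.start
                best = None
                for g in ann2.by_class("ORF"):
                    if g.chrom != sno.chrom or g.strand != sno.strand:
                        continue
                    d = (g.start - anchor) if sno.strand == "+" else (anchor - g.end)
                    if 0 <= d <= 2000 and (best is None or d < best[1]):
                        best = (g.id, d)
                assert got[sno.id] == best


def test_shared_signature_genes_direction():
    genes = ["g0", "g1", "g2"]
    a = MutantSignature(
        "a", pd.Series([1.0, 1.0, -1.0], index=genes),
        significant=pd.Series([True, True, True], index=genes),
    )
    b = MutantSignature(
        "b", pd.Series([1.0, -1.0, -1.0], index=genes),
        significant=pd.Series([True, True, False], index=genes),
    )
    assert shared_signature_genes([a, b], ["a", "b"]) == {"g0"}
    assert shared_signature_genes([a, b], ["a", "b"], same_direction=False) == {
        "g0", "g1",
    }
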