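"""Expression-signature comparison across mutants.

Each mutant's signature is its per-gene log2 fold-change M: the mean over
replicate profiles minus the mean over the pooled wildtype samples, all
measured against a common reference. Signatures are filtered (p < 0.05 and
fold change > 1.7, i.e. |M| > log2 1.7), compared by cosine-correlation
hierarchical clustering, and gene-set overlaps are scored with the upper-tail
hypergeometric test.

The per-gene p-value here is a two-sided t-test of the mutant replicates
against the wildtype pool — by default the pooled-variance Student test,
which is exactly calibrated when both groups share an error variance (the
situation a common-reference two-channel design aims for); Welch's unequal-
variance form is available but runs liberal with very few mutant replicates.
Either way this is a deliberate, documented stand-in for a large-reference-
pool error model, not a reimplementation of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .annotation import Feature, GenomeAnnotation, three_prime_end

WT_GROUP = "wt"


class SignatureError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 ratios vs a common reference.

    ``groups`` maps each sample to its group label: a mutant name, or
    ``"wt"`` for members of the wildtype pool.
    """

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise SignatureError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise SignatureError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise SignatureError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def mutants(self) -> List[str]:
        return sorted(g for g in self.groups.unique() if g != WT_GROUP)

    def samples_of(self, group: str) -> List[str]:
        return list(self.groups.index[self.groups == group])


def read_expression_matrix(matrix_path: str, samples_path: str) -> ExpressionMatrix:
    """Read a gene x sample TSV and its sample-metadata sidecar.

    The sidecar has columns ``sample`` and ``group`` (plus anything else,
    ignored); group ``wt`` marks the wildtype pool.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(samples_path, sep="\t", comment="#")
    if "sample" not in meta.columns or "group" not in meta.columns:
        raise SignatureError(f"{samples_path}: need 'sample' and 'group' columns")
    groups = meta.set_index("sample")["group"]
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_matrix(
    mat: ExpressionMatrix, matrix_path: str, samples_path: str
) -> None:
    mat.values.to_csv(matrix_path, sep="\t", float_format="%.6f")
    pd.DataFrame(
        {"sample": mat.groups.index, "group": mat.groups.values}
    ).to_csv(samples_path, sep="\t", index=False)


@dataclass
class MutantSignature:
    mutant: str
    M: pd.Series  # per-gene log2 fold-change vs wt pool
    p: Optional[pd.Series] = None
    significant: Optional[pd.Series] = None  # boolean, set by significance_filter


def fold_changes(
    mat: ExpressionMatrix,
    mutant: str,
    with_pvalues: bool = True,
    test: str = "student",
) -> MutantSignature:
    """Signature of one mutant: mean over replicates minus mean over wt pool.

    With ``with_pvalues`` a two-sided t-test per gene is attached (mutant
    replicates vs wt pool): ``test="student"`` pools the variance (exact
    under a shared error variance), ``test="welch"`` does not. With a single
    mutant replicate the test degenerates to a one-sample t of the wt pool
    against that value.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    mut_cols = mat.samples_of(mutant)
    wt_cols = mat.samples_of(WT_GROUP)
    if not mut_cols:
        raise SignatureError(f"unknown mutant {mutant!r}")
    if not wt_cols:
        raise SignatureError("expression matrix has no wildtype pool")
    mut = mat.values[mut_cols].to_numpy(dtype=float)
    wt = mat.values[wt_cols].to_numpy(dtype=float)
    M = pd.Series(mut.mean(axis=1) - wt.mean(axis=1), index=mat.genes, name=mutant)
    p = None
    if with_pvalues:
        if len(mut_cols) >= 2:
            pvals = stats.ttest_ind(
                mut, wt, axis=1, equal_var=(test == "student")
            ).pvalue
        else:
            pvals = stats.ttest_1samp(wt, popmean=mut[:, 0], axis=1).pvalue
        p = pd.Series(pvals, index=mat.genes, name=mutant)
    return MutantSignature(mutant=mutant, M=M, p=p)


def significance_filter(
    sig: MutantSignature, p_cut: float = 0.05, fc_cut: float = 1.7
) -> pd.Index:
    """Genes with p < p_cut and |M| > log2(fc_cut); direction kept in M.

    Sets ``sig.significant`` and returns the kept gene index.
    """
    if sig.p is None:
        raise SignatureError(f"signature {sig.mutant!r} has no p-values")
    keep = (sig.p < p_cut) & (sig.M.abs() > math.log2(fc_cut))
    keep &= sig.p.notna()
    sig.significant = keep
    return sig.M.index[keep]


@dataclass
class ClusterTree:
    labels: List[str]
    distance_matrix: np.ndarray  # n x n, 1 - cosine similarity
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: List[int]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        for idx, (a, b, h, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + idx
            la = h - heights[a]
            lb = h - heights[b]
            nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[node] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def signature_matrix(
    signatures: Sequence[MutantSignature], genes: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Stack signatures into a mutants x genes M matrix.

    ``genes`` defaults to the union of significant sets (requires the filter
    to have run); genes a signature does not cover contribute 0.
    """
    if genes is None:
        union: Set[str] = set()
        for s in signatures:
            if s.significant is None:
                raise SignatureError(
                    f"signature {s.mutant!r} unfiltered and no gene list given"
                )
            union |= set(s.M.index[s.significant])
        genes = sorted(union)
    genes = list(genes)
    X = pd.DataFrame(0.0, index=[s.mutant for s in signatures], columns=genes)
    for s in signatures:
        common = s.M.index.intersection(genes)
        X.loc[s.mutant, common] = s.M.loc[common].to_numpy()
    return X


def cosine_cluster(
    signatures: Sequence[MutantSignature],
    genes: Optional[Iterable[str]] = None,
    linkage_method: str = "average",
) -> ClusterTree:
    """Hierarchical clustering of signatures by cosine correlation.

    Distance(a, b) = 1 - cos(a, b) over the chosen gene set (default: union
    of significant genes, missing entries contributing 0), clustered
    agglomeratively (average linkage by default). Deterministic: scipy
    breaks merge ties by cluster index, i.e. input order.
    """
    if len(signatures) < 2:
        raise SignatureError("need at least 2 signatures to cluster")
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    X = signature_matrix(signatures, genes)
    arr = X.to_numpy(dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    for lbl, nrm in zip(X.index, norms):
        if nrm == 0:
            raise SignatureError(
                f"signature {lbl!r} has zero norm over the clustering gene set"
            )
    sim = (arr @ arr.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    return ClusterTree(
        labels=list(X.index),
        distance_matrix=D,
        linkage=Z,
        leaf_order=list(map(int, leaves)),
    )


def hypergeometric_enrichment(
    hit_set: Set[str], category: Set[str], universe: Set[str]
) -> float:
    """Upper-tail hypergeometric p-value for overlap of two gene sets.

    P[X >= k] with X ~ Hypergeom(N = |universe|, K = |category|,
    n = |hit_set|) and k the observed intersection.
    """
    if not universe:
        raise SignatureError("empty universe")
    if not hit_set <= universe or not category <= universe:
        raise SignatureError("hit set and category must be subsets of the universe")
    N, K, n = len(universe), len(category), len(hit_set)
    k = len(hit_set & category)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def profile_correlation(
    sig_a: MutantSignature, sig_b: MutantSignature
) -> Tuple[float, int]:
    """Pearson r of two signatures' M over shared finite genes; (r, n_genes)."""
    shared = sig_a.M.index.intersection(sig_b.M.index)
    a = sig_a.M.loc[shared].to_numpy(dtype=float)
    b = sig_b.M.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise SignatureError("need at least 3 shared genes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise SignatureError("zero variance in one of the signatures")
    return float(stats.pearsonr(a, b).statistic), int(len(a))


def shared_signature_genes(
    signatures: Sequence[MutantSignature],
    members: Sequence[str],
    same_direction: bool = True,
) -> Set[str]:
    """Genes significant in every named mutant (optionally same sign of M).

    Generic extraction of overlap gene sets between mutants, e.g. the genes
    a termination-factor deletion shares with a kinase deletion.
    """
    by_name = {s.mutant: s for s in signatures}
    sets = []
    for m in members:
        s = by_name[m]
        if s.significant is None:
            raise SignatureError(f"signature {m!r} not yet filtered")
        sets.append(set(s.M.index[s.significant]))
    common = set.intersection(*sets) if sets else set()
    if same_direction and common:
        keep = set()
        for g in common:
            signs = {np.sign(by_name[m].M.loc[g]) for m in members}
            if len(signs) == 1:
                keep.add(g)
        common = keep
    return common


def readthrough_proxy_genes(
    ann: GenomeAnnotation, max_distance: int = 2000
) -> Dict[str, Optional[Tuple[str, int]]]:
    """First same-strand ORF within ``max_distance`` bp downstream of each snoRNA.

    Upregulation of this proxy gene in expression data suggests defective
    termination at the snoRNA. Returns snoRNA id -> (ORF id, distance) or
    None when no ORF starts within the window.
    """
    out: Dict[str, Optional[Tuple[str, int]]] = {}
    for sno in ann.by_class("snoRNA"):
        anchor = three_prime_end(sno)
        best: Optional[Tuple[str, int]] = None
        for g in ann.lane(sno.chrom, sno.strand):
            if g.feature_class != "ORF":
                continue
            if sno.strand == "+":
                d = g.start - anchor
            else:
                d = anchor - g.end
            if 0 <= d <= max_distance and (best is None or d < best[1]):
                best = (g.id, d)
        out[sno.id] = best
    return out
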