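"""Phylogenetic signal and phylogenetically informed ordination.

Under Brownian-motion (BM) evolution on a rooted tree with branch lengths,
trait values at the tips are jointly Gaussian with covariance proportional
to C, the tip-by-tip matrix of shared root-to-MRCA path lengths.  This
module builds C from a tree, measures how strongly a trait matrix follows
that structure (Blomberg's K and its multivariate extension, with a
tip-shuffling permutation null), and ordinates traits by phylogenetic PCA —
a PCA of the evolutionary (BM-rate) covariance about the generalized
least-squares (GLS) phylogenetic mean.

K compares the observed ratio of the tip variance about the GLS mean to its
GLS counterpart against the BM expectation of that ratio, so K = 1 is
expected under pure BM, K > 1 indicates more covariance among relatives
than BM predicts, and K near 0 indicates none.  The multivariate statistic
sums squared deviations over descriptors in numerator and denominator
(Adams-style K_mult) and reduces exactly to the univariate K for a single
column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

__all__ = [
    "Phylogeny", "SignalResult", "PhyloPCAResult", "read_newick",
    "phylo_covariance", "blomberg_k", "k_mult", "permutation_test",
    "PhylogeneticPCA", "phylogenetic_pca",
]


class Phylogeny:
    """Rooted tree with branch lengths, wrapping a dendropy tree.

    Tips must be uniquely labelled; labels map to specimen ids.  Polytomies
    and zero-length branches are allowed.  The BM covariance matrix is
    computed lazily and cached.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in tree.leaf_node_iter()]
        if any(lab is None or lab == "" for lab in labels):
            raise ValueError("tree contains unlabeled tips")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        self.tip_labels: list[str] = labels
        self._cov: np.ndarray | None = None

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Parse a Newick string (not a path)."""
        try:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:
            raise ValueError(
                f"invalid Newick (malformed or duplicate tip labels): {exc}"
            ) from exc
        return cls(tree)

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def covariance(self) -> np.ndarray:
        """BM covariance C: C[i, j] = depth of the MRCA of tips i and j.

        Diagonal entries are root-to-tip depths; the root sits at depth 0
        (a root edge length, if present, is ignored).  Raises on negative
        branch lengths.
        """
        if self._cov is not None:
            return self._cov
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        n = self.n_tips
        C = np.zeros((n, n))
        root = self._tree.seed_node
        depth = {root: 0.0}
        leaves_below: dict = {}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                length = 0.0
            if length < 0:
                raise ValueError(f"negative branch length {length}")
            depth[node] = depth[node.parent_node] + length
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                leaves_below[node] = [i]
                C[i, i] = depth[node]
                continue
            groups = [leaves_below.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            C[a, b] = C[b, a] = d
            leaves_below[node] = [i for g in groups for i in g]
        self._cov = C
        return C

    def tip_depths(self) -> np.ndarray:
        return np.diag(self.covariance()).copy()

    def attach_tip(self, label: str, below: str, stem_fraction: float = 0.5,
                   branch_length: float | None = None) -> "Phylogeny":
        """Return a copy with a new tip grafted onto an existing edge.

        The edge above the node identified by ``below`` (a tip label, or the
        MRCA of a ``"lab1|lab2"`` pair) is split at ``stem_fraction`` of its
        length (measured from the parent); the new tip hangs from the split
        with pendant length ``branch_length`` (default: reaching the depth
        of the deepest existing tip).
        """
        if label in self.tip_labels:
            raise ValueError(f"tip label {label!r} already present")
        tree = dendropy.Tree(self._tree)  # deep clone, fresh taxa bindings
        if "|" in below:
            parts = below.split("|")
            taxa = [tree.taxon_namespace.get_taxon(p) for p in parts]
            if any(t is None for t in taxa):
                raise ValueError(f"unknown tip(s) in {below!r}")
            target = tree.mrca(taxa=taxa)
        else:
            taxon = tree.taxon_namespace.get_taxon(below)
            if taxon is None:
                raise ValueError(f"unknown tip {below!r}")
            target = tree.find_node_with_taxon_label(below)
        edge_len = target.edge.length or 0.0
        if not 0.0 <= stem_fraction <= 1.0:
            raise ValueError("stem_fraction must be in [0, 1]")
        # depth of the split point
        depths = {tree.seed_node: 0.0}
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        max_depth = max(depths[leaf] for leaf in tree.leaf_node_iter())
        parent = target.parent_node
        if parent is None:
            # target is the root: attach the new tip directly below it
            attach_node, split_depth = target, 0.0
        else:
            split_depth = depths[parent] + stem_fraction * edge_len
            attach_node = dendropy.Node()
            parent.remove_child(target)
            parent.add_child(attach_node)
            attach_node.edge.length = stem_fraction * edge_len
            attach_node.add_child(target)
            target.edge.length = (1.0 - stem_fraction) * edge_len
        if branch_length is None:
            branch_length = max(max_depth - split_depth, 1e-8)
        new_leaf = dendropy.Node()
        new_leaf.taxon = tree.taxon_namespace.new_taxon(label)
        attach_node.add_child(new_leaf)
        new_leaf.edge.length = branch_length
        return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from a file."""
    return Phylogeny.from_newick_file(path)


def phylo_covariance(tree: Phylogeny) -> np.ndarray:
    """BM covariance matrix of a tree (see :meth:`Phylogeny.covariance`)."""
    return tree.covariance()


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

class _SignalEngine:
    """Factorized quantities of C shared across K evaluations."""

    def __init__(self, C: np.ndarray):
        n = C.shape[0]
        try:
            self._factor = cho_factor(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "phylogenetic covariance matrix is singular; consider "
                "adjusting zero branch lengths") from exc
        ones = np.ones(n)
        self.cinv_ones = cho_solve(self._factor, ones)
        self.denom = float(ones @ self.cinv_ones)  # 1' C^-1 1
        self.n = n
        # BM expectation of the (MSE0 / MSE) ratio
        self.expected_ratio = (np.trace(C) - n / self.denom) / (n - 1)

    def solve(self, x: np.ndarray) -> np.ndarray:
        return cho_solve(self._factor, x)

    def k_stat(self, X: np.ndarray) -> float:
        """K for a (n,) trait or (n, p) trait matrix (K_mult when p > 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float).T).T  # (n, p)
        a = (self.cinv_ones @ X) / self.denom  # GLS mean per column
        R = X - a
        num = float(np.sum(R * R))
        den = float(np.sum(R * self.solve(R)))
        if num == 0.0 or den == 0.0:
            raise ValueError("constant trait: phylogenetic signal undefined")
        return (num / den) / self.expected_ratio


def _as_engine(tree: Phylogeny | np.ndarray) -> _SignalEngine:
    C = tree.covariance() if isinstance(tree, Phylogeny) else np.asarray(tree, float)
    return _SignalEngine(C)


def blomberg_k(trait: np.ndarray, tree: Phylogeny) -> float:
    """Blomberg's K for one trait (one finite value per tip, tree order).

    K = (MSE0 / MSE) / E[MSE0 / MSE], with MSE0 the mean squared deviation
    of tips about the GLS phylogenetic mean, MSE its GLS counterpart under
    C, and the expectation (tr C - n / (1'C^-1 1)) / (n - 1).  Invariant to
    affine transforms of the trait; exactly 1 on a star tree with equal
    branch lengths.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.ndim != 1:
        raise ValueError("blomberg_k expects a single trait vector; use k_mult")
    if not np.all(np.isfinite(trait)):
        raise ValueError("trait contains non-finite values")
    engine = _as_engine(tree)
    if trait.size != engine.n:
        raise ValueError(f"trait length {trait.size} != {engine.n} tips")
    return engine.k_stat(trait)


def k_mult(traits: np.ndarray, tree: Phylogeny) -> float:
    """Multivariate K: squared deviations summed over descriptors.

    Numerator and denominator of the univariate ratio are accumulated over
    all columns about the multivariate GLS mean; identical to
    :func:`blomberg_k` for a single column.
    """
    traits = np.asarray(traits, dtype=float)
    if traits.ndim != 2:
        raise ValueError("k_mult expects a 2D trait matrix")
    if not np.all(np.isfinite(traits)):
        raise ValueError("traits contain non-finite values")
    engine = _as_engine(tree)
    if traits.shape[0] != engine.n:
        raise ValueError(f"{traits.shape[0]} rows for {engine.n} tips")
    return engine.k_stat(traits)


@dataclass
class SignalResult:
    """Observed phylogenetic signal with its permutation null."""

    statistic_name: str
    observed: float
    permutation_values: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def permutation_test(statistic: str, traits: np.ndarray, tree: Phylogeny,
                     n_permutations: int = 9999, seed: int | None = None,
                     ) -> SignalResult:
    """Tip-shuffling permutation test for K or K_mult.

    Trait rows are shuffled across tips with the tree fixed; the statistic
    is recomputed per permutation.  The p-value uses the add-one convention
    p = (1 + #{perm >= observed}) / (1 + n_permutations), so it never
    reaches zero (its resolution at 9999 permutations is 1/10000 = 0.0001).
    """
    if statistic not in ("K", "K_mult"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    if seed is None:
        raise ValueError("a seed is required for a reproducible permutation test")
    traits = np.asarray(traits, dtype=float)
    if statistic == "K" and traits.ndim != 1:
        raise ValueError("statistic 'K' expects a trait vector")
    if statistic == "K_mult" and traits.ndim != 2:
        raise ValueError("statistic 'K_mult' expects a trait matrix")
    engine = _as_engine(tree)
    observed = engine.k_stat(traits)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = engine.k_stat(traits[rng.permutation(engine.n)])
    p = (1.0 + np.count_nonzero(perms >= observed)) / (1.0 + n_permutations)
    return SignalResult(statistic, observed, perms, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# Phylogenetic PCA
# ---------------------------------------------------------------------------

@dataclass
class PhyloPCAResult:
    """Phylogenetic PCA output (GLS mean, BM-rate covariance, ordination)."""

    tip_labels: list[str]
    phylogenetic_mean: np.ndarray
    evolutionary_covariance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray  # components x descriptors
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


class PhylogeneticPCA(BaseEstimator):
    """PCA of the evolutionary covariance about the GLS phylogenetic mean.

    Given traits X (tips x descriptors, rows in the tree's tip order) and
    the BM covariance C of the tree:

    - phylogenetic mean  a = (1'C^-1 1)^-1 1'C^-1 X
    - evolutionary covariance  R = (X - 1a)' C^-1 (X - 1a) / (n - 1)
    - eigen-decompose R; scores = (X - 1a) V.

    Scores for every tip (including a grafted fossil tip) come from this
    single decomposition.  When C is proportional to the identity (a star
    tree with equal branch lengths) the result coincides with ordinary PCA
    up to the shared sign convention.  Component signs follow the same
    convention as :class:`gnathomech.functional.FunctionalPCA`.
    """

    def __init__(self, tree: Phylogeny | None = None):
        self.tree = tree

    def fit(self, X, y=None):
        if self.tree is None:
            raise ValueError("PhylogeneticPCA requires a tree")
        from .functional import fix_component_signs

        X = np.asarray(X, dtype=float)
        C = self.tree.covariance()
        n = C.shape[0]
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError(f"traits must be ({n}, p); rows in tree tip order")
        p = X.shape[1]
        if n <= p:
            warnings.warn(
                f"{n} tips for {p} descriptors: evolutionary covariance is "
                f"poorly constrained", UserWarning, stacklevel=2)
        engine = _SignalEngine(C)
        a = (engine.cinv_ones @ X) / engine.denom
        centered = X - a
        R = centered.T @ engine.solve(centered) / (n - 1)
        evals, evecs = np.linalg.eigh(R)
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]
        evals = np.clip(evals, 0.0, None)
        scores = centered @ evecs
        loadings, scores = fix_component_signs(evecs.T, scores)
        self.phylogenetic_mean_ = a
        self.evolutionary_covariance_ = R
        self.components_ = loadings
        self.eigenvalues_ = evals
        self.variance_explained_ = 100.0 * evals / evals.sum()
        self.scores_ = scores
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("PhylogeneticPCA is not fitted")
        return (np.asarray(X, float) - self.phylogenetic_mean_) @ self.components_.T


def phylogenetic_pca(traits: np.ndarray, tree: Phylogeny) -> PhyloPCAResult:
    """Functional wrapper around :class:`PhylogeneticPCA`."""
    est = PhylogeneticPCA(tree=tree).fit(traits)
    return PhyloPCAResult(
        tip_labels=list(tree.tip_labels),
        phylogenetic_mean=est.phylogenetic_mean_,
        evolutionary_covariance=est.evolutionary_covariance_,
        scores=est.scores_,
        loadings=est.components_,
        eigenvalues=est.eigenvalues_,
        variance_explained=est.variance_explained_,
    )
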