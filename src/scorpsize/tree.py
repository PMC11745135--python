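"""Phylogenetic tree handling and matrix machinery.

Trees are ultrametric, time-calibrated phylogenies (branch lengths in
million years).  This module provides Newick I/O, pruning, the phylogenetic
covariance matrix C (shared root-to-MRCA path lengths, optionally scaled by
Pagel's lambda), cophenetic distances, principal-coordinate eigenvectors used
for phylogenetically informed trait imputation, and the lognormal
calibration-prior optimizer used when node-dating priors must match a fossil
age interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or lacks branch lengths."""


class PhyloTree:
    """A rooted, labelled phylogeny with branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` exposing the operations the
    comparative analyses need.  Tip labels must be unique; branch lengths are
    non-negative and interpreted in time units (My) for ultrametric trees.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise NewickError("tree has unlabelled tips")
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dups}")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'internal node'}"
                )
        self._tips: list[str] = labels
        self._depths: pd.Series | None = None
        self._mrca: pd.DataFrame | None = None

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several DataError types
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # ------------------------------------------------------------- basics

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def branch_lengths(self) -> list[float]:
        return [
            n.edge.length
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        ]

    def depths(self) -> pd.Series:
        """Root-to-tip path lengths, ordered as ``tip_labels``."""
        if self._depths is None:
            self._compute_matrices()
        return self._depths.copy()

    def depth(self) -> float:
        return float(self.depths().max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.depths().to_numpy()
        span = d.max() - d.min()
        return bool(span <= rtol * max(d.max(), np.finfo(float).tiny))

    # ------------------------------------------------------------ surgery

    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to ``keep``; unary nodes are collapsed with
        branch lengths summed, so tip-to-tip path lengths are preserved."""
        keep = list(keep)
        unknown = sorted(set(keep) - set(self._tips))
        if unknown:
            raise KeyError(f"unknown tip labels: {unknown}")
        if set(keep) == set(self._tips):
            return PhyloTree(dendropy.Tree(self._tree))
        clone = dendropy.Tree(self._tree)
        clone.retain_taxa_with_labels(keep)
        return PhyloTree(clone)

    # ----------------------------------------------------------- matrices

    def _compute_matrices(self) -> None:
        """One postorder pass filling tip depths and the MRCA-depth matrix."""
        n = self.n_tips
        index = {lbl: i for i, lbl in enumerate(self._tips)}
        depth = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = node.edge.length or 0.0
            else:
                if node.edge.length < 0:
                    raise ValueError("negative branch length in tree")
                depth[node] = depth[node.parent_node] + node.edge.length

        M = np.zeros((n, n))
        tipsets: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                M[i, i] = depth[node]
                tipsets[node] = [i]
            else:
                groups = [tipsets.pop(c) for c in node.child_nodes()]
                merged: list[int] = []
                for gi, g in enumerate(groups):
                    for h in groups[gi + 1:]:
                        M[np.ix_(g, h)] = depth[node]
                        M[np.ix_(h, g)] = depth[node]
                    merged.extend(g)
                tipsets[node] = merged
        self._depths = pd.Series(np.diag(M), index=self._tips, name="depth")
        self._mrca = pd.DataFrame(M, index=self._tips, columns=self._tips)

    def mrca_depths(self) -> pd.DataFrame:
        if self._mrca is None:
            self._compute_matrices()
        return self._mrca.copy()

    def covariance(self, lam: float = 1.0) -> pd.DataFrame:
        """Phylogenetic covariance C: C[i,i] = tip depth, C[i,j] = lambda x
        depth of MRCA(i, j).  lambda = 1 is the untransformed Brownian
        expectation; lambda = 0 removes all shared history."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
        C = self.mrca_depths().to_numpy().copy()
        diag = np.diag(C).copy()
        C *= lam
        np.fill_diagonal(C, diag)
        return pd.DataFrame(C, index=self._tips, columns=self._tips)

    def cophenetic(self) -> pd.DataFrame:
        """Patristic distances: sum of branch lengths on the path between
        each pair of tips."""
        M = self.mrca_depths().to_numpy()
        d = np.diag(M)
        D = d[:, None] + d[None, :] - 2.0 * M
        np.fill_diagonal(D, 0.0)
        return pd.DataFrame(D, index=self._tips, columns=self._tips)

    def __repr__(self) -> str:  # pragma: no cover
        kind = "ultrametric" if self.is_ultrametric() else "non-ultrametric"
        return f"<PhyloTree {self.n_tips} tips, {kind}, depth {self.depth():.3g}>"


# ------------------------------------------------------- module functions


def read_newick(text_or_path) -> PhyloTree:
    """Parse a Newick string (or read a file path ending in .nwk/.tre/.newick)."""
    s = str(text_or_path)
    if s.rstrip().endswith(";"):
        return PhyloTree.from_newick(s)
    return PhyloTree.read(text_or_path)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)


def prune_tree(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    return tree.prune(keep)


def phylo_covariance(tree: PhyloTree, lam: float = 1.0) -> pd.DataFrame:
    return tree.covariance(lam)


def cophenetic_distances(tree: PhyloTree) -> pd.DataFrame:
    return tree.cophenetic()


# ----------------------------------------------------------------- PCoA


@dataclass(frozen=True)
class EigenvectorSet:
    """Principal-coordinate axis scores for a set of species.

    ``vectors`` holds k columns of PCoA scores (scaled by sqrt(eigenvalue));
    eigenvalues are nonincreasing.  Used as phylogenetic covariates during
    trait imputation.
    """

    vectors: pd.DataFrame          # species x axes
    eigenvalues: np.ndarray        # length k, descending

    @property
    def labels(self) -> list[str]:
        return list(self.vectors.index)

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def pcoa_eigenvectors(d: pd.DataFrame, k: int = 10) -> EigenvectorSet:
    """Classical scaling (PCoA) of a distance matrix.

    Eigendecomposes the double-centred matrix -1/2 J (d o d) J and returns the
    top-k axes scaled by sqrt(eigenvalue).  Axis signs are fixed by making the
    largest-magnitude coordinate on each axis positive, so results are
    reproducible across linear-algebra backends.  Axes with non-positive
    eigenvalues are dropped (with a warning if that truncates the request);
    additive tree distances never produce them.
    """
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    n_pos = int(np.sum(vals > tol))
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            f"returning {n_pos}",
            stacklevel=2,
        )
        k = n_pos
    vals, vecs = vals[:k], vecs[:, :k]
    coords = vecs * np.sqrt(vals)
    # deterministic orientation: largest-|coordinate| entry positive
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{j + 1}" for j in range(k)]
    )
    return EigenvectorSet(vectors=frame, eigenvalues=vals)


def tree_eigenvectors(tree: PhyloTree, k: int = 10) -> EigenvectorSet:
    """PCoA eigenvectors of a tree's cophenetic distance matrix."""
    return pcoa_eigenvectors(tree.cophenetic(), k=k)


# ------------------------------------------------- lognormal calibrations


@dataclass(frozen=True)
class LognormalPrior:
    """Lognormal node-age prior, parameterized by meanlog and sdlog."""

    meanlog: float
    sdlog: float

    def __post_init__(self):
        if not self.sdlog > 0:
            raise ValueError("sdlog must be positive")

    def quantile(self, p: float) -> float:
        return float(
            stats.lognorm.ppf(p, s=self.sdlog, scale=math.exp(self.meanlog))
        )


def lognormal_from_quantiles(
    lo: float,
    hi: float,
    p_lo: float = 0.025,
    p_hi: float = 0.975,
) -> LognormalPrior:
    """Lognormal prior whose (p_lo, p_hi) quantiles equal the ages (lo, hi).

    Since ln(age) is normal, ln(q) = meanlog + sdlog * z(p) and the two
    quantile constraints form a linear system with the closed-form solution
    sdlog = (ln hi - ln lo) / (z(p_hi) - z(p_lo)),
    meanlog = ln lo - sdlog * z(p_lo).
    For the default symmetric probabilities this puts the prior median at
    the geometric mean sqrt(lo * hi).
    """
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if not (0 < p_lo < p_hi < 1):
        raise ValueError(f"need 0 < p_lo < p_hi < 1, got ({p_lo}, {p_hi})")
    z_lo, z_hi = stats.norm.ppf([p_lo, p_hi])
    sdlog = (math.log(hi) - math.log(lo)) / (z_hi - z_lo)
    meanlog = math.log(lo) - sdlog * z_lo
    return LognormalPrior(meanlog=meanlog, sdlog=sdlog)


def calibration_priors(table: pd.DataFrame) -> pd.DataFrame:
    """Batch prior optimization for a calibration table.

    ``table`` has columns node_label, min_age, max_age; returns one optimized
    (meanlog, sdlog) row per node.
    """
    required = {"node_label", "min_age", "max_age"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    rows = []
    for rec in table.itertuples(index=False):
        prior = lognormal_from_quantiles(rec.min_age, rec.max_age)
        rows.append(
            {
                "node_label": rec.node_label,
                "min_age": rec.min_age,
                "max_age": rec.max_age,
                "meanlog": prior.meanlog,
                "sdlog": prior.sdlog,
            }
        )
    return pd.DataFrame(rows)
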