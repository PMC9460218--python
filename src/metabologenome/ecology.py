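"""Beta diversity, ordination and PERMANOVA.

Distances
---------
* **Unweighted UniFrac** — fraction of observed branch length unique to one
  of the two communities: sum of lengths of branches leading only to taxa
  present in exactly one sample, divided by the sum over branches leading
  to taxa present in either. Presence means abundance > 0.
* **Weighted UniFrac** — sum over branches of length x |P_a - P_b|, where
  P is the fraction of a sample's abundance descending through the branch;
  the normalized variant divides by the same sum with |.| replaced by
  (P_a + P_b), bounding the distance by 1.
* **Spearman correlation distance** — 1 - rho over the features that are
  non-missing in both samples (used for metabolome profiles).

Both UniFrac variants are computed from a branch-incidence matrix built
once per tree (rows = branches, columns = taxa, entry = taxon descends
through branch), so whole distance matrices are a few dense matrix
products.

Ordination is classical (Torgerson) MDS: double-center -0.5 * J D^2 J,
take the top-k eigenpairs, coordinates are eigenvectors scaled by the
square roots of the eigenvalues. Negative eigenvalues (non-Euclidean
distances) are reported but never used for coordinates.

PERMANOVA is the one-way permutational MANOVA on a distance matrix:
pseudo-F from between- vs within-group squared-distance sums, with a
p-value from random label permutations, ``p = (1 + #{F_perm >= F_obs}) /
(1 + n_permutations)``. Here the grouping of interest is the subject id,
comparing intra-subject with inter-subject dissimilarity.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import TreeNode

__all__ = [
    "TreeIndex",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "correlation_distance_matrix",
    "classical_mds",
    "permanova",
    "PermanovaResult",
]


class TreeIndex:
    """Branch-incidence view of a rooted phylogeny.

    Parses a newick string (or accepts an skbio ``TreeNode``) and exposes
    ``lengths`` (per-branch lengths, root excluded) and ``incidence``
    (branches x taxa boolean matrix: taxon j descends through branch i).
    """

    def __init__(self, tree: "str | TreeNode"):
        if isinstance(tree, str):
            tree = TreeNode.read(
                io.StringIO(tree), format="newick", convert_underscores=False
            )
        self.tree = tree
        tips = list(tree.tips())
        self.taxa = [t.name for t in tips]
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("tree has duplicate tip names")
        col = {name: j for j, name in enumerate(self.taxa)}
        n_taxa = len(self.taxa)
        lengths, rows = [], []
        # postorder: each node's tip set is the union of its children's
        tipset: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(n_taxa, dtype=bool)
                mask[col[node.name]] = True
            else:
                mask = np.zeros(n_taxa, dtype=bool)
                for child in node.children:
                    mask |= tipset[id(child)]
            tipset[id(node)] = mask
            if node.parent is not None:  # root carries no branch
                lengths.append(float(node.length) if node.length is not None else 0.0)
                rows.append(mask)
        self.lengths = np.asarray(lengths, dtype=float)
        self.incidence = np.vstack(rows)
        self._col = col

    def align(self, vector: "pd.Series | dict") -> np.ndarray:
        """Map a taxon -> value vector onto this tree's taxon order;
        absent taxa become 0, unknown taxa raise by name."""
        if isinstance(vector, dict):
            vector = pd.Series(vector)
        unknown = [t for t in vector.index if t not in self._col]
        if unknown:
            raise KeyError(f"taxa not in tree: {unknown[:5]}")
        out = np.zeros(len(self.taxa), dtype=float)
        for taxon, value in vector.items():
            out[self._col[taxon]] = value
        return out


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def unweighted_unifrac(a, b, tree) -> float:
    """Unweighted UniFrac distance between two presence/abundance vectors
    (taxon-indexed Series/dicts); presence = value > 0."""
    idx = _as_index(tree)
    xa = idx.align(a) > 0
    xb = idx.align(b) > 0
    if not xa.any() or not xb.any():
        raise ValueError("both samples must contain at least one taxon")
    in_a = idx.incidence @ xa > 0
    in_b = idx.incidence @ xb > 0
    observed = float(idx.lengths[in_a | in_b].sum())
    unique = float(idx.lengths[in_a ^ in_b].sum())
    if observed == 0:
        raise ValueError("no observed branch length (zero-length tree)")
    return unique / observed


def weighted_unifrac(a, b, tree, normalized: bool = False) -> float:
    """Weighted UniFrac distance between two abundance vectors.

    Abundances are converted to within-sample fractions, so any positive
    scaling of a sample leaves the distance unchanged.
    """
    idx = _as_index(tree)
    xa = idx.align(a)
    xb = idx.align(b)
    if xa.sum() <= 0 or xb.sum() <= 0:
        raise ValueError("both samples must have positive total abundance")
    pa = idx.incidence @ (xa / xa.sum())
    pb = idx.incidence @ (xb / xb.sum())
    raw = float(idx.lengths @ np.abs(pa - pb))
    if not normalized:
        return raw
    denom = float(idx.lengths @ (pa + pb))
    return raw / denom if denom > 0 else 0.0


def unifrac_matrix(
    table: pd.DataFrame, tree, weighted: bool = False, normalized: bool = False
) -> pd.DataFrame:
    """All-pairs UniFrac distance matrix for a samples x taxa table."""
    idx = _as_index(tree)
    unknown = [t for t in table.columns if t not in idx._col]
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown[:5]}")
    x = np.zeros((table.shape[0], len(idx.taxa)))
    for j, taxon in enumerate(table.columns):
        x[:, idx._col[taxon]] = table.iloc[:, j].to_numpy(dtype=float)
    if weighted:
        totals = x.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("every sample needs positive total abundance")
        p = (x / totals) @ idx.incidence.T  # samples x branches
        lw = idx.lengths
        n = p.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            d[i] = np.abs(p - p[i]) @ lw
        if normalized:
            denom = p @ lw  # per-sample observed length-weighted mass
            d = d / np.add.outer(denom, denom)
            np.fill_diagonal(d, 0.0)
    else:
        present = (x > 0) @ idx.incidence.T > 0  # samples x branches
        lw = idx.lengths
        n = present.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            either = (present | present[i]) @ lw
            unique = (present ^ present[i]) @ lw
            with np.errstate(invalid="ignore", divide="ignore"):
                d[i] = np.where(either > 0, unique / either, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp noise
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def correlation_distance_matrix(
    table: pd.DataFrame, min_shared: int = 3
) -> pd.DataFrame:
    """Spearman correlation distance (1 - rho) between sample profiles.

    rho for each pair is computed over the features non-missing in both
    samples (at least ``min_shared`` required). Pairs where either profile
    is constant over the shared features get NaN (flagged undefined).
    """
    x = table.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    if not np.isnan(x).any():
        ranks = np.apply_along_axis(sps.rankdata, 1, x)
        if np.any(ranks.std(axis=1) == 0):
            raise ValueError("constant sample profile; distance undefined")
        rho = np.corrcoef(ranks)
        d = 1.0 - rho
    else:
        for i in range(n):
            for j in range(i + 1, n):
                ok = np.isfinite(x[i]) & np.isfinite(x[j])
                if ok.sum() < min_shared:
                    d[i, j] = d[j, i] = np.nan
                    continue
                xi, xj = x[i, ok], x[j, ok]
                if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                    d[i, j] = d[j, i] = np.nan
                    continue
                rho = np.corrcoef(sps.rankdata(xi), sps.rankdata(xj))[0, 1]
                d[i, j] = d[j, i] = 1.0 - rho
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def classical_mds(d: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling.

    Returns ``(coordinates, eigenvalues)``: a samples x k coordinate frame
    (columns axis1..axisk) and the full eigenvalue spectrum in decreasing
    order (negative eigenvalues included for inspection; axes with
    non-positive eigenvalues get zero coordinates, with a warning when k
    exceeds the positive rank).
    """
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    if dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    usable = eigval[:k] > max(1e-12 * abs(eigval[0]), 0.0) if n else eigval[:k] > 0
    if usable.sum() < k:
        warnings.warn(
            f"only {int(usable.sum())} positive eigenvalues; remaining axes zero-filled"
        )
    for axis in range(k):
        if usable[axis]:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    frame = pd.DataFrame(
        coords, index=d.index, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return frame, eigval


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA outcome."""

    pseudo_F: float
    p: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_permutations + 1)
        if not (floor <= self.p <= 1.0):
            raise ValueError("permutation p-value outside its attainable range")


def _ss_within(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> float:
    group_sums = np.einsum("ia,ij,ja->a", onehot, d2, onehot)
    return float((group_sums / (2.0 * sizes)).sum())


def permanova(
    d: pd.DataFrame,
    grouping,
    n_permutations: int = 999,
    seed: "int | None" = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a grouping factor.

    ``grouping`` maps sample id -> group (dict/Series) or is a sequence
    aligned with the matrix rows. The permutation scheme shuffles group
    labels across all samples. Requires >= 2 groups with >= 2 samples each;
    fewer than 99 permutations only triggers a warning.
    """
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    if isinstance(grouping, (dict, pd.Series)):
        labels = np.asarray([grouping[s] for s in d.index])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != n:
            raise ValueError("grouping length must match matrix size")
    codes, counts = np.unique(labels, return_counts=True)
    a = codes.size
    if a < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 samples")
    if n_permutations < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value")

    d2 = dm**2
    ss_total = float(d2.sum()) / (2.0 * n)
    code_of = {c: i for i, c in enumerate(codes)}
    onehot = np.zeros((n, a))
    for i, lab in enumerate(labels):
        onehot[i, code_of[lab]] = 1.0
    sizes = counts.astype(float)

    def pseudo_f(h: np.ndarray) -> float:
        ss_w = _ss_within(d2, h, sizes)
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore"):
            return (ss_b / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else np.inf

    f_obs = pseudo_f(onehot)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if pseudo_f(onehot[perm]) >= f_obs:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        seed=-1 if seed is None else int(seed),
        n_samples=n,
        n_groups=a,
    )
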