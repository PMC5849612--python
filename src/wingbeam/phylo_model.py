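"""Chronogram handling and Brownian-motion machinery.

A chronogram is a rooted, time-calibrated phylogenetic tree whose branch
lengths are in millions of years (MY). Under a Brownian-motion (BM) model
of trait evolution, trait variance accrues linearly along branches, so two
tips covary in proportion to the length of root-to-tip path they share.
That shared-path matrix C is the workhorse of every phylogenetically
informed statistic downstream (pPCA, phylogenetic ANCOVA, phylogenetic
signal screening).

Pagel's λ scales the off-diagonal elements of C and measures the strength
of phylogenetic autocorrelation in a trait: λ = 1 is pure BM structure,
λ = 0 is independence of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy import optimize

__all__ = [
    "Chronogram",
    "PhyloCov",
    "read_tree",
    "write_tree",
    "phylo_covariance",
    "lambda_transform",
    "simulate_bm",
    "fit_lambda",
    "place_node_age",
    "LambdaFit",
]


@dataclass(frozen=True)
class Chronogram:
    """Rooted time-calibrated tree (branch lengths in MY) with unique tips."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None and edge.length is None:
                raise ValueError("all branches must carry lengths")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip, MY."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out


@dataclass(frozen=True)
class PhyloCov:
    """BM tip covariance structure: shared root-to-tip path lengths (MY)."""

    C: np.ndarray
    tip_order: tuple[str, ...]
    lam: float = 1.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape[0] != C.shape[1] or C.shape[0] != len(self.tip_order):
            raise ValueError("C must be square and match the tip order")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")
        object.__setattr__(self, "C", C)


def read_tree(newick: str | Path) -> Chronogram:
    """Parse a Newick string or file into a chronogram."""
    src = str(newick)
    try:
        if "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"tip labels must be unique: {exc}") from exc
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return Chronogram(tree)


def write_tree(chronogram: Chronogram) -> str:
    """Serialise a chronogram back to Newick (branch lengths preserved)."""
    return chronogram.tree.as_string(schema="newick", suppress_rooting=True).strip()


def prune_to(tree: Chronogram, labels: "list[str]") -> Chronogram:
    """Subtree induced by the given tip labels (branch lengths preserved)."""
    missing = set(labels) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"labels not in tree: {sorted(missing)}")
    sub = tree.tree.extract_tree_with_taxa_labels(labels)
    sub.is_rooted = True
    return Chronogram(sub)


def phylo_covariance(tree: Chronogram) -> PhyloCov:
    """Shared-path (BM) covariance matrix of the tips, in MY.

    C[i, j] is the root-to-MRCA path length of tips i and j; the diagonal
    holds root-to-tip depths.
    """
    tips = tree.tip_labels
    n = len(tips)
    depths = tree.depths()
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = tips[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            shared = 0.5 * (depths[a] + depths[b] - d)
            C[i, j] = C[j, i] = max(shared, 0.0)
    return PhyloCov(C=C, tip_order=tuple(tips), lam=1.0)


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's λ transform: off-diagonals scaled by λ, diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCov(C=C, tip_order=cov.tip_order, lam=cov.lam * lam)


def simulate_bm(
    tree: Chronogram,
    sigma2: float,
    root_state: float = 0.0,
    n_sims: int = 1,
    seed: int | None = None,
) -> "pd.DataFrame":
    """Simulate unbounded Brownian motion along the tree.

    Each branch adds an independent Gaussian increment of variance
    sigma2 × branch length; tips inherit the cumulative sum from the root.
    Increments are drawn branch-by-branch in deterministic preorder, so a
    given seed always reproduces the same table. Returns a wide table of
    shape (n_sims, n_tips) with tips as columns.
    """
    import pandas as pd

    if not sigma2 >= 0:
        raise ValueError("BM rate sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    values[id(root)] = np.full(n_sims, float(root_state))
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_vals = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        if bl > 0 and sigma2 > 0:
            inc = rng.normal(0.0, np.sqrt(sigma2 * bl), size=n_sims)
        else:
            inc = 0.0
        values[id(node)] = parent_vals + inc
    data = {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.tree.leaf_node_iter()
    }
    return pd.DataFrame(data, columns=tree.tip_labels)


@dataclass(frozen=True)
class LambdaFit:
    """Maximum-likelihood Pagel's λ for one trait."""

    lam: float
    loglik: float
    loglik_lambda0: float
    sigma2: float
    mean: float
    identifiable: bool = True

    @property
    def lr_stat(self) -> float:
        """Likelihood-ratio statistic of λ̂ against λ = 0."""
        return 2.0 * (self.loglik - self.loglik_lambda0)


def cholesky_psd(C: np.ndarray) -> np.ndarray:
    """Cholesky factor with a tiny escalating ridge for near-singular C.

    Shared-path matrices of trees with effectively duplicated tips are
    positive semi-definite only; a ridge of at most 1e-6 of the mean
    diagonal keeps the factorisation usable without changing any result at
    the precision the analyses report.
    """
    scale = float(np.mean(np.diag(C))) or 1.0
    for ridge in (0.0, 1e-12, 1e-9, 1e-6):
        try:
            return np.linalg.cholesky(C + ridge * scale * np.eye(C.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is singular beyond repair")


def _gaussian_phylo_loglik(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of a univariate phylogenetic Gaussian model.

    The ancestral mean is the GLS estimate and the rate is profiled out,
    leaving a function of the covariance structure alone. Returns
    (loglik, mean, sigma2).
    """
    n = y.size
    L = cholesky_psd(C)
    ones = np.ones(n)
    w = np.linalg.solve(L, y)
    v = np.linalg.solve(L, ones)
    mean = float(v @ w / (v @ v))
    r = w - mean * v
    sigma2 = float(r @ r) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, mean, sigma2


def fit_lambda(trait: np.ndarray, tree: Chronogram) -> LambdaFit:
    """Maximum-likelihood Pagel's λ in [0, 1] for one tip-aligned trait.

    Bounded 1-D optimisation over the λ-transformed covariance, seeded by a
    coarse grid so local optima are not mistaken for the maximum. A trait
    with (numerically) zero variance leaves λ unidentifiable and is
    returned flagged.
    """
    y = np.asarray(trait, dtype=float)
    cov = phylo_covariance(tree)
    if y.size != len(cov.tip_order):
        raise ValueError("trait length must match the number of tips")
    if y.size < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    if np.ptp(y) < 1e-12 * max(1.0, abs(np.mean(y))):
        return LambdaFit(
            lam=0.0, loglik=np.nan, loglik_lambda0=np.nan, sigma2=0.0,
            mean=float(np.mean(y)), identifiable=False,
        )

    def neg_ll(lam: float) -> float:
        C = lambda_transform(cov, lam).C
        return -_gaussian_phylo_loglik(y, C)[0]

    grid = np.linspace(0.0, 1.0, 11)
    grid_vals = [neg_ll(g) for g in grid]
    best = int(np.argmin(grid_vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    if -res.fun < -grid_vals[best]:
        lam_hat = float(grid[best])
    ll, mean, sigma2 = _gaussian_phylo_loglik(y, lambda_transform(cov, lam_hat).C)
    ll0 = _gaussian_phylo_loglik(y, lambda_transform(cov, 0.0).C)[0]
    return LambdaFit(
        lam=lam_hat, loglik=ll, loglik_lambda0=ll0, sigma2=sigma2, mean=mean
    )


def place_node_age(
    crownward_age: float,
    rule: str = "+4MY",
    *,
    parent_age: float | None = None,
    explicit_age: float | None = None,
) -> float:
    """Age for an insufficiently resolvable divergence node.

    Rule ``"+4MY"`` places the node a standard 4 MY rootward of its closest
    established crownward node; rule ``"explicit"`` passes a supplied age
    through. Ages must stay younger than the parent node.
    """
    if rule == "+4MY":
        age = crownward_age + 4.0
    elif rule == "explicit":
        if explicit_age is None:
            raise ValueError("explicit rule requires explicit_age")
        age = explicit_age
    else:
        raise ValueError(f"unknown placement rule {rule!r}")
    if parent_age is not None and age >= parent_age:
        raise ValueError(
            f"placed age {age} MY violates ordering against parent at {parent_age} MY"
        )
    return age
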