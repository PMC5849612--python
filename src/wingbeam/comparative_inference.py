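"""Phylogenetically informed multivariate inference of locomotor mode.

The analysis chain takes, per species, four biomechanical parameters of
the wing skeleton — humeral and ulnar relative cortical thickness (CA/TA)
and mass-normalised torsional resistance (J/M) — together with body mass,
locomotor labels under two avian flight-mode schemes, and a time-calibrated
tree. It then asks two questions:

1. *Volancy* — do the parameters separate flying from flightless
   archosaurs?  Phylogenetic PCA (GLS-centred, evolutionary correlation
   matrix) followed by Partitioning Around Medoids on the first three
   component scores, cross-checked by k-means on the raw parameters.
2. *Flight mode* — which flight style do unknown ("mystery") taxa
   resemble?  Pagel's-λ screening decides whether plain linear
   discriminant analysis is adequate; Fisher LDA with Mahalanobis
   classification assigns mystery taxa; one-way MANOVA tests whether
   locomotor groups differ in multivariate mean; a simulation-based
   phylogenetic ANCOVA (Brownian-motion null) tests each parameter's
   association with locomotor class with body mass as covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .phylo_model import (
    Chronogram,
    LambdaFit,
    cholesky_psd,
    fit_lambda,
    lambda_transform,
    phylo_covariance,
)

__all__ = [
    "PARAMETER_COLUMNS",
    "TraitTable",
    "SchemeDefinition",
    "VISCOR_SCHEME",
    "CLOSE_SCHEME",
    "PCAResult",
    "ClusterResult",
    "DiscriminantResult",
    "AncovaResult",
    "SignalScreen",
    "phyl_pca",
    "pam_cluster",
    "kmeans_cluster",
    "volancy_success",
    "phylo_ancova",
    "lda_fit",
    "lda_classify",
    "manova",
    "screen_phylogenetic_signal",
    "analysis_matrix",
]

#: The four biomechanical parameters all multivariate stages consume.
PARAMETER_COLUMNS = ("ca_ta_h", "ca_ta_u", "jm_h", "jm_u")

_REQUIRED_COLUMNS = PARAMETER_COLUMNS + (
    "mass_g",
    "volant",
    "scheme_viscor",
    "scheme_close",
    "is_mystery",
)


@dataclass(frozen=True)
class SchemeDefinition:
    """A locomotor classification scheme: avian flight modes + added groups."""

    name: str
    avian_categories: tuple[str, ...]
    added_categories: tuple[str, ...]
    volant_categories: frozenset[str]

    @property
    def categories(self) -> tuple[str, ...]:
        return self.avian_categories + self.added_categories

    def is_volant(self, category: str) -> bool:
        if category not in self.categories:
            raise KeyError(f"unknown category {category!r} in scheme {self.name}")
        return category in self.volant_categories


_ADDED = (
    "volant_wing_propelled_diving",
    "long_tailed_pterosaurian",
    "short_tailed_pterosaurian",
    "non_volant_wing_propelled_diving",
    "ratite_bipedal",
    "dinosaurian_bipedal",
    "dinosaurian_omnipedal",
    "crocodilian_quadrupedal",
)
_ADDED_VOLANT = (
    "volant_wing_propelled_diving",
    "long_tailed_pterosaurian",
    "short_tailed_pterosaurian",
)

VISCOR_SCHEME = SchemeDefinition(
    name="viscor",
    avian_categories=(
        "short_flight",
        "forward_flapping_bounding",
        "high_frequency_flapping",
        "undulating",
        "gliding_soaring",
    ),
    added_categories=_ADDED,
    volant_categories=frozenset(
        (
            "short_flight",
            "forward_flapping_bounding",
            "high_frequency_flapping",
            "undulating",
            "gliding_soaring",
        )
        + _ADDED_VOLANT
    ),
)

CLOSE_SCHEME = SchemeDefinition(
    name="close",
    avian_categories=(
        "burst",
        "intermittent_bounding",
        "continuous_flapping",
        "flap_gliding",
        "soaring",
    ),
    added_categories=_ADDED,
    volant_categories=frozenset(
        (
            "burst",
            "intermittent_bounding",
            "continuous_flapping",
            "flap_gliding",
            "soaring",
        )
        + _ADDED_VOLANT
    ),
)


@dataclass(frozen=True)
class TraitTable:
    """Per-species biomechanical parameters, mass and locomotor labels.

    ``data`` is indexed by taxon name; rows flagged ``is_mystery`` carry no
    locomotor labels and are excluded from all fitting, to be projected or
    classified afterwards.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        train = self.data.loc[~self.data["is_mystery"]]
        params = train.loc[:, list(PARAMETER_COLUMNS)]
        if params.isna().any().any():
            raise ValueError("training taxa must have complete parameter values")
        if not (self.data["mass_g"].dropna() > 0).all():
            raise ValueError("body masses must be positive")
        if train["scheme_viscor"].isna().any() or train["scheme_close"].isna().any():
            raise ValueError("every training taxon needs labels under both schemes")

    @property
    def training(self) -> pd.DataFrame:
        return self.data.loc[~self.data["is_mystery"]]

    @property
    def mystery(self) -> pd.DataFrame:
        return self.data.loc[self.data["is_mystery"]]

    def aligned_to(self, tree: Chronogram, *, training_only: bool = True) -> pd.DataFrame:
        """Rows reordered to the tree's tip order (every tip must be present)."""
        df = self.training if training_only else self.data
        tips = tree.tip_labels
        mismatch = set(tips) ^ set(df.index)
        if mismatch:
            raise ValueError(f"taxa and tree tips do not match: {sorted(mismatch)}")
        return df.loc[tips]


def analysis_matrix(
    df: pd.DataFrame, *, log_jm: bool = True, standardise: bool = False
) -> pd.DataFrame:
    """The four-parameter matrix the multivariate stages consume.

    J/M spans orders of magnitude across archosaurs, so it enters the
    default pipeline log10-transformed while CA/TA stays raw; optionally
    all columns are z-standardised.
    """
    X = df.loc[:, list(PARAMETER_COLUMNS)].astype(float).copy()
    if log_jm:
        for c in ("jm_h", "jm_u"):
            if (X[c] <= 0).any():
                raise ValueError(f"{c} must be positive for log transform")
            X[c] = np.log10(X[c])
    if standardise:
        X = (X - X.mean()) / X.std(ddof=1)
    return X


# ---------------------------------------------------------------------------
# Phylogenetic PCA


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # taxa × components
    loadings: pd.DataFrame  # variables × components
    eigenvalues: np.ndarray
    gls_root_mean: pd.Series  # GLS ancestral mean per variable


def phyl_pca(
    traits: pd.DataFrame, tree: Chronogram, mode: str = "cor"
) -> PCAResult:
    """Phylogenetic PCA under Brownian motion (GLS mean, evolutionary matrix).

    The ancestral mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X replaces the sample mean and
    the evolutionary covariance (X−1a)ᵀC⁻¹(X−1a)/(n−1) replaces the sample
    covariance; ``mode="cor"`` converts it to a correlation matrix before
    the eigendecomposition. On a star tree this reduces to ordinary PCA.
    """
    if mode not in ("cor", "cov"):
        raise ValueError("mode must be 'cor' or 'cov'")
    cov = phylo_covariance(tree)
    X = traits.loc[list(cov.tip_order)].astype(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more taxa than variables")
    C = cov.C
    L = cholesky_psd(C)
    Xw = np.linalg.solve(L, X.to_numpy())
    ones_w = np.linalg.solve(L, np.ones(n))
    a = (ones_w @ Xw) / (ones_w @ ones_w)  # GLS ancestral mean, per variable
    Aw = Xw - np.outer(ones_w, a)
    V = (Aw.T @ Aw) / (n - 1)  # evolutionary covariance
    A = X.to_numpy() - a
    if mode == "cor":
        sd = np.sqrt(np.diag(V))
        A = A / sd
        V = V / np.outer(sd, sd)
    evals, evecs = np.linalg.eigh(V)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = A @ evecs
    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = V @ evecs @ np.diag(
            np.where(evals > 1e-12, 1.0 / np.sqrt(np.clip(evals, 1e-300, None)), 0.0)
        )
    comp_names = [f"PC{k + 1}" for k in range(p)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        eigenvalues=evals,
        gls_root_mean=pd.Series(a, index=X.columns),
    )


# ---------------------------------------------------------------------------
# Clustering


@dataclass(frozen=True)
class ClusterResult:
    assignments: pd.Series  # taxon → cluster id
    medoids: tuple[str, ...] | None  # medoid taxa (PAM) or None (k-means)
    centroids: np.ndarray | None
    cost: float  # total within-cluster dissimilarity (PAM) or inertia
    k: int


def _pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam_cluster(points: pd.DataFrame | np.ndarray, k: int) -> ClusterResult:
    """Partitioning Around Medoids (BUILD + SWAP), Euclidean dissimilarity.

    When the medoid search space is small (at most 10⁴ candidate sets,
    which covers two-cluster volancy partitions of any realistic taxon
    sample) the exact optimum is found by enumeration; larger problems use
    the classic BUILD + SWAP heuristic: greedy seeding, then exchanging a
    medoid for a non-medoid while the total dissimilarity to the nearest
    medoid strictly decreases, best improving swap each pass (first index
    on ties). Both paths are deterministic.
    """
    import math as _math

    X = points.to_numpy() if isinstance(points, pd.DataFrame) else np.asarray(points)
    index = (
        list(points.index)
        if isinstance(points, pd.DataFrame)
        else list(range(len(X)))
    )
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))

    if _math.comb(n, k) <= 10_000:
        best_cost, best_set = np.inf, None
        for combo in itertools.combinations(range(n), k):
            c = _pam_cost(D, list(combo))
            if c < best_cost - 1e-12:
                best_cost, best_set = c, combo
        medoids = sorted(best_set)
        assign = np.argmin(D[:, medoids], axis=1)
        return ClusterResult(
            assignments=pd.Series(assign, index=index),
            medoids=tuple(index[m] for m in medoids),
            centroids=None,
            cost=best_cost,
            k=k,
        )

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(current - D[:, j], 0.0).sum() if j not in medoids else -1.0
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))

    # SWAP
    cost = _pam_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = cost - _pam_cost(D, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost = _pam_cost(D, medoids)
            improved = True

    medoids = sorted(medoids)
    assign = np.argmin(D[:, medoids], axis=1)
    return ClusterResult(
        assignments=pd.Series(assign, index=index),
        medoids=tuple(index[m] for m in medoids),
        centroids=None,
        cost=_pam_cost(D, medoids),
        k=k,
    )


def kmeans_cluster(
    points: pd.DataFrame | np.ndarray, k: int, seed: int | None = None, n_init: int = 25
) -> ClusterResult:
    """Lloyd k-means with multiple restarts, lowest inertia kept."""
    from sklearn.cluster import KMeans

    X = points.to_numpy() if isinstance(points, pd.DataFrame) else np.asarray(points)
    index = (
        list(points.index)
        if isinstance(points, pd.DataFrame)
        else list(range(len(X)))
    )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterResult(
        assignments=pd.Series(km.labels_, index=index),
        medoids=None,
        centroids=km.cluster_centers_,
        cost=float(km.inertia_),
        k=k,
    )


def volancy_success(
    assignments: pd.Series, volant_labels: pd.Series
) -> tuple[float, list[str], dict[int, bool]]:
    """Score a two-cluster partition against known volancy.

    Clusters are mapped to volant/non-volant by majority vote among
    labelled (training) taxa; returns the percent of training taxa whose
    mapped cluster matches their label, the misclassified taxa, and the
    cluster→volant mapping. Taxa missing from ``volant_labels`` (mystery
    taxa) are excluded from the rate.
    """
    labelled = [t for t in assignments.index if t in volant_labels.index]
    a = assignments.loc[labelled]
    v = volant_labels.loc[labelled].astype(bool)
    mapping: dict[int, bool] = {}
    for cid in sorted(a.unique()):
        members = v[a == cid]
        frac = members.mean()
        if np.isclose(frac, 0.5):
            raise ValueError(f"volancy mapping tie in cluster {cid}")
        mapping[int(cid)] = bool(frac > 0.5)
    predicted = a.map(mapping)
    correct = predicted == v
    misclassified = sorted(v.index[~correct])
    return 100.0 * float(correct.mean()), misclassified, mapping


# ---------------------------------------------------------------------------
# Simulation-based phylogenetic ANCOVA


@dataclass(frozen=True)
class AncovaResult:
    f_observed: float
    null_f: np.ndarray
    p_value: float
    n_sims: int
    seed: int | None
    df_group: int
    df_resid: int


def _group_f_stats(
    Y: np.ndarray, group: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, int, int]:
    """F statistic for the group effect in y ~ covariate + group, vectorised.

    ``Y`` may hold many response vectors as columns; the fixed design is
    shared, so the residual-maker matrices are built once.
    """
    n = Y.shape[0]
    cats, codes = np.unique(group, return_inverse=True)
    G = np.zeros((n, len(cats)))
    G[np.arange(n), codes] = 1.0
    X_full = np.column_stack([np.ones(n), covariate, G[:, 1:]])
    X_red = np.column_stack([np.ones(n), covariate])

    def rss(X: np.ndarray) -> np.ndarray:
        Q, _ = np.linalg.qr(X)
        R = Y - Q @ (Q.T @ Y)
        return np.sum(R * R, axis=0)

    df1 = len(cats) - 1
    df2 = n - X_full.shape[1]
    rss_full = rss(X_full)
    rss_red = rss(X_red)
    F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return F, df1, df2


def phylo_ancova(
    y: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray,
    tree: Chronogram,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> AncovaResult:
    """Phylogenetic ANCOVA by Brownian-motion simulation.

    The observed F for the locomotor-group effect (response ~ covariate +
    group) is referred to a null distribution obtained by re-simulating the
    response under Brownian motion along the tree — rate and root state
    estimated from the data by GLS (equivalent to the independent-contrasts
    estimator) — with groups and covariate held fixed. The empirical
    p-value uses the (1 + exceedances)/(1 + n_sims) estimator so it can
    never be exactly zero. Inputs must be aligned to the tree's tip order.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate, dtype=float)
    n = y.size
    cats, counts = np.unique(group, return_counts=True)
    if len(cats) < 2:
        raise ValueError("need at least two locomotor groups")
    if (counts < 2).any():
        small = cats[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    if n_sims < 100:
        raise ValueError("need at least 100 simulations")

    cov = phylo_covariance(tree)
    if len(cov.tip_order) != n:
        raise ValueError("response length must match the number of tips")
    C = cov.C
    L = cholesky_psd(C)
    yw = np.linalg.solve(L, y)
    ow = np.linalg.solve(L, np.ones(n))
    mean = float(ow @ yw / (ow @ ow))
    r = yw - mean * ow
    sigma2 = float(r @ r) / (n - 1)

    f_obs, df1, df2 = _group_f_stats(y[:, None], group, covariate)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, n_sims))
    Y_null = mean + np.sqrt(sigma2) * (L @ Z)
    f_null, _, _ = _group_f_stats(Y_null, group, covariate)
    p = (1.0 + float(np.sum(f_null >= f_obs[0]))) / (1.0 + n_sims)
    return AncovaResult(
        f_observed=float(f_obs[0]),
        null_f=f_null,
        p_value=p,
        n_sims=n_sims,
        seed=seed,
        df_group=df1,
        df_resid=df2,
    )


# ---------------------------------------------------------------------------
# Linear discriminant analysis


@dataclass(frozen=True)
class DiscriminantResult:
    groups: tuple[str, ...]
    group_means: pd.DataFrame  # groups × variables
    axes: pd.DataFrame  # variables × discriminant axes
    eigenvalues: np.ndarray
    training_scores: pd.DataFrame
    confusion: pd.DataFrame  # true group × predicted group
    percent_correct: float
    pooled_cov: np.ndarray
    variables: tuple[str, ...]


def lda_fit(traits: pd.DataFrame, groups: pd.Series) -> DiscriminantResult:
    """Fisher linear discriminant analysis with Mahalanobis classification.

    Axes are eigenvectors of W⁻¹B (pooled within-group vs between-group
    scatter); training taxa are classified to the group mean nearest in the
    pooled-covariance Mahalanobis metric with equal priors, and the
    resubstitution confusion matrix and percent-correct are reported.
    """
    X = traits.astype(float)
    g = groups.loc[X.index]
    cats = tuple(sorted(g.unique()))
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    n, p = X.shape
    means = X.groupby(g).mean().loc[list(cats)]
    counts = g.value_counts().loc[list(cats)]
    # singleton groups (e.g. a locomotor mode represented by one fossil)
    # contribute a mean but no within-group scatter
    if int((counts >= 2).sum()) < 2:
        raise ValueError("need at least two groups with two or more members")
    if n - len(cats) < p:
        raise ValueError("too few taxa to estimate the pooled covariance")

    Xc = X.to_numpy()
    W = np.zeros((p, p))
    for cat in cats:
        block = Xc[(g == cat).to_numpy()] - means.loc[cat].to_numpy()
        W += block.T @ block
    W /= n - len(cats)  # pooled within-group covariance
    grand = X.mean().to_numpy()
    B = np.zeros((p, p))
    for cat in cats:
        d = means.loc[cat].to_numpy() - grand
        B += counts[cat] * np.outer(d, d)
    B /= n - 1

    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled within-group covariance; consider dropping a variable"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(len(cats) - 1, p)
    evals, evecs = evals[order][:n_axes], evecs[:, order][:, :n_axes]
    for k in range(n_axes):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]

    axis_names = [f"DA{k + 1}" for k in range(n_axes)]
    scores = (Xc - grand) @ evecs

    Winv = np.linalg.inv(W)
    M = means.to_numpy()
    pred_idx = _mahalanobis_assign(Xc, M, Winv)[0]
    predicted = pd.Series([cats[i] for i in pred_idx], index=X.index)
    confusion = pd.crosstab(g, predicted).reindex(
        index=list(cats), columns=list(cats), fill_value=0
    )
    pct = 100.0 * float((predicted == g).mean())
    return DiscriminantResult(
        groups=cats,
        group_means=means,
        axes=pd.DataFrame(evecs, index=X.columns, columns=axis_names),
        eigenvalues=evals,
        training_scores=pd.DataFrame(scores, index=X.index, columns=axis_names),
        confusion=confusion,
        percent_correct=pct,
        pooled_cov=W,
        variables=tuple(X.columns),
    )


def _mahalanobis_assign(
    X: np.ndarray, means: np.ndarray, Winv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    diffs = X[:, None, :] - means[None, :, :]
    d2 = np.einsum("ngp,pq,ngq->ng", diffs, Winv, diffs)
    return np.argmin(d2, axis=1), d2


def lda_classify(
    model: DiscriminantResult, mystery: pd.DataFrame
) -> pd.DataFrame:
    """Assign mystery taxa to the nearest group in the pooled metric.

    Returns one row per mystery taxon with the assigned group, squared
    Mahalanobis distances to every group, and a tie flag (ties broken by
    group order).
    """
    X = mystery.loc[:, list(model.variables)].astype(float)
    if X.isna().any().any():
        raise ValueError("mystery taxa must have complete parameter values")
    Winv = np.linalg.inv(model.pooled_cov)
    idx, d2 = _mahalanobis_assign(X.to_numpy(), model.group_means.to_numpy(), Winv)
    out = pd.DataFrame(d2, index=X.index, columns=[f"d2_{g}" for g in model.groups])
    out.insert(0, "assigned", [model.groups[i] for i in idx])
    sorted_d2 = np.sort(d2, axis=1)
    out["tie"] = np.isclose(sorted_d2[:, 0], sorted_d2[:, 1])
    return out


# ---------------------------------------------------------------------------
# MANOVA


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_approx: float
    df1: float
    df2: float
    p_value: float
    pairwise: pd.DataFrame  # Hotelling T² contrasts with corrected p


def manova(
    traits: pd.DataFrame, groups: pd.Series, correction: str = "bonferroni"
) -> ManovaResult:
    """One-way MANOVA: Wilks' Λ with Rao's F approximation.

    Pairwise group contrasts use Hotelling's T² with a Bonferroni
    correction by default (``correction="none"`` disables it).
    """
    X = traits.astype(float)
    g = groups.loc[X.index]
    cats = sorted(g.unique())
    n, p = X.shape
    k = len(cats)
    if k < 2:
        raise ValueError("need at least two groups")

    means = X.groupby(g).mean()
    grand = X.mean().to_numpy()
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for cat in cats:
        block = X.to_numpy()[(g == cat).to_numpy()] - means.loc[cat].to_numpy()
        W += block.T @ block
        d = means.loc[cat].to_numpy() - grand
        B += (g == cat).sum() * np.outer(d, d)

    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular within-group scatter")
    lam = float(np.exp(logdet_w - logdet_t))

    m = n - 1 - (p + k) / 2.0
    denom = p * p + (k - 1) ** 2 - 5
    s = np.sqrt((p**2 * (k - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * (k - 1)
    df2 = m * s - df1 / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_approx = (1.0 - lam_s) / lam_s * df2 / df1
    p_value = float(stats.f.sf(f_approx, df1, df2))

    rows = []
    pairs = list(itertools.combinations(cats, 2))
    for a, b in pairs:
        Xa = X.to_numpy()[(g == a).to_numpy()]
        Xb = X.to_numpy()[(g == b).to_numpy()]
        na, nb = len(Xa), len(Xb)
        if na + nb - 2 <= 0 or na + nb - p - 1 <= 0:
            rows.append((a, b, np.nan, np.nan, np.nan))
            continue
        Sp = (
            (Xa - Xa.mean(axis=0)).T @ (Xa - Xa.mean(axis=0))
            + (Xb - Xb.mean(axis=0)).T @ (Xb - Xb.mean(axis=0))
        ) / (na + nb - 2)
        d = Xa.mean(axis=0) - Xb.mean(axis=0)
        df2_pair = na + nb - p - 1
        if df2_pair <= 0 or np.linalg.matrix_rank(Sp) < p:
            rows.append((a, b, np.nan, np.nan, np.nan))
            continue
        t2 = (na * nb / (na + nb)) * float(d @ np.linalg.solve(Sp, d))
        f_pair = t2 * df2_pair / (p * (na + nb - 2))
        p_pair = float(stats.f.sf(f_pair, p, df2_pair))
        rows.append((a, b, t2, f_pair, p_pair))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "T2", "F", "p"])
    if correction == "bonferroni":
        pw["p_corrected"] = np.minimum(pw["p"] * len(pairs), 1.0)
    elif correction == "none":
        pw["p_corrected"] = pw["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return ManovaResult(
        wilks_lambda=lam,
        f_approx=float(f_approx),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        pairwise=pw,
    )


# ---------------------------------------------------------------------------
# Phylogenetic-signal screening


@dataclass(frozen=True)
class SignalScreen:
    lambda_fits: dict[str, LambdaFit]
    p_values: dict[str, float]
    alpha: float
    recommendation: str  # "LDA" | "lambda-transformed DA"


def screen_phylogenetic_signal(
    traits: pd.DataFrame, tree: Chronogram, alpha: float = 0.05
) -> SignalScreen:
    """Decide whether plain LDA is adequate for these traits on this tree.

    Pagel's λ is fitted per variable and tested against λ = 0 by a
    likelihood-ratio test (χ²₁ reference, Bonferroni-corrected across
    variables). If no variable rejects independence, phylogenetic
    autocorrelation is negligible and ordinary LDA is recommended;
    otherwise the data should be pre-whitened by the λ-scaled covariance
    before discriminant analysis.
    """
    fits: dict[str, LambdaFit] = {}
    pvals: dict[str, float] = {}
    per_var_alpha = alpha / traits.shape[1]
    any_signal = False
    for col in traits.columns:
        tips = tree.tip_labels
        fit = fit_lambda(traits.loc[tips, col].to_numpy(), tree)
        fits[col] = fit
        if not fit.identifiable:
            pvals[col] = 1.0
            continue
        pvals[col] = float(stats.chi2.sf(max(fit.lr_stat, 0.0), df=1))
        if pvals[col] < per_var_alpha:
            any_signal = True
    return SignalScreen(
        lambda_fits=fits,
        p_values=pvals,
        alpha=alpha,
        recommendation="lambda-transformed DA" if any_signal else "LDA",
    )


def whiten_by_lambda(
    traits: pd.DataFrame, tree: Chronogram, lam: float
) -> pd.DataFrame:
    """Pre-whiten tip data by the λ-scaled BM covariance (GLS residual space)."""
    cov = lambda_transform(phylo_covariance(tree), lam)
    X = traits.loc[list(cov.tip_order)].astype(float)
    L = cholesky_psd(cov.C)
    Xw = np.linalg.solve(L, X.to_numpy())
    return pd.DataFrame(Xw, index=X.index, columns=X.columns)
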