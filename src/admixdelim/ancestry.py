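"""Ancestry-coefficient estimation and hybrid classification.

Individual ancestry coefficients are estimated by regularized nonnegative
matrix factorization of one-hot-expanded genotypes, the approach behind
sNMF-style clustering: genotypes 0/1/2 become three indicator columns per
site, and the factorization ``X ~ Q G`` is fit by alternating least
squares with a ridge penalty ``alpha`` on ``Q``, projecting ``Q`` rows
onto the probability simplex and each per-site 3-column block of ``G``
onto the simplex after every update. Model choice (``alpha`` and the
number of clusters ``K``) uses masked-genotype cross-entropy: a fraction
of observed entries is hidden from the fit, and the loss is the negative
mean log-probability the fitted model assigns to the hidden genotype
classes. ``K`` is chosen at the elbow of the median cross-entropy curve,
falling back to a boxplot-notch criterion when no elbow forms.

Hybrid classification applies fixed ancestry thresholds: an individual
with more than 20% ancestry from a secondary cluster is called a hybrid;
10-20% is "notable"; maximum ancestry at or below 0.8 marks a highly
admixed genome; and "streaks" are individuals whose minor ancestry
(at least 10% in total) is spread over three or more clusters, each
individually below 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import GenotypeMatrix


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass
class AncestryFitConfig:
    """Settings for one factorization fit (and its replicates)."""

    K: int = 2
    alpha: float = 10.0
    replicates: int = 10
    masking_fraction: float = 0.05
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    #: "kmeans" seeds Q from a k-means partition of the genotypes (robust
    #: against rotated local optima in single fits); "random" uses a flat
    #: Dirichlet, relying on replication for robustness
    init: str = "kmeans"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 < self.masking_fraction < 0.5:
            raise ValueError("masking fraction must lie in (0, 0.5)")


@dataclass
class AncestryProfile:
    """Fitted ancestry coefficients plus diagnostics.

    ``Q`` is specimens x K and row-stochastic; ``G`` is K x sites x 3
    with each (cluster, site) row a probability vector over genotype
    classes 0/1/2.
    """

    Q: pd.DataFrame
    G: np.ndarray
    cross_entropy_train: float
    cross_entropy_val: Optional[float]
    alpha: float
    seed: int
    converged: bool = True
    loss_history: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.Q.shape[1]


@dataclass
class HybridCall:
    specimen: str
    primary_cluster: str
    q_max: float
    secondary: float
    labels: frozenset[str]

    @property
    def is_hybrid(self) -> bool:
        return "hybrid" in self.labels


@dataclass
class HybridThresholds:
    """The fixed classification thresholds."""

    hybrid_secondary: float = 0.20
    notable_low: float = 0.10
    highly_admixed_qmax: float = 0.80
    streak_total: float = 0.10
    streak_each: float = 0.10
    streak_min_clusters: int = 3


# ---------------------------------------------------------------------------
# numerical core


def _project_rows_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    # rows where cond is all False (cannot happen for finite input) fall back
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(v - theta[:, None], 0.0)


def _one_hot(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Expand genotypes to (n, sites, 3) indicators and an observed mask."""
    g = gm.genotypes
    obs = g >= 0
    x = np.zeros((*g.shape, 3), dtype=np.float32)
    for c in range(3):
        x[..., c] = (g == c)
    x[~obs] = 0.0
    return x, obs


def _loss(x3, pred, observed, q, alpha) -> float:
    resid = (x3 - pred) * observed[..., None]
    return float((resid**2).sum() + alpha * (q**2).sum())


def fit_snmf(
    gm: GenotypeMatrix,
    cfg: AncestryFitConfig,
    masked: Optional[np.ndarray] = None,
) -> AncestryProfile:
    """Fit ancestry coefficients for one replicate.

    ``masked`` is an optional boolean (specimens x sites) array of
    held-out validation entries; they are excluded from the training loss
    and scored afterwards by masked cross-entropy. The fit is
    deterministic under ``cfg.seed``. If the loss has not converged at
    ``cfg.max_iter`` the best iterate is returned with
    ``converged=False``.
    """
    if cfg.K > gm.n_specimens:
        raise ValueError("K cannot exceed the number of specimens")
    rng = np.random.default_rng(cfg.seed)
    x3, obs = _one_hot(gm)
    n, p = obs.shape
    train = obs if masked is None else (obs & ~masked)
    trainf = train.astype(np.float32)

    pooled = x3.sum(axis=0) / np.maximum(trainf.sum(axis=0), 1.0)[:, None]
    if cfg.init == "kmeans" and cfg.K > 1:
        q = _kmeans_init(gm, cfg.K, rng)
    elif cfg.init in ("kmeans", "random"):
        q = rng.dirichlet(np.ones(cfg.K), size=n).astype(np.float32)
    else:
        raise ValueError(f"unknown init {cfg.init!r}")
    g = np.clip(
        pooled[None, :, :] + 0.1 * rng.standard_normal((cfg.K, p, 3)), 0.0, None
    ).astype(np.float32)
    g = _project_blocks(g)

    pred = np.einsum("nk,kpc->npc", q, g)
    loss = _loss(x3, pred, train, q, cfg.alpha)
    history = [loss]
    converged = False
    eps = 1e-6

    for _ in range(cfg.max_iter):
        # EM-style fill of unobserved entries with the current prediction,
        # then exact least squares in flattened (3 * sites) space
        xf = np.where(train[..., None], x3, pred).reshape(n, 3 * p)

        # G update
        gram = q.T @ q + eps * np.eye(cfg.K, dtype=np.float32)
        g_new = np.linalg.solve(gram, q.T @ xf).reshape(cfg.K, p, 3)
        g_new = _project_blocks(g_new)
        pred_new = np.einsum("nk,kpc->npc", q, g_new)
        loss_new = _loss(x3, pred_new, train, q, cfg.alpha)
        if loss_new <= loss:
            g, pred, loss = g_new, pred_new, loss_new

        # Q update
        xf = np.where(train[..., None], x3, pred).reshape(n, 3 * p)
        gf = g.reshape(cfg.K, 3 * p)
        gram = gf @ gf.T + cfg.alpha * np.eye(cfg.K, dtype=np.float32)
        q_new = np.linalg.solve(gram, gf @ xf.T).T
        q_new = _project_rows_to_simplex(q_new).astype(np.float32)
        pred_new = np.einsum("nk,kpc->npc", q_new, g)
        loss_new = _loss(x3, pred_new, train, q_new, cfg.alpha)
        if loss_new <= loss:
            q, pred, loss = q_new, pred_new, loss_new

        history.append(loss)
        if abs(history[-2] - loss) <= cfg.tol * max(history[-2], 1e-12):
            converged = True
            break

    profile = AncestryProfile(
        Q=pd.DataFrame(
            np.asarray(q, dtype=float),
            index=gm.specimens,
            columns=[f"q{k + 1}" for k in range(cfg.K)],
        ),
        G=np.asarray(g, dtype=float),
        cross_entropy_train=cross_entropy(None, gm, train, _pred=pred),
        cross_entropy_val=None,
        alpha=cfg.alpha,
        seed=cfg.seed,
        converged=converged,
        loss_history=history,
    )
    if masked is not None and masked.any():
        profile.cross_entropy_val = cross_entropy(profile, gm, masked & obs)
    return profile


def _kmeans_init(gm: GenotypeMatrix, k: int, rng) -> np.ndarray:
    """Soft one-hot Q from a k-means partition of mean-imputed genotypes."""
    from sklearn.cluster import KMeans

    x = gm.genotypes.astype(np.float32)
    miss = gm.missing_mask()
    with np.errstate(invalid="ignore"):
        means = np.where(
            miss.all(axis=0), 0.0,
            np.nanmean(np.where(miss, np.nan, x), axis=0),
        )
    x = np.where(miss, means[None, :], x)
    labels = KMeans(
        n_clusters=k, n_init=4, random_state=int(rng.integers(2**31))
    ).fit_predict(x)
    q = np.full((gm.n_specimens, k), 0.1 / max(k - 1, 1), dtype=np.float32)
    q[np.arange(gm.n_specimens), labels] = 0.9
    # small jitter so replicates explore different basins
    q = q + 0.05 * rng.dirichlet(np.ones(k), size=gm.n_specimens).astype(np.float32)
    return (q / q.sum(axis=1, keepdims=True)).astype(np.float32)


def _project_blocks(g: np.ndarray) -> np.ndarray:
    k, p, _ = g.shape
    return _project_rows_to_simplex(g.reshape(k * p, 3)).reshape(k, p, 3)


def cross_entropy(
    profile: Optional[AncestryProfile],
    gm: GenotypeMatrix,
    masked_entries: np.ndarray,
    _pred: Optional[np.ndarray] = None,
) -> float:
    """Masked-genotype cross-entropy of the fitted model.

    The negative mean log-probability assigned to the observed genotype
    class over the masked entries, with predicted probabilities from
    ``Q G`` clipped to [1e-10, 1]. Perfect prediction gives 0; a uniform
    prediction over the 3 classes gives ln 3.
    """
    masked_entries = np.asarray(masked_entries, dtype=bool)
    if not masked_entries.any():
        raise ValueError("no masked entries to score")
    if _pred is None:
        assert profile is not None
        q = profile.Q.to_numpy()
        pred = np.einsum("nk,kpc->npc", q, profile.G)
    else:
        pred = _pred
    g = gm.genotypes
    rows, cols = np.nonzero(masked_entries & (g >= 0))
    probs = pred[rows, cols, g[rows, cols]]
    probs = np.clip(probs, 1e-10, 1.0)
    return float(-np.mean(np.log(probs)))


# ---------------------------------------------------------------------------
# replicated model choice


def _make_mask(obs: np.ndarray, fraction: float, rng) -> np.ndarray:
    mask = np.zeros_like(obs)
    rows, cols = np.nonzero(obs)
    m = max(1, int(round(fraction * rows.size)))
    pick = rng.choice(rows.size, size=m, replace=False)
    mask[rows[pick], cols[pick]] = True
    return mask


def _replicate_ces(
    gm: GenotypeMatrix, cfg: AncestryFitConfig, rng
) -> list[float]:
    _, obs = _one_hot(gm)
    ces = []
    for _ in range(cfg.replicates):
        mask = _make_mask(obs, cfg.masking_fraction, rng)
        rep_cfg = AncestryFitConfig(
            K=cfg.K,
            alpha=cfg.alpha,
            replicates=1,
            masking_fraction=cfg.masking_fraction,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            seed=int(rng.integers(2**31)),
        )
        profile = fit_snmf(gm, rep_cfg, masked=mask)
        ces.append(profile.cross_entropy_val)
    return ces


ALPHA_GRID = (1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)


def select_alpha(
    gm: GenotypeMatrix,
    K: int,
    grid: tuple[float, ...] = ALPHA_GRID,
    reps: int = 100,
    seed: int = 0,
    base: Optional[AncestryFitConfig] = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the regularization weight minimizing median masked CE.

    Each grid value is fit ``reps`` times with a fresh mask and
    initialization; the winner is the value with the lowest median
    validation cross-entropy, ties broken toward the smallest ``alpha``
    (weakest regularization). The full CE distributions are returned for
    plotting.
    """
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    rng = np.random.default_rng(seed)
    records = {}
    for alpha in grid:
        cfg = AncestryFitConfig(
            K=K,
            alpha=alpha,
            replicates=reps,
            masking_fraction=(base.masking_fraction if base else 0.05),
            max_iter=(base.max_iter if base else 200),
            tol=(base.tol if base else 1e-5),
            seed=seed,
        )
        records[alpha] = _replicate_ces(gm, cfg, rng)
    table = pd.DataFrame(records)
    medians = table.median(axis=0)
    best = medians.min()
    alpha_star = float(min(a for a in grid if medians[a] <= best + 1e-12))
    return alpha_star, table


@dataclass
class KSelection:
    K: int
    method: str  # "elbow", "notch" or "min" (no-elbow fallback)
    no_elbow: bool
    medians: pd.Series
    notch_low: pd.Series
    notch_high: pd.Series
    ce_table: pd.DataFrame


def select_K(
    gm: GenotypeMatrix,
    K_range: range | list[int],
    alpha: float,
    reps: int = 100,
    seed: int = 0,
    base: Optional[AncestryFitConfig] = None,
) -> KSelection:
    """Choose the number of clusters from the median CE curve.

    The primary rule is the elbow: the interior K with the largest
    positive second difference of median cross-entropy, provided the
    curve actually decreases into that K. When no elbow forms, the
    fallback is the boxplot-notch rule — the smallest K whose notch
    interval (median +/- 1.57 IQR / sqrt(reps)) does not overlap that of
    K-1 while K+1's overlaps K's. If neither rule fires, the K with the
    minimum median CE is returned with ``no_elbow`` set.
    """
    ks = sorted(K_range)
    if len(ks) < 2 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K_range must be contiguous with at least 2 values")
    rng = np.random.default_rng(seed)
    table = {}
    for k in ks:
        cfg = AncestryFitConfig(
            K=k,
            alpha=alpha,
            replicates=reps,
            masking_fraction=(base.masking_fraction if base else 0.05),
            max_iter=(base.max_iter if base else 200),
            tol=(base.tol if base else 1e-5),
            seed=seed,
        )
        table[k] = _replicate_ces(gm, cfg, rng)
    ce = pd.DataFrame(table)
    med = ce.median(axis=0)
    iqr = ce.quantile(0.75, axis=0) - ce.quantile(0.25, axis=0)
    half = 1.57 * iqr / np.sqrt(len(ce))
    lo, hi = med - half, med + half

    sel = KSelection(
        K=int(med.idxmin()),
        method="min",
        no_elbow=True,
        medians=med,
        notch_low=lo,
        notch_high=hi,
        ce_table=ce,
    )
    # elbow: largest positive second difference among interior K with a
    # materially significant drop into K (below K-1's notch interval, so
    # noise-level dips do not masquerade as elbows)
    best_d2, best_k = 0.0, None
    for k in ks[1:-1]:
        d2 = med[k - 1] - 2 * med[k] + med[k + 1]
        if med[k] < lo[k - 1] and d2 > best_d2:
            best_d2, best_k = d2, k
    if best_k is not None:
        sel.K, sel.method, sel.no_elbow = int(best_k), "elbow", False
        return sel
    # notch fallback
    for k in ks[1:]:
        improves = hi[k] < lo[k - 1]
        next_overlaps = k + 1 not in med.index or not (hi[k + 1] < lo[k])
        if improves and next_overlaps:
            sel.K, sel.method, sel.no_elbow = int(k), "notch", False
            return sel
    return sel


# ---------------------------------------------------------------------------
# hybrid classification


def match_clusters(
    profile: AncestryProfile, assignments: pd.Series | dict[str, str]
) -> dict[str, str]:
    """Map Q columns to population labels by Hungarian assignment.

    ``assignments`` maps specimen -> a-priori population. Mean ancestry
    per population forms the benefit matrix; the assignment maximizing
    total mean ancestry labels each cluster. Surplus clusters (K larger
    than the number of labelled populations) keep their ``qN`` names.
    """
    if not isinstance(assignments, pd.Series):
        assignments = pd.Series(assignments)
    q = profile.Q
    pops = sorted(assignments.unique())
    means = np.vstack(
        [q.loc[assignments.index[assignments == pop]].mean(axis=0) for pop in pops]
    )
    rows, cols = linear_sum_assignment(-means)
    mapping = {q.columns[c]: pops[r] for r, c in zip(rows, cols)}
    for col in q.columns:
        mapping.setdefault(col, col)
    return mapping


def classify_hybrids(
    profile: AncestryProfile,
    assignments: Optional[pd.Series | dict[str, str]] = None,
    thresholds: HybridThresholds = HybridThresholds(),
) -> list[HybridCall]:
    """Label every specimen from its ancestry row.

    Labels are not mutually exclusive: a row (0.79, 0.21) is both
    ``hybrid`` (secondary > 0.20) and ``highly_admixed`` (q_max <= 0.8).
    A specimen with no flag is ``pure``.
    """
    mapping = (
        match_clusters(profile, assignments) if assignments is not None else None
    )
    if mapping is not None and len(mapping) != profile.K:
        raise ValueError("cluster/assignment mismatch")
    calls = []
    t = thresholds
    for specimen, row in profile.Q.iterrows():
        vals = row.to_numpy(dtype=float)
        order = np.argsort(vals)[::-1]
        q_max = float(vals[order[0]])
        secondary = float(vals[order[1]]) if len(vals) > 1 else 0.0
        labels = set()
        if secondary > t.hybrid_secondary:
            labels.add("hybrid")
        elif t.notable_low < secondary <= t.hybrid_secondary:
            labels.add("notable")
        if q_max <= t.highly_admixed_qmax:
            labels.add("highly_admixed")
        minor = vals[order[1:]]
        spread = minor[(minor > 0) & (minor < t.streak_each)]
        if (
            (1.0 - q_max) >= t.streak_total
            and np.all(minor < t.streak_each)
            and len(spread) >= t.streak_min_clusters
        ):
            labels.add("streak")
        if not labels:
            labels.add("pure")
        cluster = profile.Q.columns[order[0]]
        calls.append(
            HybridCall(
                specimen=str(specimen),
                primary_cluster=mapping[cluster] if mapping else cluster,
                q_max=q_max,
                secondary=secondary,
                labels=frozenset(labels),
            )
        )
    return calls


def hybrid_calls_table(calls: list[HybridCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "specimen": [c.specimen for c in calls],
            "primary_cluster": [c.primary_cluster for c in calls],
            "q_max": [c.q_max for c in calls],
            "secondary": [c.secondary for c in calls],
            "labels": [",".join(sorted(c.labels)) for c in calls],
        }
    )
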