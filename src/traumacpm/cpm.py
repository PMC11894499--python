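"""Connectome-based predictive modeling (CPM).

Edges are screened on training data by their partial Pearson correlation
with the behavioral score, controlling for confounds (age, sex, and — for
follow-up targets — baseline severity).  Edges passing p < alpha are split
by sign; each subject's selected edge strengths are summed into a positive
and a negative feature, and an ordinary least-squares model maps the sums
to the score.  Performance is the Spearman rank correlation between
out-of-fold predictions and observed scores, summarized over repeated
k-fold cross-validation by the median across repeats.

``fit_cpm`` is the straightforward reference implementation of one
training fit.  ``CVEngine``/``run_cv`` evaluate the same model over
repeated k-fold partitions using fold-wise sufficient statistics
(training sums = totals − held-out-fold sums), which is algebraically
identical to refitting per fold but lets the permutation null reuse all
behavior-independent quantities across thousands of shuffles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import stdtr
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

MODEL_VARIANTS = ("combined", "positive", "negative")


@dataclass
class EdgeSelection:
    """Per-edge screening statistics and the signed selection masks."""

    r_partial: np.ndarray
    p: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    alpha: float

    @property
    def n_pos(self) -> int:
        return int(self.pos_mask.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg_mask.sum())


@dataclass
class CPMFit:
    """Linear model on summed selected edge strengths.

    ``coef_pos``/``coef_neg`` are 0 when the corresponding mask is empty;
    with both masks empty the model is intercept-only.
    """

    intercept: float
    coef_pos: float
    coef_neg: float
    selection: EdgeSelection

    def predict(self, edges: np.ndarray) -> np.ndarray:
        pos, neg = summarize_features(edges, self.selection)
        return self.intercept + self.coef_pos * pos + self.coef_neg * neg


@dataclass
class CVRun:
    """One repeated k-fold cross-validation of a CPM."""

    k: int
    repeats: int
    fold_assignments: np.ndarray      # (repeats, n) fold index per subject
    predictions: np.ndarray           # (repeats, n) out-of-fold predictions
    rho_per_repeat: np.ndarray        # (repeats,)
    seed: int
    subject_ids: list[str] | None = None

    @property
    def median_rho(self) -> float:
        return score(self)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def partial_corr_edges(edges: np.ndarray, y: np.ndarray,
                       X: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Partial Pearson correlation of every edge with ``y`` given covariates.

    Both the behavior vector and each edge column are residualized against
    [1, X] and the residuals correlated; p-values are two-tailed from the
    t distribution with n - 2 - c degrees of freedom (c = #covariates).
    With no covariates this reduces to the plain Pearson correlation.

    Parameters
    ----------
    edges : (n, E) subject-by-edge strength matrix.
    y : (n,) behavioral scores.
    X : (n, c) covariate matrix or None.
    """
    edges = np.asarray(edges, float)
    y = np.asarray(y, float)
    n = y.size
    if edges.shape[0] != n:
        raise ValueError("edges and y disagree on the number of subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior vector is constant")
    if X is None or np.size(X) == 0:
        c = 0
        res_y = y - y.mean()
        res_e = edges - edges.mean(axis=0)
    else:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != n:
            raise ValueError("covariate matrix row count does not match y")
        c = X.shape[1]
        D = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(
                "covariate matrix is rank deficient (collinear columns, "
                f"rank {np.linalg.matrix_rank(D)} < {D.shape[1]})")
        rhs = np.column_stack([y[:, None], edges])
        beta, *_ = np.linalg.lstsq(D, rhs, rcond=None)
        res = rhs - D @ beta
        res_y = res[:, 0]
        res_e = res[:, 1:]
        if np.allclose(res_y, 0):
            raise ValueError(
                "behavior vector is collinear with the covariates "
                "(is y duplicated as a covariate column?)")
    if n < c + 4:
        raise ValueError(f"need n >= c + 4 subjects (n={n}, c={c})")
    df = n - 2 - c
    num = res_e.T @ res_y
    den = np.sqrt((res_e ** 2).sum(axis=0)) * np.sqrt((res_y ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stdtr(df, -np.abs(t))
    return r, p


def select_edges(r_partial: np.ndarray, p: np.ndarray,
                 alpha: float = 0.05) -> EdgeSelection:
    """Threshold p < alpha and split selected edges by correlation sign."""
    r_partial = np.asarray(r_partial, float)
    p = np.asarray(p, float)
    if r_partial.shape != p.shape:
        raise ValueError("r and p vectors must have the same length")
    sig = p < alpha
    pos = sig & (r_partial > 0)
    neg = sig & (r_partial < 0)
    return EdgeSelection(r_partial, p, pos, neg, alpha)


def summarize_features(edges: np.ndarray, sel: EdgeSelection
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject sums of selected edge strengths, (pos_sum, neg_sum).

    ``edges`` may be a single edge vector or an (n, E) matrix; an empty
    mask yields 0.
    """
    e = np.atleast_2d(np.asarray(edges, float))
    if e.shape[1] != sel.pos_mask.size:
        raise ValueError("edge vector length does not match selection masks")
    pos = e[:, sel.pos_mask].sum(axis=1)
    neg = e[:, sel.neg_mask].sum(axis=1)
    if np.ndim(edges) == 1:
        return float(pos[0]), float(neg[0])
    return pos, neg


def fit_cpm(train_edges: np.ndarray, train_y: np.ndarray,
            train_X: np.ndarray | None = None, alpha: float = 0.05,
            variant: str = "combined") -> CPMFit:
    """Screen edges and fit the summed-strength linear model on training rows."""
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    r, p = partial_corr_edges(train_edges, train_y, train_X)
    sel = select_edges(r, p, alpha)
    if variant == "positive":
        sel = EdgeSelection(r, p, sel.pos_mask,
                            np.zeros_like(sel.neg_mask), alpha)
    elif variant == "negative":
        sel = EdgeSelection(r, p, np.zeros_like(sel.pos_mask),
                            sel.neg_mask, alpha)
    pos, neg = summarize_features(train_edges, sel)
    cols, used = [np.ones_like(train_y, dtype=float)], []
    if sel.n_pos:
        cols.append(pos)
        used.append("pos")
    if sel.n_neg:
        cols.append(neg)
        used.append("neg")
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, np.asarray(train_y, float), rcond=None)
    coef = dict(zip(used, beta[1:]))
    return CPMFit(float(beta[0]), float(coef.get("pos", 0.0)),
                  float(coef.get("neg", 0.0)), sel)


def _fold_indices(n: int, k: int, seed: int) -> np.ndarray:
    """Fold index per subject: a shuffled partition into k near-equal folds."""
    fold = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(
            KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))):
        fold[test] = f
    return fold


class _DegenerateFold(ValueError):
    pass


class _RepeatCache:
    """Behavior-independent screening statistics for one fold partition."""

    __slots__ = ("fold", "counts", "M", "dd", "de", "coef_e", "rss_e",
                 "r_crit", "n_tr", "df")

    def __init__(self, fold: np.ndarray, k: int, D: np.ndarray,
                 edges: np.ndarray, ee: np.ndarray, totals: dict,
                 alpha: float) -> None:
        n, m = D.shape
        self.fold = fold
        self.counts = np.bincount(fold, minlength=k)
        # fold membership as a one-hot matrix so every fold sum is a matmul
        M = np.zeros((k, n))
        M[fold, np.arange(n)] = 1.0
        self.M = M
        s_dd = np.einsum("kn,na,nb->kab", M, D, D)
        s_de = np.stack([M @ (D[:, a:a + 1] * edges) for a in range(m)],
                        axis=1)                              # (k, m, E)
        s_ee = M @ ee
        self.n_tr = n - self.counts
        self.dd = totals["dd"][None] - s_dd                  # (k, m, m)
        self.de = totals["de"][None] - s_de                  # (k, m, E)
        self.coef_e = np.linalg.solve(self.dd, self.de)
        self.rss_e = np.maximum(
            (totals["ee"][None] - s_ee) - (self.de * self.coef_e).sum(1), 0.0)
        self.df = self.n_tr - 2 - (m - 1)
        # |partial r| > r_crit  <=>  two-tailed t-test p < alpha
        t_crit = stats.t.isf(alpha / 2.0, self.df)
        self.r_crit = t_crit / np.sqrt(self.df + t_crit ** 2)


class CVEngine:
    """Repeated k-fold CPM evaluator reusable across behavior vectors.

    Fold partitions (repeat r from ``seed + r``) and all edge-side
    statistics are computed once; ``run(y)`` then evaluates the full
    selection + prediction pipeline for any behavior vector, which makes
    permutation nulls and per-cluster models cheap.  With ``persistent``
    off, repeat caches are built on the fly and discarded (lower memory
    for one-shot runs).
    """

    def __init__(self, edges: np.ndarray, X: np.ndarray | None = None, *,
                 k: int = 10, repeats: int = 100, alpha: float = 0.05,
                 seed: int = 0, variant: str = "combined",
                 persistent: bool = True) -> None:
        if variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}")
        edges = np.asarray(edges, float)
        n = edges.shape[0]
        if n < 2 * k:
            raise ValueError(f"need at least 2k={2 * k} subjects, got {n}")
        if X is None or np.size(X) == 0:
            D = np.ones((n, 1))
        else:
            X = np.atleast_2d(np.asarray(X, float))
            D = np.column_stack([np.ones(n), X])
            if np.linalg.matrix_rank(D) < D.shape[1]:
                raise ValueError("covariate matrix is rank deficient")
        if n < D.shape[1] + 3:
            raise ValueError("too few subjects for the covariate count")
        self.edges, self.D = edges, D
        self.n, self.m = n, D.shape[1]
        self.k, self.repeats, self.alpha = k, repeats, alpha
        self.seed, self.variant = seed, variant
        self._ee = edges * edges
        self._totals = {"dd": D.T @ D, "de": D.T @ edges,
                        "ee": self._ee.sum(axis=0)}
        self._folds = np.stack([_fold_indices(n, k, seed + r)
                                for r in range(repeats)])
        self._caches: list[_RepeatCache | None] = [None] * repeats
        self._persistent = persistent

    def _cache(self, rep: int) -> _RepeatCache:
        cache = self._caches[rep]
        if cache is None:
            cache = _RepeatCache(self._folds[rep], self.k, self.D,
                                 self.edges, self._ee, self._totals,
                                 self.alpha)
            if self._persistent:
                self._caches[rep] = cache
        return cache

    def _run_repeat(self, cache: _RepeatCache, y: np.ndarray,
                    W: np.ndarray, t_ey: np.ndarray,
                    selection_counts: np.ndarray | None) -> np.ndarray:
        n, k = self.n, self.k
        t_dy = self.D.T @ y
        t_yy = y @ y
        s_ey = cache.M @ W
        s_dy = cache.M @ (self.D * y[:, None])
        s_yy = cache.M @ (y * y)
        dy = t_dy[None] - s_dy                               # (k, m)
        coef_y = np.linalg.solve(cache.dd, dy[:, :, None])[:, :, 0]
        rss_y = (t_yy - s_yy) - (dy * coef_y).sum(1)
        bad = rss_y <= 1e-12 * cache.n_tr
        if bad.any():
            raise _DegenerateFold(
                f"constant behavior in training fold {int(np.argmax(bad))}")
        cross = (t_ey[None] - s_ey) - np.einsum("km,kme->ke", coef_y, cache.de)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cross / np.sqrt(cache.rss_e * rss_y[:, None])
        r = np.nan_to_num(np.clip(r, -1.0, 1.0))
        pos = r > cache.r_crit[:, None]                      # (k, E)
        neg = r < -cache.r_crit[:, None]
        if self.variant == "positive":
            neg[:] = False
        elif self.variant == "negative":
            pos[:] = False
        if selection_counts is not None:
            selection_counts += pos.sum(0)
            selection_counts += neg.sum(0)
        # summed selected strengths for all subjects x folds in two matmuls;
        # an all-zero feature column (empty mask) leaves lstsq predictions
        # identical to dropping it (minimum-norm solution, coefficient 0)
        f_pos = self.edges @ pos.T.astype(float)
        f_neg = self.edges @ neg.T.astype(float)
        preds = np.empty(n)
        ones = np.ones(n)
        for f in range(k):
            test = cache.fold == f
            F = np.column_stack([ones, f_pos[:, f], f_neg[:, f]])
            beta, *_ = np.linalg.lstsq(F[~test], y[~test], rcond=None)
            preds[test] = F[test] @ beta
        return preds

    def run(self, y: np.ndarray,
            selection_counts: np.ndarray | None = None,
            subject_ids: list[str] | None = None) -> CVRun:
        y = np.asarray(y, float)
        if y.shape != (self.n,):
            raise ValueError("behavior vector length does not match edges")
        if np.ptp(y) == 0:
            raise ValueError("behavior vector is constant")
        W = self.edges * y[:, None]
        t_ey = W.sum(axis=0)
        preds = np.full((self.repeats, self.n), np.nan)
        rhos = np.full(self.repeats, np.nan)
        for rep in range(self.repeats):
            try:
                preds[rep] = self._run_repeat(self._cache(rep), y, W, t_ey,
                                              selection_counts)
            except _DegenerateFold as err:
                log.warning("repeat %d aborted: %s", rep, err)
                continue
            rhos[rep] = spearman(preds[rep], y)
        return CVRun(self.k, self.repeats, self._folds.copy(), preds, rhos,
                     self.seed, subject_ids)


def run_cv(edges: np.ndarray, y: np.ndarray, X: np.ndarray | None = None, *,
           k: int = 10, repeats: int = 100, alpha: float = 0.05,
           seed: int = 0, variant: str = "combined",
           subject_ids: list[str] | None = None,
           selection_counts: np.ndarray | None = None) -> CVRun:
    """Repeated k-fold cross-validated CPM.

    Repeat r draws its fold partition from seed + r, so any repeat can be
    re-executed in isolation.  A training fold with constant behavior is a
    degenerate draw: that repeat is skipped with a warning (rho = NaN).

    ``selection_counts`` (length E, int), if given, accumulates how often
    each edge was selected (either sign) across all folds and repeats.
    """
    engine = CVEngine(edges, X, k=k, repeats=repeats, alpha=alpha, seed=seed,
                      variant=variant, persistent=False)
    return engine.run(y, selection_counts=selection_counts,
                      subject_ids=subject_ids)


def score(run: CVRun) -> float:
    """Median Spearman rho across repeats (NaN repeats excluded)."""
    rhos = run.rho_per_repeat[~np.isnan(run.rho_per_repeat)]
    if rhos.size == 0:
        raise ValueError("no valid repeats to summarize")
    return float(np.median(rhos))
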