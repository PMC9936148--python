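"""Two-stage feature selection: a redundancy-penalized lasso (mutcorLasso)
chained with a modified relief-f.

mutcorLasso minimizes

    ||y - X'w||^2 + alpha ||w||_1 + beta w' C w

where C is the elementwise square of R, and R_kl is the cosine similarity
of feature rows k and l plus the absolute mutual information between them.
The quadratic term penalizes giving weight to pairs of mutually redundant
features. The solver is the fixed-point iteration

    w_{t+1} = M_t [M_t B M_t + alpha I]^{-1} M_t X y,   M_t = diag(w_t),
    B = X X' + beta C,

run from a random (0,1) start until the weight change drops below ``tol``
or 1000 iterations. Relief-f then re-weights the surviving features by how
well they separate each sampled trial from its nearest other-class misses
relative to its nearest same-class hits, under an L1 per-feature distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "MutcorModel",
    "ReliefModel",
    "SelectionResult",
    "mutual_information",
    "build_penalty_matrix",
    "mutcorlasso_fit",
    "mutcorlasso_select",
    "relief_f",
    "select_pipeline",
]


@dataclass
class MutcorModel:
    w: np.ndarray
    alpha: float
    beta: float
    iterations_run: int
    objective_trace: np.ndarray
    R: np.ndarray | None = None
    C: np.ndarray | None = None


@dataclass
class ReliefModel:
    w: np.ndarray
    k: int
    iters: int
    sample_rate: float
    selected: list[int] = field(default_factory=list)


@dataclass
class SelectionResult:
    """Outcome of one or both selection stages on a named feature matrix."""

    names: list[str]  # names of the input features
    lasso_scores: np.ndarray  # per input feature, max |w| over class targets
    lasso_selected: list[int]  # indices into the input features
    relief_weights: np.ndarray | None = None  # per lasso-surviving feature
    selected: list[int] = field(default_factory=list)  # final indices into input

    @property
    def selected_names(self) -> list[str]:
        return [self.names[i] for i in self.selected]


def mutual_information(x: np.ndarray, z: np.ndarray, bins: int = 10) -> float:
    """Histogram mutual information (natural log, equal-width bins).

    A constant vector occupies a single bin and yields MI = 0.
    """
    x, z = np.asarray(x, float), np.asarray(z, float)
    if x.shape != z.shape or x.ndim != 1:
        raise ValueError("x and z must be equal-length vectors")
    if x.size < 10:
        raise ValueError("need at least 10 samples for the histogram estimate")
    if x.tobytes() > z.tobytes():  # canonical order: bitwise-exact symmetry
        x, z = z, x
    counts, _, _ = np.histogram2d(x, z, bins=bins)
    p = counts / counts.sum()
    px = p.sum(axis=1, keepdims=True)
    pz = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ pz)[nz])))


def build_penalty_matrix(X: np.ndarray, bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Redundancy matrix R (cosine + |MI|) and its elementwise square C.

    ``X`` is features x samples. Rows with zero norm contribute 0 to the
    cosine part (their direction is undefined).
    """
    X = np.asarray(X, float)
    p = X.shape[0]
    if p < 2:
        raise ValueError("need at least 2 features")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, np.inf)
    cos = (X @ X.T) / np.outer(safe, safe)
    R = np.empty((p, p))
    for k in range(p):
        for l in range(k, p):
            mi = mutual_information(X[k], X[l], bins)
            R[k, l] = R[l, k] = cos[k, l] + abs(mi)
    return R, R * R


def mutcorlasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    beta: float = 0.1,
    C: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    rng: np.random.Generator | int | None = None,
    bins: int = 10,
) -> MutcorModel:
    """Fit the penalized regression by the diagonal fixed-point update.

    ``X`` is features x samples, ``y`` one numeric target per sample.
    ``C`` may be precomputed (it depends on X only); with ``beta=0`` it is
    skipped entirely and the objective reduces to the standard lasso.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    p, n = X.shape
    if y.shape != (n,):
        raise ValueError("y length must equal the number of samples")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rng = np.random.default_rng(rng)
    if beta > 0 and C is None:
        _, C = build_penalty_matrix(X, bins)
    B = X @ X.T
    if beta > 0:
        B = B + beta * C
    Xy = X @ y
    w = rng.uniform(0.0, 1.0, size=p)
    eye = np.eye(p)

    def objective(wv: np.ndarray) -> float:
        r = y - X.T @ wv
        obj = float(r @ r) + alpha * float(np.abs(wv).sum())
        if beta > 0:
            obj += beta * float(wv @ C @ wv)
        return obj

    trace = [objective(w)]
    it = 0
    for it in range(1, max_iter + 1):
        M = w  # diagonal of M_t
        inner = (M[:, None] * B * M[None, :]) + alpha * eye
        try:
            u = np.linalg.solve(inner, M * Xy)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular inner matrix in mutcorLasso update") from exc
        w_new = M * u
        if not np.all(np.isfinite(w_new)):
            raise RuntimeError("mutcorLasso diverged; reduce learning rates alpha/beta")
        delta = np.max(np.abs(w_new - w))
        w = w_new
        trace.append(objective(w))
        if delta < tol:
            break
    return MutcorModel(w, alpha, beta, it, np.asarray(trace), C=C)


def mutcorlasso_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_keep: int = 20,
    alpha: float = 0.5,
    beta: float = 0.1,
    bins: int = 10,
    rng: np.random.Generator | int | None = None,
) -> SelectionResult:
    """Rank features by mutcorLasso weight and keep the strongest ``n_keep``.

    Multi-class labels are handled one-vs-rest: one regression per class on
    a binary 0/1 target, a feature's score being its largest |w| across
    classes. Features with |w| below 1e-8 everywhere are treated as
    eliminated before the top-n cut.
    """
    labels = np.asarray(labels, int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if n_keep > fm.n_features:
        raise ValueError(f"n_keep={n_keep} exceeds {fm.n_features} features")
    rng = np.random.default_rng(rng)
    X = fm.values.T  # features x samples
    C = None
    if beta > 0:
        _, C = build_penalty_matrix(X, bins)
    scores = np.zeros(fm.n_features)
    for c in classes:
        y = (labels == c).astype(float)
        model = mutcorlasso_fit(X, y, alpha=alpha, beta=beta, C=C, rng=rng, bins=bins)
        scores = np.maximum(scores, np.abs(model.w))
    scores = np.where(scores < 1e-8, 0.0, scores)
    order = np.lexsort((np.arange(scores.size), -scores))  # ties -> lower index
    selected = sorted(int(i) for i in order[:n_keep])
    return SelectionResult(list(fm.names), scores, selected)


def relief_f(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 6,
    iters: int = 60,
    sample_rate: float = 0.35,
    rng: np.random.Generator | int | None = None,
    rounds: np.ndarray | None = None,
) -> ReliefModel:
    """Relief-f feature weights on a samples x features matrix in [0, 1].

    A candidate pool of ceil(sample_rate * n) trials is drawn once; each of
    ``iters`` rounds picks a trial R from the pool, finds its k nearest
    same-class hits and, per other class c, k nearest misses under the L1
    distance, and updates each feature weight by
    -sum_H diff/(m k) + sum_c [p(c)/(1-p(class(R)))] sum_{M_c} diff/(m k)
    with diff the absolute per-feature difference and m = iters.

    ``rounds`` fixes the sequence of sampled trial indices explicitly
    (overriding the seeded pool), which makes the weights a deterministic
    function of (X, labels, rounds).
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    n, p = X.shape
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts <= k):
        tight = classes[counts <= k]
        raise ValueError(f"classes {tight.tolist()} have <= k={k} samples")
    rng = np.random.default_rng(rng)
    priors = {int(c): cnt / n for c, cnt in zip(classes, counts)}
    if rounds is None:
        pool = rng.choice(n, size=int(np.ceil(sample_rate * n)), replace=False)
        rounds = rng.choice(pool, size=iters, replace=True)
    elif len(rounds) != iters:
        raise ValueError("rounds must list one sampled index per iteration")
    w = np.zeros(p)
    m = iters
    for r in rounds:
        r = int(r)
        xr = X[r]
        d = np.abs(X - xr).sum(axis=1)
        d[r] = np.inf
        cr = int(labels[r])
        same = np.flatnonzero(labels == cr)
        hits = same[np.argsort(d[same], kind="stable")[:k]]
        w -= np.abs(X[hits] - xr).sum(axis=0) / (m * k)
        for c in classes:
            c = int(c)
            if c == cr:
                continue
            other = np.flatnonzero(labels == c)
            misses = other[np.argsort(d[other], kind="stable")[:k]]
            scale = priors[c] / (1.0 - priors[cr])
            w += scale * np.abs(X[misses] - xr).sum(axis=0) / (m * k)
    return ReliefModel(w, k, iters, sample_rate)


def select_pipeline(
    fm: FeatureMatrix,
    labels: np.ndarray,
    n_keep_lasso: int = 20,
    n_keep_relief: int = 10,
    alpha: float = 0.5,
    beta: float = 0.1,
    relief_k: int = 6,
    relief_iters: int = 60,
    relief_sample_rate: float = 0.35,
    bins: int = 10,
    rng: np.random.Generator | int | None = None,
) -> SelectionResult:
    """mutcorLasso then relief-f: e.g. 120 -> 20 -> 10 features by default."""
    if n_keep_relief > n_keep_lasso:
        raise ValueError("n_keep_relief must not exceed n_keep_lasso")
    rng = np.random.default_rng(rng)
    stage1 = mutcorlasso_select(fm, labels, n_keep_lasso, alpha, beta, bins, rng)
    survivors = fm.subset(stage1.lasso_selected)
    relief = relief_f(
        survivors.values, labels, relief_k, relief_iters, relief_sample_rate, rng
    )
    order = np.lexsort((np.arange(relief.w.size), -relief.w))
    kept_local = sorted(int(i) for i in order[:n_keep_relief])
    relief.selected = kept_local
    final = [stage1.lasso_selected[i] for i in kept_local]
    return SelectionResult(
        list(fm.names), stage1.lasso_scores, stage1.lasso_selected,
        relief_weights=relief.w, selected=final,
    )
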