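"""Multi-class score CSP: pairwise spatial filters, channel scoring and
selection, and CSP trial features.

Common spatial patterns solve, for each unordered class pair, the
generalized eigenproblem of the two class-average covariance matrices after
composite whitening; projections onto the leading/trailing eigenvectors
maximize the between-class variance ratio. Here every channel additionally
receives a score — the L1 mass of its row across all retained unit-norm
filters of all pairs, each filter weighted by its discriminability
(2*lambda - 1)^2 — and the top-scoring channels are kept, which prunes
electrodes before the spectral/network feature stages.

Generalized eigenvectors carry no intrinsic scale (they are whitening-
orthonormal, so filters pointing at high-variance channels come out with
small Euclidean norm); unit-normalizing each filter before scoring makes
the score well-defined, and the (2*lambda - 1)^2 factor zeroes out filters
whose eigenvalue sits at the uninformative 0.5 point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .epochs import EpochSet
from .features import FeatureMatrix

__all__ = ["CspModel", "fit_mscsp", "csp_trial_features"]


@dataclass
class CspModel:
    class_pairs: list[tuple[int, int]]
    filters: dict[tuple[int, int], np.ndarray]  # (n_channels, 2m) per pair
    eigenvalues: dict[tuple[int, int], np.ndarray]
    channel_scores: np.ndarray
    selected_channels: list[int]
    channel_names: list[str]

    @property
    def n_channels(self) -> int:
        return self.channel_scores.size


def _avg_normalized_cov(data: np.ndarray) -> np.ndarray:
    """Class-average spatial covariance; each trial's covariance is
    trace-normalized before averaging so high-power trials do not dominate."""
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_mscsp(
    epochs: EpochSet,
    m_filters_per_pair: int = 2,
    n_channels_keep: int | None = None,
    reg: float = 1e-10,
) -> CspModel:
    """Fit one-vs-one CSP filters for every class pair and score channels.

    ``channel_score(ch)`` sums (2*lambda-1)^2 * |filter weight at ch| over
    all pairs and all retained filters (m leading + m trailing eigenvectors
    per pair, unit-normalized); ``selected_channels`` are the top-scoring
    ``n_channels_keep`` channels.
    """
    classes = epochs.classes
    if classes.size < 2:
        raise ValueError("fit_mscsp needs at least two classes")
    for c in classes:
        if np.sum(epochs.labels == c) < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
    n_ch = epochs.n_channels
    if n_channels_keep is None:
        n_channels_keep = n_ch
    covs = {c: _avg_normalized_cov(epochs.data[epochs.labels == c]) for c in classes}

    pairs = [(int(a), int(b)) for i, a in enumerate(classes) for b in classes[i + 1:]]
    filters: dict[tuple[int, int], np.ndarray] = {}
    eigvals: dict[tuple[int, int], np.ndarray] = {}
    scores = np.zeros(n_ch)
    for a, b in pairs:
        ca, cb = covs[a], covs[b]
        comp = ca + cb + reg * np.eye(n_ch)
        try:
            # generalized symmetric eigenproblem ca w = lambda (ca + cb) w
            w_eig, vecs = linalg.eigh(ca, comp)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "rank-deficient covariance; add trials or increase regularization"
            ) from exc
        if not np.all(np.isfinite(w_eig)):
            raise ValueError(
                "rank-deficient covariance; add trials or increase regularization"
            )
        order = np.argsort(w_eig)[::-1]
        w_eig, vecs = w_eig[order], vecs[:, order]
        m = min(m_filters_per_pair, n_ch // 2) or 1
        keep = np.r_[np.arange(m), np.arange(n_ch - m, n_ch)]
        filters[(a, b)] = vecs[:, keep]
        eigvals[(a, b)] = w_eig[keep]
        unit = vecs[:, keep] / np.linalg.norm(vecs[:, keep], axis=0)
        scores += (np.abs(unit) * (2.0 * w_eig[keep] - 1.0) ** 2).sum(axis=1)

    order = np.argsort(scores)[::-1]
    selected = sorted(int(i) for i in order[:n_channels_keep])
    return CspModel(pairs, filters, eigvals, scores, selected, list(epochs.channel_names))


def csp_trial_features(model: CspModel, epochs: EpochSet) -> FeatureMatrix:
    """Log-variance and mean of each CSP projection, per trial.

    Variance is normalized across the trial's filters of a pair before the
    log (the classic CSP feature); zero variance is floored at machine
    epsilon so the log stays finite. Names encode pair/filter/statistic,
    e.g. ``csp1v2_f0_logvar``.
    """
    if epochs.n_channels != model.n_channels:
        raise ValueError(
            f"channel mismatch: model fitted on {model.n_channels}, got {epochs.n_channels}"
        )
    blocks, names = [], []
    eps = np.finfo(float).eps
    for pair in model.class_pairs:
        W = model.filters[pair]  # (n_ch, 2m)
        proj = np.einsum("cf,tcs->tfs", W, epochs.data)
        var = proj.var(axis=2)
        var_norm = var / np.maximum(var.sum(axis=1, keepdims=True), eps)
        logvar = np.log(np.maximum(var_norm, eps))
        mean = proj.mean(axis=2)
        blocks.append(np.concatenate([logvar, mean], axis=1))
        tag = f"csp{pair[0]}v{pair[1]}"
        names += [f"{tag}_f{i}_logvar" for i in range(W.shape[1])]
        names += [f"{tag}_f{i}_mean" for i in range(W.shape[1])]
    return FeatureMatrix(np.hstack(blocks), names)
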