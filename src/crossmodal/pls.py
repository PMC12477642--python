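"""Two-block partial least squares, canonical mode.

Finds paired unit-norm weight vectors over the channels of two voxel-by-
channel matrices that maximize the covariance of the resulting voxel
scores. Components are extracted by the iterative NIPALS power algorithm,
with both blocks deflated by their own scores after each component
(canonical mode), so successive score vectors within a block are mutually
orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PLSModel", "PLSConvergenceError", "fit_pls", "normalize_scores", "score_correlations"]


class PLSConvergenceError(RuntimeError):
    """NIPALS iteration failed to converge within the iteration budget."""


@dataclass
class PLSModel:
    """Fitted two-block PLS decomposition.

    Attributes
    ----------
    weights_x, weights_y : ndarray, shape (n_components, n_channels)
        Unit-norm channel weights per component.
    scores_x, scores_y : ndarray, shape (n_rows, n_components)
        Latent voxel scores per component.
    column_means_*, column_sds_* : ndarray
        Standardization applied to each block before fitting.
    score_covariances : ndarray, shape (n_components,)
        Sample covariance of the paired scores, in extraction order.
    frobenius_x, frobenius_y : ndarray, shape (n_components + 1,)
        Block Frobenius norms after standardization and after each
        deflation (monotonically decreasing).
    """

    n_components: int
    weights_x: np.ndarray
    weights_y: np.ndarray
    scores_x: np.ndarray
    scores_y: np.ndarray
    column_means_x: np.ndarray
    column_sds_x: np.ndarray
    column_means_y: np.ndarray
    column_sds_y: np.ndarray
    score_covariances: np.ndarray
    frobenius_x: np.ndarray
    frobenius_y: np.ndarray
    scores_normalized: bool = False


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a canonical-mode two-block PLS by NIPALS.

    Parameters
    ----------
    X, Y : ndarray, shape (n_rows, n_channels)
        Paired blocks over the same rows (within-mask voxels). Each block
        needs at least 2 channels and at least as many rows as channels.
    n_components : int
        Number of component pairs to extract.
    tol : float
        Convergence threshold on the change of the X-weight vector.
    max_iter : int
        Iteration budget per component.

    Notes
    -----
    Columns are standardized to mean 0, SD 1 before fitting; the applied
    means/SDs are stored on the model. The sign of each component is fixed
    so its largest-magnitude X weight is positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2D (rows x channels)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("each block needs at least 2 channels")
    if n < max(X.shape[1], Y.shape[1]):
        raise ValueError("need at least as many rows as channels")
    if not 1 <= n_components <= min(X.shape[1], Y.shape[1]):
        raise ValueError("invalid n_components")

    mx, my = X.mean(axis=0), Y.mean(axis=0)
    sx, sy = X.std(axis=0, ddof=1), Y.std(axis=0, ddof=1)
    if np.any(sx == 0) or np.any(sy == 0):
        raise ValueError("rank-deficient block: constant channel column")
    Xd = (X - mx) / sx
    Yd = (Y - my) / sy

    k = n_components
    weights_x = np.empty((k, X.shape[1]))
    weights_y = np.empty((k, Y.shape[1]))
    scores_x = np.empty((n, k))
    scores_y = np.empty((n, k))
    covs = np.empty(k)
    frob_x = [float(np.linalg.norm(Xd))]
    frob_y = [float(np.linalg.norm(Yd))]

    for comp in range(k):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        w_old = np.zeros(X.shape[1])
        for _ in range(max_iter):
            w = Xd.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                raise ValueError("rank-deficient block during extraction")
            w /= w_norm
            t = Xd @ w
            c = Yd.T @ t
            c_norm = np.linalg.norm(c)
            if c_norm == 0:
                raise ValueError("rank-deficient block during extraction")
            c /= c_norm
            u = Yd @ c
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            raise PLSConvergenceError(
                f"component {comp + 1} did not converge in {max_iter} iterations"
            )

        if w[int(np.argmax(np.abs(w)))] < 0:  # deterministic sign
            w, c, t, u = -w, -c, -t, -u

        weights_x[comp] = w
        weights_y[comp] = c
        scores_x[:, comp] = t
        scores_y[:, comp] = u
        covs[comp] = float(t @ u) / (n - 1)

        # canonical mode: each block deflated by its own scores
        Xd = Xd - np.outer(t, (Xd.T @ t) / (t @ t))
        Yd = Yd - np.outer(u, (Yd.T @ u) / (u @ u))
        frob_x.append(float(np.linalg.norm(Xd)))
        frob_y.append(float(np.linalg.norm(Yd)))

    return PLSModel(
        n_components=k,
        weights_x=weights_x,
        weights_y=weights_y,
        scores_x=scores_x,
        scores_y=scores_y,
        column_means_x=mx,
        column_sds_x=sx,
        column_means_y=my,
        column_sds_y=sy,
        score_covariances=covs,
        frobenius_x=np.array(frob_x),
        frobenius_y=np.array(frob_y),
    )


def normalize_scores(model: PLSModel) -> PLSModel:
    """Rescale every score map to an absolute maximum of exactly 1."""
    new_scores = []
    for scores in (model.scores_x, model.scores_y):
        peak = np.abs(scores).max(axis=0)
        if np.any(peak == 0):
            raise ValueError("cannot normalize an all-zero score map")
        new_scores.append(scores / peak)
    return replace(
        model,
        scores_x=new_scores[0],
        scores_y=new_scores[1],
        scores_normalized=True,
    )


def score_correlations(model: PLSModel) -> np.ndarray:
    """Spearman correlation between the paired score maps, per component."""
    from .stats import spearman_rho

    return np.array(
        [
            spearman_rho(model.scores_x[:, k], model.scores_y[:, k])
            for k in range(model.n_components)
        ]
    )
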