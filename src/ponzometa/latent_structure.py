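"""PCA on the scored rating items, parallel analysis, weighted importance.

The 52 scored items are decomposed by singular-value decomposition of the
standardized item matrix (equivalently, correlation-matrix PCA).  Component
retention uses parallel analysis: an observed eigenvalue is kept while it
exceeds a reference quantile of eigenvalues obtained from many random
standard-normal datasets of the same shape.

The *weighted total feature importance* links a prediction model to the
latent components: for component j it is the matrix product

    W_j = sum_i  importance_i * loading_ij,

i.e. the projection of a model's (sparse) feature-importance vector onto
each component's loading pattern.  Larger |W_j| means the model draws more
on that component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAResult",
    "pca_svd",
    "parallel_analysis",
    "weighted_total_importance",
]


@dataclass
class PCAResult:
    loadings: np.ndarray            # (p, m) unit-norm component directions
    explained_variance_ratio: np.ndarray
    scores: np.ndarray              # (n, m)
    item_names: list[str]
    n_retained: int | None = None


def pca_svd(X: np.ndarray, item_names: list[str] | None = None,
            assume_standardized: bool = True) -> PCAResult:
    """PCA via SVD of the standardized n x p item matrix.

    Loadings are the right singular vectors (unit norm, mutually orthogonal);
    explained-variance proportions are squared singular values over their
    total.  Sign convention: each loading column is flipped so that its
    largest-magnitude entry is positive (signs are otherwise arbitrary).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if assume_standardized and np.any(np.abs(X.mean(axis=0)) > 1e-6):
        raise ValueError("columns are not centered; standardize first")
    if not assume_standardized:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance column")
        X = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    props = s**2 / (s**2).sum()
    if item_names is None:
        item_names = [f"item_{j:02d}" for j in range(p)]
    return PCAResult(Vt.T, props, U * s, list(item_names))


def _eigvals_standardized(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    Z = (X - X.mean(axis=0))
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    return np.sort(np.linalg.eigvalsh(Z.T @ Z / n))[::-1]


def parallel_analysis(
    X: np.ndarray,
    n_random: int = 1_000,
    quantile: float = 0.95,
    seed: int | None = None,
    criterion: str = "quantile",
) -> int:
    """Number of components whose eigenvalue beats the random-data reference.

    Reference eigenvalues come from ``n_random`` i.i.d. standard-normal
    datasets of identical shape, standardized the same way as the data.
    ``criterion='quantile'`` compares against the stated quantile per
    eigenvalue rank (default 0.95); ``'mean'`` against the mean.  Counting
    stops at the first non-exceeding component.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    if criterion not in ("quantile", "mean"):
        raise ValueError("criterion must be 'quantile' or 'mean'")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = _eigvals_standardized(X)
    rng = np.random.default_rng(seed)
    null = np.empty((n_random, p))
    for r in range(n_random):
        null[r] = _eigvals_standardized(rng.standard_normal((n, p)))
    if criterion == "quantile":
        ref = np.quantile(null, quantile, axis=0)
    else:
        ref = null.mean(axis=0)
    exceed = obs > ref
    k = 0
    for flag in exceed[: min(n - 1, p)]:
        if not flag:
            break
        k += 1
    return k


def weighted_total_importance(
    importance: np.ndarray | dict[str, float],
    loadings: np.ndarray,
    item_names: list[str] | None = None,
) -> np.ndarray:
    """Per-component weighted total feature importance.

    ``importance`` is either a length-p vector aligned with the loading rows
    (zeros for unselected items) or a {item: value} mapping resolved against
    ``item_names``.  Returns the length-m vector  W = importance @ loadings.
    """
    loadings = np.asarray(loadings, dtype=float)
    p = loadings.shape[0]
    if isinstance(importance, dict):
        if item_names is None:
            raise ValueError("item_names required to align a mapping")
        unknown = set(importance) - set(item_names)
        if unknown:
            raise ValueError(f"importance names not among items: {sorted(unknown)}")
        vec = np.zeros(p)
        index = {w: i for i, w in enumerate(item_names)}
        for word, val in importance.items():
            vec[index[word]] = val
    else:
        vec = np.asarray(importance, dtype=float)
        if vec.shape != (p,):
            raise ValueError(
                f"importance length {vec.shape} does not match {p} loading rows")
    return vec @ loadings
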