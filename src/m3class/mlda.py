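"""Maximum-uncertainty linear discriminant analysis (MLDA).

Classical two-class LDA needs the pooled within-class scatter S_w to be
invertible, which fails when features outnumber samples. The
maximum-uncertainty variant replaces every eigenvalue of S_w that falls
below the eigenvalue mean by that mean, yielding a symmetric
positive-definite matrix for any non-degenerate input, and then applies the
usual Fisher rule: w = S*^-1 (mu1 - mu0), with the decision boundary at the
midpoint of the projected class means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class MldaModel:
    weights: np.ndarray
    bias: float
    class_means: tuple[np.ndarray, np.ndarray]  # (mu0, mu1)
    regularized_scatter: np.ndarray
    class_labels: tuple[int, int] = (0, 1)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def to_json(self) -> str:
        eigvals = np.linalg.eigvalsh(self.regularized_scatter)
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "bias": float(self.bias),
                "class_means": [m.tolist() for m in self.class_means],
                "class_labels": list(self.class_labels),
                "scatter_eigenvalues": {
                    "min": float(eigvals.min()),
                    "max": float(eigvals.max()),
                    "mean": float(eigvals.mean()),
                },
            }
        )


def regularize_scatter(sw: np.ndarray, sym_tol: float = 1e-8) -> np.ndarray:
    """Floor the eigenvalues of a symmetric scatter matrix at their mean.

    S = V diag(max(lambda_i, mean lambda)) V^T. The result is SPD whenever
    the eigenvalue mean is positive, making the discriminant solvable even
    for n < p.
    """
    sw = np.asarray(sw, dtype=float)
    if sw.ndim != 2 or sw.shape[0] != sw.shape[1]:
        raise ValueError("scatter must be a square matrix")
    scale = max(1.0, float(np.abs(sw).max()))
    if np.abs(sw - sw.T).max() > sym_tol * scale:
        raise ValueError("scatter matrix is not symmetric")
    eigvals, eigvecs = np.linalg.eigh(sw)
    floored = np.maximum(eigvals, eigvals.mean())
    return (eigvecs * floored) @ eigvecs.T


def fit_mlda(x: np.ndarray, y: np.ndarray) -> MldaModel:
    """Fit the maximum-uncertainty linear discriminant on binary labels.

    The pooled within-class scatter is the sum (not average) of
    class-centered outer products; weights solve S* w = mu1 - mu0 and the
    bias puts score 0 at the midpoint of the projected class means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("x must be 2D with at least one feature")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("y must contain both classes 0 and 1")
    mu0 = x[y == 0].mean(axis=0)
    mu1 = x[y == 1].mean(axis=0)
    sw = np.zeros((x.shape[1], x.shape[1]))
    for mu, cls in ((mu0, 0), (mu1, 1)):
        centered = x[y == cls] - mu
        sw += centered.T @ centered
    s_star = regularize_scatter(sw)
    weights = np.linalg.solve(s_star, mu1 - mu0)
    bias = -0.5 * float(weights @ (mu0 + mu1))
    return MldaModel(weights, bias, (mu0, mu1), s_star)


def predict_mlda(model: MldaModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discriminant scores w^T x + b and hard labels (score > 0 -> class 1).

    An exact tie (score 0) goes to class 0, the fixed documented tie-break.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {x.shape[1]} does not match model ({model.n_features})"
        )
    scores = x @ model.weights + model.bias
    labels = (scores > 0).astype(int)
    return labels, scores
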