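"""Shapley feature attributions for tree ensembles, and the IMPACT score.

The model's stress probability for an observation x is decomposed as

    P_X(stress) = base + sum_i phi_i

where ``base`` is the mean model output over a background sample and
phi_i is the Shapley value of feature i under the interventional
(marginal) removal semantics: a feature outside the coalition S takes its
value from a background row, and f_S(x) is averaged over background rows.
This convention makes the additivity identity hold exactly for tree
ensembles.

Two routes are provided and must agree to 1e-8:

* :func:`exact_shapley` — brute-force enumeration of all 2^M coalitions
  (the independent oracle; refuses M > 15);
* :func:`tree_shapley` — a polynomial-cost algorithm that walks each
  tree's leaves once.  For a single background row z, a leaf is reached
  by the hybrid point of coalition S iff every path feature where only x
  falls inside the leaf's box is in S (the set A) and every feature where
  only z falls inside is outside S (the set B); features where both fall
  inside are unconstrained and features where neither does kill the leaf.
  The Shapley value of that 0/1 coalition game is closed-form:
  (a-1)! b! / (a+b)! for i in A and -a! (b-1)! / (a+b)! for i in B, with
  a = |A|, b = |B|.  Summing leaf values weighted by these coefficients
  and averaging over background rows gives phi exactly.

The signed IMPACT percentage of feature i is
``100 * phi_i / sum_j |phi_j|``, so the absolute impacts always total
100% unless every phi is zero (a degenerate explanation, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .features import FeatureMatrix
from .model import StressModel, Tree, _forest_proba
from .registry import StressReportError

EXACT_MAX_FEATURES = 15
ADDITIVITY_TOL = 1e-8


@dataclass
class ShapleyExplanation:
    """Additive decomposition of one prediction."""

    feature_names: list[str]
    base: float
    phi: np.ndarray
    p_x: float
    impact_pct: np.ndarray
    degenerate: bool

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "p_x": self.p_x,
            "degenerate": self.degenerate,
            "features": {
                name: {"phi": float(p), "impact_pct": float(ip)}
                for name, p, ip in zip(self.feature_names, self.phi, self.impact_pct)
            },
        }


def impact(phi: np.ndarray) -> tuple[np.ndarray, bool]:
    """Signed percentage contributions: 100 * phi_i / sum|phi|.

    All-zero phi yields an all-zero vector flagged degenerate rather than
    an error (a report can still be rendered, with neutral impacts).
    """
    phi = np.asarray(phi, dtype=float)
    denom = np.sum(np.abs(phi))
    if denom == 0:
        return np.zeros_like(phi), True
    return 100.0 * phi / denom, False


def _as_background(background) -> np.ndarray:
    if isinstance(background, FeatureMatrix):
        background = background.X
    B = np.asarray(background, dtype=float)
    if B.ndim == 1:
        B = B[None, :]
    if B.size == 0:
        raise StressReportError("background sample is empty")
    return B


def sample_background(fm: FeatureMatrix, size: int = 100, seed: int = 0) -> np.ndarray:
    """Seeded background sample of training rows (without replacement when
    possible) used as the interventional reference distribution."""
    X = fm.X
    rng = np.random.default_rng(seed)
    if len(X) <= size:
        return X.copy()
    idx = rng.choice(len(X), size=size, replace=False)
    return X[np.sort(idx)]


def _as_vector(model: StressModel, x) -> np.ndarray:
    if isinstance(x, dict):
        x = np.array([float(x[f]) for f in model.feature_names])
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != model.n_features:
        raise StressReportError(
            f"expected {model.n_features} features, got {len(x)}"
        )
    return x


def _explanation(
    model: StressModel, base: float, phi: np.ndarray, p_x: float
) -> ShapleyExplanation:
    pct, degenerate = impact(phi)
    return ShapleyExplanation(
        feature_names=list(model.feature_names),
        base=float(base),
        phi=phi,
        p_x=float(p_x),
        impact_pct=pct,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Exact oracle: full coalition enumeration


def exact_shapley(model: StressModel, x, background) -> ShapleyExplanation:
    """Brute-force Shapley values by enumerating all 2^M coalitions.

    For each coalition S the model output is averaged over background
    rows whose features inside S are replaced by x's values.  Intended as
    the independent oracle for :func:`tree_shapley`; refuses M > 15.
    """
    x = _as_vector(model, x)
    B = _as_background(background)
    M = model.n_features
    if M > EXACT_MAX_FEATURES:
        raise StressReportError(
            f"exact enumeration limited to M <= {EXACT_MAX_FEATURES}; use tree_shapley"
        )
    f = np.empty(1 << M)
    for S in range(1 << M):
        H = B.copy()
        for i in range(M):
            if S >> i & 1:
                H[:, i] = x[i]
        f[S] = float(np.mean(model.predict_proba_matrix(H)))
    weights = np.array([_subset_weight(s, M) for s in range(M)])
    phi = np.zeros(M)
    for S in range(1 << M):
        s = bin(S).count("1")
        for i in range(M):
            if not (S >> i & 1):
                phi[i] += weights[s] * (f[S | (1 << i)] - f[S])
    return _explanation(model, base=f[0], phi=phi, p_x=f[(1 << M) - 1])


def _subset_weight(s: int, M: int) -> float:
    # |S|! (M - |S| - 1)! / M!
    return 1.0 / (comb(M - 1, s) * M)


# ---------------------------------------------------------------------------
# Fast route: leaf-box coalition game per tree


def _leaf_boxes(tree: Tree, n_features: int):
    """Depth-first leaf enumeration; each leaf yields (path feature
    indices, per-feature open/closed bounds lo < x <= hi, leaf value)."""
    boxes = []

    def walk(node: int, lo: dict[int, float], hi: dict[int, float]) -> None:
        if tree.children_left[node] == -1:
            feats = np.array(sorted(set(lo) | set(hi)), dtype=np.intp)
            lo_arr = np.array([lo.get(f, -np.inf) for f in feats])
            hi_arr = np.array([hi.get(f, np.inf) for f in feats])
            boxes.append((feats, lo_arr, hi_arr, float(tree.value[node])))
            return
        f, t = int(tree.feature[node]), float(tree.threshold[node])
        new_hi = dict(hi)
        new_hi[f] = min(hi.get(f, np.inf), t)
        walk(int(tree.children_left[node]), lo, new_hi)
        new_lo = dict(lo)
        new_lo[f] = max(lo.get(f, -np.inf), t)
        walk(int(tree.children_right[node]), new_lo, hi)

    walk(0, {}, {})
    return boxes


def _weight_table(max_count: int) -> np.ndarray:
    """W[a, b] = (a-1)! b! / (a+b)! for a >= 1 (0 when a == 0)."""
    W = np.zeros((max_count + 1, max_count + 1))
    for a in range(1, max_count + 1):
        for b in range(0, max_count + 1):
            W[a, b] = 1.0 / (a * comb(a + b, a))
    return W


def explain_matrix(
    model: StressModel, X, background
) -> tuple[float, np.ndarray, np.ndarray]:
    """Interventional TreeSHAP for every row of ``X`` at once.

    Returns ``(base, Phi, p)`` with ``Phi[r]`` the per-feature Shapley
    vector of row r and ``p[r]`` the model output; ``base + Phi.sum(1)``
    equals ``p`` to floating-point accuracy.
    """
    if not model.trees:
        raise StressReportError("model has no trees")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    B = _as_background(background)
    n_x, M = X.shape
    n_bg = len(B)
    T = len(model.trees)
    max_depth = max((t.max_depth for t in model.trees), default=1)
    W = _weight_table(max(max_depth, 1))
    phi = np.zeros((n_x, M))
    base = 0.0
    for tree in model.trees:
        for feats, lo, hi, value in _leaf_boxes(tree, M):
            scale = value / (T * n_bg)
            if len(feats) == 0:
                base += value / T
                continue
            x_in = (X[:, feats] > lo) & (X[:, feats] <= hi)      # (n_x, p)
            z_in = (B[:, feats] > lo) & (B[:, feats] <= hi)      # (n_bg, p)
            base += scale * np.sum(z_in.all(axis=1))
            xf = x_in.astype(float)
            zf = z_in.astype(float)
            a = xf @ (1.0 - zf).T          # x-only path features per (x, z)
            b = (1.0 - xf) @ zf.T          # z-only
            c = (1.0 - xf) @ (1.0 - zf).T  # neither: leaf unreachable
            valid = c == 0
            ai = a.astype(np.intp)
            bi = b.astype(np.intp)
            pos_w = np.where(valid, W[ai, bi], 0.0)
            neg_w = np.where(valid, W[bi, ai], 0.0)
            contrib = xf * (pos_w @ (1.0 - zf)) - (1.0 - xf) * (neg_w @ zf)
            phi[:, feats] += scale * contrib  # path features are unique per leaf
    p = model.predict_proba_matrix(X)
    return float(base), phi, p


def tree_shapley(model: StressModel, x, background) -> ShapleyExplanation:
    """Polynomial-cost Shapley explanation for one observation; agrees
    with :func:`exact_shapley` to 1e-8 wherever both run."""
    x = _as_vector(model, x)
    base, phi, p = explain_matrix(model, x[None, :], background)
    return _explanation(model, base=base, phi=phi[0], p_x=float(p[0]))


def additivity_check(
    expl: ShapleyExplanation, model: StressModel, x, background
) -> float:
    """Residual of the local-accuracy identity |base + sum(phi) - f(x)|."""
    x = _as_vector(model, x)
    f_x = float(model.predict_proba_matrix(x[None, :])[0])
    return abs(expl.base + float(np.sum(expl.phi)) - f_x)
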