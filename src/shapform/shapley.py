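"""Shapley-value feature attribution on the margin (log-odds) scale.

Three routes with one contract:

* :func:`exact_shapley` — 2^p coalition enumeration, the oracle (p <= 14);
* :func:`linear_shapley` — closed form for linear margins, the production
  path: phi_j = beta_j * (x_j - background_j) in standardized units;
* :func:`kernel_shapley` — weighted-least-squares approximation over
  coalition indicators, usable with any black-box predictor.

All three satisfy efficiency: base value plus the attributions of a row sum
to the model margin at that row.  Attribution is interventional (features
outside a coalition are replaced by background values, treated as
independent), which coincides with the closed form for linear models.

Additivity is exact on the margin scale, not on probabilities — attributions
here are log-odds contributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial

import numpy as np

#: Enumeration cut-off: beyond this many coalitions we refuse (exact) or
#: subsample (kernel).
MAX_ENUMERATION = 2 ** 14


@dataclass
class ShapMatrix:
    """Per-row, per-feature attributions plus the shared base value."""

    values: np.ndarray                # n_eval x p, log-odds units
    base_value: float                 # expected margin over the background
    item_ids: list[str] | None = None
    background_summary: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.item_ids is not None and len(self.item_ids) != self.values.shape[1]:
            raise ValueError("item_ids do not align with attribution columns")

    def check_efficiency(self, margins, tol: float = 1e-8) -> None:
        """Assert base + sum(phi) reproduces each row's margin."""
        margins = np.asarray(margins, dtype=float).ravel()
        total = self.base_value + self.values.sum(axis=1)
        err = np.max(np.abs(total - margins)) if margins.size else 0.0
        if err > tol:
            raise AssertionError(f"efficiency violated: max error {err:.3e} > {tol:g}")

    def to_csv(self, path, respondent_ids=None) -> None:
        import pandas as pd

        cols = self.item_ids or [f"f{j}" for j in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=cols)
        if respondent_ids is not None:
            df.insert(0, "respondent_id", list(respondent_ids))
        with open(path, "w") as fh:
            fh.write(f"# base_value={self.base_value!r}\n")
            df.to_csv(fh, index=False)


def exact_shapley(value_fn, p: int) -> np.ndarray:
    """Shapley values by full coalition enumeration.

    ``value_fn(frozenset_of_indices) -> float`` is any set function on
    subsets of range(p).  phi_i averages the marginal contribution of i over
    all coalitions S not containing i, weighted |S|!(p-|S|-1)!/p!.
    """
    if p > 14:
        raise ValueError(
            f"p={p} means 2^{p} coalition evaluations; use kernel_shapley"
        )
    universe = list(range(p))
    # cache v(S) for all subsets, keyed by bitmask
    v = np.empty(2 ** p)
    for mask in range(2 ** p):
        members = frozenset(i for i in universe if mask >> i & 1)
        v[mask] = value_fn(members)

    fact = [factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for i in universe:
        bit = 1 << i
        for mask in range(2 ** p):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[p - s - 1] / fact[p]
            phi[i] += w * (v[mask | bit] - v[mask])
    return phi


def model_value_fn(predict_margin, x, background):
    """Interventional coalition value for a model at evaluation row ``x``.

    v(S) = mean over background rows of the margin with features in S taken
    from ``x`` and the rest from the background row.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))

    def value(coalition) -> float:
        synth = background.copy()
        idx = sorted(coalition)
        synth[:, idx] = x[idx]
        return float(np.mean(predict_margin(synth)))

    return value


def linear_shapley(model, X_eval, background_means=None) -> ShapMatrix:
    """Closed-form attributions for a fitted linear-margin model.

    phi_ij = beta_j * (x_ij - background_j) / scale_j; the base value is the
    model margin at the background point.  Defaults the background to the
    model's training feature means, in which case base = intercept.
    """
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    if background_means is None:
        background = model.feature_means
    else:
        background = np.asarray(background_means, dtype=float).ravel()
    if X_eval.shape[1] != model.coefficients.size or background.size != model.coefficients.size:
        raise ValueError("dimension mismatch between model, X_eval and background")
    beta_over_scale = model.coefficients / model.feature_scales
    values = (X_eval - background) * beta_over_scale
    base = float(model.predict_margin(background[None, :])[0])
    return ShapMatrix(
        values=values,
        base_value=base,
        item_ids=list(model.item_ids) if model.item_ids is not None else None,
        background_summary=background.copy(),
    )


def _kernel_weights(p: int, sizes: np.ndarray) -> np.ndarray:
    """Shapley kernel weight (p-1) / (C(p,|z|) |z| (p-|z|)) per coalition."""
    return np.array(
        [(p - 1) / (comb(p, int(s)) * s * (p - s)) for s in sizes], dtype=float
    )


def kernel_shapley(
    predict_fn,
    x_eval,
    background_sample,
    n_samples: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Kernel-weighted least-squares Shapley approximation for one row.

    Enumerates all 2^p - 2 proper coalitions when that fits the enumeration
    budget, otherwise draws ``n_samples`` coalitions by the kernel's size
    distribution (fixed seed).  Efficiency is enforced exactly by
    substituting the constraint sum(phi) = v(full) - v(empty) into the least
    squares system.
    """
    x_eval = np.asarray(x_eval, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background_sample, dtype=float))
    p = x_eval.size
    if p < 2:
        raise ValueError("kernel SHAP needs at least two features")
    if np.allclose(background.std(axis=0), 0) and np.allclose(
        background[0], x_eval
    ):
        raise ValueError("background identical to evaluation row: singular system")

    value = model_value_fn(predict_fn, x_eval, background)
    v0 = value(frozenset())
    v1 = value(frozenset(range(p)))

    if 2 ** p <= MAX_ENUMERATION:
        masks = []
        for size in range(1, p):
            masks.extend(combinations(range(p), size))
    else:
        rng = np.random.default_rng(seed)
        n_samples = n_samples or 2048
        sizes = np.arange(1, p)
        size_w = _kernel_weights(p, sizes) * [comb(p, int(s)) for s in sizes]
        size_w = size_w / size_w.sum()
        masks = []
        seen = set()
        for s in rng.choice(sizes, size=n_samples, p=size_w):
            members = tuple(sorted(rng.choice(p, size=int(s), replace=False)))
            if members not in seen:
                seen.add(members)
                masks.append(members)

    Z = np.zeros((len(masks), p))
    vz = np.empty(len(masks))
    for r, members in enumerate(masks):
        Z[r, list(members)] = 1.0
        vz[r] = value(frozenset(members))
    sizes = Z.sum(axis=1)
    w = _kernel_weights(p, sizes)

    # eliminate phi_p via the efficiency constraint
    total = v1 - v0
    y = vz - v0 - Z[:, -1] * total
    A = Z[:, :-1] - Z[:, [-1]]
    Aw = A * w[:, None]
    G = Aw.T @ A
    G[np.diag_indices_from(G)] += 1e-12
    phi_head = np.linalg.solve(G, Aw.T @ y)
    phi = np.append(phi_head, total - phi_head.sum())
    return phi


def kernel_shap_matrix(
    predict_fn, X_eval, background_sample, item_ids=None, **kwargs
) -> ShapMatrix:
    """Row-wise :func:`kernel_shapley` packaged as a :class:`ShapMatrix`."""
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=float))
    background = np.atleast_2d(np.asarray(background_sample, dtype=float))
    base = float(np.mean(predict_fn(background)))
    values = np.vstack(
        [kernel_shapley(predict_fn, row, background, **kwargs) for row in X_eval]
    )
    return ShapMatrix(
        values=values,
        base_value=base,
        item_ids=list(item_ids) if item_ids is not None else None,
        background_summary=background.mean(axis=0),
    )


def global_importance(shap: ShapMatrix, signed: bool = False) -> np.ndarray:
    """Per-feature global importance: mean |phi| (or signed mean) over rows.

    The absolute mean is the default because signed contributions cancel
    across respondents and cannot rank features.
    """
    if shap.values.shape[0] < 1:
        raise ValueError("need at least one evaluation row")
    if signed:
        return shap.values.mean(axis=0)
    return np.abs(shap.values).mean(axis=0)
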