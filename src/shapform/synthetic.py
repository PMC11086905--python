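"""Synthetic questionnaire cohorts with a known latent-factor ground truth.

Generative mechanism (a multidimensional graded-response / ordinal-probit
model):

1. latent factor scores ``f ~ MVN(0, R)`` for the five correlated syndrome
   dimensions;
2. per item j, a latent propensity ``eta_j = sum_k loading[j,k] f_k + e``
   with unit-normal noise; the ordinal response is the number of the item's
   four ordered thresholds that ``eta_j`` exceeds (0..4);
3. binary outcomes are Bernoulli with ``logit p = b0 + f . coeffs``, the
   intercept calibrated by bisection so the expected prevalence hits its
   target exactly.

Outcomes depend on the latent factors rather than the observed responses,
so item-level measurement noise attenuates prediction realistically.  The
default calibration produces a total-score reliability (Cronbach's alpha)
of about 0.98 for the 61-item bank, with the entrapment factor carrying the
largest outcome weight.

All randomness flows from one master seed, split deterministically into
per-sampler child seeds via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .instrument import (
    CRITERIA,
    ItemBank,
    OutcomeLabels,
    ResponseMatrix,
    ValidationError,
)
from .reference import default_item_bank

#: Default targets for realized outcome prevalence.
DEFAULT_PREV_SI = 0.1911
DEFAULT_PREV_SI_P = 0.0233

#: Default inter-factor correlation (symptoms form an interrelated network).
DEFAULT_FACTOR_CORR = 0.6

#: Default loading of an item on its own criterion's factor, in units of the
#: unit-normal item noise; 1.6 yields alpha ~= 0.98 over 61 items.
DEFAULT_LOADING = 1.6

#: Base ordered cut-points, scaled per item by its latent standard deviation.
DEFAULT_CUTS = (-1.5, -0.5, 0.5, 1.5)

#: Default outcome log-odds per factor SD; entrapment (first) weighted
#: highest for both outcomes.
DEFAULT_COEFFS_SI = (1.8, 0.8, 0.6, 0.7, 0.5)
DEFAULT_COEFFS_SI_P = (2.2, 1.0, 0.8, 0.6, 0.15)


@dataclass
class SyntheticConfig:
    n: int
    loadings: np.ndarray            # p x 5
    factor_corr: np.ndarray         # 5 x 5
    thresholds: np.ndarray          # p x 4, strictly increasing per row
    outcome_coeffs_si: np.ndarray
    outcome_coeffs_si_p: np.ndarray
    target_prev_si: float = DEFAULT_PREV_SI
    target_prev_si_p: float = DEFAULT_PREV_SI_P
    seed: int = 0
    bank: ItemBank = field(default_factory=default_item_bank)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.outcome_coeffs_si = np.asarray(self.outcome_coeffs_si, dtype=float)
        self.outcome_coeffs_si_p = np.asarray(self.outcome_coeffs_si_p, dtype=float)
        p = len(self.bank)
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.loadings.shape != (p, len(CRITERIA)):
            raise ValidationError(f"loadings must be {p} x {len(CRITERIA)}")
        if self.thresholds.shape != (p, 4):
            raise ValidationError(f"thresholds must be {p} x 4")
        if not np.all(np.diff(self.thresholds, axis=1) > 0):
            raise ValidationError("each item's thresholds must be strictly increasing")
        _validate_correlation(self.factor_corr)
        for name, prev in (("target_prev_si", self.target_prev_si),
                           ("target_prev_si_p", self.target_prev_si_p)):
            if not 0 < prev < 1:
                raise ValidationError(f"{name} must lie strictly in (0, 1)")

    @classmethod
    def default(cls, n: int = 10357, seed: int = 0,
                bank: ItemBank | None = None, **overrides) -> "SyntheticConfig":
        """The documented default calibration for a given cohort size."""
        bank = bank or default_item_bank()
        loadings = default_loadings(bank)
        return cls(
            n=n,
            loadings=loadings,
            factor_corr=equicorrelation(DEFAULT_FACTOR_CORR),
            thresholds=default_thresholds(loadings, equicorrelation(DEFAULT_FACTOR_CORR)),
            outcome_coeffs_si=np.array(DEFAULT_COEFFS_SI),
            outcome_coeffs_si_p=np.array(DEFAULT_COEFFS_SI_P),
            seed=seed,
            bank=bank,
            **overrides,
        )


@dataclass
class Cohort:
    bank: ItemBank
    responses: ResponseMatrix       # severity scale (reverse coding applied)
    outcomes: OutcomeLabels
    factor_scores: np.ndarray       # n x 5 ground truth
    config: SyntheticConfig

    def raw_responses(self) -> ResponseMatrix:
        """Responses on the raw administration scale (reverse items inverted)."""
        values = self.responses.values.copy()
        flagged = [
            j for j, i in enumerate(self.responses.item_ids)
            if self.bank[i].reverse_coded
        ]
        if flagged:
            values[:, flagged] = 4 - values[:, flagged]
        return ResponseMatrix(
            respondent_ids=list(self.responses.respondent_ids),
            item_ids=list(self.responses.item_ids),
            values=values,
            reverse_coding_applied=False,
        )


def equicorrelation(rho: float, k: int = 5) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def default_loadings(bank: ItemBank, loading: float = DEFAULT_LOADING) -> np.ndarray:
    """Each item loads ``loading`` on its own criterion's factor only."""
    p = len(bank)
    out = np.zeros((p, len(CRITERIA)))
    crit_col = {c: k for k, c in enumerate(CRITERIA)}
    for j, item in enumerate(bank.items):
        out[j, crit_col[item.criterion]] = loading
    return out


def default_thresholds(loadings: np.ndarray, factor_corr: np.ndarray,
                       cuts=DEFAULT_CUTS) -> np.ndarray:
    """Scale the base cut-points by each item's latent standard deviation."""
    latent_var = 1.0 + np.einsum("jk,kl,jl->j", loadings, factor_corr, loadings)
    return np.sqrt(latent_var)[:, None] * np.asarray(cuts)[None, :]


def _validate_correlation(corr: np.ndarray) -> None:
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValidationError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] <= 1e-10:
        raise ValidationError(
            f"correlation matrix not positive definite: smallest eigenvalue "
            f"{eigvals[0]:.3e}"
        )


def sample_latent_factors(n: int, factor_corr, seed) -> np.ndarray:
    """n x k zero-mean unit-variance MVN draws with the given correlation."""
    factor_corr = np.asarray(factor_corr, dtype=float)
    _validate_correlation(factor_corr)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(factor_corr)
    return rng.standard_normal((n, factor_corr.shape[0])) @ chol.T


def sample_item_responses(factors: np.ndarray, config: SyntheticConfig,
                          seed) -> ResponseMatrix:
    """Ordinal responses: count of an item's thresholds below its propensity.

    Reverse-flagged items are emitted already on the severity scale (the
    returned matrix is marked as reverse-coded).
    """
    rng = np.random.default_rng(seed)
    factors = np.asarray(factors, dtype=float)
    n = factors.shape[0]
    eta = factors @ config.loadings.T + rng.standard_normal((n, len(config.bank)))
    responses = (eta[:, :, None] > config.thresholds[None, :, :]).sum(axis=2)
    return ResponseMatrix(
        respondent_ids=[f"r{i}" for i in range(n)],
        item_ids=config.bank.item_ids,
        values=responses.astype(np.int64),
        reverse_coding_applied=True,
    )


def calibrate_outcome_intercept(factors: np.ndarray, coeffs,
                                target_prev: float,
                                tol: float = 1e-6) -> float:
    """Bisection for b0 with mean(expit(b0 + f.coeffs)) = target_prev.

    The mean is strictly increasing in b0, so plain bisection always
    converges; the bracket is widened first if needed.
    """
    if not 0 < target_prev < 1:
        raise ValidationError("target_prev must lie strictly in (0, 1)")
    linpred = np.asarray(factors, dtype=float) @ np.asarray(coeffs, dtype=float)

    def realized(b0: float) -> float:
        return float(np.mean(expit(b0 + linpred)))

    lo, hi = logit(target_prev) - 1.0, logit(target_prev) + 1.0
    while realized(lo) > target_prev:
        lo -= 2.0
    while realized(hi) < target_prev:
        hi += 2.0
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_prev:
            lo = mid
        else:
            hi = mid
        if abs(realized(mid) - target_prev) < tol:
            return mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Compose the samplers into a full cohort with ground truth retained."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    factors = sample_latent_factors(config.n, config.factor_corr, seeds[0])
    responses = sample_item_responses(factors, config, seeds[1])

    outcomes = {}
    for label, coeffs, target, seed in (
        ("si", config.outcome_coeffs_si, config.target_prev_si, seeds[2]),
        ("si_p", config.outcome_coeffs_si_p, config.target_prev_si_p, seeds[3]),
    ):
        b0 = calibrate_outcome_intercept(factors, coeffs, target)
        prob = expit(b0 + factors @ np.asarray(coeffs, dtype=float))
        rng = np.random.default_rng(seed)
        outcomes[label] = (rng.random(config.n) < prob).astype(np.int64)

    return Cohort(
        bank=config.bank,
        responses=responses,
        outcomes=OutcomeLabels(si=outcomes["si"], si_p=outcomes["si_p"]),
        factor_scores=factors,
        config=config,
    )
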