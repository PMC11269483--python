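"""Bayesian model comparison by log marginal likelihood.

The marginal likelihood (model evidence) of each family member is
estimated by bridge sampling over the model's unconstrained parameter
space, with a moment-matched Gaussian proposal and the Meng–Wong
fixed-point iteration; a plain importance-sampling estimator is
available as a fallback.  Under equiprobable model priors the log
posterior model probability is the evidence normalised by
log-sum-exp across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .models import MODELS

__all__ = [
    "ModelEvidence",
    "bridge_sampling_log_ml",
    "log_marginal_likelihood",
    "posterior_model_probabilities",
    "comparison_table",
    "compare_models",
]


@dataclass
class ModelEvidence:
    """Evidence summary for one model (one comparison-table row)."""

    model_id: int
    log_marginal_likelihood: float
    se: float = np.nan
    converged: bool = True
    log_posterior_prob: float = np.nan
    rank: int | None = None

    @property
    def label(self) -> str:
        return MODELS[self.model_id].label


def _fit_proposal(draws: np.ndarray, ridge: float = 1e-8):
    mean = draws.mean(axis=0)
    cov = np.cov(draws, rowvar=False)
    cov = np.atleast_2d(cov) + ridge * np.eye(draws.shape[1])
    return multivariate_normal(mean=mean, cov=cov, allow_singular=True)


def _bridge_iterate(l1: np.ndarray, l2: np.ndarray, maxiter: int = 2000, tol: float = 1e-12) -> float:
    """Meng–Wong fixed point on log ratios.

    ``l1``: log(post/proposal) at posterior draws; ``l2``: same at
    proposal draws.  Returns the log normalising constant.
    """
    n1, n2 = l1.size, l2.size
    ls1 = np.log(n1 / (n1 + n2))
    ls2 = np.log(n2 / (n1 + n2))
    lr = logsumexp(l2) - np.log(n2)  # importance-sampling start
    for _ in range(maxiter):
        num = l2 - np.logaddexp(ls1 + l2, ls2 + lr)
        den = -np.logaddexp(ls1 + l1, ls2 + lr)
        lr_new = (logsumexp(num) - np.log(n2)) - (logsumexp(den) - np.log(n1))
        if not np.isfinite(lr_new):
            raise FloatingPointError("bridge-sampling iteration diverged (non-finite estimate)")
        if abs(lr_new - lr) < tol:
            return float(lr_new)
        lr = lr_new
    return float(lr)


def bridge_sampling_log_ml(
    posterior_draws: np.ndarray,
    log_post_fn,
    seed: int = 0,
    n_proposal: int | None = None,
    method: str = "bridge",
    n_batches: int = 5,
) -> tuple[float, float]:
    """Estimate the log normalising constant of an unnormalised density.

    Parameters
    ----------
    posterior_draws : (N, D) array
        Draws from the (normalised) target.  Half are used to fit the
        Gaussian proposal, half enter the bridge estimator.
    log_post_fn : callable
        Vectorised unnormalised log target, (M, D) -> (M,).
    method : "bridge" or "importance"
    n_batches : int
        Disjoint batches used for the batch standard error.

    Returns ``(log_ml, se)``.
    """
    rng = np.random.default_rng(seed)
    draws = np.atleast_2d(np.asarray(posterior_draws, dtype=float))
    n = draws.shape[0]
    if n < 4:
        raise ValueError("need at least 4 posterior draws")
    perm = rng.permutation(n)
    fit_half, est_half = draws[perm[: n // 2]], draws[perm[n // 2 :]]
    prop = _fit_proposal(fit_half)
    n2 = n_proposal if n_proposal is not None else est_half.shape[0]
    prop_draws = prop.rvs(size=n2, random_state=np.random.RandomState(seed + 1))
    prop_draws = np.atleast_2d(prop_draws)
    if prop_draws.shape[0] != n2:  # 1-D target
        prop_draws = prop_draws.reshape(n2, -1)
    l1 = np.asarray(log_post_fn(est_half)) - prop.logpdf(est_half)
    l2 = np.asarray(log_post_fn(prop_draws)) - prop.logpdf(prop_draws)
    if not (np.all(np.isfinite(l1)) and np.any(np.isfinite(l2))):
        raise FloatingPointError(
            "non-finite log ratios in evidence estimation; "
            f"l1 finite: {np.isfinite(l1).mean():.2f}, l2 finite: {np.isfinite(l2).mean():.2f}"
        )
    l2 = np.where(np.isfinite(l2), l2, -np.inf)

    def estimate(l1_, l2_):
        if method == "importance":
            return float(logsumexp(l2_) - np.log(l2_.size))
        return _bridge_iterate(l1_, l2_)

    log_ml = estimate(l1, l2)
    # batch standard error over disjoint splits of both draw sets
    k = min(n_batches, l1.size, l2.size)
    if k >= 2:
        ests = []
        for b in range(k):
            ests.append(estimate(l1[b::k], l2[b::k]))
        se = float(np.std(ests, ddof=1) / np.sqrt(k))
    else:
        se = np.nan
    if not np.isfinite(log_ml):
        raise FloatingPointError("evidence estimate is non-finite")
    return log_ml, se


def log_marginal_likelihood(
    results, seed: int = 0, thin: int | None = None, method: str = "bridge"
) -> tuple[float, float]:
    """Bridge-sampling evidence of a fitted hierarchical RL model.

    ``results`` is a :class:`~revlearn.hierarchical.HierarchicalRLResults`;
    the target is the model's exact unnormalised posterior (normalised
    prior times likelihood) on the unconstrained space, so the estimate
    is the model's marginal likelihood.
    """
    draws = results.flat_draws()
    if thin is None:
        # keep the proposal fit well-conditioned without exploding runtime
        thin = max(1, draws.shape[0] // max(4 * results.model.ndim, 2000))
    draws = draws[::thin]
    return bridge_sampling_log_ml(draws, results.model.log_prob, seed=seed, method=method)


def posterior_model_probabilities(log_mls: np.ndarray) -> np.ndarray:
    """Log posterior model probabilities under equiprobable model priors:
    ``log_ml_m - logsumexp(log_mls)``."""
    v = np.asarray(log_mls, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two models")
    if not np.all(np.isfinite(v)):
        raise ValueError("log marginal likelihoods must be finite")
    return v - logsumexp(v)


def comparison_table(evidences: list[ModelEvidence]) -> pd.DataFrame:
    """Ranked model-comparison table.

    Converged models are ranked by log marginal likelihood (ties broken
    by smaller model id) and given log posterior probabilities under
    equiprobable priors; non-converged models are kept in the table with
    an explicit marker instead of a rank or probability.
    """
    ids = [e.model_id for e in evidences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    conv = [e for e in evidences if e.converged]
    if len(conv) >= 2:
        lp = posterior_model_probabilities([e.log_marginal_likelihood for e in conv])
        for e, v in zip(conv, lp):
            e.log_posterior_prob = float(v)
    order = sorted(conv, key=lambda e: (-e.log_marginal_likelihood, e.model_id))
    for r, e in enumerate(order, start=1):
        e.rank = r
    rows = []
    for e in sorted(evidences, key=lambda e: e.model_id):
        rows.append(
            {
                "model": e.model_id,
                "parameters": e.label,
                "rank": e.rank if e.converged else "not converged",
                "log_marginal_likelihood": e.log_marginal_likelihood,
                "log_posterior_prob": e.log_posterior_prob if e.converged else np.nan,
                "se": e.se,
            }
        )
    return pd.DataFrame(rows)


def compare_models(
    trials: pd.DataFrame,
    model_ids: list[int],
    seed: int = 0,
    fit_kwargs: dict | None = None,
    priors=None,
) -> tuple[list[ModelEvidence], pd.DataFrame]:
    """Fit each requested model to the trial log and rank by evidence."""
    from .hierarchical import HierarchicalRLModel

    fit_kwargs = dict(fit_kwargs or {})
    evidences = []
    for i, mid in enumerate(model_ids):
        model = HierarchicalRLModel(trials, MODELS[mid], priors=priors)
        res = model.fit(seed=seed + i, **fit_kwargs)
        lml, se = log_marginal_likelihood(res, seed=seed + 100 + i)
        evidences.append(
            ModelEvidence(
                model_id=mid,
                log_marginal_likelihood=lml,
                se=se,
                converged=res.converged,
            )
        )
    return evidences, comparison_table(evidences)
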