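"""Hierarchical Bayesian fitting of the RL model family.

The model, for a cohort of subjects indexed ``s`` in dose groups
``g(s)`` and a family member with free parameters ``p``:

    mu_{g,p}   ~ Normal(0, 1)            group-level mean, transformed scale
    sigma_p    ~ HalfNormal(1)           between-subject SD, shared across groups
    z_{s,p}    ~ Normal(0, 1)            non-centered subject offsets
    theta_{s,p} = mu_{g(s),p} + sigma_p * z_{s,p}

    choices_s  ~ RL(inv_transform(theta_s))

with logit transforms for the learning rates and rho, a log transform
for beta, and identity for the stickiness weights.  The likelihood is
exactly :func:`revlearn.models.session_log_likelihood`, evaluated
through the compiled kernels.

Sampling uses an ensemble MCMC sampler (differential-evolution moves)
over the joint unconstrained space, initialised at a posterior-mode
estimate.  Convergence is gated on split-Rhat of the group-level
parameters; non-convergence raises a :class:`ConvergenceWarning`,
never silently accepted.

Usage::

    model = HierarchicalRLModel(trials, MODELS[9])
    res = model.fit(seed=1)
    res.summary()
    res.group_difference("alpha_pun", "low", "vehicle").flag
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

import emcee

from .cohort import to_natural
from .likelihood import PackedTrials, pack_trials, loglik_walkers
from .models import MODELS, PARAM_TRANSFORMS, AgentParams, ModelSpec
from .task import StimulusSet

__all__ = [
    "PriorConfig",
    "HierarchicalRLModel",
    "HierarchicalRLResults",
    "GroupContrast",
    "EvidenceFlag",
    "ConvergenceWarning",
    "hdi",
    "fit_hierarchical",
]

KERNEL_ORDER = ["alpha_rew", "alpha_pun", "beta", "kappa_side", "kappa_stim", "rho"]
NEUTRAL = np.array([np.nan, np.nan, np.nan, 0.0, 0.0, 1.0])  # alphas/beta always free

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceWarning(UserWarning):
    pass


class EvidenceFlag(str, enum.Enum):
    STRONG = "STRONG"      # 0 outside the 95% HDI
    MODERATE = "MODERATE"  # 0 outside the 75% HDI only
    NONE = "NONE"


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative defaults on the transformed scales."""

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 1.0
    q_init: float = 0.5


def hdi(draws: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest empirical interval containing ``mass`` of the draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 finite draws")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


@dataclass
class GroupContrast:
    """Posterior contrast of one parameter's group means (treated - control),
    on the transformed scale, with the HDI-based evidence flag."""

    parameter: str
    group_a: str
    group_b: str
    draws: np.ndarray
    hdi75: tuple[float, float] = field(init=False)
    hdi95: tuple[float, float] = field(init=False)
    flag: EvidenceFlag = field(init=False)

    def __post_init__(self) -> None:
        self.hdi75 = hdi(self.draws, 0.75)
        self.hdi95 = hdi(self.draws, 0.95)
        if not (self.hdi95[0] <= 0.0 <= self.hdi95[1]):
            self.flag = EvidenceFlag.STRONG
        elif not (self.hdi75[0] <= 0.0 <= self.hdi75[1]):
            self.flag = EvidenceFlag.MODERATE
        else:
            self.flag = EvidenceFlag.NONE

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def direction(self) -> str:
        return "increase" if self.mean > 0 else "decrease"


class HierarchicalRLModel:
    """Hierarchical RL model over a cohort trial log.

    Parameters
    ----------
    trials : DataFrame
        Trial log with the standard columns (one row per trial).
    spec : ModelSpec or int
        Which family member to fit (1-9).
    priors : PriorConfig, optional
    stimulus_set : StimulusSet, optional
        Identifier mapping for the three stimuli (defaults A/B/C).
    group_order : sequence of str, optional
        Group ordering; defaults to vehicle/low/high when present, else
        order of appearance.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spec: ModelSpec | int,
        priors: PriorConfig | None = None,
        stimulus_set: StimulusSet | None = None,
        group_order: list[str] | None = None,
    ):
        self.spec = MODELS[spec] if isinstance(spec, int) else spec
        self.priors = priors if priors is not None else PriorConfig()
        self.packed: PackedTrials = pack_trials(
            trials, stimulus_set, q_init=self.priors.q_init
        )
        groups_present = list(dict.fromkeys(self.packed.groups))
        if group_order is None:
            canonical = ["vehicle", "low", "high"]
            if set(groups_present) <= set(canonical):
                group_order = [g for g in canonical if g in groups_present]
            else:
                group_order = groups_present
        if set(group_order) != set(groups_present):
            raise ValueError(f"group_order {group_order} != groups in data {groups_present}")
        self.groups = list(group_order)
        self.group_idx = np.array([self.groups.index(g) for g in self.packed.groups])
        self.param_names = list(self.spec.param_names)
        self.n_groups = len(self.groups)
        self.n_subjects = self.packed.n_subjects
        self.n_params = len(self.param_names)
        # theta layout: mu (G x P, C-order) | log_sigma (P) | z (S x P, C-order)
        self.ndim = self.n_groups * self.n_params + self.n_params + self.n_subjects * self.n_params
        # map free parameter columns into the fixed 6-slot kernel order
        self._free_to_kernel = []
        for j, name in enumerate(self.param_names):
            if name == "alpha":
                self._free_to_kernel.append((j, [0, 1], "logit"))
            else:
                self._free_to_kernel.append((j, [KERNEL_ORDER.index(name)], PARAM_TRANSFORMS[name]))

    # -- parameter bookkeeping -------------------------------------------------

    def split_theta(self, theta: np.ndarray):
        """(W, D) -> mu (W,G,P), log_sigma (W,P), z (W,S,P)."""
        theta = np.atleast_2d(theta)
        G, P, S = self.n_groups, self.n_params, self.n_subjects
        mu = theta[:, : G * P].reshape(-1, G, P)
        ls = theta[:, G * P : G * P + P]
        z = theta[:, G * P + P :].reshape(-1, S, P)
        return mu, ls, z

    def subject_transformed(self, theta: np.ndarray) -> np.ndarray:
        """Subject-level parameters on the transformed scale, (W, S, P)."""
        mu, ls, z = self.split_theta(theta)
        return mu[:, self.group_idx, :] + np.exp(ls)[:, None, :] * z

    def kernel_params(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale (W, S, 6) kernel parameter array."""
        tr = self.subject_transformed(theta)
        W, S, _ = tr.shape
        out = np.empty((W, S, 6))
        out[:, :, 3] = 0.0
        out[:, :, 4] = 0.0
        out[:, :, 5] = 1.0
        for j, cols, kind in self._free_to_kernel:
            if kind == "logit":
                v = expit(tr[:, :, j])
            elif kind == "log":
                v = np.exp(tr[:, :, j])
            else:
                v = tr[:, :, j]
            for c in cols:
                out[:, :, c] = v
        return out

    # -- posterior density -----------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Exact (normalised) log prior density on the unconstrained space,
        including the log-sigma Jacobian — required for marginal-likelihood
        estimation, not just sampling."""
        mu, ls, z = self.split_theta(theta)
        pr = self.priors
        lp = -0.5 * np.sum(((mu - pr.mu_loc) / pr.mu_scale) ** 2, axis=(1, 2))
        lp -= mu.shape[1] * mu.shape[2] * (np.log(pr.mu_scale) + 0.5 * _LOG_2PI)
        sigma = np.exp(ls)
        # half-normal on sigma, plus Jacobian d sigma / d log sigma = sigma
        lp += np.sum(
            np.log(2.0) - np.log(pr.sigma_scale) - 0.5 * _LOG_2PI
            - 0.5 * (sigma / pr.sigma_scale) ** 2 + ls,
            axis=1,
        )
        lp += -0.5 * np.sum(z**2, axis=(1, 2)) - z.shape[1] * z.shape[2] * 0.5 * _LOG_2PI
        return lp

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        P = self.kernel_params(theta)
        return loglik_walkers(self.packed, P, self.spec.rho_mode)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior (vectorised over walkers).  Its
        normalising constant over the unconstrained space is the model's
        marginal likelihood."""
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        ok = np.all(np.isfinite(theta), axis=1)
        out = np.full(theta.shape[0], -np.inf)
        if np.any(ok):
            ll = self.log_likelihood(theta[ok])
            out[ok] = lp[ok] + ll
        return out

    def _log_prob_scalar(self, theta: np.ndarray) -> float:
        return float(self.log_prob(theta[None, :])[0])

    def map_estimate(self, maxiter: int = 150, seed: int = 0) -> np.ndarray:
        """Posterior-mode estimate used to initialise the walkers."""
        rng = np.random.default_rng(seed)
        x0 = 0.1 * rng.standard_normal(self.ndim)
        res = optimize.minimize(
            lambda th: -self._log_prob_scalar(th),
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 10 * maxiter * self.ndim},
        )
        return res.x

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        draws: int = 400,
        tune: int = 600,
        walkers: int | None = None,
        seed: int = 0,
        init: str = "map",
        map_maxiter: int = 150,
        rhat_threshold: float = 1.05,
        progress: bool = False,
    ) -> "HierarchicalRLResults":
        """Run the ensemble sampler and return a results object.

        ``tune`` steps are discarded as burn-in; ``draws`` steps are kept
        from every walker.  Reproducible for fixed seed and settings.
        """
        if walkers is None:
            walkers = 2 * self.ndim + 2
        walkers = max(walkers, 2 * self.ndim + 2)
        if walkers % 2:
            walkers += 1
        rng = np.random.default_rng(seed)
        if init == "map":
            center = self.map_estimate(maxiter=map_maxiter, seed=seed)
        else:
            center = np.zeros(self.ndim)
        p0 = center[None, :] + 0.05 * rng.standard_normal((walkers, self.ndim))
        moves = [(emcee.moves.DEMove(), 0.9), (emcee.moves.DESnookerMove(), 0.1)]
        sampler = emcee.EnsembleSampler(
            walkers, self.ndim, self.log_prob, vectorize=True, moves=moves
        )
        state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
        state = sampler.run_mcmc(state, tune, progress=progress)
        sampler.reset()
        sampler.run_mcmc(state, draws, progress=progress)
        chain = sampler.get_chain()  # (draws, walkers, dim)
        logp = sampler.get_log_prob()
        return HierarchicalRLResults(
            model=self,
            chain=np.moveaxis(chain, 0, 1),  # (walkers, draws, dim)
            log_prob_chain=logp.T,
            seed=seed,
            rhat_threshold=rhat_threshold,
        )


class HierarchicalRLResults:
    """Posterior draws, diagnostics and summaries for a fitted model.

    The walker ensemble is treated as the chain dimension for split-Rhat
    and effective-sample-size diagnostics of the group-level parameters.
    """

    def __init__(
        self,
        model: HierarchicalRLModel,
        chain: np.ndarray,
        log_prob_chain: np.ndarray,
        seed: int,
        rhat_threshold: float = 1.05,
    ):
        self.model = model
        self.chain = chain
        self.log_prob_chain = log_prob_chain
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self._diag = None
        bad = self.max_rhat
        self.converged = bool(bad <= rhat_threshold)
        if not self.converged:
            warnings.warn(
                f"group-level split-Rhat {bad:.3f} exceeds {rhat_threshold}; "
                "treat posterior summaries with caution",
                ConvergenceWarning,
                stacklevel=2,
            )

    # -- draws access ----------------------------------------------------------

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    def flat_draws(self) -> np.ndarray:
        """All retained draws, flattened to (n_draws_total, ndim)."""
        return self.chain.reshape(-1, self.model.ndim)

    def mu_draws(self, parameter: str, group: str) -> np.ndarray:
        """Flat draws of one group-level mean on the transformed scale."""
        if parameter not in self.model.param_names:
            raise KeyError(f"model {self.spec.model_id} has no parameter {parameter!r}")
        if group not in self.model.groups:
            raise KeyError(f"unknown group {group!r}")
        g = self.model.groups.index(group)
        p = self.model.param_names.index(parameter)
        return self.chain[:, :, g * self.model.n_params + p].ravel()

    def sigma_draws(self, parameter: str) -> np.ndarray:
        p = self.model.param_names.index(parameter)
        off = self.model.n_groups * self.model.n_params
        return np.exp(self.chain[:, :, off + p].ravel())

    def _pseudo_chains(self, idx: int, n_chains: int = 4) -> np.ndarray:
        """Pool the walker ensemble into a few draw-ordered pseudo-chains.

        Walkers in an interacting ensemble are not independent chains:
        per-walker split-Rhat stays elevated long after the ensemble is
        stationary.  Pooling walker groups draw-major keeps the time
        ordering, so split-Rhat still detects residual drift (insufficient
        burn-in) while not penalising slow per-walker diffusion.
        """
        w = self.chain.shape[0]
        n_chains = min(n_chains, w)
        chains = []
        for g in range(n_chains):
            block = self.chain[g::n_chains, :, idx]  # (w/g, draws)
            chains.append(block.T.reshape(-1))  # draw-major
        m = min(len(c) for c in chains)
        return np.stack([c[:m] for c in chains])

    def _group_level_idata(self) -> az.InferenceData:
        G, P = self.model.n_groups, self.model.n_params
        data = {}
        for g, gname in enumerate(self.model.groups):
            for p, pname in enumerate(self.model.param_names):
                data[f"mu_{pname}_{gname}"] = self._pseudo_chains(g * P + p)
        for p, pname in enumerate(self.model.param_names):
            data[f"sigma_{pname}"] = np.exp(self._pseudo_chains(G * P + p))
        return az.from_dict(posterior=data)

    @property
    def diagnostics(self) -> pd.DataFrame:
        """Split-Rhat and bulk ESS per group-level parameter."""
        if self._diag is None:
            idata = self._group_level_idata()
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            rows = []
            for name in rhat.data_vars:
                rows.append(
                    {
                        "name": name,
                        "rhat": float(rhat[name].values),
                        "ess_bulk": float(ess[name].values),
                    }
                )
            self._diag = pd.DataFrame(rows)
        return self._diag

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())

    # -- summaries -------------------------------------------------------------

    def summary(self, hdi_mass: float = 0.95) -> pd.DataFrame:
        """Posterior summary of the group-level means (transformed and
        natural scales) with HDIs and convergence diagnostics."""
        rows = []
        diag = self.diagnostics.set_index("name")
        for pname in self.model.param_names:
            for gname in self.model.groups:
                d = self.mu_draws(pname, gname)
                lo, hi = hdi(d, hdi_mass)
                key = f"mu_{pname}_{gname}"
                rows.append(
                    {
                        "parameter": pname,
                        "group": gname,
                        "mean": float(np.mean(d)),
                        "sd": float(np.std(d)),
                        f"hdi{int(hdi_mass * 100)}_lo": lo,
                        f"hdi{int(hdi_mass * 100)}_hi": hi,
                        "mean_natural": float(np.mean(to_natural(pname, d))),
                        "rhat": float(diag.loc[key, "rhat"]),
                        "ess_bulk": float(diag.loc[key, "ess_bulk"]),
                    }
                )
        return pd.DataFrame(rows)

    def group_difference(self, parameter: str, treated: str, control: str) -> GroupContrast:
        """HDI-flagged contrast of group means (treated - control) on the
        transformed scale, matching how drug effects are reported."""
        a = self.mu_draws(parameter, treated)
        b = self.mu_draws(parameter, control)
        return GroupContrast(parameter, treated, control, a - b)

    def effect_table(self, control: str = "vehicle") -> pd.DataFrame:
        """All treated-vs-control contrasts with direction arrows and flags."""
        rows = []
        for pname in self.model.param_names:
            for g in self.model.groups:
                if g == control:
                    continue
                c = self.group_difference(pname, g, control)
                arrow = "-"
                if c.flag is not EvidenceFlag.NONE:
                    arrow = "↑" if c.mean > 0 else "↓"
                rows.append(
                    {
                        "parameter": pname,
                        "group": g,
                        "mean_diff": c.mean,
                        "hdi75_lo": c.hdi75[0],
                        "hdi75_hi": c.hdi75[1],
                        "hdi95_lo": c.hdi95[0],
                        "hdi95_hi": c.hdi95[1],
                        "flag": c.flag.value,
                        "direction": arrow,
                    }
                )
        return pd.DataFrame(rows)

    def subject_posterior_means(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters on the natural scale."""
        tr = self.model.subject_transformed(self.flat_draws())  # (N, S, P)
        rows = []
        for s, sid in enumerate(self.model.packed.subjects):
            row = {"subject_id": sid, "group_label": self.model.packed.groups[s]}
            for p, pname in enumerate(self.model.param_names):
                row[pname] = float(np.mean(to_natural(pname, tr[:, s, p])))
                row[f"{pname}_transformed"] = float(np.mean(tr[:, s, p]))
            rows.append(row)
        return pd.DataFrame(rows)

    def group_mean_params(self, group: str) -> AgentParams:
        """Posterior group means mapped to a natural-scale parameter vector
        (used for posterior-predictive simulation)."""
        vals = {}
        for pname in self.model.param_names:
            vals[pname] = float(to_natural(pname, np.mean(self.mu_draws(pname, group))))
        return AgentParams.from_free(self.spec, vals)

    def posterior_predictive_simulate(
        self,
        seed: int,
        n_per_group: int = 12,
        sessions_pre: int = 3,
        sessions_post: int = 14,
        max_trials: int = 200,
        stimulus_set: StimulusSet | None = None,
    ):
        """Simulate cohorts from the posterior group-mean parameters and
        score them with the conventional behavioural metrics.

        Returns ``(trials, metrics)``.
        """
        from .cohort import generate_cohort, CohortConfig
        from .metrics import conventional_metrics

        means = {
            g: {
                p: float(np.mean(self.mu_draws(p, g)))
                for p in self.model.param_names
            }
            for g in self.model.groups
        }
        cfg = CohortConfig(
            n_per_group=n_per_group,
            group_labels=tuple(self.model.groups),
            sessions_pre=sessions_pre,
            sessions_post=sessions_post,
            max_trials=max_trials,
            model=self.spec,
            group_means=means,
            group_sds={g: {p: 1e-9 for p in self.model.param_names} for g in self.model.groups},
            seed=seed,
        )
        trials, _ = generate_cohort(cfg)
        sset = stimulus_set if stimulus_set is not None else StimulusSet()
        metrics = conventional_metrics(trials, sset, reversal_session=sessions_pre + 1)
        return trials, metrics


def fit_hierarchical(
    trials: pd.DataFrame,
    spec: ModelSpec | int,
    priors: PriorConfig | None = None,
    **fit_kwargs,
) -> HierarchicalRLResults:
    """Functional facade: build a :class:`HierarchicalRLModel` and fit it."""
    return HierarchicalRLModel(trials, spec, priors=priors).fit(**fit_kwargs)
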