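"""Hierarchical Bayesian estimation of the RL model parameters.

Each participant i has an unconstrained parameter triple
theta_i = (theta_a+, theta_a-, theta_beta) drawn from a group-level
normal distribution, and the native-scale parameters are obtained by a
probit transform:

    alpha = Phi(theta_alpha)           in (0, 1)
    beta  = BETA_MAX * Phi(theta_beta) in (0, BETA_MAX)

    theta_ik ~ Normal(mu_k, sigma_k)
    mu_k     ~ Normal(0, 1)
    sigma_k  ~ half-Normal(s0_k),  s0 = (0.2, 0.2, 1.0)

Partial pooling through the group distribution shrinks improbable
individual estimates toward the group mean.

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme:
per-participant random-walk updates of each theta component (the
likelihood factorises over participants, so all participants are
updated in one vectorised pass), an exact conjugate Gibbs draw for each
group mean, and a slice-sampling update for each group scale. Because
60-trial sessions inform each participant only weakly, the centered
group updates alone mix poorly near the funnel (small group scales), so
each sweep additionally re-updates (mu_k, log sigma_k) in the
non-centered parameterization — holding the standardized individual
effects fixed and accepting against the likelihood — an
ancillarity-sufficiency interweaving step that decorrelates the group
parameters from the individual ones. Multiple independent chains are
run from jittered starting points; rank-normalized split R-hat and
effective sample sizes are computed with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .model import PROB_FLOOR, AgentParameters, session_log_likelihood
from .task import Session, TaskConfig

BETA_MAX = 10.0
_GROUP_SCALE_PRIOR = np.array([0.2, 0.2, 1.0])
PARAM_NAMES = ("alpha_pos", "alpha_neg", "beta")
_LOG_FLOOR = np.log(PROB_FLOOR)

__all__ = [
    "BETA_MAX",
    "PARAM_NAMES",
    "MCMCConfig",
    "PosteriorSummary",
    "ConvergenceWarning",
    "to_native",
    "from_native",
    "pack_sessions",
    "batch_log_likelihood",
    "fit_hierarchical",
    "fit_individual_map",
    "convergence_check",
    "posterior_predictive",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the configured threshold."""


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    thin: int = 1
    seed: int | None = None
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_samples, self.thin) < 1:
            raise ValueError("chain/warmup/sample/thin counts must be positive")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must exceed 1")


# ---------------------------------------------------------------------------
# parameter transforms


def to_native(raw) -> AgentParameters:
    """Map an unconstrained triple to native-scale parameters.

    Learning rates go through the standard-normal CDF; beta through the
    CDF scaled by ``BETA_MAX``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (3,):
        raise ValueError("expected an unconstrained triple")
    a_pos, a_neg = special.ndtr(raw[0]), special.ndtr(raw[1])
    beta = BETA_MAX * special.ndtr(raw[2])
    return AgentParameters(float(a_pos), float(a_neg), float(beta))


def from_native(params: AgentParameters) -> np.ndarray:
    """Inverse of :func:`to_native`; requires strictly interior values."""
    if not (0.0 < params.alpha_pos < 1.0 and 0.0 < params.alpha_neg < 1.0):
        raise ValueError("learning rates must be strictly inside (0, 1)")
    if not (0.0 < params.beta < BETA_MAX):
        raise ValueError(f"beta must be strictly inside (0, {BETA_MAX})")
    return np.array(
        [
            special.ndtri(params.alpha_pos),
            special.ndtri(params.alpha_neg),
            special.ndtri(params.beta / BETA_MAX),
        ]
    )


def _native_arrays(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised transform of stacked unconstrained triples (..., 3)."""
    return (
        special.ndtr(theta[..., 0]),
        special.ndtr(theta[..., 1]),
        BETA_MAX * special.ndtr(theta[..., 2]),
    )


# ---------------------------------------------------------------------------
# vectorised likelihood


def pack_sessions(
    sessions: list[Session], censor_nonresponse: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack sessions into (P, T) choice/outcome arrays plus a likelihood mask.

    Choices are coded A=0, B=1. All sessions must have equal length
    (the standard design fixes 60 trials). The mask flags trials that
    enter the likelihood sum; with ``censor_nonresponse`` the
    computer-selected non-response trials are masked out (their
    outcomes still drive value updates).
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    lengths = {len(s) for s in sessions}
    if 0 in lengths:
        raise ValueError("session with zero trials")
    if len(lengths) != 1:
        raise ValueError(f"sessions have unequal lengths: {sorted(lengths)}")
    T = lengths.pop()
    P = len(sessions)
    choices = np.zeros((P, T), dtype=np.int64)
    outcomes = np.zeros((P, T), dtype=float)
    mask = np.ones((P, T), dtype=bool)
    for i, s in enumerate(sessions):
        for j, rec in enumerate(s.trials):
            choices[i, j] = 0 if rec.choice == "A" else 1
            outcomes[i, j] = rec.outcome
            if censor_nonresponse and not rec.responded:
                mask[i, j] = False
    return choices, outcomes, mask


def batch_log_likelihood(
    choices: np.ndarray,
    outcomes: np.ndarray,
    mask: np.ndarray,
    a_pos: np.ndarray,
    a_neg: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Per-participant session log-likelihood, vectorised over participants.

    Numerically identical (up to the shared probability floor) to
    :func:`revlearn.model.session_log_likelihood` applied row by row.
    """
    P, T = choices.shape
    ev = np.zeros((P, 2))
    ll = np.zeros(P)
    rows = np.arange(P)
    for t in range(T):
        c = choices[:, t]
        sign = 1.0 - 2.0 * c  # +1 if A chosen, -1 if B
        x = sign * beta * (ev[:, 0] - ev[:, 1])
        log_p = -np.logaddexp(0.0, -x)  # log sigmoid(x)
        np.maximum(log_p, _LOG_FLOOR, out=log_p)
        ll += np.where(mask[:, t], log_p, 0.0)
        ev_c = ev[rows, c]
        pe = outcomes[:, t] - ev_c
        alpha = np.where(pe > 0, a_pos, a_neg)
        ev[rows, c] = ev_c + alpha * pe
    return ll


def _ll_kernel_py(choices, outcomes, mask, a_pos, a_neg, beta):
    P, T = choices.shape
    ll = np.zeros(P)
    for i in range(P):
        ev0 = 0.0
        ev1 = 0.0
        for t in range(T):
            c = choices[i, t]
            x = beta[i] * (ev0 - ev1)
            if c == 1:
                x = -x
            if x >= 0.0:
                lp = -np.log1p(np.exp(-x))
            else:
                lp = x - np.log1p(np.exp(x))
            if lp < _LOG_FLOOR:
                lp = _LOG_FLOOR
            if mask[i, t]:
                ll[i] += lp
            evc = ev0 if c == 0 else ev1
            pe = outcomes[i, t] - evc
            alpha = a_pos[i] if pe > 0.0 else a_neg[i]
            evc += alpha * pe
            if c == 0:
                ev0 = evc
            else:
                ev1 = evc
    return ll


try:  # compiled kernel keeps MCMC sweeps cheap; numpy path is equivalent
    import numba

    _ll_kernel = numba.njit(cache=True)(_ll_kernel_py)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _ll_kernel = _ll_kernel_py


def _theta_log_likelihood(data, theta: np.ndarray) -> np.ndarray:
    a_pos, a_neg, beta = _native_arrays(theta)
    choices, outcomes, mask = data
    return _ll_kernel(
        choices, outcomes, mask,
        np.ascontiguousarray(a_pos), np.ascontiguousarray(a_neg), np.ascontiguousarray(beta),
    )


# ---------------------------------------------------------------------------
# samplers


def _slice_sample(logpdf, x0: float, rng: np.random.Generator, w: float = 0.5) -> float:
    """One stepping-out slice-sampling update of a scalar density."""
    log_y = logpdf(x0) + np.log(rng.random())
    u = rng.random()
    left, right = x0 - u * w, x0 + (1.0 - u) * w
    for _ in range(100):
        if logpdf(left) <= log_y:
            break
        left -= w
    for _ in range(100):
        if logpdf(right) <= log_y:
            break
        right += w
    for _ in range(1000):
        x1 = rng.uniform(left, right)
        if logpdf(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep current point


def _run_chain(data, P: int, cfg: MCMCConfig, seed_seq: np.random.SeedSequence):
    """One MCMC chain; returns kept draws of theta (D,P,3), mu (D,3), sigma (D,3)."""
    rng = np.random.default_rng(seed_seq)
    s0 = _GROUP_SCALE_PRIOR

    # jittered overdispersed start
    mu = rng.normal(0.0, 0.5, size=3)
    sigma = np.abs(rng.normal(0.0, s0)) + 0.05
    theta = mu + sigma * rng.normal(size=(P, 3))
    cur_ll = _theta_log_likelihood(data, theta)

    step = np.full((P, 3), 0.4)  # per-participant, per-component RW scales
    group_step = np.full(3, 0.1)  # (mu, log sigma) joint proposals, per component
    n_sweeps = cfg.n_warmup + cfg.n_samples * cfg.thin
    keep_every = cfg.thin
    draws_theta = np.empty((cfg.n_samples, P, 3))
    draws_mu = np.empty((cfg.n_samples, 3))
    draws_sigma = np.empty((cfg.n_samples, 3))
    kept = 0

    for sweep in range(n_sweeps):
        # 1. per-participant random-walk Metropolis, one component at a time
        for k in range(3):
            prop = theta.copy()
            prop[:, k] = theta[:, k] + step[:, k] * rng.normal(size=P)
            prop_ll = _theta_log_likelihood(data, prop)
            log_prior_diff = (
                (theta[:, k] - mu[k]) ** 2 - (prop[:, k] - mu[k]) ** 2
            ) / (2.0 * sigma[k] ** 2)
            log_accept = prop_ll - cur_ll + log_prior_diff
            accept = np.log(rng.random(P)) < log_accept
            theta[accept, k] = prop[accept, k]
            cur_ll = np.where(accept, prop_ll, cur_ll)
            if sweep < cfg.n_warmup:
                gamma = (sweep + 1) ** -0.6
                step[:, k] *= np.exp(gamma * (accept.astype(float) - 0.44))

        # 2. conjugate Gibbs draw of each group mean (prior Normal(0, 1))
        for k in range(3):
            prec = 1.0 + P / sigma[k] ** 2
            mean = (theta[:, k].sum() / sigma[k] ** 2) / prec
            mu[k] = rng.normal(mean, np.sqrt(1.0 / prec))

        # 3. slice-sample each group scale on the log scale
        for k in range(3):
            resid_sq = np.sum((theta[:, k] - mu[k]) ** 2)

            def log_post(w, _rs=resid_sq, _k=k):
                s = np.exp(w)
                # half-Normal(s0) prior + normal likelihood of theta + log-Jacobian
                return (
                    -(s**2) / (2.0 * s0[_k] ** 2)
                    - P * w
                    - _rs / (2.0 * s**2)
                    + w
                )

            sigma[k] = np.exp(_slice_sample(log_post, np.log(sigma[k]), rng))

        # 4. interweaving: re-update each (sigma_k, mu_k) in the
        #    non-centered parameterization (standardized individual
        #    effects held fixed), so the group parameters can move
        #    through the funnel that the centered conditionals cannot
        #    traverse. The scale is slice-sampled on the log scale
        #    against the full likelihood; the mean gets an adaptive
        #    Metropolis step.
        for k in range(3):
            raw = (theta[:, k] - mu[k]) / sigma[k]
            base = theta  # current columns for the other components

            def log_post_w(w, _k=k, _raw=raw):
                prop = base.copy()
                prop[:, _k] = mu[_k] + np.exp(w) * _raw
                ll = _theta_log_likelihood(data, prop).sum()
                s = np.exp(w)
                return ll - s**2 / (2.0 * s0[_k] ** 2) + w

            w_new = _slice_sample(log_post_w, np.log(sigma[k]), rng)
            sigma[k] = np.exp(w_new)
            theta[:, k] = mu[k] + sigma[k] * raw
            cur_ll = _theta_log_likelihood(data, theta)

            mu_p = mu[k] + group_step[k] * rng.normal()
            prop = theta.copy()
            prop[:, k] = mu_p + sigma[k] * raw
            prop_ll = _theta_log_likelihood(data, prop)
            log_accept = prop_ll.sum() - cur_ll.sum() + 0.5 * (mu[k] ** 2 - mu_p**2)
            accepted = np.log(rng.random()) < log_accept
            if accepted:
                mu[k] = mu_p
                theta[:, k] = prop[:, k]
                cur_ll = prop_ll
            if sweep < cfg.n_warmup:
                gamma = (sweep + 1) ** -0.6
                group_step[k] *= np.exp(gamma * (float(accepted) - 0.44))

        if sweep >= cfg.n_warmup and (sweep - cfg.n_warmup + 1) % keep_every == 0:
            draws_theta[kept] = theta
            draws_mu[kept] = mu
            draws_sigma[kept] = sigma
            kept += 1

    return draws_theta[:kept], draws_mu[:kept], draws_sigma[:kept]


# ---------------------------------------------------------------------------
# posterior summary


@dataclass
class PosteriorSummary:
    """Per-participant and group-level posterior summaries with diagnostics.

    ``individual`` has one row per participant with posterior means and
    95% credible intervals on the native scale; ``group`` has one row
    per parameter with the group-level native-scale location (the probit
    transform of the group mean) and the unconstrained-scale scale.
    ``rhat``/``ess`` map variable names to arrays of diagnostics.
    """

    individual: pd.DataFrame
    group: pd.DataFrame
    rhat: dict[str, np.ndarray]
    ess: dict[str, np.ndarray]
    config: MCMCConfig
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def max_rhat(self) -> float:
        return float(max(np.max(v) for v in self.rhat.values()))

    def participant_parameters(self) -> list[AgentParameters]:
        return [
            AgentParameters(r.alpha_pos_mean, r.alpha_neg_mean, r.beta_mean)
            for r in self.individual.itertuples()
        ]


def fit_hierarchical(
    sessions: list[Session],
    mcmc: MCMCConfig | None = None,
    censor_nonresponse: bool = False,
) -> PosteriorSummary:
    """Fit the hierarchical model to a cohort of sessions by MCMC.

    Runs ``n_chains`` independent chains and summarises the pooled
    posterior. A :class:`ConvergenceWarning` (not an error) is emitted
    when any rank-normalized split R-hat reaches the configured
    threshold.
    """
    import arviz as az

    mcmc = mcmc or MCMCConfig()
    if len(sessions) < 2:
        raise ValueError("hierarchical fit needs at least 2 sessions")
    data = pack_sessions(sessions, censor_nonresponse=censor_nonresponse)
    P = len(sessions)

    seed_seqs = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    theta_c, mu_c, sigma_c = [], [], []
    for ss in seed_seqs:
        th, m, s = _run_chain(data, P, mcmc, ss)
        theta_c.append(th)
        mu_c.append(m)
        sigma_c.append(s)
    theta = np.stack(theta_c)  # (chains, draws, P, 3)
    mu = np.stack(mu_c)  # (chains, draws, 3)
    sigma = np.stack(sigma_c)

    a_pos, a_neg, beta = _native_arrays(theta)
    native = {"alpha_pos": a_pos, "alpha_neg": a_neg, "beta": beta}
    group_native = {
        "mu_alpha_pos": special.ndtr(mu[..., 0]),
        "mu_alpha_neg": special.ndtr(mu[..., 1]),
        "mu_beta": BETA_MAX * special.ndtr(mu[..., 2]),
    }
    group_sigma = {f"sigma_{n}": sigma[..., k] for k, n in enumerate(PARAM_NAMES)}

    posterior = {**native, **group_native, **group_sigma}
    idata = az.from_dict(posterior=posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz refactor chatter
        rhat_ds = az.rhat(idata, method="rank")
        ess_ds = az.ess(idata)
    rhat = {k: np.atleast_1d(np.asarray(rhat_ds[k])) for k in posterior}
    ess = {k: np.atleast_1d(np.asarray(ess_ds[k])) for k in posterior}

    ids = [s.participant_id for s in sessions]
    ind_rows = {"participant_id": ids}
    for name, arr in native.items():
        flat = arr.reshape(-1, P)
        ind_rows[f"{name}_mean"] = flat.mean(axis=0)
        ind_rows[f"{name}_ci_low"] = np.quantile(flat, 0.025, axis=0)
        ind_rows[f"{name}_ci_high"] = np.quantile(flat, 0.975, axis=0)
    individual = pd.DataFrame(ind_rows)

    grp_rows = []
    for k, name in enumerate(PARAM_NAMES):
        loc = group_native[f"mu_{name}"].ravel()
        sc = sigma[..., k].ravel()
        grp_rows.append(
            {
                "parameter": name,
                "group_mean": loc.mean(),
                "group_mean_ci_low": np.quantile(loc, 0.025),
                "group_mean_ci_high": np.quantile(loc, 0.975),
                "group_scale": sc.mean(),
                "group_scale_ci_low": np.quantile(sc, 0.025),
                "group_scale_ci_high": np.quantile(sc, 0.975),
            }
        )
    group = pd.DataFrame(grp_rows)

    summary = PosteriorSummary(
        individual=individual,
        group=group,
        rhat=rhat,
        ess=ess,
        config=mcmc,
        draws={"theta": theta, "mu": mu, "sigma": sigma, **native},
    )
    ok, offenders = convergence_check(summary, mcmc.rhat_threshold)
    if not ok:
        warnings.warn(
            f"R-hat >= {mcmc.rhat_threshold} for: {', '.join(offenders)}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return summary


def convergence_check(
    summary: PosteriorSummary, threshold: float | None = None
) -> tuple[bool, list[str]]:
    """Pass iff every sampled quantity's R-hat is below the threshold."""
    if not summary.rhat:
        raise ValueError("summary carries no R-hat diagnostics")
    threshold = threshold if threshold is not None else summary.config.rhat_threshold
    offenders = []
    for name, values in summary.rhat.items():
        values = np.atleast_1d(values)
        if np.any(~np.isfinite(values)):
            raise ValueError(f"missing/non-finite R-hat for {name}")
        for idx in np.nonzero(values >= threshold)[0]:
            label = name if values.size == 1 else f"{name}[{idx}]"
            offenders.append(label)
    return (len(offenders) == 0, offenders)


# ---------------------------------------------------------------------------
# non-hierarchical MAP cross-check


def fit_individual_map(
    session: Session,
    n_restarts: int = 10,
    seed: int | None = None,
    censor_nonresponse: bool = False,
    prior_scale: float = 1.0,
) -> tuple[AgentParameters, float]:
    """Per-participant MAP estimate with weakly-informative priors.

    Maximises the session log-likelihood plus independent
    Normal(0, prior_scale) priors on the unconstrained scale, over
    several random restarts; a large ``prior_scale`` approaches the
    (transform-bounded) maximum-likelihood estimate. Returns the best
    parameters and the attained log-posterior. Used as a
    non-hierarchical cross-check of the MCMC fit.
    """
    rng = np.random.default_rng(seed)

    def neg_log_post(raw: np.ndarray) -> float:
        ll = session_log_likelihood(session, to_native(raw), censor_nonresponse)
        return -(ll - 0.5 * float(raw @ raw) / prior_scale**2)

    best: tuple[float, np.ndarray] | None = None
    failures = 0
    for r in range(max(1, n_restarts)):
        x0 = np.zeros(3) if r == 0 else rng.normal(0.0, 1.0, size=3)
        res = optimize.minimize(neg_log_post, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if not res.success:
            failures += 1
            continue
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    if best is None:
        raise RuntimeError(f"MAP optimisation failed on all {failures} restarts")
    return to_native(best[1]), -best[0]


# ---------------------------------------------------------------------------
# posterior predictive


def posterior_predictive(
    summary: PosteriorSummary,
    config: TaskConfig | None = None,
    n_reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate sessions at posterior-mean parameters and summarise behaviour.

    Returns one row per participant x replicate with accuracy and
    achieved reversal count, for comparison with observed behaviour.
    """
    from .model import RLPolicy
    from .task import run_session, summarize_behavior

    config = config or TaskConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    params = summary.participant_parameters()
    ids = summary.individual["participant_id"].tolist()
    for (pid, p), ss in zip(zip(ids, params), root.spawn(len(params))):
        for rep, child in enumerate(ss.spawn(n_reps)):
            rng = np.random.default_rng(child)
            sess = run_session(RLPolicy(p, rng), config, participant_id=str(pid), rng=rng)
            b = summarize_behavior(sess)
            rows.append(
                {"participant_id": pid, "rep": rep,
                 "accuracy": b.accuracy, "n_reversals": b.n_reversals}
            )
    return pd.DataFrame(rows)
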