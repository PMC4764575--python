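"""Bayesian MCMC for the switching autoregressive sister-pair model.

Fits one paired trajectory at a time, sampling model parameters and the
hidden per-frame pair state path from the joint posterior
pi(a, b, c0, c+/-, s2, p, sigma | X).

Identifiability
---------------
Conditional on the state path, the displacement model is linear in the
drive and relaxation coefficients, but the design is exactly singular in
(c0, c_plus, c_minus): only the summed drives gamma+ = c0 + c_plus and
gamma- = c0 + c_minus enter the likelihood.  The sampler therefore works
in the identifiable parametrisation (gamma+, gamma-, a, b) — conjugate
multivariate-normal Gibbs draw with a Metropolis-Hastings correction for
the rest-length prior — and draws c0 from its exact conditional: a normal
density on the relaxed separation 2*c0/(b+a) truncated to the interval
(max(0, gamma-), gamma+) enforced by the sign constraints
c_plus > 0 > c_minus and c0 > 0.  The rest-length prior is what identifies
c0 (and hence c_plus, c_minus) — mirroring the role of the
nocodazole-derived rest length in the experimental analysis.

Hidden states are drawn either by an exact forward-filter/backward-sampling
pass (default) or by single-site Gibbs sweeps; both target the same
posterior (verified on an enumerable toy case), but single-site updates mix
slowly because direct transitions between the two coherent states have
probability zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from ._kernels import ffbs_draw, single_site_sweep
from .core import (SISTER1_PLUS, SISTER2_PLUS, ModelParams, PairedTrajectory,
                   is_coherent, transition_matrix)
from .events import point_state_estimate

__all__ = [
    "Priors", "ChainConfig", "ChainResult", "ConvergenceReport",
    "PosteriorSummary", "InferenceResult",
    "MIN_TRACK_FRAMES",
    "loglik_trajectory", "obs_loglik_matrix", "design_matrix",
    "update_linear_params", "update_noise_var", "update_switch_probs",
    "sample_state_path", "run_chain", "summarize_posterior",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("a", "b", "c0", "c_plus", "c_minus", "s2",
               "p_incoherent", "p_coherent")

#: Tracks shorter than this (75% of a 150-frame movie) are excluded.
MIN_TRACK_FRAMES = 112


@dataclass
class Priors:
    """Prior specification for the MCMC.

    The only informative prior is a normal density on the relaxed
    inter-sister separation 2*c0/(b+a) (rest length, nm); drives and
    relaxation coefficients otherwise carry flat priors subject to sign
    constraints, the switch probabilities Beta priors, and the noise
    variance a weakly-informative inverse-gamma.
    """

    rest_length_mean: float = 788.0
    rest_length_sd: float = 100.0
    s2_shape: float = 1.0      # inverse-gamma shape
    s2_scale: float = 1.0      # inverse-gamma scale (nm^2)
    switch_alpha: float = 1.0  # Beta(alpha, beta) on each switch probability
    switch_beta: float = 1.0

    def rest_length_logpdf(self, length: float) -> float:
        if not np.isfinite(self.rest_length_sd):
            return 0.0  # flat (improper over the constrained interval)
        z = (length - self.rest_length_mean) / self.rest_length_sd
        return -0.5 * z * z


def obs_loglik_matrix(traj: PairedTrajectory, params: ModelParams) -> np.ndarray:
    """Per-frame Gaussian log-likelihood of each of the 4 pair states,
    shape (n_steps, 4)."""
    dx1, dx2 = traj.displacements()
    x1t, x2t = traj.x1[:-1], traj.x2[:-1]
    base1 = params.c0 - params.a * x1t + params.b * x2t
    base2 = -params.c0 - params.a * x2t + params.b * x1t
    out = np.empty((traj.n_steps, 4))
    norm = np.log(2.0 * np.pi * params.s2)
    for j in range(4):
        c1 = params.drive(bool(SISTER1_PLUS[j]))
        c2 = params.drive(bool(SISTER2_PLUS[j]))
        r1 = dx1 - (base1 + c1)
        r2 = dx2 - (base2 - c2)
        out[:, j] = -(r1 * r1 + r2 * r2) / (2.0 * params.s2) - norm
    return out


def loglik_trajectory(traj: PairedTrajectory, path: np.ndarray,
                      params: ModelParams) -> float:
    """Observation log-likelihood of the trajectory given a state path."""
    path = np.asarray(path)
    if len(path) != traj.n_steps:
        raise ValueError("path length must equal the number of displacement steps")
    if params.s2 == 0.0:
        X, y = design_matrix(traj, path)
        beta = _gammas_from(params)
        resid = y - X @ beta
        if np.any(resid != 0.0):
            log.warning("s2 = 0 with nonzero residuals: log-likelihood is -inf")
            return -np.inf
        return np.inf
    L = obs_loglik_matrix(traj, params)
    return float(L[np.arange(len(path)), path].sum())


def design_matrix(traj: PairedTrajectory,
                  path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stacked linear system for (gamma+, gamma-, a, b) given the state path.

    Rows 0..n-1 are sister 1's displacements, rows n..2n-1 sister 2's.
    """
    path = np.asarray(path)
    n = traj.n_steps
    dx1, dx2 = traj.displacements()
    x1t, x2t = traj.x1[:-1], traj.x2[:-1]
    s1p = SISTER1_PLUS[path].astype(float)
    s2p = SISTER2_PLUS[path].astype(float)
    X = np.zeros((2 * n, 4))
    X[:n, 0] = s1p
    X[:n, 1] = 1.0 - s1p
    X[:n, 2] = -x1t
    X[:n, 3] = x2t
    X[n:, 0] = -s2p
    X[n:, 1] = -(1.0 - s2p)
    X[n:, 2] = -x2t
    X[n:, 3] = x1t
    y = np.concatenate([dx1, dx2])
    return X, y


def _gammas_from(params: ModelParams) -> np.ndarray:
    return np.array([params.c0 + params.c_plus, params.c0 + params.c_minus,
                     params.a, params.b])


def update_linear_params(traj: PairedTrajectory, path: np.ndarray,
                         current: ModelParams, priors: Priors,
                         rng: np.random.Generator, constrain: bool = True,
                         ) -> tuple[tuple[float, float, float, float, float],
                                    dict]:
    """Draw (a, b, c0, c_plus, c_minus) from their conditional posterior.

    Two sub-steps: an independence Metropolis-Hastings draw of the
    identifiable coefficients (gamma+, gamma-, a, b) from the conjugate
    normal conditional (accepted with probability given by the ratio of
    rest-length prior densities, rejected outright on sign-constraint
    violation), then an exact truncated-normal Gibbs draw of c0.

    Returns the new parameter tuple and an info dict with keys
    ``accepted`` and ``held`` (drive coefficients lacking data support are
    held at their current values).
    """
    X, y = design_matrix(traj, np.asarray(path))
    cur = _gammas_from(current)
    active = np.flatnonzero(np.abs(X).sum(axis=0) > 0.0)
    held = [i for i in range(4) if i not in active]
    info = {"accepted": False, "held": held}
    Xa = X[:, active]
    XtX = Xa.T @ Xa
    prop = cur.copy()
    try:
        XtXi = np.linalg.inv(XtX)
        beta_hat = XtXi @ (Xa.T @ y)
        cov = current.s2 * XtXi
        prop[active] = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    except np.linalg.LinAlgError:
        log.warning("singular design for linear-parameter update; holding values")
        info["held"] = list(range(4))
        return _assemble(cur, current.c0), info
    gp, gm, a, b = prop
    ok = a > 0 and b > 0
    if constrain:
        ok = ok and (gp > current.c0) and (gm < current.c0)
    if ok:
        new_len = 2.0 * current.c0 / (a + b)
        old_len = 2.0 * current.c0 / (cur[2] + cur[3])
        log_ratio = (priors.rest_length_logpdf(new_len)
                     - priors.rest_length_logpdf(old_len))
        if np.log(rng.random()) < log_ratio:
            info["accepted"] = True
            return _assemble(prop, current.c0), info
    return _assemble(cur, current.c0), info


def _assemble(gammas: np.ndarray, c0: float,
              ) -> tuple[float, float, float, float, float]:
    gp, gm, a, b = gammas
    return (a, b, c0, gp - c0, gm - c0)


def update_rest_length_c0(params_tuple: tuple, priors: Priors,
                          rng: np.random.Generator) -> float:
    """Exact Gibbs draw of c0 from the rest-length prior truncated to the
    sign-constraint interval (max(0, gamma-), gamma+)."""
    a, b, c0, c_plus, c_minus = params_tuple
    gp, gm = c0 + c_plus, c0 + c_minus
    lo, hi = max(0.0, gm), gp
    if not lo < hi:
        return c0
    if not np.isfinite(priors.rest_length_sd):
        return float(rng.uniform(lo, hi))
    mu = 0.5 * priors.rest_length_mean * (a + b)
    sd = 0.5 * priors.rest_length_sd * (a + b)
    eps = 1e-6 * (hi - lo)
    plo, phi = ndtr((lo - mu) / sd), ndtr((hi - mu) / sd)
    if phi - plo < 1e-14:
        # prior mass essentially outside the window: pin near the closest edge
        return lo + eps if mu < lo else hi - eps
    u = plo + rng.random() * (phi - plo)
    return float(np.clip(mu + sd * ndtri(u), lo + eps, hi - eps))


def update_noise_var(traj: PairedTrajectory, path: np.ndarray,
                     linear_params: tuple, priors: Priors,
                     rng: np.random.Generator) -> float:
    """Conjugate inverse-gamma draw of the noise variance from the residual
    sum of squares pooled over both sisters."""
    a, b, c0, c_plus, c_minus = linear_params
    X, y = design_matrix(traj, np.asarray(path))
    beta = np.array([c0 + c_plus, c0 + c_minus, a, b])
    resid = y - X @ beta
    rss = float(resid @ resid)
    shape = priors.s2_shape + 0.5 * len(resid)
    scale = priors.s2_scale + 0.5 * rss
    return float(scale / rng.gamma(shape, 1.0))


def update_switch_probs(path: np.ndarray, priors: Priors,
                        rng: np.random.Generator) -> tuple[float, float]:
    """Beta-conjugate draws of the per-frame switch probabilities.

    Opportunities are counted separately by the coherence class of the
    departing state; a class never visited draws from the prior.
    """
    path = np.asarray(path)
    frm, to = path[:-1], path[1:]
    coh = is_coherent(frm)
    switched = frm != to
    k_c, n_c = int(switched[coh].sum()), int(coh.sum())
    k_i, n_i = int(switched[~coh].sum()), int((~coh).sum())
    a0, b0 = priors.switch_alpha, priors.switch_beta
    p_coh = float(rng.beta(a0 + k_c, b0 + n_c - k_c))
    p_inc = float(rng.beta(a0 + k_i, b0 + n_i - k_i))
    return p_inc, p_coh


def sample_state_path(traj: PairedTrajectory, params: ModelParams,
                      current_path: np.ndarray | None,
                      rng: np.random.Generator,
                      method: str = "ffbs") -> np.ndarray:
    """Draw a hidden state path given the parameters.

    ``method="ffbs"`` draws exactly from the conditional path posterior;
    ``method="single_site"`` applies one in-place Gibbs sweep starting from
    ``current_path``.
    """
    logL = obs_loglik_matrix(traj, params)
    T4 = transition_matrix(params.p_incoherent, params.p_coherent)
    u = rng.random(traj.n_steps)
    if method == "ffbs":
        return ffbs_draw(logL, T4, u)
    if method == "single_site":
        if current_path is None:
            raise ValueError("single_site sweep requires a current path")
        path = np.array(current_path, dtype=np.int8, copy=True)
        single_site_sweep(path, logL, T4, u)
        return path
    raise ValueError(f"unknown state sampler {method!r}")


# ---------------------------------------------------------------------------
# chain driver

@dataclass
class ChainConfig:
    """MCMC run configuration (defaults sized so a single 150-frame
    trajectory fits in a few seconds)."""

    n_burn: int = 2000
    n_draws: int = 4000
    n_chains: int = 3
    state_sampler: str = "ffbs"      # or "single_site"
    sweeps_per_iter: int = 1         # single-site sweeps per iteration
    rhat_threshold: float = 1.1
    agreement_threshold: float = 0.9
    seed: int | None = None
    jitter_sd: float = 0.15          # log-scale dispersion of chain inits


@dataclass
class ChainResult:
    """Post-burn-in samples of one chain."""

    chain_id: int
    draws: dict[str, np.ndarray]
    state_counts: np.ndarray         # (n_steps, 4) post-burn-in tallies
    acceptance_rate: float
    log: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.draws["a"])

    @property
    def state_marginals(self) -> np.ndarray:
        tot = self.state_counts.sum(axis=1, keepdims=True)
        return self.state_counts / np.maximum(tot, 1)

    @property
    def modal_path(self) -> np.ndarray:
        return point_state_estimate(self.state_marginals)


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    state_agreement: float
    converged: bool
    rhat_threshold: float
    agreement_threshold: float


@dataclass
class PosteriorSummary:
    mean: dict[str, float]
    sd: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    state_marginals: np.ndarray

    @property
    def modal_path(self) -> np.ndarray:
        return point_state_estimate(self.state_marginals)


@dataclass
class InferenceResult:
    chains: list[ChainResult]
    report: ConvergenceReport
    summary: PosteriorSummary

    @property
    def excluded(self) -> bool:
        return not self.report.converged


def _heuristic_path(traj: PairedTrajectory) -> np.ndarray:
    """Initial state path from 3-frame smoothed residuals of a state-free
    AR fit.

    A first regression with a single intercept per sister absorbs the
    baseline drive and relaxation; the residual sign then reflects the
    switching drive component (positive residual = polymerising for
    sister 1, mirrored for sister 2).
    """
    dx1, dx2 = traj.displacements()
    x1t, x2t = traj.x1[:-1], traj.x2[:-1]
    n = traj.n_steps
    X = np.zeros((2 * n, 3))
    X[:n, 0], X[n:, 0] = 1.0, -1.0
    X[:n, 1], X[n:, 1] = -x1t, -x2t
    X[:n, 2], X[n:, 2] = x2t, x1t
    y = np.concatenate([dx1, dx2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if n >= 3:
        kern = np.ones(3) / 3.0
        r1 = np.convolve(resid[:n], kern, mode="same")
        r2 = np.convolve(resid[n:], kern, mode="same")
    else:
        r1, r2 = resid[:n], resid[n:]
    s1p = r1 > 0
    s2p = r2 < 0
    return ((~s1p).astype(np.int8) * 2 + (~s2p).astype(np.int8))


def _init_params(traj: PairedTrajectory, path: np.ndarray, priors: Priors,
                 rng: np.random.Generator, jitter_sd: float) -> ModelParams:
    X, y = design_matrix(traj, path)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    gp, gm, a, b = beta
    j = np.exp(rng.normal(0.0, jitter_sd, size=6))
    a = max(a, 1e-4) * j[0]
    b = max(b, 1e-4) * j[1]
    gp = max(gp, 1.0) * j[2]
    gm = min(gm, gp - 1.0)
    lo, hi = max(0.0, gm), gp
    c0 = np.clip(0.5 * priors.rest_length_mean * (a + b),
                 lo + 0.01 * (hi - lo), hi - 0.01 * (hi - lo))
    resid = y - X @ beta
    s2 = max(float(resid @ resid) / max(len(resid) - 4, 1), 1e-3) * j[3]
    p_inc = float(np.clip(0.3 * j[4], 1e-3, 0.99))
    p_coh = float(np.clip(0.08 * j[5], 1e-3, 0.99))
    return ModelParams(a=a, b=b, c0=float(c0), c_plus=gp - c0, c_minus=gm - c0,
                       s2=s2, p_incoherent=p_inc, p_coherent=p_coh, dt=traj.dt)


def _run_single_chain(traj: PairedTrajectory, priors: Priors,
                      config: ChainConfig, chain_id: int,
                      rng: np.random.Generator) -> ChainResult:
    path = _heuristic_path(traj)
    params = _init_params(traj, path, priors, rng, config.jitter_sd)
    n_iter = config.n_burn + config.n_draws
    draws = {k: np.empty(config.n_draws) for k in PARAM_NAMES}
    counts = np.zeros((traj.n_steps, 4), dtype=np.int64)
    n_acc = 0
    chain_log: list[str] = []
    for it in range(n_iter):
        if config.state_sampler == "ffbs":
            path = sample_state_path(traj, params, path, rng, "ffbs")
        else:
            for _ in range(config.sweeps_per_iter):
                path = sample_state_path(traj, params, path, rng, "single_site")
        p_inc, p_coh = update_switch_probs(path, priors, rng)
        lin, info = update_linear_params(traj, path, params, priors, rng)
        c0 = update_rest_length_c0(lin, priors, rng)
        lin = (lin[0], lin[1], c0, lin[3] + lin[2] - c0, lin[4] + lin[2] - c0)
        s2 = update_noise_var(traj, path, lin, priors, rng)
        params = ModelParams(a=lin[0], b=lin[1], c0=lin[2], c_plus=lin[3],
                             c_minus=lin[4], s2=s2, p_incoherent=p_inc,
                             p_coherent=p_coh, dt=traj.dt)
        if info["held"]:
            chain_log.append(f"iter {it}: held coefficients {info['held']}")
        if it >= config.n_burn:
            n_acc += info["accepted"]
            k = it - config.n_burn
            for name, val in zip(PARAM_NAMES,
                                 (params.a, params.b, params.c0,
                                  params.c_plus, params.c_minus, params.s2,
                                  params.p_incoherent, params.p_coherent)):
                draws[name][k] = val
            counts[np.arange(traj.n_steps), path] += 1
    return ChainResult(chain_id=chain_id, draws=draws, state_counts=counts,
                       acceptance_rate=n_acc / max(config.n_draws, 1),
                       log=chain_log)


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-free version)."""
    halves = []
    for row in chains_draws:
        h = len(row) // 2
        halves.extend([row[:h], row[h:2 * h]])
    x = np.asarray(halves, dtype=float)
    m, n = x.shape
    if n < 2:
        return np.inf
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    bn = means.var(ddof=1)
    if w <= 0:
        return 1.0 if bn <= 0 else np.inf
    var_hat = (n - 1) / n * w + bn
    return float(np.sqrt(var_hat / w))


def assess_convergence(chains: list[ChainResult],
                       config: ChainConfig) -> ConvergenceReport:
    rhat = {}
    for name in PARAM_NAMES:
        arr = np.stack([c.draws[name] for c in chains])
        rhat[name] = _split_rhat(arr)
    modal = np.stack([c.modal_path for c in chains])
    agreement = float((modal == modal[0]).all(axis=0).mean())
    converged = (all(r < config.rhat_threshold for r in rhat.values())
                 and agreement >= config.agreement_threshold)
    return ConvergenceReport(rhat=rhat, state_agreement=agreement,
                             converged=converged,
                             rhat_threshold=config.rhat_threshold,
                             agreement_threshold=config.agreement_threshold)


def summarize_posterior(chains: list[ChainResult]) -> PosteriorSummary:
    """Pooled post-burn-in posterior summaries and per-frame state marginals."""
    if not chains:
        raise ValueError("summarize_posterior requires at least one chain")
    mean, sd, lo, hi = {}, {}, {}, {}
    for name in PARAM_NAMES:
        pooled = np.concatenate([c.draws[name] for c in chains])
        mean[name] = float(pooled.mean())
        sd[name] = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
        lo[name] = float(np.quantile(pooled, 0.025))
        hi[name] = float(np.quantile(pooled, 0.975))
    counts = np.sum([c.state_counts for c in chains], axis=0)
    marg = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
    return PosteriorSummary(mean=mean, sd=sd, ci_low=lo, ci_high=hi,
                            state_marginals=marg)


def run_chain(traj: PairedTrajectory, priors: Priors | None = None,
              config: ChainConfig | None = None,
              enforce_min_length: bool = True) -> InferenceResult:
    """Run independent MCMC chains on one trajectory and assess convergence.

    Non-convergence is not an error: the result is flagged ``excluded`` and
    downstream cohort analyses drop the trajectory, mirroring the exclusion
    of weakly oscillatory tracks whose chains fail to agree.
    """
    priors = priors or Priors()
    config = config or ChainConfig()
    if enforce_min_length and len(traj) < MIN_TRACK_FRAMES:
        raise ValueError(
            f"trajectory has {len(traj)} frames; inference requires "
            f">= {MIN_TRACK_FRAMES} consecutive frames")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_single_chain(traj, priors, config, i, np.random.default_rng(s))
        for i, s in enumerate(seeds)
    ]
    if config.n_chains > 1 or config.n_draws >= 4:
        report = assess_convergence(chains, config)
    else:
        report = ConvergenceReport(rhat={}, state_agreement=np.nan,
                                   converged=False,
                                   rhat_threshold=config.rhat_threshold,
                                   agreement_threshold=config.agreement_threshold)
    return InferenceResult(chains=chains, report=report,
                           summary=summarize_posterior(chains))
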