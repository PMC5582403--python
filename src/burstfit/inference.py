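"""Metropolis random-walk sampling of the parameter posterior.

The posterior is the multinomial snapshot likelihood times a flat prior with
hard physiological bounds (a Heaviside box): parameters may not fall below a
small positive floor, and transcription rates are capped at a maximum
consistent with polymerase traffic on a single gene.  The marginal evidence
P(Y) is never computed — it cancels in the Metropolis ratio — so reported
posterior values are unnormalized log-posteriors.

Proposals are multivariate-normal steps on the linear parameter scale with a
fixed diagonal covariance; the chain records every step's parameter vector,
log-likelihood, and acceptance flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .likelihood import SnapshotDataset, log_likelihood
from .model import ParameterSet, StateSpace

__all__ = [
    "PriorSpec",
    "Chain",
    "default_sigma",
    "log_prior",
    "propose",
    "metropolis_run",
    "detect_burn_in",
    "posterior_summary",
    "random_init",
]

#: proposal variance per free component, keyed by base parameter name
DEFAULT_PROPOSAL_VARIANCES = {"k1": 1e-5, "k0": 1e-5, "mu0": 1e-5, "mu1": 1e-3}


@dataclass(frozen=True)
class PriorSpec:
    """Flat prior with Heaviside bounds.

    ``lower_bound`` marks values that are effectively negative
    (non-physiological); ``mu_max`` caps the transcription rates (mRNA/min),
    reflecting the maximum polymerase initiation traffic on one gene —
    plausible values sit in the 12–18 range.  ``mu_params`` lists the base
    parameter names the cap applies to.
    """

    lower_bound: float = 1e-8
    mu_max: float = 18.0
    mu_params: tuple[str, ...] = ("mu0", "mu1")

    def __post_init__(self) -> None:
        if self.lower_bound < 0 or self.mu_max <= self.lower_bound:
            raise ValueError("require 0 <= lower_bound < mu_max")

    def upper_for(self, component: str) -> float:
        base = component[:-2] if component.endswith(("_U", "_S")) else component
        return self.mu_max if base in self.mu_params else np.inf


@dataclass
class Chain:
    """A Metropolis trace: one row per iteration.

    ``thetas`` is T x m over the free-parameter components (order given by
    ``free_names``); ``loglik`` stores the full multinomial log-likelihood of
    the state at each iteration (not the proposal).
    """

    thetas: np.ndarray
    loglik: np.ndarray
    accepted: np.ndarray
    free_names: tuple[str, ...]
    sigma: np.ndarray
    seed: int
    burn_in_index: int = 0
    loglik_fn: Callable[[np.ndarray], float] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.thetas.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def post_burn_in(self) -> tuple[np.ndarray, np.ndarray]:
        """(thetas, loglik) with the burn-in segment removed."""
        return self.thetas[self.burn_in_index:], self.loglik[self.burn_in_index:]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thetas, columns=list(self.free_names))
        df.insert(0, "iteration", np.arange(len(self)))
        df["loglik"] = self.loglik
        df["accepted"] = self.accepted.astype(int)
        return df


def default_sigma(free_names: Sequence[str]) -> np.ndarray:
    """Diagonal proposal covariance matching the free-parameter ordering."""
    diag = []
    for comp in free_names:
        base = comp[:-2] if comp.endswith(("_U", "_S")) else comp
        diag.append(DEFAULT_PROPOSAL_VARIANCES.get(base, 1e-5))
    return np.diag(diag)


def log_prior(theta_free: np.ndarray, free_names: Sequence[str], prior: PriorSpec) -> float:
    """0 inside the Heaviside box, -inf outside."""
    for val, comp in zip(np.asarray(theta_free, dtype=float), free_names):
        if val < prior.lower_bound or val > prior.upper_for(comp):
            return -np.inf
    return 0.0


class _Proposer:
    """Multivariate-normal random-walk proposals with a fixed covariance."""

    def __init__(self, sigma: np.ndarray, rng: np.random.Generator):
        sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
        try:
            root = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # PSD but singular (e.g., a zero diagonal entry): eigh-based root
            evals, evecs = np.linalg.eigh(sigma)
            if evals.min() < -1e-12 * max(1.0, evals.max()):
                raise ValueError("proposal covariance must be positive semi-definite")
            root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        self._chol = root
        self.sigma = sigma
        self.rng = rng

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        z = self.rng.standard_normal(theta.shape[0])
        return theta + self._chol @ z


def propose(theta_free: np.ndarray, sigma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random-walk proposal theta + N(0, sigma) on the linear scale."""
    return _Proposer(sigma, rng)(np.asarray(theta_free, dtype=float))


def random_init(
    params: ParameterSet,
    prior: PriorSpec,
    rng: np.random.Generator,
    *,
    rate_init_max: float = 1.0,
    basal_init_max: float = 0.5,
) -> ParameterSet:
    """Draw a random starting point uniformly within initialization ranges.

    The active-state transcription rate is drawn up to the prior cap
    ``mu_max``; the basal rate mu0 only up to ``basal_init_max`` (the off
    state is by definition the low-synthesis state — starting it high puts
    the chain in the label-swapped mirror mode, which small-step proposals
    cannot leave); switching rates, whose prior is unbounded above, are
    drawn up to ``rate_init_max`` (switching much faster than the sampling
    interval is not resolvable, so larger starts only add burn-in).
    """
    vec = []
    for comp in params.free_names:
        base = comp[:-2] if comp.endswith(("_U", "_S")) else comp
        hi = prior.upper_for(comp)
        if base == "mu0":
            hi = min(hi, basal_init_max)
        elif not np.isfinite(hi):
            hi = rate_init_max
        vec.append(rng.uniform(prior.lower_bound, hi))
    return params.with_free_vector(np.array(vec))


def moment_init(
    data: SnapshotDataset,
    params: ParameterSet,
    prior: PriorSpec | None = None,
) -> ParameterSet:
    """Method-of-moments starting point for the two-state model family.

    Closed-form estimates from simple summary statistics:

    * the active-TS fraction at t = 0 and at the last time point estimate
      the pre- and post-stimulus burst fractions p = k1 / (k1 + k0);
    * the relaxation of the TS fraction over the first post-stimulus
      interval estimates the switching speed k1^S + k0;
    * the pre-stimulus mRNA mean and the extrapolated post-stimulus
      steady-state mean give two linear equations for (mu0, mu1).

    Estimates are clamped into the prior box.  This is only a starting
    point — the sampler owns the posterior — but it removes most of the
    burn-in that a blind random start would need.
    """
    if prior is None:
        prior = PriorSpec()
    model = params.model
    delta = params.values_U["delta"]
    n_all = model.n_alleles

    def _means(table) -> tuple[float, float]:
        n = sum(table.values())
        ts = sum(s * c for (s, _), c in table.items()) / n
        mr = sum(mm * c for (_, mm), c in table.items()) / n
        return ts, mr

    eps = 1e-3
    ts0, m0 = _means(data.counts[0])
    tsl, ml = _means(data.counts[-1])
    pU = float(np.clip(ts0 / n_all, eps, 1 - eps))
    pS = float(np.clip(tsl / n_all, eps, 1 - eps))

    # switching speed from the first post-stimulus TS fraction
    rate = 0.5
    if len(data.time_points) > 2:
        t1 = data.time_points[1]
        ts1, _ = _means(data.counts[1])
        p1 = float(np.clip(ts1 / n_all, eps, 1 - eps))
        if abs(pS - pU) > 5 * eps:
            frac = (pS - p1) / (pS - pU)
            if 0 < frac < 1:
                rate = -np.log(np.clip(frac, 1e-3, 0.999)) / t1
    rate = float(np.clip(rate, 0.02, 2.0))
    k0_est = rate * (1 - pS)
    k1S_est = rate * pS
    k1U_est = k0_est * pU / (1 - pU)

    # post-stimulus steady-state mRNA mean, extrapolated from the last two times
    m_inf = ml
    if len(data.time_points) > 2:
        t_prev, t_last = data.time_points[-2], data.time_points[-1]
        _, m_prev = _means(data.counts[-2])
        decay = np.exp(-delta * (t_last - t_prev))
        if decay < 0.999:
            m_inf = (ml - m_prev * decay) / (1 - decay)
    m_inf = float(np.clip(m_inf, ml, n_all * prior.mu_max / delta))

    # per-allele synthesis balance at the two quasi-steady states
    det = pS - pU
    if abs(det) > 5 * eps:
        rhs = np.array([delta * m0 / n_all, delta * m_inf / n_all])
        mat = np.array([[1 - pU, pU], [1 - pS, pS]])
        mu0_est, mu1_est = np.linalg.solve(mat, rhs)
    else:
        mu0_est = delta * m0 / n_all
        mu1_est = delta * m_inf / (n_all * pS)

    lo = max(prior.lower_bound * 10, 1e-6)
    mu_hi = prior.mu_max * 0.95

    def _clampmu(x: float) -> float:
        return float(np.clip(x, lo, mu_hi))

    mu0_est = _clampmu(mu0_est)
    mu1_est = max(_clampmu(mu1_est), mu0_est)

    est_U = {"k1": max(k1U_est, lo), "k0": max(k0_est, lo),
             "mu0": mu0_est, "mu1": mu1_est, "delta": delta}
    est_S = dict(est_U)
    if "k1" in model.stimulus_params:
        est_S["k1"] = max(k1S_est, lo)
    if "k0" in model.stimulus_params:
        # pre-stimulus deactivation consistent with the shared activation rate
        est_U["k0"] = max(est_U["k1"] * (1 - pU) / pU, lo)
        est_S["k0"] = max(k0_est, lo)
    if "mu1" in model.stimulus_params:
        est_U["mu1"] = max(_clampmu((delta * m0 / n_all - mu0_est * (1 - pU)) / pU),
                           mu0_est)
        est_S["mu1"] = max(_clampmu((delta * m_inf / n_all - mu0_est * (1 - pS)) / pS),
                           mu0_est)
    if "mu0" in model.stimulus_params:
        est_S["mu0"] = est_S["mu0"]

    vu, vs = dict(params.values_U), dict(params.values_S)
    for name in model.parameter_names:
        if name in params.fixed:
            continue
        vu[name] = est_U[name]
        vs[name] = est_S[name] if name in model.stimulus_params else est_U[name]
    return ParameterSet(model, vu, vs, params.fixed)


def find_finite_init(
    data: SnapshotDataset,
    params: ParameterSet,
    space: StateSpace,
    prior: PriorSpec,
    rng: np.random.Generator,
    *,
    rate_init_max: float = 2.0,
    max_tries: int = 200,
) -> ParameterSet:
    """Random starting point with a finite log-posterior.

    Repeatedly draws :func:`random_init` candidates until the data have
    nonzero probability under the candidate (starting points far into the
    tails make some observed state numerically impossible and are useless
    as chain seeds).
    """
    for _ in range(max_tries):
        cand = random_init(params, prior, rng, rate_init_max=rate_init_max)
        if np.isfinite(log_likelihood(data, cand, space)):
            return cand
    raise RuntimeError(
        f"no finite-posterior starting point found in {max_tries} draws; "
        "check the data against the model/state space"
    )


def metropolis_run(
    data: SnapshotDataset,
    init: ParameterSet,
    space: StateSpace,
    *,
    prior: PriorSpec | None = None,
    sigma: np.ndarray | None = None,
    T: int = 100_000,
    seed: int = 0,
    progress: bool = False,
) -> Chain:
    """Sample the posterior by the Metropolis random walk.

    Each iteration draws phi ~ theta_t + N(0, Sigma), evaluates the
    log-posterior, and accepts with probability min(exp(delta), 1) computed
    in log space; rejected proposals repeat the current state.  Proposals
    outside the prior box are rejected without evaluating the likelihood.
    The run is fully reproducible from ``seed``.
    """
    if prior is None:
        prior = PriorSpec()
    free_names = init.free_names
    m = len(free_names)
    if sigma is None:
        sigma = default_sigma(free_names)
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if sigma.shape != (m, m):
        raise ValueError(f"sigma must be {m}x{m} for {m} free parameters")

    rng = np.random.default_rng(seed)
    proposer = _Proposer(sigma, rng)

    def loglik_of(vec: np.ndarray) -> float:
        return log_likelihood(data, init.with_free_vector(vec), space)

    theta = init.to_free_vector()
    lp = log_prior(theta, free_names, prior)
    ll = loglik_of(theta) if np.isfinite(lp) else -np.inf
    if not np.isfinite(lp + ll):
        raise ValueError(
            "initial parameters have non-finite log-posterior; choose a "
            "different starting point (e.g., random_init)"
        )

    thetas = np.empty((T, m))
    logliks = np.empty(T)
    accepted = np.zeros(T, dtype=bool)
    iterator = range(T)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="metropolis")
        except ImportError:
            pass
    for t in iterator:
        phi = proposer(theta)
        lp_phi = log_prior(phi, free_names, prior)
        if np.isfinite(lp_phi):
            ll_phi = loglik_of(phi)
            delta = (lp_phi + ll_phi) - (lp + ll)
            if delta >= 0 or np.log(rng.random()) < delta:
                theta, lp, ll = phi, lp_phi, ll_phi
                accepted[t] = True
        thetas[t] = theta
        logliks[t] = ll

    if not accepted.any():
        raise RuntimeError(
            "no proposal was accepted; the proposal covariance is likely too "
            "large for this posterior — try a smaller sigma"
        )
    chain = Chain(
        thetas=thetas,
        loglik=logliks,
        accepted=accepted,
        free_names=free_names,
        sigma=sigma,
        seed=seed,
        loglik_fn=loglik_of,
    )
    chain.burn_in_index = detect_burn_in(chain)
    rate = chain.accepted[chain.burn_in_index:].mean()
    if not 0.05 <= rate <= 0.6:
        warnings.warn(
            f"post-burn-in acceptance rate {rate:.3f} outside [0.05, 0.6]; "
            "consider adjusting the proposal covariance",
            RuntimeWarning,
            stacklevel=2,
        )
    return chain


def maximize_likelihood(
    data: SnapshotDataset,
    start: ParameterSet,
    space: StateSpace,
    prior: PriorSpec | None = None,
    *,
    maxfev: int = 1500,
) -> tuple[ParameterSet, float]:
    """Approximate maximum-likelihood fit by Nelder-Mead in log-parameter space.

    Working on log rates keeps every proposal positive and puts rates
    spanning orders of magnitude on a common scale.  Points outside the
    prior box are assigned infinite cost.  Returns the fitted parameters
    and their log-likelihood.
    """
    from scipy.optimize import minimize

    if prior is None:
        prior = PriorSpec()
    caps = np.array([prior.upper_for(c) for c in start.free_names])
    x0 = np.maximum(start.to_free_vector(), prior.lower_bound * 10)

    def nll(z: np.ndarray) -> float:
        x = np.exp(z)
        if np.any(x > caps) or np.any(x < prior.lower_bound):
            return np.inf
        ll = log_likelihood(data, start.with_free_vector(x), space)
        return -ll if np.isfinite(ll) else np.inf

    res = minimize(
        nll, np.log(x0), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-4, "maxfev": maxfev},
    )
    best = start.with_free_vector(np.exp(res.x))
    return best, -float(res.fun)


def laplace_proposal_sigma(
    data: SnapshotDataset,
    mode: ParameterSet,
    space: StateSpace,
) -> np.ndarray:
    """Diagonal proposal covariance calibrated to the posterior curvature.

    Central-difference curvature of -ln L at the (approximate) mode gives a
    Laplace estimate of each marginal posterior scale; the proposal standard
    deviation is set to 2.4/sqrt(m) of that scale, the classic random-walk
    Metropolis scaling.  Components with non-positive curvature (flat or
    noisy directions) fall back to the default step.  The covariance is
    fixed before sampling starts — the recorded chain itself is plain
    Metropolis.
    """
    x = mode.to_free_vector()
    m = x.size
    f0 = -log_likelihood(data, mode, space)
    var = np.empty(m)
    for j, comp in enumerate(mode.free_names):
        h = max(1e-3 * x[j], 1e-6)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 1e-12)
        fp = -log_likelihood(data, mode.with_free_vector(xp), space)
        fm = -log_likelihood(data, mode.with_free_vector(xm), space)
        curv = (fp - 2 * f0 + fm) / h**2
        if np.isfinite(curv) and curv > 0:
            var[j] = (2.4 / np.sqrt(m)) ** 2 / curv
        else:
            base = comp[:-2] if comp.endswith(("_U", "_S")) else comp
            var[j] = DEFAULT_PROPOSAL_VARIANCES.get(base, 1e-5)
    return np.diag(var)


def fit_mcmc(
    data: SnapshotDataset,
    params: ParameterSet,
    space: StateSpace,
    *,
    prior: PriorSpec | None = None,
    T: int = 100_000,
    seed: int = 0,
    sigma: np.ndarray | str = "auto",
    init: ParameterSet | str = "auto",
    init_jitter: float = 0.0,
    progress: bool = False,
) -> Chain:
    """Full fitting pipeline: initialize, calibrate the proposal, sample.

    ``init="auto"`` builds a method-of-moments starting point and polishes
    it to the approximate maximum-likelihood fit; ``sigma="auto"``
    calibrates the proposal covariance there (:func:`laplace_proposal_sigma`).
    ``init_jitter`` multiplies the starting point by lognormal noise of the
    given relative scale — used to give replica chains distinct
    initializations.
    """
    if prior is None:
        prior = PriorSpec()
    rng = np.random.default_rng(seed)
    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"unknown init mode {init!r}")
        start = moment_init(data, params, prior)
        if not np.isfinite(log_likelihood(data, start, space)):
            start = find_finite_init(data, params, space, prior, rng)
        start, _ = maximize_likelihood(data, start, space, prior)
    else:
        start = init
    if init_jitter > 0:
        jittered = start.to_free_vector() * np.exp(
            init_jitter * rng.standard_normal(len(start.free_names))
        )
        caps = np.array([prior.upper_for(c) for c in start.free_names])
        jittered = np.clip(jittered, prior.lower_bound * 2, caps * 0.999)
        start = start.with_free_vector(jittered)
    if isinstance(sigma, str):
        if sigma != "auto":
            raise ValueError(f"unknown sigma mode {sigma!r}")
        sigma = laplace_proposal_sigma(data, start, space)
    return metropolis_run(
        data, start, space, prior=prior, sigma=sigma, T=T, seed=seed, progress=progress
    )


def detect_burn_in(chain: Chain) -> int:
    """First iteration whose log-likelihood is within 0.5% of the maximum.

    Burn-in is the initial climb of the log-likelihood toward its plateau;
    it ends at the first index t with ``loglik_t >= L_max - 0.005 |L_max|``.
    If that would discard more than half the chain (or the band is never
    entered), T/2 is used with a warning.
    """
    ll = chain.loglik
    T = len(ll)
    if T < 2:
        return 0
    l_max = float(np.max(ll))
    threshold = l_max - 0.005 * abs(l_max)
    hits = np.nonzero(ll >= threshold)[0]
    if hits.size == 0:
        warnings.warn("burn-in rule never satisfied; using T/2", RuntimeWarning, stacklevel=2)
        return T // 2
    idx = int(hits[0])
    if idx > T // 2:
        warnings.warn(
            f"burn-in rule selects index {idx} > T/2; capping at T/2",
            RuntimeWarning,
            stacklevel=2,
        )
        return T // 2
    return idx


def posterior_summary(chain: Chain, bins: int = 50) -> pd.DataFrame:
    """Posterior mean, sd, central 95% interval, and histogram per parameter.

    Computed on post-burn-in samples only.
    """
    thetas, _ = chain.post_burn_in()
    if thetas.shape[0] == 0:
        raise ValueError("no post-burn-in samples to summarize")
    rows = []
    for j, name in enumerate(chain.free_names):
        x = thetas[:, j]
        lo, hi = np.percentile(x, [2.5, 97.5])
        hist, edges = np.histogram(x, bins=bins)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "ci95_low": float(lo),
                "ci95_high": float(hi),
                "hist_counts": hist,
                "hist_edges": edges,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
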