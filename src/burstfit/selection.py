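"""Information-criterion scoring and ranking of parameter-stimulus models.

BIC and AICc are computed from the maximum log-likelihood seen during a
sampling run; DIC uses the posterior deviance over the post-burn-in segment.
The sample size n is, by default, the total number of cells across all time
points (each cell is one multinomial draw); a per-time-point convention can
be selected where a different accounting is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import Chain
from .model import ModelSpec, ParameterSet, build_two_state_model

__all__ = [
    "ICResult", "bic", "aicc", "dic", "score_chain", "compare_models",
    "candidate_parameter_sets", "winner",
]

#: stimulus hypotheses screened by default: which parameters the stimulus touches
DEFAULT_STIMULUS_SUBSETS = (
    ("k1",), ("k0",), ("mu1",), ("k1", "mu1"), ("k0", "mu1"), ("k1", "k0", "mu1"),
)


def candidate_parameter_sets(
    delta: float,
    subsets=DEFAULT_STIMULUS_SUBSETS,
    n_alleles: int = 2,
) -> dict[str, ParameterSet]:
    """Template parameter sets for a panel of parameter-stimulus hypotheses.

    Each candidate shares the two-state reaction system and the fixed
    degradation rate; they differ only in which kinetic parameters switch
    value at induction.  Starting values are placeholders — fitting replaces
    them.
    """
    base = build_two_state_model(n_alleles)
    start = {"k1": 0.1, "k0": 0.1, "mu0": 0.05, "mu1": 1.0, "delta": delta}
    out = {}
    for subset in subsets:
        name = "+".join(subset) + "_stim"
        model = ModelSpec(
            n_alleles=n_alleles,
            reactions=base.reactions,
            parameter_names=base.parameter_names,
            stimulus_params=tuple(subset),
            name=name,
        )
        out[name] = ParameterSet(model, dict(start), dict(start), frozenset({"delta"}))
    return out


def bic(max_loglik: float, m: int, n: int) -> float:
    """Bayesian information criterion: -2 ln L_hat + m ln n."""
    if n <= 0:
        raise ValueError(f"sample size n must be positive, got {n}")
    if m < 0:
        raise ValueError(f"free-parameter count m must be >= 0, got {m}")
    return -2.0 * max_loglik + m * np.log(n)


def aicc(max_loglik: float, m: int, n: int, *, as_printed: bool = False) -> float:
    """Small-sample Akaike information criterion.

    Default: -2 ln L_hat + 2m + 2m(m+1)/(n-m-1), the standard AICc in which
    the parameter count is penalized.  ``as_printed=True`` flips the sign of
    the 2m term (some sources print the formula with -2m; that variant
    rewards extra parameters and is provided only for comparison).
    """
    if m < 0:
        raise ValueError(f"free-parameter count m must be >= 0, got {m}")
    if n <= m + 1:
        raise ValueError(f"AICc undefined for n={n} <= m+1={m + 1}")
    first_order = -2.0 * m if as_printed else 2.0 * m
    return -2.0 * max_loglik + first_order + 2.0 * m * (m + 1) / (n - m - 1)


def dic(chain: Chain, *, d_at_mean: float | None = None) -> float:
    """Deviance information criterion: 2 D_bar - D(theta_bar).

    D_bar is the mean deviance -2 ln L over post-burn-in samples; D(theta_bar)
    is the deviance at the post-burn-in posterior mean (means taken on the
    linear parameter scale), requiring one extra likelihood evaluation via
    the chain's attached likelihood function unless supplied directly.
    """
    thetas, loglik = chain.post_burn_in()
    if loglik.size == 0:
        raise ValueError("chain has no post-burn-in samples")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("non-finite log-likelihood in the post-burn-in segment")
    d_bar = float(np.mean(-2.0 * loglik))
    if d_at_mean is None:
        if chain.loglik_fn is None:
            raise ValueError("chain has no attached likelihood function; pass d_at_mean")
        d_at_mean = -2.0 * chain.loglik_fn(thetas.mean(axis=0))
    return 2.0 * d_bar - float(d_at_mean)


@dataclass(frozen=True)
class ICResult:
    """Information-criterion scores for one model fit on one data set."""

    model_name: str
    m: int
    n: int
    max_loglik: float
    BIC: float
    AICc: float
    DIC: float
    D_bar: float
    D_at_mean: float


def score_chain(chain: Chain, model_name: str, n: int) -> ICResult:
    """All three criteria for a finished sampling run."""
    m = len(chain.free_names)
    max_ll = float(np.max(chain.loglik))
    thetas, loglik = chain.post_burn_in()
    d_bar = float(np.mean(-2.0 * loglik))
    d_mean = -2.0 * chain.loglik_fn(thetas.mean(axis=0)) if chain.loglik_fn else np.nan
    return ICResult(
        model_name=model_name,
        m=m,
        n=n,
        max_loglik=max_ll,
        BIC=bic(max_ll, m, n),
        AICc=aicc(max_ll, m, n),
        DIC=2.0 * d_bar - d_mean,
        D_bar=d_bar,
        D_at_mean=d_mean,
    )


def compare_models(results: list[ICResult]) -> pd.DataFrame:
    """Rank candidate models per criterion.

    Returns a table with each criterion's score, the delta to the best
    score, and a per-criterion rank (ties broken in favor of fewer free
    parameters).  All results must come from fits to the same data (same n).
    """
    if len(results) < 2:
        raise ValueError("need at least two model results to compare")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"results mix different sample sizes: {sorted(ns)}")
    df = pd.DataFrame(
        {
            "model": [r.model_name for r in results],
            "m": [r.m for r in results],
            "max_loglik": [r.max_loglik for r in results],
            "BIC": [r.BIC for r in results],
            "AICc": [r.AICc for r in results],
            "DIC": [r.DIC for r in results],
        }
    )
    for crit in ("BIC", "AICc", "DIC"):
        df[f"delta_{crit}"] = df[crit] - df[crit].min()
        order = df.sort_values([crit, "m"], kind="mergesort").index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[f"rank_{crit}"] = ranks
    return df.set_index("model")


def winner(comparison: pd.DataFrame, criterion: str = "BIC") -> str:
    """Name of the model ranked first under ``criterion``."""
    return comparison[f"rank_{criterion}"].idxmin()
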