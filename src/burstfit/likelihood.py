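"""Snapshot container and the product-of-multinomials log-likelihood.

Each observation time contributes one multinomial draw over cell states: the
count vector of observed (active-TS, mRNA) states is scored against the
model's predicted distribution at that time — stationary under theta^U at
the pre-stimulus time point (tau = 0), and the theta^S-evolved transient at
every later time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .distributions import evolve_times, stationary_distribution
from .model import ModelSpec, ParameterSet, StateSpace, build_rate_matrix

__all__ = ["SnapshotDataset", "log_likelihood", "LOG_FLOOR"]

#: probabilities at or below this floor make an observed state impossible
LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class SnapshotDataset:
    """Per-cell smFISH snapshot counts at one pre- and several post-stimulus
    time points.

    ``counts[t]`` maps an observed cell state ``(ts_count, mrna_count)`` to
    the number of cells found in it at ``time_points[t]`` (minutes after the
    stimulus; the first time point must be 0, the pre-stimulus sample).
    """

    time_points: tuple[float, ...]
    counts: tuple[Mapping[tuple[int, int], int], ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.time_points) != len(self.counts):
            raise ValueError("one count table required per time point")
        if not self.time_points or self.time_points[0] != 0:
            raise ValueError("the first time point must be 0 (pre-stimulus)")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")
        for t, table in zip(self.time_points, self.counts):
            for (ts, m), c in table.items():
                if ts < 0 or m < 0 or c < 0 or c != int(c):
                    raise ValueError(
                        f"invalid count entry at t={t}: state ({ts},{m}) count {c}"
                    )

    @property
    def n_cells(self) -> tuple[int, ...]:
        """Total cells per time point."""
        return tuple(sum(tab.values()) for tab in self.counts)

    @property
    def n_total(self) -> int:
        return sum(self.n_cells)

    def max_observed(self) -> tuple[int, int]:
        """Largest observed (ts_count, mrna_count) across all time points."""
        ts = max((s for tab in self.counts for (s, _) in tab), default=0)
        m = max((mm for tab in self.counts for (_, mm) in tab), default=0)
        return ts, m

    def validate_against(self, model: ModelSpec, space: StateSpace) -> None:
        ts_max, m_max = self.max_observed()
        if ts_max > model.n_alleles:
            raise ValueError(
                f"observed {ts_max} active transcription sites but the model "
                f"allows at most {model.n_alleles}"
            )
        if m_max > space.M:
            raise ValueError(
                f"observed mRNA count {m_max} exceeds the truncation M={space.M}; "
                f"raise M"
            )


def _multinomial_logcoef(table: Mapping[tuple[int, int], int]) -> float:
    y = np.array(list(table.values()), dtype=float)
    return float(gammaln(y.sum() + 1.0) - gammaln(y + 1.0).sum())


def log_likelihood(
    data: SnapshotDataset,
    params: ParameterSet,
    space: StateSpace,
) -> float:
    """Log-likelihood of the snapshot data under a parameter set.

    ln L = sum_t [ ln(n_t!) - sum_k ln(Y^t_k!) + sum_i Y^t_i ln P(x_i, tau_t) ]

    computed with log-gamma throughout.  The multinomial coefficient is
    theta-independent (it cancels in Metropolis ratios) but is included so
    that stored likelihoods feed information criteria on a common scale.
    Returns ``-inf`` if any observed state has predicted probability at or
    below the underflow floor.
    """
    model = params.model
    data.validate_against(model, space)

    A_U = build_rate_matrix(model, params.values_U, space)
    P_star = stationary_distribution(A_U, space)

    dists = {0.0: P_star.values}
    post_times = [t for t in data.time_points if t > 0]
    if post_times:
        A_S = build_rate_matrix(model, params.values_S, space)
        for t, pv in zip(post_times, evolve_times(A_S, P_star, post_times)):
            dists[t] = pv.values

    total = 0.0
    for t, table in zip(data.time_points, data.counts):
        if not table:
            continue
        P = dists[float(t)]
        ts = np.array([s for (s, _) in table], dtype=int)
        m = np.array([mm for (_, mm) in table], dtype=int)
        y = np.array(list(table.values()), dtype=float)
        p_obs = P[space.index(ts, m)]
        if np.any(p_obs <= LOG_FLOOR):
            return -np.inf
        total += _multinomial_logcoef(table) + float(y @ np.log(p_obs))
    return total
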