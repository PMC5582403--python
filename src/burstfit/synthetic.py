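"""Synthetic snapshot data sets and an independent stochastic-simulation oracle.

Technical replicates are drawn exactly as a population snapshot experiment
would sample them: n cells per time point, multinomially from the model's
own distributions — the stationary law of theta^U at the pre-stimulus time
and the theta^S-evolved transients afterwards.

The Gillespie stochastic simulation algorithm (SSA) is kept deliberately
independent of the master-equation solvers: it simulates the untruncated
reaction system trajectory by trajectory (vectorized across trajectories)
and serves as a brute-force cross-check of the distribution code.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .distributions import evolve_times, stationary_distribution
from .likelihood import SnapshotDataset
from .model import ModelSpec, ParameterSet, StateSpace, build_rate_matrix, build_two_state_model

__all__ = [
    "truth_presets",
    "simulate_snapshots",
    "gillespie_ssa",
    "DEFAULT_TIMES",
    "DEFAULT_N_CELLS",
]

#: default snapshot times (minutes after the stimulus)
DEFAULT_TIMES = (0.0, 5.0, 15.0, 25.0)
#: default sampling density (cells per time point)
DEFAULT_N_CELLS = 100


def truth_presets() -> dict[str, ParameterSet]:
    """The two ground-truth models used for synthetic validation.

    * ``k1_stim`` — only the promoter activation rate jumps at induction:
      k1 0.01 -> 1 /min; k0 = 0.1 /min, mu1 = 2, mu0 = 0.01 mRNA/min,
      delta = 0.05 /min.
    * ``k1k0mu1_stim`` — activation, deactivation, and the active-state
      synthesis rate all change: k1 0.01 -> 1 /min, k0 1 -> 0.01 /min,
      mu1 0.2 -> 2 mRNA/min; mu0 = 0.01 mRNA/min, delta = 0.05 /min.

    The degradation rate delta is fixed (treated as independently measured).
    """
    m1 = build_two_state_model(2)
    k1_model = ModelSpec(
        n_alleles=m1.n_alleles,
        reactions=m1.reactions,
        parameter_names=m1.parameter_names,
        stimulus_params=("k1",),
        name="k1_stim",
    )
    k1 = ParameterSet(
        model=k1_model,
        values_U={"k1": 0.01, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05},
        values_S={"k1": 1.0, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05},
        fixed=frozenset({"delta"}),
    )
    full_model = ModelSpec(
        n_alleles=m1.n_alleles,
        reactions=m1.reactions,
        parameter_names=m1.parameter_names,
        stimulus_params=("k1", "k0", "mu1"),
        name="k1k0mu1_stim",
    )
    k1k0mu1 = ParameterSet(
        model=full_model,
        values_U={"k1": 0.01, "k0": 1.0, "mu0": 0.01, "mu1": 0.2, "delta": 0.05},
        values_S={"k1": 1.0, "k0": 0.01, "mu0": 0.01, "mu1": 2.0, "delta": 0.05},
        fixed=frozenset({"delta"}),
    )
    return {"k1_stim": k1, "k1k0mu1_stim": k1k0mu1}


def simulate_snapshots(
    params: ParameterSet,
    space: StateSpace,
    times: Sequence[float] = DEFAULT_TIMES,
    n_cells: int | Sequence[int] = DEFAULT_N_CELLS,
    seed: int = 0,
) -> SnapshotDataset:
    """Draw one technical replicate of snapshot data from known parameters.

    Cells at t = 0 are sampled multinomially from the stationary
    distribution of theta^U; cells at each later time from the theta^S
    transient started at that stationary law.  Sampling is an exact
    multinomial over the flattened state distribution, mirroring how a
    microscope samples n independent cells from the population.
    """
    times = [float(t) for t in times]
    if not times or times[0] != 0:
        raise ValueError("times must start at 0 (the pre-stimulus sample)")
    if np.isscalar(n_cells):
        n_per = [int(n_cells)] * len(times)
    else:
        n_per = [int(n) for n in n_cells]
        if len(n_per) != len(times):
            raise ValueError("n_cells list must match the number of time points")
    if any(n < 1 for n in n_per):
        raise ValueError("n_cells must be >= 1")

    model = params.model
    A_U = build_rate_matrix(model, params.values_U, space)
    P_star = stationary_distribution(A_U, space)
    dists = [P_star.values]
    post = times[1:]
    if post:
        A_S = build_rate_matrix(model, params.values_S, space)
        dists += [pv.values for pv in evolve_times(A_S, P_star, post)]

    rng = np.random.default_rng(seed)
    counts = []
    for P, n in zip(dists, n_per):
        draw = rng.multinomial(n, P / P.sum())
        nz = np.nonzero(draw)[0]
        rho1, m = space.decode(nz)
        counts.append({(int(r), int(mm)): int(c) for r, mm, c in zip(rho1, m, draw[nz])})
    return SnapshotDataset(
        time_points=tuple(times),
        counts=tuple(counts),
        provenance={
            "generator": "simulate_snapshots",
            "seed": int(seed),
            "truth_U": dict(params.values_U),
            "truth_S": dict(params.values_S),
            "model": model.name,
            "M": space.M,
        },
    )


def _ssa_step_batch(
    rho1: np.ndarray,
    m: np.ndarray,
    t: np.ndarray,
    t_end: float,
    model: ModelSpec,
    theta: Mapping[str, float],
    rng: np.random.Generator,
) -> None:
    """Advance every still-running trajectory by one reaction (in place)."""
    props = np.stack(model.propensities(rho1, m, theta))  # (n_reactions, n_traj)
    a0 = props.sum(axis=0)
    live = a0 > 0
    dt = np.full(t.shape, np.inf)
    dt[live] = rng.exponential(1.0, live.sum()) / a0[live]
    new_t = t + dt
    fire = new_t <= t_end
    t[:] = np.where(fire, new_t, t_end)
    t[~live] = t_end  # absorbed: no reaction can occur
    if not fire.any():
        return
    # choose the reaction per firing trajectory by inverse CDF on propensities
    u = rng.random(t.shape) * a0
    cum = np.cumsum(props, axis=0)
    choice = (u[None, :] >= cum).sum(axis=0)
    for k, reaction in enumerate(model.reactions):
        sel = fire & (choice == k)
        d_rho, d_m = reaction.stoich
        rho1[sel] += d_rho
        m[sel] += d_m


def gillespie_ssa(
    theta: Mapping[str, float],
    model: ModelSpec,
    t_end: float,
    n_traj: int,
    seed: int = 0,
    initial_state: tuple[int, int] | tuple[np.ndarray, np.ndarray] = (0, 0),
    record_times: Sequence[float] | None = None,
) -> np.ndarray | list[tuple[np.ndarray, np.ndarray]]:
    """Exact stochastic simulation of the untruncated reaction system.

    Runs ``n_traj`` independent trajectories from ``initial_state`` (a single
    (rho1, m) pair or per-trajectory arrays) to ``t_end`` minutes under
    ``theta``.  Returns the array of end states, shape (n_traj, 2), or — when
    ``record_times`` is given — a list of (rho1, m) snapshots at those times.

    All trajectories advance in lockstep (vectorized over the batch); each
    individual trajectory still follows the exact Gillespie law.
    """
    for name in model.parameter_names:
        if theta[name] < 0:
            raise ValueError(f"rate {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    r0, m0 = initial_state
    rho1 = np.broadcast_to(np.asarray(r0, dtype=np.int64), (n_traj,)).copy()
    m = np.broadcast_to(np.asarray(m0, dtype=np.int64), (n_traj,)).copy()
    t = np.zeros(n_traj)

    checkpoints = sorted(float(x) for x in (record_times if record_times is not None else []))
    if checkpoints and (checkpoints[0] < 0 or checkpoints[-1] > t_end):
        raise ValueError("record_times must lie within [0, t_end]")
    snapshots: list[tuple[np.ndarray, np.ndarray]] = []

    targets = [(c, True) for c in checkpoints]
    if not checkpoints or checkpoints[-1] < float(t_end):
        targets.append((float(t_end), False))
    for target, is_checkpoint in targets:
        while True:
            running = t < target
            if not running.any():
                break
            idx = np.nonzero(running)[0]
            r_sub, m_sub, t_sub = rho1[idx], m[idx], t[idx]
            _ssa_step_batch(r_sub, m_sub, t_sub, target, model, theta, rng)
            rho1[idx], m[idx], t[idx] = r_sub, m_sub, t_sub
        if is_checkpoint:
            snapshots.append((rho1.copy(), m.copy()))

    if record_times is not None:
        return snapshots
    return np.stack([rho1, m], axis=1)
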