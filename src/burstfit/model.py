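"""Stochastic gene-expression model family, state space, and generator matrix.

The core object is a reaction system over the cell state ``x = [rho1, m]``,
where ``rho1`` is the number of active promoter alleles (0..n_alleles for a
two-state promoter) and ``m`` the number of mRNA molecules.  The chemical
master equation for the truncated state space is ``dP/dt = A(theta) P`` with
a sparse generator ``A`` whose columns sum to zero.

Reactions are data — a stoichiometry plus a propensity rule over named
parameters — so model variants (other allele counts, other switching
topologies) can be declared without touching the solver code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Reaction",
    "ModelSpec",
    "ParameterSet",
    "StateSpace",
    "build_two_state_model",
    "build_rate_matrix",
]

# Propensity rule signature: (rho1 array, m array, theta mapping) -> array
PropensityRule = Callable[[np.ndarray, np.ndarray, Mapping[str, float]], np.ndarray]


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: a stoichiometric change and its propensity.

    ``stoich`` is ``(d_rho1, d_m)``; exactly one entry is nonzero and equal
    to +/-1.  ``propensity`` evaluates a_k(x; theta) vectorized over states.
    """

    name: str
    stoich: tuple[int, int]
    propensity: PropensityRule

    def __post_init__(self) -> None:
        d_rho, d_m = self.stoich
        changed = (d_rho != 0) + (d_m != 0)
        if changed != 1 or abs(d_rho) + abs(d_m) != 1:
            raise ValueError(
                f"reaction {self.name!r}: stoichiometry must change exactly one "
                f"of (rho1, m) by +/-1, got {self.stoich}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """A promoter/mRNA reaction system with named kinetic parameters.

    Parameters
    ----------
    n_alleles
        Number of independently regulated gene copies (2 for a diploid,
        post-mitotic cell).
    reactions
        The elementary reactions.
    parameter_names
        Ordered kinetic parameter names, e.g. ``("k1", "k0", "mu0", "mu1",
        "delta")``.
    stimulus_params
        Names whose value switches from the unstimulated to the stimulated
        value at t = 0.
    """

    n_alleles: int
    reactions: tuple[Reaction, ...]
    parameter_names: tuple[str, ...]
    stimulus_params: tuple[str, ...] = ()
    name: str = "two_state"

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise ValueError(f"n_alleles must be >= 1, got {self.n_alleles}")
        unknown = set(self.stimulus_params) - set(self.parameter_names)
        if unknown:
            raise ValueError(f"stimulus_params not in parameter_names: {sorted(unknown)}")

    @property
    def p(self) -> int:
        """Number of distinct promoter states per cell (rho1 in 0..n_alleles)."""
        return self.n_alleles + 1

    def propensities(
        self, rho1: np.ndarray, m: np.ndarray, theta: Mapping[str, float]
    ) -> list[np.ndarray]:
        """Evaluate every reaction propensity over arrays of states."""
        rho1 = np.asarray(rho1)
        m = np.asarray(m)
        return [np.broadcast_to(r.propensity(rho1, m, theta), rho1.shape).astype(float)
                for r in self.reactions]


@dataclass(frozen=True)
class ParameterSet:
    """Concrete pre-stimulus (theta^U) and post-stimulus (theta^S) values.

    ``values_S`` must agree with ``values_U`` on every parameter the stimulus
    does not touch; ``fixed`` names parameters that are held constant during
    inference (typically the mRNA degradation rate delta, measured
    independently).
    """

    model: ModelSpec
    values_U: Mapping[str, float]
    values_S: Mapping[str, float]
    fixed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = set(self.model.parameter_names)
        for label, vals in (("values_U", self.values_U), ("values_S", self.values_S)):
            missing = names - set(vals)
            if missing:
                raise ValueError(f"{label} missing parameters: {sorted(missing)}")
        for name in self.model.parameter_names:
            if self.values_U[name] < 0 or self.values_S[name] < 0:
                raise ValueError(f"parameter {name!r} must be >= 0")
            if name not in self.model.stimulus_params and (
                self.values_U[name] != self.values_S[name]
            ):
                raise ValueError(
                    f"{name!r} is not a stimulus parameter but differs between "
                    f"theta^U and theta^S"
                )
        bad_fixed = self.fixed & set(self.model.stimulus_params)
        if bad_fixed:
            raise ValueError(f"stimulus parameters cannot be fixed: {sorted(bad_fixed)}")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Ordered names of the free-parameter vector.

        Each stimulus parameter contributes a pre- (``name_U``) and a post-
        stimulus (``name_S``) component; other non-fixed parameters
        contribute one component under their bare name.
        """
        out: list[str] = []
        for name in self.model.parameter_names:
            if name in self.fixed:
                continue
            if name in self.model.stimulus_params:
                out.extend([f"{name}_U", f"{name}_S"])
            else:
                out.append(name)
        return tuple(out)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def to_free_vector(self) -> np.ndarray:
        vec = []
        for comp in self.free_names:
            if comp.endswith("_U") and comp[:-2] in self.model.stimulus_params:
                vec.append(self.values_U[comp[:-2]])
            elif comp.endswith("_S") and comp[:-2] in self.model.stimulus_params:
                vec.append(self.values_S[comp[:-2]])
            else:
                vec.append(self.values_U[comp])
        return np.array(vec, dtype=float)

    def with_free_vector(self, vec: Sequence[float]) -> "ParameterSet":
        """Return a copy with the free components replaced by ``vec``."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise ValueError(f"expected free vector of length {self.n_free}")
        vu = dict(self.values_U)
        vs = dict(self.values_S)
        for comp, val in zip(self.free_names, vec):
            if comp.endswith("_U") and comp[:-2] in self.model.stimulus_params:
                vu[comp[:-2]] = float(val)
            elif comp.endswith("_S") and comp[:-2] in self.model.stimulus_params:
                vs[comp[:-2]] = float(val)
            else:
                vu[comp] = float(val)
                vs[comp] = float(val)
        return ParameterSet(self.model, vu, vs, self.fixed)


class StateSpace:
    """Enumeration of cell states ``x = (rho1, m)`` with ``m <= M``.

    Linear ordering is row-major by promoter state then mRNA count:
    ``index(rho1, m) = rho1 * (M + 1) + m`` (0-based), so ``N = p * (M + 1)``.
    """

    def __init__(self, M: int, p: int):
        if M < 0 or p < 1:
            raise ValueError("require M >= 0 and p >= 1")
        self.M = int(M)
        self.p = int(p)
        self.N = self.p * (self.M + 1)

    def index(self, rho1, m):
        rho1 = np.asarray(rho1)
        m = np.asarray(m)
        if np.any(rho1 < 0) or np.any(rho1 >= self.p) or np.any(m < 0) or np.any(m > self.M):
            raise IndexError("state out of range")
        return rho1 * (self.M + 1) + m

    def decode(self, idx):
        idx = np.asarray(idx)
        if np.any(idx < 0) or np.any(idx >= self.N):
            raise IndexError("linear index out of range")
        return idx // (self.M + 1), idx % (self.M + 1)

    def states(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (rho1, m) for all N states in linear order."""
        idx = np.arange(self.N)
        return self.decode(idx)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StateSpace(M={self.M}, p={self.p}, N={self.N})"


def build_two_state_model(n_alleles: int = 2) -> ModelSpec:
    """The two-state (telegraph) promoter model for ``n_alleles`` independent
    gene copies.

    Four reactions act on the cell state (rho1, m):

    * activation:    rho1 -> rho1 + 1   at rate k1 * (n_alleles - rho1)
    * inactivation:  rho1 -> rho1 - 1   at rate k0 * rho1
    * synthesis:     m -> m + 1         at rate mu0 * (n_alleles - rho1) + mu1 * rho1
    * degradation:   m -> m - 1         at rate delta * m

    Alleles are assumed independent and exchangeable, so only the number of
    active copies is tracked.
    """
    if n_alleles < 1:
        raise ValueError(f"n_alleles must be >= 1, got {n_alleles}")
    n = int(n_alleles)
    reactions = (
        Reaction("activation", (1, 0), lambda r, m, th: th["k1"] * (n - r)),
        Reaction("inactivation", (-1, 0), lambda r, m, th: th["k0"] * r),
        Reaction("synthesis", (0, 1), lambda r, m, th: th["mu0"] * (n - r) + th["mu1"] * r),
        Reaction("degradation", (0, -1), lambda r, m, th: th["delta"] * m),
    )
    return ModelSpec(
        n_alleles=n,
        reactions=reactions,
        parameter_names=("k1", "k0", "mu0", "mu1", "delta"),
    )


def build_rate_matrix(
    model: ModelSpec,
    theta: Mapping[str, float],
    space: StateSpace,
    *,
    absorbing: bool = False,
) -> sp.csr_matrix:
    """Assemble the sparse generator A(theta) on the truncated state space.

    ``A[j, i]`` holds the propensity of the reaction taking state i to state
    j; the diagonal carries minus the total outflow, so every column sums to
    zero and ``exp(A t)`` is stochastic on the retained states.  By default a
    reaction that would leave the truncation (``m > M``) is dropped from both
    the off-diagonal and the diagonal, keeping A a proper (probability
    conserving) generator.

    With ``absorbing=True`` the outflow of boundary-crossing reactions is
    kept on the diagonal, so ``1 - sum(exp(A t) P0)`` is exactly the
    probability mass that escaped the truncation — the certified
    finite-state-projection error bound used to validate the choice of M.
    """
    if space.p != model.p:
        raise ValueError(f"state space has p={space.p} but model requires p={model.p}")
    for name in model.parameter_names:
        if name not in theta:
            raise ValueError(f"theta missing parameter {name!r}")
        if theta[name] < 0:
            raise ValueError(f"theta[{name!r}] must be >= 0, got {theta[name]}")

    rho1, m = space.states()
    src = space.index(rho1, m)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for reaction, a in zip(model.reactions, model.propensities(rho1, m, theta)):
        d_rho, d_m = reaction.stoich
        new_rho = rho1 + d_rho
        new_m = m + d_m
        ok = (
            (new_rho >= 0) & (new_rho < space.p) & (new_m >= 0) & (new_m <= space.M)
            & (a > 0)
        )
        dest = new_rho[ok] * (space.M + 1) + new_m[ok]
        rows.append(dest)
        cols.append(src[ok])
        vals.append(a[ok])
        out = (a > 0) if absorbing else ok  # absorbing: charge outflow at the boundary too
        rows.append(src[out])
        cols.append(src[out])
        vals.append(-a[out])

    if rows:
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(space.N, space.N),
        ).tocsr()
    else:  # all propensities zero
        A = sp.csr_matrix((space.N, space.N))
    return A
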