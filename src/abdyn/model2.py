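"""Nine-affinity-class repertoire kinetics with somatic hypermutation
(Model 2).

Each affinity class i carries its own complex x_i and free antibody y_i;
all classes compete for one shared antigen z (held constant, as for a
self-antigen continuously replenished by the host).  Binding, clearance
and decay work exactly as in the single-antibody model, per class.

Somatic hypermutation acts only on the *production* term: of the new
antibody generated at rate k4*x_i, a fraction 1-p is an exact copy, and
the mutated fraction p is redistributed over classes {i-1, i, i+1}
according to the normal-distribution kernel.  Existing antibody never
converts.  Because kernel rows sum to 1, redistribution conserves total
production flux: summed over classes it is always k4 * sum(x).

A foreign-antigen variant differs only through an elevated k4 (stronger
T-helper stimulation); an optional flag additionally lets the antigen
replicate, for exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .affinity_grid import AffinityGrid, MutationKernel
from .errors import IntegrationError
from .model1 import DEFAULT_ATOL, DEFAULT_RTOL
from .trajectory import Trajectory

__all__ = [
    "Model2Params",
    "Model2State",
    "rhs_shm",
    "rhs_shm_foreign",
    "production",
    "integrate_shm",
]


@dataclass(frozen=True)
class Model2Params:
    """Grid + kernel + shared rates for the repertoire system.

    ``p`` is the somatic-hypermutation rate: the probability that a newly
    produced antibody is a mutant rather than an exact copy.
    """

    grid: AffinityGrid
    kernel: MutationKernel
    k3: float
    k4: float
    k6: float
    p: float
    k1: float = 0.0
    k5: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.kernel.n != self.grid.n:
            raise ValueError(
                f"kernel has {self.kernel.n} classes, grid has {self.grid.n}"
            )
        for name in ("k1", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.grid.n


@dataclass(frozen=True)
class Model2State:
    """Per-class complexes x, per-class free antibody y, shared antigen z."""

    x: np.ndarray
    y: np.ndarray
    z: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
                and np.isfinite(self.z)):
            raise ValueError("state must be finite")
        if np.any(x < 0) or np.any(y < 0) or self.z < 0:
            raise ValueError("state must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.x)

    def as_array(self) -> np.ndarray:
        return np.concatenate([[self.z], self.x, self.y])


def _unpack(state, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(state, Model2State):
        x, y, z = state.x, state.y, state.z
    else:
        x, y, z = state
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError(
            f"state dimensions {x.shape}/{y.shape} do not match n={n}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.isfinite(z)):
        raise ValueError("state must be finite")
    return x, y, float(z)


def production(x: np.ndarray, params: Model2Params) -> np.ndarray:
    """Per-class antibody production flux, SHM redistribution included.

    prod_i = (1-p) k4 x_i                      exact copies
           + p k4 [ stay_i x_i                 mutants that stay in class
                  + weaker_(i+1) x_(i+1)       mutants arriving from above
                  + stronger_(i-1) x_(i-1) ]   mutants arriving from below

    Sums to k4 * sum(x) for any state because kernel rows sum to 1.
    """
    k = params.kernel
    inflow = np.zeros_like(x)
    inflow[:-1] += k.p_weaker[1:] * x[1:]
    inflow[1:] += k.p_stronger[:-1] * x[:-1]
    p = params.p
    return params.k4 * ((1.0 - p) * x + p * (k.p_stay * x + inflow))


def rhs_shm(state, params: Model2Params) -> tuple[np.ndarray, np.ndarray, float]:
    """Derivatives (dx, dy, dz) for the self-antigen repertoire system;
    dz/dt is identically 0."""
    x, y, z = _unpack(state, params.n)
    k2, km2 = params.grid.k2, params.grid.k_minus2
    bind = k2 * y * z
    unbind = km2 * x
    dx = bind - unbind - params.k3 * x
    dy = unbind - bind + production(x, params) - params.k6 * y
    return dx, dy, 0.0


def rhs_shm_foreign(
    state, params: Model2Params, replicating: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Foreign-antigen variant: identical kinetics (presets differ only by
    an elevated k4).  With ``replicating=True`` the antigen additionally
    gains (k1 - k5) z plus the net binding fluxes (off by default)."""
    x, y, z = _unpack(state, params.n)
    dx, dy, _ = rhs_shm((x, y, z), params)
    dz = 0.0
    if replicating:
        k2, km2 = params.grid.k2, params.grid.k_minus2
        dz = (params.k1 - params.k5) * z + float(
            np.sum(km2 * x - k2 * y * z))
    return dx, dy, dz


def integrate_shm(
    state0,
    params: Model2Params,
    t_end: float,
    n_points: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    replicating: bool = False,
) -> Trajectory:
    """Integrate the repertoire system over [0, t_end] on a uniform grid.

    Trajectory columns are ``z, x_1..x_n, y_1..y_n``.  Error behaviour
    matches :func:`abdyn.model1.integrate`.
    """
    if not isinstance(state0, Model2State):
        x0, y0, z0 = state0
        state0 = Model2State(np.asarray(x0), np.asarray(y0), z0)
    n = params.n
    if state0.n != n:
        raise ValueError(f"state has {state0.n} classes, params expect {n}")

    def rhs_flat(s, _params):
        z, x, y = s[0], s[1:n + 1], s[n + 1:]
        dx, dy, dz = rhs_shm_foreign((x, y, z), params,
                                     replicating=replicating)
        return np.concatenate([[dz], dx, dy])

    labels = ("z",) + tuple(f"x_{i}" for i in range(1, n + 1)) + tuple(
        f"y_{i}" for i in range(1, n + 1))

    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, s: rhs_flat(s, params),
        (0.0, t_end),
        state0.as_array(),
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else None
        raise IntegrationError(f"solver failed: {sol.message}", last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state encountered")
    if np.min(states) < -10.0 * atol:
        raise IntegrationError(
            f"negative undershoot beyond -10*atol (min {np.min(states):g})"
        )
    return Trajectory(times=times, states=states, labels=labels)
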