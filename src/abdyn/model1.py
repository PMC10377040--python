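"""Single-antibody mass-action kinetics (Model 1).

Three coupled species: antibody–antigen complex *x*, free antibody *y*,
antigen *z*.  Six processes: antigen replication (k1), reversible binding
(k2 forward, k_minus2 reverse), immune clearance of the complex (k3),
complex-stimulated production of new antibody (k4, standing in for
T-helper-cell stimulation strength), antigen degradation (k5) and natural
antibody decay (k6).

Two antigen regimes share the x and y balances:

* pathogen — the antigen replicates, dz/dt includes (k1 - k5) z plus the
  binding fluxes;
* self-antigen — the host replenishes the antigen as fast as binding
  consumes it, so z is held constant (dz/dt = 0) and k1, k5 are unused.

A multi-antibody competition variant lets several antibody clones with
different association rates bind one shared replicating pathogen; it
reduces exactly to the pathogen system for a single clone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError
from .trajectory import Trajectory

__all__ = [
    "Model1Params",
    "Model1State",
    "CompetitionState",
    "rhs_pathogen",
    "rhs_self",
    "rhs_competition",
    "integrate",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6


@dataclass(frozen=True)
class Model1Params:
    """Rate constants for the single-antibody system.

    k1 (antigen replication) and k5 (antigen degradation) only matter for
    the pathogen regime and default to 0.
    """

    k2: float
    k_minus2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k6: float = 0.0
    k1: float = 0.0
    k5: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.k3 <= self.k6:
            # Complex clearance should dominate natural antibody decay for
            # the deletion mechanism to operate; tolerated but suspicious.
            warnings.warn(
                f"k3={self.k3} does not exceed k6={self.k6}; complex "
                "clearance is expected to dominate antibody decay",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Model1State:
    """Concentrations (arbitrary units): complex x, free antibody y,
    antigen z."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.z)
        if not all(np.isfinite(vals)):
            raise ValueError("state must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("state must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class CompetitionState:
    """m antibody clones sharing one pathogen: per-clone complex and free
    antibody vectors plus the scalar antigen."""

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
    def m(self) -> int:
        return len(self.x)

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.x, self.y, [self.z]])


def _as_xyz(state) -> np.ndarray:
    arr = state.as_array() if isinstance(state, Model1State) else np.asarray(
        state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-component state, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state must be finite")
    return arr


def rhs_pathogen(state, params: Model1Params) -> np.ndarray:
    """Time derivatives (dx/dt, dy/dt, dz/dt) for the replicating-pathogen
    system."""
    x, y, z = _as_xyz(state)
    p = params
    bind = p.k2 * y * z
    unbind = p.k_minus2 * x
    dx = bind - unbind - p.k3 * x
    dy = unbind - bind + p.k4 * x - p.k6 * y
    dz = unbind - bind - p.k5 * z + p.k1 * z
    return np.array([dx, dy, dz])


def rhs_self(state, params: Model1Params) -> np.ndarray:
    """Derivatives for the constant self-antigen system: same x and y
    balances as the pathogen system, dz/dt identically 0."""
    x, y, z = _as_xyz(state)
    p = params
    bind = p.k2 * y * z
    unbind = p.k_minus2 * x
    dx = bind - unbind - p.k3 * x
    dy = unbind - bind + p.k4 * x - p.k6 * y
    return np.array([dx, dy, 0.0])


_SHARED_RATES = ("k1", "k3", "k4", "k5", "k6")


def _check_competition_params(params: Sequence[Model1Params]) -> None:
    if len(params) == 0:
        raise ValueError("need at least one antibody")
    first = params[0]
    for p in params[1:]:
        for name in _SHARED_RATES:
            if getattr(p, name) != getattr(first, name):
                raise ValueError(
                    f"all antibodies must share {name}; "
                    f"got {getattr(p, name)} vs {getattr(first, name)}"
                )


def rhs_competition(
    states: Sequence[tuple[float, float]],
    z: float,
    params_per_antibody: Sequence[Model1Params],
) -> tuple[list[tuple[float, float]], float]:
    """Derivatives for m antibody clones competing for one pathogen.

    ``states`` is a list of (x_j, y_j) pairs.  Each clone has its own
    binding kinetics (k2_j, k_minus2_j); replication, clearance,
    stimulation and decay rates are shared.  The pathogen balance sums the
    binding/dissociation fluxes of every clone on top of net replication.

    Returns ([(dx_j, dy_j), ...], dz).
    """
    if len(states) != len(params_per_antibody):
        raise ValueError(
            f"{len(states)} states but {len(params_per_antibody)} parameter sets"
        )
    _check_competition_params(params_per_antibody)
    shared = params_per_antibody[0]
    dz = (shared.k1 - shared.k5) * z
    out = []
    for (x, y), p in zip(states, params_per_antibody):
        bind = p.k2 * y * z
        unbind = p.k_minus2 * x
        dx = bind - unbind - p.k3 * x
        dy = unbind - bind + p.k4 * x - p.k6 * y
        dz += unbind - bind
        out.append((dx, dy))
    return out, dz


def _flat_rhs(rhs: Callable, state0, params) -> tuple[
        Callable, np.ndarray, tuple[str, ...]]:
    """Adapt one of the module RHS functions to a flat solve_ivp callable."""
    if rhs is rhs_competition:
        if not isinstance(state0, CompetitionState):
            x0, y0, z0 = state0
            state0 = CompetitionState(np.asarray(x0), np.asarray(y0), z0)
        m = state0.m
        if len(params) != m:
            raise ValueError(f"{m} antibodies but {len(params)} parameter sets")
        _check_competition_params(params)
        k2 = np.array([p.k2 for p in params])
        km2 = np.array([p.k_minus2 for p in params])
        shared = params[0]

        def f(t, s):
            x, y, z = s[:m], s[m:2 * m], s[2 * m]
            bind = k2 * y * z
            unbind = km2 * x
            dx = bind - unbind - shared.k3 * x
            dy = unbind - bind + shared.k4 * x - shared.k6 * y
            dz = (shared.k1 - shared.k5) * z + np.sum(unbind - bind)
            return np.concatenate([dx, dy, [dz]])

        labels = tuple(f"x_{j + 1}" for j in range(m)) + tuple(
            f"y_{j + 1}" for j in range(m)) + ("z",)
        return f, state0.as_array(), labels

    y0 = _as_xyz(state0)

    def f(t, s):  # noqa: ARG001 - autonomous system
        return rhs(s, params)

    return f, y0, ("x", "y", "z")


def integrate(
    rhs: Callable,
    state0,
    params,
    t_end: float,
    n_points: int = 500,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate one of the Model 1 systems on a uniform sample grid.

    ``rhs`` is :func:`rhs_pathogen`, :func:`rhs_self` or
    :func:`rhs_competition`; ``state0``/``params`` must match it.  The
    solver is adaptive and stiffness-capable (LSODA by default).

    Raises
    ------
    IntegrationError
        On solver failure or a negative undershoot beyond 10*atol (a
        symptom of unresolved stiffness; not silently clipped).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    f, y0, labels = _flat_rhs(rhs, state0, params)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        f, (0.0, t_end), y0, method=method, t_eval=times, rtol=rtol, atol=atol
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else None
        raise IntegrationError(f"solver failed: {sol.message}", last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.all(np.isfinite(states), axis=1)))
        raise IntegrationError(
            "non-finite state encountered", float(times[max(bad - 1, 0)])
        )
    if np.min(states) < -10.0 * atol:
        bad = int(np.argmax(np.min(states, axis=1) < -10.0 * atol))
        raise IntegrationError(
            f"negative undershoot beyond -10*atol (min {np.min(states):g})",
            float(times[max(bad - 1, 0)]),
        )
    return Trajectory(times=times, states=states, labels=labels)
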