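"""Named scenario presets and repertoire summary metrics.

Each preset packages one of the canonical experiments — clonal deletion,
affinity selection under pathogen infection, SHM-driven self-tolerance,
SHM-driven affinity maturation, and the repertoire-aging sweep — with its
published parameter set, a documented time horizon and the sweep members
(antibody variants or SHM rates) it compares.

Horizons are model choices, not published values: time in these models is
dimensionless and the canonical experiments state no time scale.  Each
horizon is fixed by a stated stopping rule (see the constants below) and
shipped as a package default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import model1, model2
from .affinity_grid import build_grid, build_kernel, initial_composition
from .model1 import CompetitionState, Model1Params, Model1State
from .model2 import Model2Params, Model2State
from .trajectory import Trajectory

__all__ = [
    "ScenarioSpec",
    "SummaryMetrics",
    "PRESET_NAMES",
    "preset",
    "run",
    "metrics",
]

# Default horizons (dimensionless time), one per preset.
#
# clonal_deletion: run until the strong binder (k2=1e-8) has fallen well
#   below 10% of its initial level (it crosses 10% near t~9.4 under the
#   shipped parameters; t=20 leaves the contrast fully developed).
# pathogen_selection: long enough for the pathogen to be cleared and the
#   five clones' abundances to separate cleanly by affinity (the pathogen
#   collapses shortly before t=200).
# shm_self_tolerance: long enough that every affinity class, including
#   the slow mid-grid ones fed by mutation, has peaked and is declining.
# shm_foreign: the maturation cascade out of the weakest class crosses
#   eight classes through successively tiny mutant fluxes; the
#   strong-binder takeoff only dominates the seeded clone's decay after
#   t~800, so the horizon sits at 1000.
# aging_sweep: long enough for the composition to shift visibly toward
#   strong binders (class 7 dominant at p=0.2; the shift saturates by
#   t~300-400).
HORIZON_CLONAL_DELETION = 20.0
HORIZON_PATHOGEN_SELECTION = 200.0
HORIZON_SHM_SELF_TOLERANCE = 300.0
HORIZON_SHM_FOREIGN = 1000.0
HORIZON_AGING_SWEEP = 400.0

# Intermediate report times for the aging sweep's "evolution through
# time" view (fractions of the horizon).
AGING_LADDER_FRACTIONS = (0.0, 0.125, 0.25, 0.5, 0.75, 1.0)

PRESET_NAMES = (
    "clonal_deletion",
    "pathogen_selection",
    "shm_self_tolerance",
    "shm_foreign",
    "aging_sweep",
)

#: Seeded class for the shm_foreign preset: the weakest binder (class 1,
#: k2 = 1e-13), so affinity maturation out of a poor initial repertoire is
#: observable.  Configurable via ScenarioSpec construction.
SHM_FOREIGN_SEED_CLASS = 1


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully parameterized experiment.

    ``members`` maps a sweep label (an antibody variant or a ``p=...``
    value) to the parameter bundle for that run; all members share
    ``initial_state``.  ``params`` exposes the first member's bundle as
    the scenario's base parameter set.
    """

    name: str
    model: str
    members: Mapping[str, object]
    initial_state: object
    t_end: float
    n_points: int = 500
    p_values: tuple[float, ...] | None = None
    report_times: tuple[float, ...] | None = None
    rtol: float = model1.DEFAULT_RTOL
    atol: float = model1.DEFAULT_ATOL

    _MODELS = (
        "model1_self",
        "model1_pathogen",
        "model1_competition",
        "model2_self",
        "model2_foreign",
    )

    def __post_init__(self) -> None:
        if self.model not in self._MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {self._MODELS}"
            )
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not self.members:
            raise ValueError("scenario needs at least one member")

    @property
    def params(self):
        """Base parameter bundle (the first sweep member's)."""
        return next(iter(self.members.values()))


@dataclass(frozen=True)
class SummaryMetrics:
    """Repertoire summaries along one Model 2 trajectory.

    composition rows are y_i / sum(y) (NaN where the total is 0);
    dominant_class is the 1-based argmax of y with ties broken toward the
    lower index; mean_class_index is the abundance-weighted mean class.
    """

    times: np.ndarray
    total_antibody: np.ndarray
    composition: np.ndarray
    dominant_class: np.ndarray
    mean_class_index: np.ndarray
    y0: np.ndarray

    @property
    def n(self) -> int:
        return self.composition.shape[1]

    def time_to_fraction(self, class_index: int, fraction: float) -> float | None:
        """First sample time at which y_i drops to ``fraction`` of its
        initial level, or None if it never does."""
        if not 1 <= class_index <= self.n:
            raise IndexError(f"class index {class_index} outside 1..{self.n}")
        y = self.composition * self.total_antibody[:, None]
        yi = y[:, class_index - 1]
        hit = np.nonzero(yi <= fraction * self.y0[class_index - 1])[0]
        return float(self.times[hit[0]]) if len(hit) else None

    def at_time(self, t: float) -> dict:
        """Summaries at the sample closest to ``t``."""
        j = int(np.argmin(np.abs(self.times - t)))
        return {
            "time": float(self.times[j]),
            "total_antibody": float(self.total_antibody[j]),
            "composition": self.composition[j].tolist(),
            "dominant_class": int(self.dominant_class[j]),
            "mean_class_index": float(self.mean_class_index[j]),
        }

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "total_antibody": self.total_antibody.tolist(),
            "composition": self.composition.tolist(),
            "dominant_class": self.dominant_class.tolist(),
            "mean_class_index": self.mean_class_index.tolist(),
        }


def _default_grid_and_kernel():
    grid = build_grid()
    return grid, build_kernel(grid)


def preset(name: str) -> ScenarioSpec:
    """Return the named preset with its published parameter set.

    Valid names: clonal_deletion, pathogen_selection, shm_self_tolerance,
    shm_foreign, aging_sweep.
    """
    if name == "clonal_deletion":
        # Two antibody variants against a constant self-antigen: the
        # strong binder (k2=1e-8) is deleted faster than the weak one.
        common = dict(k_minus2=1e-18, k3=0.5, k4=0.1, k6=0.02)
        return ScenarioSpec(
            name=name,
            model="model1_self",
            members={
                "strong_binder": Model1Params(k2=1e-8, **common),
                "weak_binder": Model1Params(k2=1e-9, **common),
            },
            initial_state=Model1State(x=0.0, y=1e5, z=3e7),
            t_end=HORIZON_CLONAL_DELETION,
        )

    if name == "pathogen_selection":
        # Five antibody clones with one-decade-spanning affinities compete
        # for a replicating pathogen; k_minus2 scales with k2 (shared Kd).
        shared = dict(k1=0.1, k3=1.0, k4=2.0, k5=0.02, k6=0.02)
        k2s = (1e-5, 9e-6, 8e-6, 7e-6, 6e-6)
        km2s = (1e-14, 9e-15, 8e-15, 7e-15, 6e-15)
        members = {
            "competition": [
                Model1Params(k2=a, k_minus2=b, **shared)
                for a, b in zip(k2s, km2s)
            ]
        }
        m = len(k2s)
        return ScenarioSpec(
            name=name,
            model="model1_competition",
            members=members,
            initial_state=CompetitionState(
                x=np.zeros(m), y=np.ones(m), z=1.0
            ),
            t_end=HORIZON_PATHOGEN_SELECTION,
        )

    grid, kernel = _default_grid_and_kernel()

    if name == "shm_self_tolerance":
        # Strong self-binder seeded in class 9; sweep the SHM rate.
        p_values = (0.1, 0.2, 0.3, 0.4)
        members = {
            f"p={p:g}": Model2Params(
                grid=grid, kernel=kernel, k3=0.5, k4=0.6, k6=0.02, p=p
            )
            for p in p_values
        }
        y0 = np.zeros(9)
        y0[8] = 1e5
        return ScenarioSpec(
            name=name,
            model="model2_self",
            members=members,
            initial_state=Model2State(x=np.zeros(9), y=y0, z=2e6),
            t_end=HORIZON_SHM_SELF_TOLERANCE,
            p_values=p_values,
        )

    if name == "shm_foreign":
        # Foreign antigen (elevated k4); seed the weakest-binding class
        # and compare no-SHM against SHM at 0.5.
        p_values = (0.0, 0.5)
        members = {
            f"p={p:g}": Model2Params(
                grid=grid, kernel=kernel, k3=0.5, k4=1.1, k6=0.02, p=p
            )
            for p in p_values
        }
        y0 = np.zeros(9)
        y0[SHM_FOREIGN_SEED_CLASS - 1] = 1e5
        # Concentrations span >10 decades along the cascade; the default
        # atol would treat the mutant seed fluxes as noise.
        return ScenarioSpec(
            name=name,
            model="model2_foreign",
            members=members,
            initial_state=Model2State(x=np.zeros(9), y=y0, z=2e6),
            t_end=HORIZON_SHM_FOREIGN,
            p_values=p_values,
            rtol=1e-10,
            atol=1e-12,
        )

    if name == "aging_sweep":
        # Naive repertoire distributed by the normal bin masses; moderate
        # self stimulation (k4=0.7); sweep the SHM rate.
        p_values = (0.0, 0.2, 0.5)
        members = {
            f"p={p:g}": Model2Params(
                grid=grid, kernel=kernel, k3=0.5, k4=0.7, k6=0.02, p=p
            )
            for p in p_values
        }
        y0 = initial_composition(grid, 1e6)
        t_end = HORIZON_AGING_SWEEP
        return ScenarioSpec(
            name=name,
            model="model2_self",
            members=members,
            initial_state=Model2State(x=np.zeros(9), y=y0, z=2e6),
            t_end=t_end,
            p_values=p_values,
            report_times=tuple(f * t_end for f in AGING_LADDER_FRACTIONS),
        )

    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}"
    )


def metrics(trajectory: Trajectory) -> SummaryMetrics:
    """Summarize a Model 2 trajectory (columns z, x_1.., y_1..).

    Raises ValueError for trajectories without a per-class antibody block.
    """
    if not trajectory.labels or trajectory.labels[0] != "z":
        raise ValueError(
            "metrics requires a Model 2 trajectory (leading 'z' column "
            "followed by per-class x_i, y_i)"
        )
    y = trajectory.columns("y")
    total = y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        composition = np.where(total[:, None] > 0, y / total[:, None], np.nan)
    classes = np.arange(1, y.shape[1] + 1)
    dominant = np.argmax(y, axis=1) + 1  # argmax ties break toward low index
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_idx = np.where(total > 0, (y * classes).sum(axis=1) / total, np.nan)
    return SummaryMetrics(
        times=trajectory.times,
        total_antibody=total,
        composition=composition,
        dominant_class=dominant,
        mean_class_index=mean_idx,
        y0=y[0].copy(),
    )


def _run_member(spec: ScenarioSpec, params, rtol: float, atol: float):
    if spec.model == "model1_self":
        return model1.integrate(
            model1.rhs_self, spec.initial_state, params, spec.t_end,
            spec.n_points, rtol, atol,
        )
    if spec.model == "model1_pathogen":
        return model1.integrate(
            model1.rhs_pathogen, spec.initial_state, params, spec.t_end,
            spec.n_points, rtol, atol,
        )
    if spec.model == "model1_competition":
        return model1.integrate(
            model1.rhs_competition, spec.initial_state, params, spec.t_end,
            spec.n_points, rtol, atol,
        )
    # model2_self / model2_foreign: antigen constant in both (the foreign
    # preset differs only through k4)
    return model2.integrate_shm(
        spec.initial_state, params, spec.t_end, spec.n_points, rtol, atol,
    )


def run(
    spec: ScenarioSpec,
    out_dir: str | Path | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> dict[str, tuple[Trajectory, SummaryMetrics | None]]:
    """Integrate every sweep member and compute summary metrics.

    Deterministic: identical inputs give identical outputs.  Metrics are
    computed for Model 2 members only (Model 1 trajectories have a single
    antibody and no repertoire composition).

    When ``out_dir`` is given, writes one trajectory CSV per member plus a
    metrics JSON for the scenario.
    """
    rtol = spec.rtol if rtol is None else rtol
    atol = spec.atol if atol is None else atol
    results: dict[str, tuple[Trajectory, SummaryMetrics | None]] = {}
    for label, params in spec.members.items():
        try:
            traj = _run_member(spec, params, rtol, atol)
        except Exception as exc:
            raise type(exc)(
                f"scenario {spec.name!r}, member {label!r}: {exc}"
            ) from exc
        summ = metrics(traj) if spec.model.startswith("model2") else None
        results[label] = (traj, summ)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload: dict = {
            "scenario": spec.name,
            "model": spec.model,
            "t_end": spec.t_end,
            "n_points": spec.n_points,
            "members": {},
        }
        if spec.report_times is not None:
            payload["report_times"] = list(spec.report_times)
        for label, (traj, summ) in results.items():
            slug = label.replace("=", "").replace(".", "_")
            traj.to_csv(out / f"{spec.name}_{slug}.csv")
            if summ is not None:
                entry = summ.to_dict()
                if spec.report_times is not None:
                    entry["ladder"] = [
                        summ.at_time(t) for t in spec.report_times
                    ]
                payload["members"][label] = entry
        with open(out / f"{spec.name}_metrics.json", "w") as fh:
            json.dump(payload, fh, indent=1)
    return results
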