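"""Discrete antibody affinity classes and the somatic-hypermutation kernel.

Antibody–antigen binding strength is summarized by the equilibrium
dissociation constant Kd = k_minus2 / k2 (dissociation over association
rate).  Empirically, log10-Kd across antigen–antibody complexes is well
described by a normal distribution with mean -9 and unit variance; this
module discretizes that axis into unit-width bins ("affinity classes") and
derives, for each class, the probability that a point mutation moves a
newly produced antibody to the adjacent weaker-binding class, leaves it in
place, or moves it to the adjacent stronger-binding class.

Classes are indexed 1..n in ascending binding strength: class 1 is the
weakest binder (largest Kd), class n the strongest.  Under the defaults
(n=9, shared k_minus2 = 1e-18, k2 from 1e-13 to 1e-5) the log10-Kd ladder
runs -5, -6, ..., -13 and class 5 sits at the distribution mean.

The mutation kernel lumps all normal-distribution mass outside a class's
own bin into its two immediate neighbours: mass on the weaker-binding side
goes entirely to class i-1, mass on the stronger-binding side to class
i+1.  At the edges of the grid, mass that would leave the ladder is folded
into "stay", so every row is a proper probability triple.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError

__all__ = [
    "AffinityClass",
    "AffinityGrid",
    "MutationKernel",
    "build_grid",
    "bin_mass",
    "mutation_split",
    "build_kernel",
    "initial_composition",
]

_LADDER_RTOL = 1e-9  # relative tolerance on the decade-spacing precondition


@dataclass(frozen=True)
class AffinityClass:
    """One discrete affinity class.

    Parameters
    ----------
    index : int
        1-based position on the ladder (ascending binding strength).
    log10_kd : float
        log10 of the equilibrium dissociation constant; more negative
        means stronger binding.
    k2 : float
        Association rate constant (per concentration per time).
    k_minus2 : float
        Dissociation rate constant (per time).
    """

    index: int
    log10_kd: float
    k2: float
    k_minus2: float

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.k_minus2 <= 0:
            raise ValueError("k2 and k_minus2 must be positive")
        derived = math.log10(self.k_minus2 / self.k2)
        if abs(derived - self.log10_kd) > 1e-12:
            raise ValueError(
                f"log10_kd={self.log10_kd} inconsistent with "
                f"log10(k_minus2/k2)={derived}"
            )


@dataclass(frozen=True)
class AffinityGrid:
    """An ordered ladder of affinity classes plus the log10-Kd distribution
    (normal with mean ``mu`` and standard deviation ``sigma``) that drives
    mutation transitions and the initial repertoire composition."""

    classes: tuple[AffinityClass, ...]
    mu: float = -9.0
    sigma: float = 1.0
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        k2s = [c.k2 for c in self.classes]
        kds = [c.log10_kd for c in self.classes]
        if any(b <= a for a, b in zip(k2s, k2s[1:])):
            raise ValueError("k2 must be strictly increasing with class index")
        for a, b in zip(kds, kds[1:]):
            if abs((a - b) - self.bin_width) > 1e-9:
                raise ValueError(
                    "log10_kd must decrease by exactly bin_width per class"
                )

    @property
    def n(self) -> int:
        return len(self.classes)

    @property
    def k2(self) -> np.ndarray:
        return np.array([c.k2 for c in self.classes])

    @property
    def k_minus2(self) -> np.ndarray:
        return np.array([c.k_minus2 for c in self.classes])

    @property
    def log10_kd(self) -> np.ndarray:
        return np.array([c.log10_kd for c in self.classes])

    def __getitem__(self, i: int) -> AffinityClass:
        """1-based class lookup."""
        self._check_index(i)
        return self.classes[i - 1]

    def _check_index(self, i: int) -> None:
        if not 1 <= i <= self.n:
            raise IndexError(f"class index {i} outside 1..{self.n}")


@dataclass(frozen=True)
class MutationKernel:
    """Per-class probabilities that a mutated offspring moves one class
    weaker, stays, or moves one class stronger.  Rows sum to 1."""

    p_weaker: np.ndarray
    p_stay: np.ndarray
    p_stronger: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.p_stay)
        if not (len(self.p_weaker) == len(self.p_stronger) == n):
            raise ValueError("kernel columns must have equal length")
        rows = self.p_weaker + self.p_stay + self.p_stronger
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("kernel rows must sum to 1")

    @property
    def n(self) -> int:
        return len(self.p_stay)

    def row(self, i: int) -> tuple[float, float, float]:
        """1-based (p_weaker, p_stay, p_stronger) for class ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"class index {i} outside 1..{self.n}")
        j = i - 1
        return (
            float(self.p_weaker[j]),
            float(self.p_stay[j]),
            float(self.p_stronger[j]),
        )

    def as_dataframe(self, grid: AffinityGrid) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_index": np.arange(1, self.n + 1),
                "log10_kd": grid.log10_kd,
                "k2": grid.k2,
                "k_minus2": grid.k_minus2,
                "p_weaker": self.p_weaker,
                "p_stay": self.p_stay,
                "p_stronger": self.p_stronger,
            }
        )

    def to_csv(self, grid: AffinityGrid, path=None) -> str | None:
        """Dump the kernel as CSV at full double precision.

        Returns the CSV text when ``path`` is None.
        """
        df = self.as_dataframe(grid)
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format="%.17g")
            return buf.getvalue()
        df.to_csv(path, index=False, float_format="%.17g")
        return None


def build_grid(
    n: int = 9,
    k2_weakest: float = 1e-13,
    k2_strongest: float = 1e-5,
    k_minus2: float = 1e-18,
    mu: float = -9.0,
    sigma: float = 1.0,
) -> AffinityGrid:
    """Construct a decade-spaced ladder of ``n`` affinity classes.

    Association rates are log-evenly spaced from ``k2_weakest`` to
    ``k2_strongest`` (the ratio must be exactly 10^(n-1), i.e. one decade
    per class); all classes share ``k_minus2``, so log10-Kd descends by one
    per class.

    Raises
    ------
    ValueError
        If ``n < 1`` or a rate is non-positive.
    ConfigurationError
        If the k2 endpoints are not decade-spaced for ``n`` classes.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k2_weakest <= 0 or k2_strongest <= 0 or k_minus2 <= 0:
        raise ValueError("rate constants must be positive")
    expected_ratio = 10.0 ** (n - 1)
    ratio = k2_strongest / k2_weakest
    if abs(ratio / expected_ratio - 1.0) > _LADDER_RTOL:
        raise ConfigurationError(
            f"k2_strongest/k2_weakest = {ratio:g}, expected 10^(n-1) = "
            f"{expected_ratio:g} for decade-spaced classes"
        )
    exponents = math.log10(k2_weakest) + np.arange(n)
    classes = tuple(
        AffinityClass(
            index=i + 1,
            log10_kd=math.log10(k_minus2) - e,
            k2=10.0**e,
            k_minus2=k_minus2,
        )
        for i, e in enumerate(exponents)
    )
    return AffinityGrid(classes=classes, mu=mu, sigma=sigma)


def _bin_edges(grid: AffinityGrid, i: int) -> tuple[float, float]:
    """(lower, upper) log10-Kd edges of class i's bin; lower is the
    stronger-binding side."""
    center = grid[i].log10_kd
    half = grid.bin_width / 2.0
    return center - half, center + half


def bin_mass(grid: AffinityGrid, i: int) -> float:
    """Normal(mu, sigma^2) mass on class ``i``'s log10-Kd bin
    [center - w/2, center + w/2)."""
    grid._check_index(i)
    lower, upper = _bin_edges(grid, i)
    dist = norm(loc=grid.mu, scale=grid.sigma)
    return float(dist.cdf(upper) - dist.cdf(lower))


def mutation_split(grid: AffinityGrid, i: int) -> tuple[float, float, float]:
    """(p_weaker, p_stay, p_stronger) for a mutated offspring of class ``i``.

    The offspring's log10-Kd is conceptually redrawn from
    Normal(mu, sigma^2).  Mass inside class i's own bin is "stay"; all mass
    on the weaker-binding side (larger log10-Kd) is lumped into the single
    adjacent weaker class, all mass on the stronger-binding side into the
    adjacent stronger class.  At the ends of the ladder the off-grid lump
    is folded into "stay", so the triple sums to 1 exactly.
    """
    grid._check_index(i)
    lower, upper = _bin_edges(grid, i)
    dist = norm(loc=grid.mu, scale=grid.sigma)
    p_stronger_side = float(dist.cdf(lower))       # log10_kd < lower
    p_weaker_side = float(dist.sf(upper))          # log10_kd > upper
    p_weaker = p_weaker_side if i > 1 else 0.0
    p_stronger = p_stronger_side if i < grid.n else 0.0
    # "stay" takes the bin's own mass plus any off-grid lump; computing it
    # as the complement makes the row sum exactly 1 in floating point.
    p_stay = 1.0 - p_weaker - p_stronger
    return p_weaker, p_stay, p_stronger


def build_kernel(grid: AffinityGrid) -> MutationKernel:
    """Apply :func:`mutation_split` to every class of ``grid``."""
    triples = [mutation_split(grid, i) for i in range(1, grid.n + 1)]
    pw, ps, pst = (np.array(col) for col in zip(*triples))
    return MutationKernel(p_weaker=pw, p_stay=ps, p_stronger=pst)


def initial_composition(grid: AffinityGrid, total: float) -> np.ndarray:
    """Distribute ``total`` antibody over the classes in proportion to the
    normal bin masses (the naive, pre-selection repertoire).

    The fractions sum to slightly less than 1: mass in the tails beyond
    the outermost bins is excluded.
    """
    if total < 0:
        raise ValueError(f"total must be >= 0, got {total}")
    masses = np.array([bin_mass(grid, i) for i in range(1, grid.n + 1)])
    return total * masses
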