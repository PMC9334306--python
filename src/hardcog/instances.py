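"""Domain types for the three NP-complete decision problems.

The package studies decision variants of Boolean satisfiability (3SAT), the
Euclidean traveling salesperson problem (TSP) and the 0-1 knapsack problem
(KP).  Each instance type carries the data defining one decision question
("is this formula satisfiable?", "is there a closed tour of length at most
L?", "is there a subset with weight <= c and value >= p?") together with the
*constrainedness* order parameter alpha that governs the probability that a
random instance is satisfiable:

* 3SAT: ``alpha = M / N`` (clauses per variable),
* TSP:  ``alpha = -L / (M_side * sqrt(N))`` with ``M_side`` the map-square
  side length (alpha is negative by construction; larger path limits make
  the instance *less* constrained, i.e. alpha more negative),
* KP:   the pair ``alpha_p = p / sum(v_i)`` and ``alpha_c = c / sum(w_i)``.

Random ensembles of each problem undergo a satisfiability phase transition
in alpha; instances near the threshold are, on average, the hardest.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .exceptions import InvalidInstanceError

# Region / TCC labels used throughout the package.
UNDER = "underconstrained"
THRESHOLD = "threshold"
OVER = "overconstrained"
REGIONS = (UNDER, THRESHOLD, OVER)
TCC_LOW = "low"
TCC_HIGH = "high"


class VacuousConstraintWarning(UserWarning):
    """A constraint can never bind (e.g. knapsack capacity >= total weight)."""


@dataclass(frozen=True)
class Sat3Instance:
    """A 3SAT formula: a conjunction of 3-literal OR-clauses over N variables.

    Literals are nonzero signed 1-based variable indices (DIMACS convention):
    ``-3`` is the negation of variable 3.  The three variables within a
    clause are pairwise distinct.
    """

    num_vars: int
    clauses: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.num_vars < 1:
            raise InvalidInstanceError("3SAT instance needs at least one variable")
        clauses = tuple(tuple(int(l) for l in cl) for cl in self.clauses)
        object.__setattr__(self, "clauses", clauses)
        for i, cl in enumerate(clauses):
            if len(cl) != 3:
                raise InvalidInstanceError(f"clause {i} has {len(cl)} literals, expected 3")
            for lit in cl:
                if lit == 0 or abs(lit) > self.num_vars:
                    raise InvalidInstanceError(
                        f"clause {i} literal {lit} outside 1..{self.num_vars}"
                    )
            if len({abs(l) for l in cl}) != 3:
                raise InvalidInstanceError(f"clause {i} repeats a variable: {cl}")

    @property
    def num_clauses(self) -> int:
        return len(self.clauses)

    def fingerprint(self) -> str:
        payload = f"sat3|{self.num_vars}|{self.clauses}"
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TspInstance:
    """A Euclidean TSP decision instance on a square map.

    ``coords`` are N (x, y) points in map units, ``map_side`` the side length
    of the map square, and ``path_limit`` the maximum allowed closed-tour
    length.  Pairwise distances are Euclidean at full floating precision.
    """

    coords: tuple[tuple[float, float], ...]
    map_side: float
    path_limit: float

    def __post_init__(self) -> None:
        coords = tuple((float(x), float(y)) for x, y in self.coords)
        object.__setattr__(self, "coords", coords)
        if len(coords) < 3:
            raise InvalidInstanceError("TSP instance needs at least 3 cities")
        if not self.map_side > 0:
            raise InvalidInstanceError("map_side must be positive")
        if not self.path_limit > 0:
            raise InvalidInstanceError("path_limit must be positive")
        for i, (x, y) in enumerate(coords):
            if not (0 <= x <= self.map_side and 0 <= y <= self.map_side):
                warnings.warn(
                    f"city {i} at ({x}, {y}) lies outside [0, {self.map_side}]^2",
                    VacuousConstraintWarning,
                    stacklevel=2,
                )

    @property
    def num_cities(self) -> int:
        return len(self.coords)

    def coord_array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=np.float64)

    def distance_matrix(self) -> np.ndarray:
        """Full-precision Euclidean distance matrix (no TSPLIB rounding)."""
        xy = self.coord_array()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def fingerprint(self) -> str:
        payload = f"tsp|{self.map_side!r}|{self.path_limit!r}|{self.coords!r}"
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class KpInstance:
    """A 0-1 knapsack decision instance.

    Decide whether a subset S of items exists with
    ``sum(w_i, i in S) <= capacity`` and ``sum(v_i, i in S) >= target_profit``.
    Weights, values, capacity and target profit are positive integers.
    """

    weights: tuple[int, ...]
    values: tuple[int, ...]
    capacity: int
    target_profit: int

    def __post_init__(self) -> None:
        weights = tuple(int(w) for w in self.weights)
        values = tuple(int(v) for v in self.values)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "values", values)
        if len(weights) == 0:
            raise InvalidInstanceError("knapsack instance needs at least one item")
        if len(weights) != len(values):
            raise InvalidInstanceError("weights and values must have equal length")
        if any(w < 1 for w in weights) or any(v < 1 for v in values):
            raise InvalidInstanceError("weights and values must be positive integers")
        if self.capacity < 1 or self.target_profit < 1:
            raise InvalidInstanceError("capacity and target profit must be positive")
        if self.capacity >= sum(weights):
            warnings.warn(
                "capacity >= total weight: the weight constraint is vacuous",
                VacuousConstraintWarning,
                stacklevel=2,
            )

    @property
    def num_items(self) -> int:
        return len(self.weights)

    def fingerprint(self) -> str:
        payload = (
            f"kp|{self.weights}|{self.values}|{self.capacity}|{self.target_profit}"
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


Instance = Union[Sat3Instance, TspInstance, KpInstance]


def problem_name(instance: Instance) -> str:
    if isinstance(instance, Sat3Instance):
        return "sat3"
    if isinstance(instance, TspInstance):
        return "tsp"
    if isinstance(instance, KpInstance):
        return "kp"
    raise TypeError(f"not a problem instance: {instance!r}")


@dataclass(frozen=True)
class ConstrainednessProfile:
    """Constrainedness of one instance, optionally with its region/TCC label.

    ``alpha`` is the problem's order parameter (for KP, the profit ratio
    alpha_p; the capacity ratio is carried in ``alpha_c``).  ``tcc`` is
    ``"high"`` iff the instance sits in the threshold region.
    """

    alpha: float
    alpha_c: Optional[float] = None
    region: Optional[str] = None
    tcc: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region is not None and self.region not in REGIONS:
            raise InvalidInstanceError(f"unknown region {self.region!r}")
        if self.tcc is not None:
            if self.tcc not in (TCC_LOW, TCC_HIGH):
                raise InvalidInstanceError(f"unknown TCC label {self.tcc!r}")
            if self.region is not None and (
                (self.tcc == TCC_HIGH) != (self.region == THRESHOLD)
            ):
                raise InvalidInstanceError(
                    "TCC is high if and only if the region is the threshold"
                )


def constrainedness(instance: Instance) -> ConstrainednessProfile:
    """Compute the constrainedness order parameter of an instance.

    Returns a profile with ``alpha`` only (region and TCC unset); use
    :func:`hardcog.metrics.tcc_label` to classify against a region spec.
    """
    if isinstance(instance, Sat3Instance):
        return ConstrainednessProfile(alpha=instance.num_clauses / instance.num_vars)
    if isinstance(instance, TspInstance):
        n = instance.num_cities
        alpha = -instance.path_limit / (instance.map_side * math.sqrt(n))
        return ConstrainednessProfile(alpha=alpha)
    if isinstance(instance, KpInstance):
        alpha_p = instance.target_profit / sum(instance.values)
        alpha_c = instance.capacity / sum(instance.weights)
        return ConstrainednessProfile(alpha=alpha_p, alpha_c=alpha_c)
    raise TypeError(f"not a problem instance: {instance!r}")
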