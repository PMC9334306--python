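"""Hardness metrics and empirical satisfiability-threshold machinery.

Three task-independent metrics are computed per instance:

* **TCC** (typical-case complexity): an ensemble-level label — ``high`` for
  instances in the threshold region of the constrainedness parameter,
  ``low`` in the under-/over-constrained regions.
* **Witness count**: the number of state-space configurations (assignments,
  directed tours from a fixed start, item subsets) satisfying all the
  instance's constraints.  Exact for 3SAT and KP; for TSP the enumeration
  halts at a cap (default 30000) and the bundle records the truncation.
* **IC** (instance complexity): ``|alpha - alpha*|``, the normalized gap
  between the decision threshold and the optimization optimum —

  - 3SAT: ``(M - maxsat) / N``
  - TSP:  ``|L - min tour| / sqrt(map area * N)``
  - KP:   ``|p - max profit| / sum(v_i)``

  Smaller IC means the decision boundary sits closer to the optimum, i.e. a
  harder instance.  Every satisfiable 3SAT instance has IC = 0.

The satisfiability curve sweeps alpha, Monte-Carlo-estimating the fraction
of random instances that are satisfiable, and the threshold estimate is the
grid point whose fraction is nearest one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _tsp
from .exceptions import ConsistencyError, RangeError, UnclassifiedAlphaError
from .generators import GeneratorConfig, sample_kp, sample_sat3, sample_tsp, tsp_path_limit
from .instances import (
    TCC_HIGH,
    TCC_LOW,
    THRESHOLD,
    Instance,
    KpInstance,
    Sat3Instance,
    TspInstance,
    constrainedness,
    problem_name,
)
from .solvers import SolveResult, _kp_totals, _sat_counts, is_satisfiable, solve

WITNESS_CAP = 30000


@dataclass(frozen=True)
class MetricBundle:
    """Per-instance hardness metrics."""

    problem: str
    alpha: float
    alpha_c: Optional[float]
    region: Optional[str]
    tcc: Optional[str]
    satisfiable: bool
    witnesses: int
    witnesses_capped: bool
    ic: float
    fingerprint: str


# ---------------------------------------------------------------------------
# Witness counting
# ---------------------------------------------------------------------------

def count_witnesses(instance: Instance, cap: int = WITNESS_CAP) -> tuple[int, bool]:
    """Count solution witnesses. Returns (count, capped).

    3SAT and KP counts are exact (the 2^N state space is enumerated).  TSP
    counts directed tours with a fixed start city (reversals distinct) and
    stop once ``cap`` witnesses have been found, reporting ``capped=True``.
    """
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    if isinstance(instance, Sat3Instance):
        counts = _sat_counts(instance)
        return int((counts == instance.num_clauses).sum()), False
    if isinstance(instance, KpInstance):
        tot_w, tot_v = _kp_totals(instance)
        ok = (tot_w <= instance.capacity) & (tot_v >= instance.target_profit)
        return int(ok.sum()), False
    if isinstance(instance, TspInstance):
        d = instance.distance_matrix()
        count, _nodes = _tsp.count_tours_within(d, float(instance.path_limit), cap)
        count = int(count)
        return count, count >= cap
    raise TypeError(f"not a problem instance: {instance!r}")


# ---------------------------------------------------------------------------
# Instance complexity
# ---------------------------------------------------------------------------

def instance_complexity(instance: Instance, solve_result: SolveResult) -> float:
    """IC = |alpha - alpha*|, from an instance and its solve result."""
    if solve_result.fingerprint != instance.fingerprint():
        raise ConsistencyError(
            "solve result was not computed from this instance "
            f"({solve_result.fingerprint} != {instance.fingerprint()})"
        )
    if isinstance(instance, Sat3Instance):
        return (instance.num_clauses - solve_result.optimum) / instance.num_vars
    if isinstance(instance, TspInstance):
        denom = instance.map_side * math.sqrt(instance.num_cities)
        return abs(instance.path_limit - solve_result.optimum) / denom
    if isinstance(instance, KpInstance):
        return abs(instance.target_profit - solve_result.optimum) / sum(instance.values)
    raise TypeError(f"not a problem instance: {instance!r}")


# ---------------------------------------------------------------------------
# Region / TCC classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionBand:
    """Closed interval of alpha values (a point band when lo == hi)."""

    lo: float
    hi: float
    tol: float = 1e-9

    def contains(self, alpha: float) -> bool:
        return self.lo - self.tol <= alpha <= self.hi + self.tol


@dataclass(frozen=True)
class RegionSpec:
    """The three alpha bands a study design declares."""

    problem: str
    bands: dict[str, RegionBand]

    def classify(self, alpha: float) -> str:
        for region, band in self.bands.items():
            if band.contains(alpha):
                return region
        raise UnclassifiedAlphaError(
            f"alpha = {alpha} falls outside every declared {self.problem} band"
        )


def tcc_label(alpha: float, region_spec: RegionSpec) -> tuple[str, str]:
    """Map alpha to (region, tcc); TCC is high iff the region is threshold."""
    region = region_spec.classify(alpha)
    return region, TCC_HIGH if region == THRESHOLD else TCC_LOW


def compute_metrics(
    instance: Instance,
    solve_result: Optional[SolveResult] = None,
    region_spec: Optional[RegionSpec] = None,
    cap: int = WITNESS_CAP,
) -> MetricBundle:
    """Assemble the full metric bundle for one instance."""
    if solve_result is None:
        solve_result = solve(instance, compute_effort=False)
    profile = constrainedness(instance)
    region = tcc = None
    if region_spec is not None:
        region, tcc = tcc_label(profile.alpha, region_spec)
    witnesses, capped = count_witnesses(instance, cap=cap)
    ic = instance_complexity(instance, solve_result)
    return MetricBundle(
        problem=problem_name(instance),
        alpha=profile.alpha,
        alpha_c=profile.alpha_c,
        region=region,
        tcc=tcc,
        satisfiable=solve_result.satisfiable,
        witnesses=witnesses,
        witnesses_capped=capped,
        ic=ic,
        fingerprint=instance.fingerprint(),
    )


# ---------------------------------------------------------------------------
# Satisfiability curve and threshold
# ---------------------------------------------------------------------------

@dataclass
class SatCurve:
    """Empirical satisfiable fraction along an alpha grid."""

    problem: str
    size: int
    alphas: np.ndarray
    fractions: np.ndarray
    n_per_point: int

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.alphas.ndim != 1 or len(self.alphas) == 0:
            raise ValueError("alpha grid must be a nonempty 1-D array")
        if np.any(np.diff(self.alphas) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def standard_errors(self) -> np.ndarray:
        f = self.fractions
        return np.sqrt(f * (1 - f) / self.n_per_point)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "n_sampled": self.n_per_point,
                "fraction_satisfiable": self.fractions,
                "se": self.standard_errors(),
            }
        )

    def plot(self, ax=None):
        """Satisfiable fraction vs alpha with binomial error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.alphas, self.fractions, yerr=self.standard_errors(), fmt="o-", ms=3)
        ax.axhline(0.5, color="grey", ls="--", lw=0.8)
        ax.set_xlabel(r"constrainedness $\alpha$")
        ax.set_ylabel("P(satisfiable)")
        ax.set_title(f"{self.problem}, N={self.size}, {self.n_per_point}/point")
        return ax


@dataclass(frozen=True)
class ThresholdEstimate:
    """Grid alpha whose satisfiable fraction is nearest one half."""

    alpha_s: float
    grid_step: float
    n_per_point: int


def satisfiability_curve(
    problem: str,
    size: int,
    alpha_grid: Sequence[float],
    n_per_point: int,
    rng: np.random.Generator,
    map_side: float = 1000.0,
    clause_cap: Optional[int] = None,
) -> SatCurve:
    """Monte-Carlo satisfiable fraction along an alpha grid.

    For 3SAT, fresh instances are generated and solved exactly at every grid
    point.  For TSP, ``n_per_point`` coordinate sets are generated once and
    each map's exact optimal tour is computed once; the grid then varies only
    the path limit, so all grid points share the same maps (this is how the
    instance ensemble is constructed and makes the curve for one map a step
    function of alpha).
    """
    grid = np.asarray(list(alpha_grid), dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("alpha grid must be nonempty")
    if n_per_point < 1:
        raise ValueError("n_per_point must be >= 1")
    if problem == "sat3":
        fractions = np.empty(len(grid))
        for i, alpha in enumerate(grid):
            config = GeneratorConfig(
                problem="sat3", size=size, alpha=float(alpha), clause_cap=clause_cap
            )
            sat = 0
            for _ in range(n_per_point):
                try:
                    inst = sample_sat3(config, rng)
                except Exception as exc:
                    raise type(exc)(f"at grid alpha={alpha}: {exc}") from exc
                sat += is_satisfiable(inst)
            fractions[i] = sat / n_per_point
        return SatCurve("sat3", size, grid, fractions, n_per_point)
    if problem == "tsp":
        optima = np.empty(n_per_point)
        for j in range(n_per_point):
            coords = rng.uniform(0.0, map_side, size=(size, 2))
            inst = TspInstance(
                coords=tuple((float(x), float(y)) for x, y in coords),
                map_side=map_side,
                path_limit=1.0,  # placeholder; optimum does not depend on it
            )
            optima[j] = solve(inst, compute_effort=False).optimum
        limits = np.array([tsp_path_limit(a, size, map_side) for a in grid])
        fractions = (optima[None, :] <= limits[:, None]).mean(axis=1)
        return SatCurve("tsp", size, grid, fractions, n_per_point)
    if problem == "kp":
        # grid interpreted as alpha_p values at fixed default alpha_c band
        fractions = np.empty(len(grid))
        for i, alpha in enumerate(grid):
            config = GeneratorConfig(
                problem="kp", size=size, alpha_p_band=(float(alpha), float(alpha) + 1e-2)
            )
            sat = 0
            for _ in range(n_per_point):
                inst = sample_kp(config, rng)
                sat += is_satisfiable(inst)
            fractions[i] = sat / n_per_point
        return SatCurve("kp", size, grid, fractions, n_per_point)
    raise ValueError(f"unknown problem {problem!r}")


def estimate_threshold(curve: SatCurve) -> ThresholdEstimate:
    """Grid point whose satisfiable fraction is nearest 0.5.

    Ties are broken toward the less-constrained side (smaller alpha for both
    3SAT and TSP, where satisfiability is non-increasing in alpha).
    """
    f = curve.fractions
    if f.min() > 0.5 or f.max() < 0.5:
        raise RangeError("curve does not bracket a satisfiable fraction of 0.5")
    dist = np.abs(f - 0.5)
    # ties (up to float noise) resolve to the first = smallest-alpha point
    idx = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0])
    steps = np.diff(curve.alphas)
    return ThresholdEstimate(
        alpha_s=float(curve.alphas[idx]),
        grid_step=float(np.median(steps)) if len(steps) else 0.0,
        n_per_point=curve.n_per_point,
    )


def max_isotonic_residual(curve: SatCurve) -> float:
    """Largest deviation from the best non-increasing fit, in pooled-SE units.

    Used to test that the satisfiable fraction is monotonically non-increasing
    in alpha up to sampling noise.
    """
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(curve.alphas, curve.fractions)
    resid = np.abs(curve.fractions - fitted)
    pooled_se = math.sqrt(
        max(np.mean(curve.fractions * (1 - curve.fractions)), 0.25 / curve.n_per_point)
        / curve.n_per_point
    )
    return float(resid.max() / pooled_se)
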