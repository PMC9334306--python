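"""Random-instance samplers for the three problem ensembles.

The ensembles mirror the study's generation procedures:

* 3SAT: ``M = round(alpha * N)`` clauses; each clause picks 3 distinct
  variables uniformly without replacement and independent fair-coin signs.
  The M clauses are pairwise distinct by default (at N = 5 only 80 clauses
  exist, so duplicates would dilute the effective constrainedness and shift
  the empirical threshold well above the reference value of 4.8; a config
  flag permits duplicates).  The number of clauses is capped (default 36,
  the number that fits on the task screen).
* TSP: N city coordinates i.i.d. uniform on a square of side ``map_side``
  (default 1000 map units); the path limit follows from alpha through
  ``L = -alpha * map_side * sqrt(N)``.
* KP: integer weights and values i.i.d. uniform on [1, 100] with N = 6
  items by default (the source ensemble's item distribution is not pinned
  down further; the ranges are exposed in the config).  Capacity and target
  profit are derived from capacity/profit ratios drawn uniformly from
  configurable bands, with resampling until the *realized* ratios land
  inside the bands after integer rounding.

Everything is driven by a ``numpy.random.Generator``; (config, seed) fully
determines the emitted instance.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, GenerationError
from .instances import KpInstance, Sat3Instance, TspInstance

DEFAULT_CLAUSE_CAP = 36
DEFAULT_MAP_SIDE = 1000.0


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent, named random stream derived from a master seed.

    Each pipeline stage gets its own stream so regenerating one problem
    family does not perturb another.
    """
    return np.random.default_rng([master_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass
class GeneratorConfig:
    """Ensemble parameters for one problem family.

    ``alpha`` is the target constrainedness (ignored for KP, which uses the
    two ratio bands instead).  ``seed`` is optional; sampling functions also
    accept an explicit ``numpy.random.Generator``.
    """

    problem: str
    size: int
    alpha: Optional[float] = None
    map_side: float = DEFAULT_MAP_SIDE
    seed: Optional[int] = None
    clause_cap: Optional[int] = DEFAULT_CLAUSE_CAP
    distinct_clauses: bool = True
    alpha_c_band: tuple[float, float] = (0.40, 0.45)
    alpha_p_band: tuple[float, float] = (0.60, 0.65)
    weight_range: tuple[int, int] = (1, 100)
    value_range: tuple[int, int] = (1, 100)

    def __post_init__(self) -> None:
        if self.problem not in ("sat3", "tsp", "kp"):
            raise ConfigurationError(f"unknown problem {self.problem!r}")
        min_size = 3 if self.problem == "tsp" else 1
        if self.size < min_size:
            raise ConfigurationError(
                f"{self.problem} needs size >= {min_size}, got {self.size}"
            )
        for band in (self.alpha_c_band, self.alpha_p_band):
            if not (0 < band[0] <= band[1] < 1):
                raise ConfigurationError(f"ratio band {band} not a subinterval of (0,1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _resolve_rng(config: GeneratorConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else config.rng()


def sample_sat3(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> Sat3Instance:
    """Draw one random 3SAT instance with M = round(alpha * N) clauses."""
    if config.problem != "sat3":
        raise ConfigurationError("config.problem must be 'sat3'")
    if config.alpha is None or config.alpha < 0:
        raise ConfigurationError("sat3 sampling needs a nonnegative alpha")
    rng = _resolve_rng(config, rng)
    n = config.size
    m = round_half_away(config.alpha * n)
    if config.clause_cap is not None and m > config.clause_cap:
        raise ConfigurationError(
            f"round(alpha*N) = {m} exceeds the clause cap {config.clause_cap}"
        )
    clauses = _draw_clauses(n, m, rng)
    if config.distinct_clauses:
        seen = {_canonical_clause(cl) for cl in clauses}
        attempts = 0
        while len(seen) < m:
            extra = _draw_clauses(n, m - len(seen), rng)
            for cl in extra:
                key = _canonical_clause(cl)
                if key not in seen:
                    seen.add(key)
                    clauses.append(cl)
            attempts += 1
            if attempts > 1000:
                raise GenerationError("could not draw enough distinct clauses")
        # keep only the first occurrence of each canonical clause, in order
        kept, seen2 = [], set()
        for cl in clauses:
            key = _canonical_clause(cl)
            if key not in seen2:
                seen2.add(key)
                kept.append(cl)
        clauses = kept[:m]
    return Sat3Instance(num_vars=n, clauses=tuple(clauses))


def _draw_clauses(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    if m == 0:
        return []
    base = np.tile(np.arange(1, n + 1), (m, 1))
    variables = rng.permuted(base, axis=1)[:, :3]
    signs = rng.integers(0, 2, size=(m, 3)) * 2 - 1
    lits = variables * signs
    return [tuple(int(x) for x in row) for row in lits]


def _canonical_clause(cl: tuple[int, int, int]) -> tuple[int, ...]:
    return tuple(sorted(cl, key=abs))


def sample_tsp(config: GeneratorConfig, rng: Optional[np.random.Generator] = None) -> TspInstance:
    """Draw one random Euclidean TSP instance on the map square."""
    if config.problem != "tsp":
        raise ConfigurationError("config.problem must be 'tsp'")
    if config.alpha is None or config.alpha >= 0:
        raise ConfigurationError("tsp alpha is negative by construction")
    rng = _resolve_rng(config, rng)
    n = config.size
    coords = rng.uniform(0.0, config.map_side, size=(n, 2))
    limit = -config.alpha * config.map_side * math.sqrt(n)
    return TspInstance(
        coords=tuple((float(x), float(y)) for x, y in coords),
        map_side=config.map_side,
        path_limit=limit,
    )


def tsp_path_limit(alpha: float, num_cities: int, map_side: float = DEFAULT_MAP_SIDE) -> float:
    """Path limit implied by a constrainedness value: L = -alpha * M * sqrt(N)."""
    if alpha >= 0:
        raise ConfigurationError("tsp alpha is negative by construction")
    return -alpha * map_side * math.sqrt(num_cities)


def sample_kp(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 1000,
) -> KpInstance:
    """Draw one random knapsack instance with realized ratios inside the bands.

    Capacity and target profit are rounded from ratios drawn uniformly from
    ``alpha_c_band`` and ``alpha_p_band``; draws whose realized (post-
    rounding) ratios escape the band are rejected and resampled.
    """
    if config.problem != "kp":
        raise ConfigurationError("config.problem must be 'kp'")
    rng = _resolve_rng(config, rng)
    n = config.size
    (w_lo, w_hi), (v_lo, v_hi) = config.weight_range, config.value_range
    (c_lo, c_hi), (p_lo, p_hi) = config.alpha_c_band, config.alpha_p_band
    for _ in range(max_retries):
        weights = rng.integers(w_lo, w_hi + 1, size=n)
        values = rng.integers(v_lo, v_hi + 1, size=n)
        sw, sv = int(weights.sum()), int(values.sum())
        capacity = round_half_away(rng.uniform(c_lo, c_hi) * sw)
        profit = round_half_away(rng.uniform(p_lo, p_hi) * sv)
        if capacity < 1 or profit < 1 or capacity >= sw:
            continue
        if not (c_lo <= capacity / sw <= c_hi and p_lo <= profit / sv <= p_hi):
            continue
        return KpInstance(
            weights=tuple(int(w) for w in weights),
            values=tuple(int(v) for v in values),
            capacity=capacity,
            target_profit=profit,
        )
    raise GenerationError(
        f"could not realize ratios inside bands {config.alpha_c_band}/{config.alpha_p_band} "
        f"after {max_retries} retries"
    )
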