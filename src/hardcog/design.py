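"""Stratified experimental instance sets.

An experiment set draws instances from three constrainedness regions
(underconstrained / threshold / overconstrained).  Under- and over-
constrained strata are sampled at random from their candidate pools without
further screening.  The threshold stratum is balanced on two factors:
satisfiability (equal numbers of yes- and no-instances) and solver effort
relative to the candidate-pool median at that alpha (equal numbers below
and at-or-below vs above the median — "low" vs "high" algorithmic
difficulty).  Ties sit on the low side.

The packaged study designs are:

* 3SAT (N=5): 16 at alpha=2, 32 at alpha=4.8 (8 per satisfiable x effort
  cell), 16 at alpha=7 — 64 instances.
* TSP (N=20): 18 at alpha=-0.99, 36 at alpha=-0.85 (9 per cell), 18 at
  alpha=-0.71 — 72 instances, no two sharing a coordinate set.
* KP (N=6): alpha_c in [0.40, 0.45] throughout; 18 with alpha_p in
  [0.35, 0.4], 36 with alpha_p in [0.6, 0.65] (9 per cell), 18 with
  alpha_p in [0.85, 0.9] — 72 instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DegeneratePoolError, DesignError
from .generators import (
    DEFAULT_MAP_SIDE,
    GeneratorConfig,
    sample_kp,
    sample_sat3,
    tsp_path_limit,
)
from .instances import OVER, THRESHOLD, UNDER, Instance, TspInstance
from .metrics import MetricBundle, RegionBand, RegionSpec, compute_metrics, WITNESS_CAP
from .solvers import SolveResult, solve


@dataclass(frozen=True)
class DesignSpec:
    """Stratified-design parameters for one problem."""

    problem: str
    size: int
    region_alphas: dict[str, float | tuple[float, float]]  # point alpha or band
    counts: dict[str, int]
    pool_size: int
    map_side: float = DEFAULT_MAP_SIDE
    clause_cap: Optional[int] = 36
    alpha_c_band: tuple[float, float] = (0.40, 0.45)
    witness_cap: int = WITNESS_CAP
    max_pool_extensions: int = 5

    def __post_init__(self) -> None:
        if set(self.region_alphas) != {UNDER, THRESHOLD, OVER}:
            raise ValueError("region_alphas must cover all three regions")
        if self.counts[THRESHOLD] % 4 != 0:
            raise ValueError("threshold count must split into 4 equal cells")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def region_spec(self) -> RegionSpec:
        bands = {}
        for region, spec in self.region_alphas.items():
            if isinstance(spec, tuple):
                bands[region] = RegionBand(lo=spec[0], hi=spec[1])
            else:
                bands[region] = RegionBand(lo=spec, hi=spec)
        return RegionSpec(problem=self.problem, bands=bands)


SAT3_STUDY_DESIGN = DesignSpec(
    problem="sat3",
    size=5,
    region_alphas={UNDER: 2.0, THRESHOLD: 4.8, OVER: 7.0},
    counts={UNDER: 16, THRESHOLD: 32, OVER: 16},
    pool_size=1000,
)

TSP_STUDY_DESIGN = DesignSpec(
    problem="tsp",
    size=20,
    region_alphas={UNDER: -0.99, THRESHOLD: -0.85, OVER: -0.71},
    counts={UNDER: 18, THRESHOLD: 36, OVER: 18},
    pool_size=100,
)

KP_STUDY_DESIGN = DesignSpec(
    problem="kp",
    size=6,
    region_alphas={
        UNDER: (0.35, 0.40),
        THRESHOLD: (0.60, 0.65),
        OVER: (0.85, 0.90),
    },
    counts={UNDER: 18, THRESHOLD: 36, OVER: 18},
    pool_size=1000,
)

STUDY_DESIGNS = {
    "sat3": SAT3_STUDY_DESIGN,
    "tsp": TSP_STUDY_DESIGN,
    "kp": KP_STUDY_DESIGN,
}


def effort_median_split(
    efforts: "list[int] | np.ndarray",
    median: Optional[float] = None,
) -> list[str]:
    """Label efforts low/high relative to a median (pool median by default).

    Values at or below the median are labelled ``low``.  A constant pool is
    degenerate: all instances get ``low`` and a warning is emitted.
    """
    efforts = np.asarray(efforts)
    if len(efforts) < 2:
        raise DegeneratePoolError("effort split needs a pool of at least 2")
    if median is None:
        median = float(np.median(efforts))
    if efforts.min() == efforts.max():
        warnings.warn("constant solver effort in pool; all labelled low", UserWarning)
        return ["low"] * len(efforts)
    return ["low" if e <= median else "high" for e in efforts]


@dataclass(frozen=True)
class InstanceRecord:
    """One designed instance with its labels and metrics."""

    instance_id: str
    instance: Instance
    result: SolveResult
    bundle: MetricBundle
    region: str
    satisfiable: bool
    effort: int
    effort_label: Optional[str]  # only threshold-stratum instances carry one


@dataclass
class InstanceSet:
    """An ordered stratified instance set with a tabular manifest."""

    problem: str
    spec: DesignSpec
    seed: int
    records: list[InstanceRecord]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            b = rec.bundle
            rows.append(
                {
                    "instance_id": rec.instance_id,
                    "problem": self.problem,
                    "alpha": b.alpha,
                    "alpha_c": b.alpha_c,
                    "region": rec.region,
                    "tcc": b.tcc,
                    "satisfiable": rec.satisfiable,
                    "effort": rec.effort,
                    "effort_label": rec.effort_label,
                    "witnesses": b.witnesses,
                    "witnesses_capped": b.witnesses_capped,
                    "ic": b.ic,
                    "n_clauses": (
                        rec.instance.num_clauses if self.problem == "sat3" else np.nan
                    ),
                    "fingerprint": b.fingerprint,
                }
            )
        return pd.DataFrame(rows)

    def save_manifest(self, path) -> None:
        self.manifest.to_csv(path, index=False)


def build_instance_set(spec: DesignSpec, seed: int) -> InstanceSet:
    """Generate pools, solve exactly, compute metrics and fill every stratum."""
    if spec.problem == "tsp":
        records = _build_tsp(spec, seed)
    elif spec.problem in ("sat3", "kp"):
        records = _build_pooled(spec, seed)
    else:
        raise ValueError(f"unknown problem {spec.problem!r}")
    return InstanceSet(problem=spec.problem, spec=spec, seed=seed, records=records)


def _gen_config(spec: DesignSpec, region: str) -> GeneratorConfig:
    target = spec.region_alphas[region]
    if spec.problem == "sat3":
        return GeneratorConfig(
            problem="sat3", size=spec.size, alpha=float(target), clause_cap=spec.clause_cap
        )
    if spec.problem == "kp":
        return GeneratorConfig(
            problem="kp",
            size=spec.size,
            alpha_c_band=spec.alpha_c_band,
            alpha_p_band=tuple(target),
        )
    raise ValueError(spec.problem)


def _build_pooled(spec: DesignSpec, seed: int) -> list[InstanceRecord]:
    """3SAT / KP: independent candidate pools per region."""
    region_spec = spec.region_spec()
    sampler = sample_sat3 if spec.problem == "sat3" else sample_kp
    records: list[InstanceRecord] = []
    for region in (UNDER, THRESHOLD, OVER):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, hash_region(region)])
        config = _gen_config(spec, region)
        pool: list[tuple[Instance, SolveResult]] = []

        def extend_pool() -> None:
            for _ in range(spec.pool_size):
                inst = sampler(config, rng)
                pool.append((inst, solve(inst, compute_effort=True)))

        extend_pool()
        if region != THRESHOLD:
            take = spec.counts[region]
            chosen = rng.choice(len(pool), size=take, replace=False)
            picked = [pool[i] for i in sorted(chosen)]
        else:
            per_cell = spec.counts[THRESHOLD] // 4
            picked_cells = None
            for _ in range(spec.max_pool_extensions + 1):
                efforts = [res.effort for _, res in pool]
                labels = effort_median_split(efforts)
                cells: dict[tuple[bool, str], list[int]] = {}
                for i, (_, res) in enumerate(pool):
                    cells.setdefault((res.satisfiable, labels[i]), []).append(i)
                deficient = [
                    cell
                    for cell in [(True, "low"), (True, "high"), (False, "low"), (False, "high")]
                    if len(cells.get(cell, [])) < per_cell
                ]
                if not deficient:
                    picked_cells = []
                    for cell in [(True, "low"), (True, "high"), (False, "low"), (False, "high")]:
                        idx = np.array(cells[cell])
                        chosen = rng.choice(len(idx), size=per_cell, replace=False)
                        picked_cells.extend(
                            (pool[i][0], pool[i][1], labels[i]) for i in sorted(idx[chosen])
                        )
                    break
                extend_pool()
            if picked_cells is None:
                raise DesignError(
                    f"{spec.problem} threshold stratum: cell(s) {deficient} "
                    f"still deficient after {spec.max_pool_extensions} pool extensions"
                )
            picked = picked_cells
        for k, item in enumerate(picked):
            if region == THRESHOLD:
                inst, res, label = item
            else:
                (inst, res), label = item, None
            bundle = compute_metrics(inst, res, region_spec, cap=spec.witness_cap)
            records.append(
                InstanceRecord(
                    instance_id=f"{spec.problem}_{region[:5]}_{k:03d}",
                    instance=inst,
                    result=res,
                    bundle=bundle,
                    region=region,
                    satisfiable=res.satisfiable,
                    effort=res.effort,
                    effort_label=label,
                )
            )
    return records


def _build_tsp(spec: DesignSpec, seed: int) -> list[InstanceRecord]:
    """TSP: one shared pool of coordinate sets; strata use disjoint maps.

    Every map is solved once (exact optimum + branch-and-bound effort); the
    per-region path limits then decide satisfiability.  No two selected
    instances share a coordinate set.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, hash_region("tsp_pool")])
    region_spec = spec.region_spec()
    limits = {r: tsp_path_limit(spec.region_alphas[r], spec.size, spec.map_side) for r in spec.region_alphas}

    maps: list[np.ndarray] = []
    optima: list[float] = []
    efforts: list[int] = []

    def extend_pool() -> None:
        for _ in range(spec.pool_size):
            coords = rng.uniform(0.0, spec.map_side, size=(spec.size, 2))
            inst = TspInstance(
                coords=tuple((float(x), float(y)) for x, y in coords),
                map_side=spec.map_side,
                path_limit=limits[THRESHOLD],
            )
            res = solve(inst, compute_effort=True)
            maps.append(coords)
            optima.append(res.optimum)
            efforts.append(res.effort)

    extend_pool()
    per_cell = spec.counts[THRESHOLD] // 4
    chosen_threshold: Optional[list[tuple[int, str]]] = None
    for _ in range(spec.max_pool_extensions + 1):
        labels = effort_median_split(efforts)
        sat = [opt <= limits[THRESHOLD] for opt in optima]
        cells: dict[tuple[bool, str], list[int]] = {}
        for i in range(len(maps)):
            cells.setdefault((sat[i], labels[i]), []).append(i)
        deficient = [
            cell
            for cell in [(True, "low"), (True, "high"), (False, "low"), (False, "high")]
            if len(cells.get(cell, [])) < per_cell
        ]
        n_extra = spec.counts[UNDER] + spec.counts[OVER]
        if not deficient and len(maps) >= spec.counts[THRESHOLD] + n_extra:
            chosen_threshold = []
            for cell in [(True, "low"), (True, "high"), (False, "low"), (False, "high")]:
                idx = np.array(cells[cell])
                pick = rng.choice(len(idx), size=per_cell, replace=False)
                chosen_threshold.extend((int(i), labels[i]) for i in sorted(idx[pick]))
            break
        extend_pool()
    if chosen_threshold is None:
        raise DesignError(
            f"tsp threshold stratum: cell(s) {deficient} still deficient after "
            f"{spec.max_pool_extensions} pool extensions"
        )

    used = {i for i, _ in chosen_threshold}
    remaining = np.array([i for i in range(len(maps)) if i not in used])
    n_needed = spec.counts[UNDER] + spec.counts[OVER]
    pick = rng.choice(len(remaining), size=n_needed, replace=False)
    extra = [int(remaining[i]) for i in sorted(pick)]
    under_maps = extra[: spec.counts[UNDER]]
    over_maps = extra[spec.counts[UNDER]:]

    records: list[InstanceRecord] = []
    plan = (
        [(UNDER, i, None) for i in under_maps]
        + [(THRESHOLD, i, lab) for i, lab in chosen_threshold]
        + [(OVER, i, None) for i in over_maps]
    )
    counter: dict[str, int] = {}
    for region, i, label in plan:
        inst = TspInstance(
            coords=tuple((float(x), float(y)) for x, y in maps[i]),
            map_side=spec.map_side,
            path_limit=limits[region],
        )
        res = SolveResult(
            problem="tsp",
            satisfiable=optima[i] <= limits[region],
            optimum=optima[i],
            effort=efforts[i],
            witness=None,
            fingerprint=inst.fingerprint(),
        )
        bundle = compute_metrics(inst, res, region_spec, cap=spec.witness_cap)
        k = counter.get(region, 0)
        counter[region] = k + 1
        records.append(
            InstanceRecord(
                instance_id=f"tsp_{region[:5]}_{k:03d}",
                instance=inst,
                result=res,
                bundle=bundle,
                region=region,
                satisfiable=res.satisfiable,
                effort=res.effort,
                effort_label=label,
            )
        )
    return records


def hash_region(name: str) -> int:
    import zlib

    return zlib.crc32(name.encode())
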