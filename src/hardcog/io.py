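"""Readers and writers for the on-disk instance formats.

3SAT instances use DIMACS CNF.  TSP instances use a TSPLIB-style node
coordinate file (EUC_2D declared) plus a small ``key: value`` sidecar
carrying the path limit and map side, because TSPLIB has no slot for a
decision threshold.  Note one deliberate deviation from the TSPLIB
standard: although the files declare EUC_2D, distances are computed
internally at full floating precision, never rounded to integers — the
constrainedness parameter and the satisfiability threshold live in
continuous Euclidean geometry.  Knapsack instances use a small CSV (one
row per item) with a commented header block for capacity and target
profit, as no standard format exists.

All writers emit a provenance comment line.  All readers reject inputs
violating the type invariants instead of silently repairing them.
"""

from __future__ import annotations

import os
from typing import Optional

from . import __version__
from .exceptions import FormatError
from .instances import KpInstance, Sat3Instance, TspInstance


def _provenance(extra: Optional[str]) -> str:
    tag = f"hardcog v{__version__}"
    return f"{tag} {extra}" if extra else tag


# ---------------------------------------------------------------------------
# DIMACS CNF (3SAT)
# ---------------------------------------------------------------------------

def write_dimacs(instance: Sat3Instance, path: str | os.PathLike, comment: Optional[str] = None) -> None:
    lines = [f"c {_provenance(comment)}"]
    lines.append(f"p cnf {instance.num_vars} {instance.num_clauses}")
    for cl in instance.clauses:
        lines.append(f"{cl[0]} {cl[1]} {cl[2]} 0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dimacs(path: str | os.PathLike) -> Sat3Instance:
    num_vars = None
    declared_m = None
    clauses: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("c") or line.startswith("%"):
                continue
            if line.startswith("p"):
                parts = line.split()
                if len(parts) != 4 or parts[1] != "cnf":
                    raise FormatError(f"malformed problem line: {line!r}")
                num_vars, declared_m = int(parts[2]), int(parts[3])
                continue
            if num_vars is None:
                raise FormatError("clause encountered before 'p cnf' header")
            lits = [int(tok) for tok in line.split()]
            if lits and lits[-1] == 0:
                lits = lits[:-1]
            idx = len(clauses)
            if len(lits) != 3:
                raise FormatError(f"clause {idx} has {len(lits)} literals, expected 3")
            if len({abs(l) for l in lits}) != 3:
                raise FormatError(f"clause {idx} repeats a variable: {lits}")
            if any(l == 0 or abs(l) > num_vars for l in lits):
                raise FormatError(f"clause {idx} has a literal outside 1..{num_vars}")
            clauses.append((lits[0], lits[1], lits[2]))
    if num_vars is None:
        raise FormatError("missing 'p cnf' header")
    if declared_m != len(clauses):
        raise FormatError(
            f"header declares {declared_m} clauses but file contains {len(clauses)}"
        )
    return Sat3Instance(num_vars=num_vars, clauses=tuple(clauses))


# ---------------------------------------------------------------------------
# TSPLIB node coordinates + sidecar (TSP)
# ---------------------------------------------------------------------------

def write_tsp(
    instance: TspInstance,
    path: str | os.PathLike,
    sidecar: str | os.PathLike,
    comment: Optional[str] = None,
    name: str = "hardcog",
) -> None:
    lines = [
        f"NAME : {name}",
        "TYPE : TSP",
        f"COMMENT : {_provenance(comment)}",
        f"DIMENSION : {instance.num_cities}",
        "EDGE_WEIGHT_TYPE : EUC_2D",
        "NODE_COORD_SECTION",
    ]
    for i, (x, y) in enumerate(instance.coords, start=1):
        lines.append(f"{i} {x!r} {y!r}")
    lines.append("EOF")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(sidecar, "w") as fh:
        fh.write(f"# {_provenance(comment)}\n")
        fh.write(f"PATH_LIMIT: {instance.path_limit!r}\n")
        fh.write(f"MAP_SIDE: {instance.map_side!r}\n")


def read_tsp(path: str | os.PathLike, sidecar: str | os.PathLike) -> TspInstance:
    dimension = None
    coords: list[tuple[float, float]] = []
    in_coords = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "EOF":
                break
            if in_coords:
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"malformed coordinate line: {line!r}")
                idx = int(parts[0])
                if idx != len(coords) + 1:
                    raise FormatError(f"coordinate index {idx} out of order")
                coords.append((float(parts[1]), float(parts[2])))
                continue
            if line.startswith("NODE_COORD_SECTION"):
                in_coords = True
                continue
            if ":" in line:
                key, value = (part.strip() for part in line.split(":", 1))
                if key == "DIMENSION":
                    dimension = int(value)
                elif key == "EDGE_WEIGHT_TYPE" and value != "EUC_2D":
                    raise FormatError(f"unsupported edge weight type {value!r}")
    if dimension is not None and dimension != len(coords):
        raise FormatError(
            f"DIMENSION declares {dimension} cities but file has {len(coords)}"
        )
    sidecar_vals: dict[str, float] = {}
    with open(sidecar) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise FormatError(f"malformed sidecar line: {line!r}")
            key, value = (part.strip() for part in line.split(":", 1))
            sidecar_vals[key.upper()] = float(value)
    if "PATH_LIMIT" not in sidecar_vals:
        raise FormatError("sidecar is missing PATH_LIMIT")
    if "MAP_SIDE" not in sidecar_vals:
        raise FormatError("sidecar is missing MAP_SIDE")
    return TspInstance(
        coords=tuple(coords),
        map_side=sidecar_vals["MAP_SIDE"],
        path_limit=sidecar_vals["PATH_LIMIT"],
    )


# ---------------------------------------------------------------------------
# Knapsack CSV
# ---------------------------------------------------------------------------

def write_kp(instance: KpInstance, path: str | os.PathLike, comment: Optional[str] = None) -> None:
    lines = [
        f"# {_provenance(comment)}",
        f"# CAPACITY: {instance.capacity}",
        f"# TARGET_PROFIT: {instance.target_profit}",
        "weight,value",
    ]
    for w, v in zip(instance.weights, instance.values):
        lines.append(f"{w},{v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_kp(path: str | os.PathLike) -> KpInstance:
    capacity = None
    profit = None
    rows: list[tuple[int, int]] = []
    header_seen = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.upper().startswith("CAPACITY:"):
                    capacity = int(body.split(":", 1)[1])
                elif body.upper().startswith("TARGET_PROFIT:"):
                    profit = int(body.split(":", 1)[1])
                continue
            if not header_seen:
                if line.replace(" ", "").lower() != "weight,value":
                    raise FormatError(f"expected 'weight,value' header, got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"malformed item row: {line!r}")
            rows.append((int(parts[0]), int(parts[1])))
    if capacity is None or profit is None:
        raise FormatError("missing CAPACITY or TARGET_PROFIT header comment")
    return KpInstance(
        weights=tuple(w for w, _ in rows),
        values=tuple(v for _, v in rows),
        capacity=capacity,
        target_profit=profit,
    )
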