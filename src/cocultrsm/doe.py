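"""Central composite designs (CCD) for response-surface experiments.

A CCD for ``k`` factors combines three kinds of runs in coded units:

* *factorial* points — every corner of the cube, all levels at ±1;
* *axial* (star) points — one factor at ±alpha, the others at 0;
* *center* points — all factors at 0, replicated to estimate pure error.

With all three present each factor is exercised at five distinct coded
levels ``{-alpha, -1, 0, +1, +alpha}``.  Coded level ``x`` maps to a natural
(laboratory) value ``center + step * x``; the coding is linear and symmetric
around the design center.
"""

from __future__ import annotations

import csv
import io
import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DimensionError,
    InvalidDesignError,
    InvalidParameterError,
    ParseError,
    ValidationError,
)

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "DesignTable",
    "rotatable_alpha",
    "generate_ccd",
    "code_levels",
    "decode_levels",
    "write_design",
    "read_design",
]

POINT_TYPES = ("factorial", "axial", "center")


def rotatable_alpha(k: int, factorial_fraction: int = 0) -> float:
    """Axial distance giving a rotatable CCD: ``(2^(k-p))^(1/4)``."""
    return (2 ** (k - factorial_fraction)) ** 0.25


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor and its linear coded-unit mapping.

    ``center`` is the natural value at coded 0 and ``step`` the natural-unit
    width of one coded unit, so coded +1 sits at ``center + step``.
    """

    name: str
    center: float
    step: float
    alpha: float = rotatable_alpha(3)
    units: str = ""

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidParameterError(f"factor {self.name!r}: step must be > 0")
        if self.alpha <= 0:
            raise InvalidParameterError(f"factor {self.name!r}: alpha must be > 0")

    def code(self, natural: float) -> float:
        return (natural - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + self.step * coded


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    coded_levels: tuple[float, ...]
    point_type: str
    block: int = 1
    replicate: int = 1
    run_order: int = 0

    def __post_init__(self) -> None:
        if self.point_type not in POINT_TYPES:
            raise ValidationError(f"unknown point_type {self.point_type!r}")


@dataclass
class DesignTable:
    """A concrete run list: factors, points, and the randomization seed."""

    factors: list[FactorSpec]
    points: list[DesignPoint]
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.factors)

    def __len__(self) -> int:
        return len(self.points)

    def coded_matrix(self) -> np.ndarray:
        """(N, k) array of coded levels, in run_id order."""
        return np.array([p.coded_levels for p in self.points], dtype=float)

    def natural_matrix(self) -> np.ndarray:
        coded = self.coded_matrix()
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return centers + steps * coded

    def validate(self) -> None:
        ids = [p.run_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate run_id in design")
        order = sorted(p.run_order for p in self.points)
        if order != list(range(1, len(self.points) + 1)):
            raise ValidationError("run_order is not a permutation of 1..N")
        for p in self.points:
            if len(p.coded_levels) != self.k:
                raise DimensionError(
                    f"run {p.run_id}: {len(p.coded_levels)} levels for {self.k} factors"
                )

    def to_frame(self):
        """Design as a pandas DataFrame (coded and natural columns)."""
        import pandas as pd

        rows = []
        for p in self.points:
            row = {
                "run_id": p.run_id,
                "block": p.block,
                "run_order": p.run_order,
                "point_type": p.point_type,
                "replicate": p.replicate,
            }
            for f, c in zip(self.factors, p.coded_levels):
                row[f"coded_{f.name}"] = c
            for f, c in zip(self.factors, p.coded_levels):
                row[f"natural_{f.name}"] = f.decode(c)
            rows.append(row)
        return pd.DataFrame(rows)


def _default_factors(k: int, alpha: float) -> list[FactorSpec]:
    names = [chr(ord("A") + i) for i in range(k)]
    return [FactorSpec(name=n, center=0.0, step=1.0, alpha=alpha) for n in names]


def _assign_blocks(
    points: list[DesignPoint], n_blocks: int, strategy: str
) -> list[DesignPoint]:
    if n_blocks <= 1:
        return [replace(p, block=1) for p in points]
    if strategy == "round_robin" or n_blocks > 2:
        return [
            replace(p, block=1 + i % n_blocks) for i, p in enumerate(points)
        ]
    # Two-block day split: factorial replicate 1 plus half the centers run on
    # day 1; axial points, the second factorial replicate and the remaining
    # centers on day 2.
    out = []
    centers = [p for p in points if p.point_type == "center"]
    half = math.ceil(len(centers) / 2)
    center_day1 = {p.run_id for p in centers[:half]}
    for p in points:
        if p.point_type == "factorial":
            blk = 1 if p.replicate == 1 else 2
        elif p.point_type == "axial":
            blk = 2
        else:
            blk = 1 if p.run_id in center_day1 else 2
        out.append(replace(p, block=blk))
    return out


def generate_ccd(
    k: int,
    factorial_reps: int = 2,
    axial_reps: int = 2,
    center_reps: int = 6,
    alpha: float | None = None,
    n_blocks: int = 1,
    seed: int = 0,
    factors: list[FactorSpec] | None = None,
    block_strategy: str = "day_split",
) -> DesignTable:
    """Build a replicated, blocked central composite design.

    The run count obeys ``N = factorial_reps * 2**k + axial_reps * 2*k +
    center_reps``.  ``alpha`` defaults to the rotatable value ``2**(k/4)``.
    Point composition is deterministic; only the run order is randomized,
    by a permutation drawn from ``seed``.
    """
    if k < 2:
        raise InvalidDesignError("a central composite design needs k >= 2 factors")
    if min(factorial_reps, axial_reps, center_reps) < 0:
        raise InvalidParameterError("replicate counts must be >= 0")
    if factorial_reps + axial_reps + center_reps == 0:
        raise InvalidDesignError("at least one point type must be present")
    if alpha is None:
        alpha = factors[0].alpha if factors else rotatable_alpha(k)
    if alpha <= 0:
        raise InvalidParameterError("alpha must be > 0")
    if factors is None:
        factors = _default_factors(k, alpha)
    elif len(factors) != k:
        raise DimensionError(f"{len(factors)} factor specs for k={k}")

    pts: list[DesignPoint] = []
    rid = 1
    for rep in range(1, factorial_reps + 1):
        for corner in itertools.product((-1.0, 1.0), repeat=k):
            pts.append(DesignPoint(rid, corner, "factorial", replicate=rep))
            rid += 1
    for rep in range(1, axial_reps + 1):
        for i in range(k):
            for sgn in (-1.0, 1.0):
                lv = [0.0] * k
                lv[i] = sgn * alpha
                pts.append(DesignPoint(rid, tuple(lv), "axial", replicate=rep))
                rid += 1
    for rep in range(1, center_reps + 1):
        pts.append(DesignPoint(rid, (0.0,) * k, "center", replicate=rep))
        rid += 1

    pts = _assign_blocks(pts, n_blocks, block_strategy)
    order = np.random.default_rng(seed).permutation(len(pts)) + 1
    pts = [replace(p, run_order=int(o)) for p, o in zip(pts, order)]
    return DesignTable(factors=list(factors), points=pts, seed=seed)


def code_levels(natural, factors: list[FactorSpec]) -> np.ndarray:
    """Natural-unit values -> coded units, ``(x - center) / step``."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(factors):
        raise DimensionError(
            f"{natural.shape[-1]} values for {len(factors)} factors"
        )
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (natural - centers) / steps


def decode_levels(coded, factors: list[FactorSpec]) -> np.ndarray:
    """Coded units -> natural units, inverse of :func:`code_levels`."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise DimensionError(f"{coded.shape[-1]} values for {len(factors)} factors")
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + steps * coded


# -- serialization ----------------------------------------------------------

_META_PREFIX = "#"


def write_design(path, table: DesignTable) -> None:
    """Write a design as commented-header CSV; lossless for all fields."""
    buf = io.StringIO()
    buf.write(f"{_META_PREFIX} cocultrsm-design v1\n")
    buf.write(f"{_META_PREFIX} seed: {table.seed}\n")
    for f in table.factors:
        meta = {
            "name": f.name,
            "center": f.center,
            "step": f.step,
            "alpha": f.alpha,
            "units": f.units,
        }
        buf.write(f"{_META_PREFIX} factor: {json.dumps(meta)}\n")
    writer = csv.writer(buf)
    header = ["run_id", "block", "run_order", "point_type", "replicate"]
    header += [f"coded_{f.name}" for f in table.factors]
    writer.writerow(header)
    for p in sorted(table.points, key=lambda p: p.run_id):
        writer.writerow(
            [p.run_id, p.block, p.run_order, p.point_type, p.replicate]
            + [repr(c) for c in p.coded_levels]
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_design(path) -> DesignTable:
    """Parse a design written by :func:`write_design`.

    Raises :class:`ParseError` with the offending line number on malformed
    input and :class:`ValidationError` on invariant violations.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()

    seed = 0
    factors: list[FactorSpec] = []
    data_start = 0
    for i, line in enumerate(lines):
        if not line.startswith(_META_PREFIX):
            data_start = i
            break
        body = line[len(_META_PREFIX):].strip()
        if body.startswith("seed:"):
            try:
                seed = int(body.split(":", 1)[1])
            except ValueError:
                raise ParseError("invalid seed", line=i + 1) from None
        elif body.startswith("factor:"):
            try:
                meta = json.loads(body.split(":", 1)[1])
                factors.append(FactorSpec(**meta))
            except (json.JSONDecodeError, TypeError) as exc:
                raise ParseError(f"invalid factor metadata: {exc}", line=i + 1) from None
    else:
        raise ParseError("no data rows found", line=len(lines))

    reader = csv.reader(lines[data_start:])
    header = next(reader)
    required = ["run_id", "block", "run_order", "point_type", "replicate"]
    for col in required:
        if col not in header:
            raise ParseError(f"missing column {col!r}", line=data_start + 1)
    coded_cols = [h for h in header if h.startswith("coded_")]
    if not factors:
        factors = [
            FactorSpec(name=c.removeprefix("coded_"), center=0.0, step=1.0)
            for c in coded_cols
        ]
    idx = {c: header.index(c) for c in required + coded_cols}

    points = []
    for n, row in enumerate(reader, start=data_start + 2):
        if not row:
            continue
        try:
            points.append(
                DesignPoint(
                    run_id=int(row[idx["run_id"]]),
                    block=int(row[idx["block"]]),
                    run_order=int(row[idx["run_order"]]),
                    point_type=row[idx["point_type"]],
                    replicate=int(row[idx["replicate"]]),
                    coded_levels=tuple(float(row[idx[c]]) for c in coded_cols),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"bad data row: {exc}", line=n) from None
    return DesignTable(factors=factors, points=points, seed=seed)
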