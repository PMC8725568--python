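"""Tumor-marker cross-classification and second-stage design matrices.

Breast tumors are cross-classified by estrogen receptor (ER), progesterone
receptor (PR) and HER2 status (each negative/positive) and histologic grade
(ordinal 1-3), giving 2*2*2*3 = 24 disease cells.  This module owns

* the marker schema and the deterministic enumeration of cells,
* consistency of partially observed marker patterns with cells,
* the mapping of cells to the five clinical surrogate ("intrinsic-like")
  subtypes, and
* the second-stage design matrices that decompose per-cell genotype
  log-odds-ratios into a small number of case-case parameters.

Cell coding is the single source of truth for every downstream model: binary
markers are coded negative=0 / positive=1, grade is coded ordinally 0/1/2
with grade 1 as reference, and cells are ordered lexicographically over
(ER, PR, HER2, grade).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

MISSING = None

#: Canonical marker names in model order.
MARKER_NAMES = ("ER", "PR", "HER2", "grade")

#: Intrinsic-like subtype labels, in reporting order.
SUBTYPE_LABELS = (
    "luminalA",
    "luminalB_HER2neg",
    "luminalB_HER2pos",
    "HER2pos_nonluminal",
    "triple_negative",
)

DESIGN_KINDS = ("main_effects", "subtype_indicators", "grade_indicators", "saturated")


@dataclass(frozen=True)
class MarkerSchema:
    """Ordered collection of categorical tumor markers.

    Parameters
    ----------
    markers
        Ordered ``(name, levels)`` pairs.  Levels are ordered; the first
        level is the reference.  Ordinal markers are coded 0, 1, 2, ...
        from their level order.
    ordinal
        Names of markers treated as ordinal (a single linear case-case
        parameter) rather than binary/categorical.
    """

    markers: tuple[tuple[str, tuple[str, ...]], ...]
    ordinal: frozenset[str] = frozenset()

    def __post_init__(self):
        names = [m[0] for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        for name, levels in self.markers:
            if len(levels) < 2:
                raise ValueError(f"marker {name!r} needs >=2 levels, got {levels!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.markers)

    def levels(self, name: str) -> tuple[str, ...]:
        for n, lv in self.markers:
            if n == name:
                return lv
        raise KeyError(name)

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(lv) for _, lv in self.markers]))

    def is_default(self) -> bool:
        return self == default_schema()


def default_schema() -> MarkerSchema:
    """ER/PR/HER2 binary, grade ordinal 1-3: the 24-cell classification."""
    return MarkerSchema(
        markers=(
            ("ER", ("neg", "pos")),
            ("PR", ("neg", "pos")),
            ("HER2", ("neg", "pos")),
            ("grade", ("1", "2", "3")),
        ),
        ordinal=frozenset({"grade"}),
    )


@dataclass(frozen=True)
class TumorCell:
    """One fully cross-classified disease cell."""

    cell_id: int
    levels: tuple[str, ...]

    def level(self, schema: MarkerSchema, name: str) -> str:
        return self.levels[schema.names.index(name)]


def enumerate_cells(schema: MarkerSchema) -> list[TumorCell]:
    """All cells in deterministic lexicographic order over marker levels."""
    combos = itertools.product(*[lv for _, lv in schema.markers])
    return [TumorCell(i, c) for i, c in enumerate(combos)]


@dataclass(frozen=True)
class ObservedPattern:
    """Per-marker observed level or ``None`` for missing.

    ``values`` aligns with the schema's marker order.
    """

    values: tuple[str | None, ...]

    @classmethod
    def from_dict(cls, schema: MarkerSchema, observed: dict[str, str | None]) -> "ObservedPattern":
        unknown = set(observed) - set(schema.names)
        if unknown:
            raise KeyError(f"pattern references unknown markers: {sorted(unknown)}")
        return cls(tuple(observed.get(n, None) for n in schema.names))

    def n_observed(self) -> int:
        return sum(v is not None for v in self.values)


def consistent_cells(pattern: ObservedPattern, schema: MarkerSchema) -> set[int]:
    """Cell ids matching every observed marker value of *pattern*."""
    if len(pattern.values) != len(schema.markers):
        raise ValueError("pattern length does not match schema")
    for v, (name, levels) in zip(pattern.values, schema.markers):
        if v is not None and v not in levels:
            raise ValueError(f"value {v!r} is not a level of marker {name!r}")
    out = set()
    for cell in enumerate_cells(schema):
        if all(v is None or v == lv for v, lv in zip(pattern.values, cell.levels)):
            out.add(cell.cell_id)
    return out


def map_intrinsic(cell: TumorCell, schema: MarkerSchema | None = None) -> str:
    """Intrinsic-like subtype of a fully classified cell.

    Definitions (hormone-receptor positive means ER+ and/or PR+):

    * luminal A-like: HR+, HER2-, grade 1 or 2
    * luminal B-like/HER2-negative: HR+, HER2-, grade 3
    * luminal B-like/HER2-positive: HR+, HER2+ (any grade)
    * HER2-positive/non-luminal: ER- and PR-, HER2+
    * triple-negative: ER-, PR-, HER2-
    """
    schema = schema or default_schema()
    if not schema.is_default():
        raise ValueError("intrinsic-like subtypes are defined on the default schema")
    er, pr, her2, grade = cell.levels
    luminal = er == "pos" or pr == "pos"
    if luminal:
        if her2 == "pos":
            return "luminalB_HER2pos"
        return "luminalA" if grade in ("1", "2") else "luminalB_HER2neg"
    if her2 == "pos":
        return "HER2pos_nonluminal"
    return "triple_negative"


def consistent_intrinsic(pattern: ObservedPattern, schema: MarkerSchema | None = None) -> set[str]:
    """Subtypes compatible with a partially observed pattern."""
    schema = schema or default_schema()
    cells = enumerate_cells(schema)
    return {map_intrinsic(cells[i], schema) for i in consistent_cells(pattern, schema)}


@dataclass(frozen=True)
class SecondStageDesign:
    """Linear decomposition beta = A @ theta of per-cell genotype log-ORs.

    ``matrix`` is M x p; ``labels`` names the p second-stage parameters.
    """

    kind: str
    matrix: np.ndarray = field(repr=False)
    labels: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]


def marker_codes(schema: MarkerSchema) -> np.ndarray:
    """M x n_markers numeric coding of every cell (reference level = 0)."""
    cells = enumerate_cells(schema)
    codes = np.empty((len(cells), len(schema.markers)), dtype=float)
    for i, cell in enumerate(cells):
        for j, (name, levels) in enumerate(schema.markers):
            codes[i, j] = levels.index(cell.levels[j])
    return codes


def second_stage_design(schema: MarkerSchema, kind: str) -> SecondStageDesign:
    """Build a second-stage design matrix.

    ``main_effects``: baseline + one case-case column per marker (ordinal
    markers get their 0/1/2 code).  ``subtype_indicators``: one-hot over the
    five intrinsic-like subtypes.  ``grade_indicators``: one-hot over grade.
    ``saturated``: identity, one free log-OR per cell.
    """
    cells = enumerate_cells(schema)
    M = len(cells)
    if kind == "main_effects":
        A = np.hstack([np.ones((M, 1)), marker_codes(schema)])
        labels = ("baseline",) + schema.names
    elif kind == "saturated":
        A = np.eye(M)
        labels = tuple("cell_" + "_".join(c.levels) for c in cells)
    elif kind == "subtype_indicators":
        if not schema.is_default():
            raise ValueError("subtype_indicators requires the default schema")
        A = np.zeros((M, len(SUBTYPE_LABELS)))
        for c in cells:
            A[c.cell_id, SUBTYPE_LABELS.index(map_intrinsic(c, schema))] = 1.0
        labels = SUBTYPE_LABELS
    elif kind == "grade_indicators":
        if not schema.is_default():
            raise ValueError("grade_indicators requires the default schema")
        grades = schema.levels("grade")
        A = np.zeros((M, len(grades)))
        for c in cells:
            A[c.cell_id, grades.index(c.level(schema, "grade"))] = 1.0
        labels = tuple(f"grade{g}" for g in grades)
    else:
        raise ValueError(f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}")
    return SecondStageDesign(kind=kind, matrix=A, labels=labels)
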