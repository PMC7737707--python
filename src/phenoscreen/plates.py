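"""Multiwell-plate modelling for high-content drug screens.

Screens are laid out on 384-well plates (16 lettered rows A-P by 24
numbered columns): each drug occupies one row as a serial-dilution
series in duplicate, and binary-combination experiments use a dose-pair
matrix with single-drug edge wells plus untreated controls.  Results are
re-keyed from physical wells to (condition, dose) "virtual plates" with
duplicate averaging before any curve fitting.

Concentrations are molar throughout; :data:`MICROMOLAR` / :data:`NANOMOLAR`
are provided so interface code can write ``4 * MICROMOLAR``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MOLAR",
    "MICROMOLAR",
    "NANOMOLAR",
    "WellAddress",
    "WellAssignment",
    "ScreenAnnotation",
    "DilutionSeries",
    "PlateLayout",
    "build_dilution_series",
    "column_to_concentration",
    "build_screen_layout",
    "build_combination_layout",
    "assemble_virtual_plate",
]

MOLAR = 1.0
MICROMOLAR = 1e-6
NANOMOLAR = 1e-9

_ROW_LETTERS = string.ascii_uppercase

ROLE_CONTROL = "control"
ROLE_TREATED = "treated"
ROLE_EMPTY = "empty"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A physical well, e.g. ``WellAddress('B', 3)`` == B03."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in _ROW_LETTERS:
            raise ValueError(f"row must be a single letter A-Z, got {self.row!r}")
        if self.column < 1:
            raise ValueError(f"column must be >= 1, got {self.column}")

    @property
    def row_index(self) -> int:
        """0-based row index (A -> 0)."""
        return _ROW_LETTERS.index(self.row)

    @classmethod
    def from_string(cls, name: str) -> "WellAddress":
        """Parse 'B3' or 'B03'."""
        name = name.strip().upper()
        if len(name) < 2 or not name[0].isalpha():
            raise ValueError(f"cannot parse well name {name!r}")
        return cls(name[0], int(name[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"


@dataclass(frozen=True)
class WellAssignment:
    """Contents of one well: role, up to two drugs, replicate group."""

    role: str
    drugs: tuple[str, ...] = ()
    concentrations: tuple[float, ...] = ()
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in (ROLE_CONTROL, ROLE_TREATED, ROLE_EMPTY):
            raise ValueError(f"unknown role {self.role!r}")
        if len(self.drugs) != len(self.concentrations):
            raise ValueError("drugs and concentrations must have equal length")
        if self.role == ROLE_TREATED:
            if not self.drugs:
                raise ValueError("treated well must name at least one drug")
            if any(c <= 0 for c in self.concentrations):
                raise ValueError("treated well concentrations must be positive")
        if self.role == ROLE_CONTROL and self.drugs:
            raise ValueError("control well must not carry a drug")


@dataclass(frozen=True)
class ScreenAnnotation:
    """Screening annotation for one drug.

    ``gi50`` anchors the dose ladder: series start at ``start_multiple * gi50``
    (default 10x).  ``dm_column`` is the column index of half effect in the
    screen's duplicate-pair convention; :func:`column_to_concentration` maps
    it back to a concentration via ``10 * gi50 * 3**(1 - dm_column / 2)``.
    """

    drug_id: str
    gi50: float
    start_multiple: float = 10.0
    dm_column: float | None = None

    def __post_init__(self) -> None:
        if self.gi50 <= 0:
            raise ValueError(f"gi50 must be positive, got {self.gi50}")
        if self.start_multiple <= 0:
            raise ValueError("start_multiple must be positive")
        if self.dm_column is not None and self.dm_column < 1:
            raise ValueError("dm_column must be >= 1")


@dataclass(frozen=True)
class DilutionSeries:
    """A strictly decreasing geometric concentration ladder."""

    start: float
    fold: float
    n_levels: int
    concentrations: tuple[float, ...]

    def __len__(self) -> int:
        return self.n_levels


def build_dilution_series(start: float, fold: float, n_levels: int) -> DilutionSeries:
    """Geometric dilution ladder ``start / fold**k`` for k = 0..n_levels-1.

    Examples
    --------
    >>> build_dilution_series(4.0, 2.0, 5).concentrations
    (4.0, 2.0, 1.0, 0.5, 0.25)
    """
    if start <= 0:
        raise ValueError(f"start concentration must be positive, got {start}")
    if fold <= 1:
        raise ValueError(f"dilution fold must be > 1, got {fold}")
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    concs = tuple(start / fold**k for k in range(n_levels))
    return DilutionSeries(start=start, fold=fold, n_levels=n_levels, concentrations=concs)


def column_to_concentration(annotation: ScreenAnnotation) -> float:
    """Concentration of the half-effect column: ``10 * gi50 * 3**(1 - dm/2)``.

    This is the screen's convention for converting a half-effect column
    index (duplicate columns share a dose, hence the /2) into the dose
    on the 3-fold ladder that starts at 10x GI50.
    """
    if annotation.dm_column is None:
        raise ValueError(f"{annotation.drug_id}: dm_column is not set")
    return 10.0 * annotation.gi50 * 3.0 ** (1.0 - annotation.dm_column / 2.0)


@dataclass
class PlateLayout:
    """Well -> assignment map for one physical or logical plate."""

    plate_id: str
    wells: dict[WellAddress, WellAssignment] = field(default_factory=dict)
    n_rows: int = 16
    n_cols: int = 24

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    def _check_bounds(self, well: WellAddress) -> None:
        if well.row_index >= self.n_rows or well.column > self.n_cols:
            raise ValueError(
                f"well {well} outside {self.n_rows}x{self.n_cols} plate bounds"
            )

    def assign(self, well: WellAddress, assignment: WellAssignment) -> None:
        self._check_bounds(well)
        if well in self.wells:
            raise ValueError(f"well {well} already assigned")
        self.wells[well] = assignment

    def wells_with_role(self, role: str) -> list[WellAddress]:
        return sorted(w for w, a in self.wells.items() if a.role == role)

    @property
    def control_wells(self) -> list[WellAddress]:
        return self.wells_with_role(ROLE_CONTROL)

    @property
    def treated_wells(self) -> list[WellAddress]:
        return self.wells_with_role(ROLE_TREATED)

    def replicate_groups(self) -> dict[str, list[WellAddress]]:
        groups: dict[str, list[WellAddress]] = {}
        for well in sorted(self.wells):
            a = self.wells[well]
            if a.role == ROLE_EMPTY:
                continue
            groups.setdefault(a.replicate_group, []).append(well)
        return groups

    def validate(self) -> None:
        """Re-check the layout invariants (used after deserialisation)."""
        seen: set[WellAddress] = set()
        for well, a in self.wells.items():
            self._check_bounds(well)
            if well in seen:
                raise ValueError(f"duplicate well {well}")
            seen.add(well)
            # WellAssignment.__post_init__ enforces per-well invariants;
            # re-trigger for objects built by a reader.
            WellAssignment(a.role, a.drugs, a.concentrations, a.replicate_group)
        if len(self.wells) > self.capacity:
            raise ValueError("more wells assigned than plate capacity")

    # -- serialisation -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for well in sorted(self.wells):
            a = self.wells[well]
            rows.append(
                {
                    "well": str(well),
                    "role": a.role,
                    "drug_1": a.drugs[0] if len(a.drugs) > 0 else "",
                    "conc_1": a.concentrations[0] if len(a.drugs) > 0 else "",
                    "drug_2": a.drugs[1] if len(a.drugs) > 1 else "",
                    "conc_2": a.concentrations[1] if len(a.drugs) > 1 else "",
                    "replicate_group": a.replicate_group,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "well", "role", "drug_1", "conc_1", "drug_2", "conc_2",
                "replicate_group",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, plate_id: str = "plate",
        n_rows: int = 16, n_cols: int = 24,
    ) -> "PlateLayout":
        layout = cls(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols)
        for _, row in frame.iterrows():
            drugs: list[str] = []
            concs: list[float] = []
            for d, c in (("drug_1", "conc_1"), ("drug_2", "conc_2")):
                drug = row.get(d, "")
                if isinstance(drug, str) and drug:
                    drugs.append(drug)
                    concs.append(float(row[c]))
            layout.assign(
                WellAddress.from_string(row["well"]),
                WellAssignment(
                    role=row["role"],
                    drugs=tuple(drugs),
                    concentrations=tuple(concs),
                    replicate_group=str(row.get("replicate_group", "") or ""),
                ),
            )
        layout.validate()
        return layout

    @classmethod
    def from_csv(cls, path, plate_id: str = "plate") -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False), plate_id=plate_id)

    def to_json(self, path) -> None:
        payload = {
            "plate_id": self.plate_id,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "wells": self.to_frame().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlateLayout":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_frame(
            pd.DataFrame(payload["wells"]),
            plate_id=payload["plate_id"],
            n_rows=payload["n_rows"],
            n_cols=payload["n_cols"],
        )


def _well(row_index: int, column: int) -> WellAddress:
    return WellAddress(_ROW_LETTERS[row_index], column)


def build_screen_layout(
    drugs: Sequence[ScreenAnnotation],
    fold: float = 3.0,
    n_levels: int = 10,
    duplicates: int = 2,
    control_wells: Iterable[WellAddress] = (),
    plate_id: str = "screen",
    n_rows: int = 16,
    n_cols: int = 24,
) -> PlateLayout:
    """Single-drug screen: one row-block per drug, dilutions along the row.

    Each drug's ladder starts at ``start_multiple * gi50`` and descends
    ``fold``-wise for ``n_levels`` levels; duplicates sit in adjacent
    columns, so level ``k`` occupies columns ``k*duplicates+1 ..
    (k+1)*duplicates``.
    """
    control_wells = list(control_wells)
    layout = PlateLayout(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols)

    per_drug = n_levels * duplicates
    needed = len(drugs) * per_drug + len(control_wells)
    if per_drug > n_cols or len(drugs) > n_rows or needed > layout.capacity:
        raise ValueError(
            f"layout needs {len(drugs)} rows x {per_drug} columns "
            f"+ {len(control_wells)} controls; exceeds {n_rows}x{n_cols} plate"
        )

    for well in control_wells:
        layout.assign(well, WellAssignment(role=ROLE_CONTROL, replicate_group="control"))

    for i, drug in enumerate(drugs):
        series = build_dilution_series(drug.start_multiple * drug.gi50, fold, n_levels)
        for k, conc in enumerate(series.concentrations):
            for d in range(duplicates):
                layout.assign(
                    _well(i, k * duplicates + d + 1),
                    WellAssignment(
                        role=ROLE_TREATED,
                        drugs=(drug.drug_id,),
                        concentrations=(conc,),
                        replicate_group=f"{drug.drug_id}|L{k}",
                    ),
                )
    layout.validate()
    return layout


def build_combination_layout(
    drugA: ScreenAnnotation,
    drugB: ScreenAnnotation,
    centerA: float,
    centerB: float,
    fold: float = 2.0,
    n_levels: int = 5,
    duplicates: int = 2,
    startA: float | None = None,
    startB: float | None = None,
    n_controls: int = 4,
    plate_id: str = "combination",
    n_rows: int = 16,
    n_cols: int = 24,
) -> PlateLayout:
    """Binary-combination matrix layout.

    The core is an ``n_levels x n_levels`` dose-pair grid (drug A varies
    along rows, drug B along columns), each pair in ``duplicates``
    adjacent columns; single-drug edges for each level of each drug and
    ``n_controls`` untreated wells complete the plate.  Each ladder runs
    decreasing from ``fold**((n_levels-1)/2) * center`` unless an
    explicit start is given, so it spans ``fold**(n_levels-1)`` around
    the center.
    """
    if n_levels < 2:
        raise ValueError("combination matrix needs n_levels >= 2")
    if centerA <= 0 or centerB <= 0:
        raise ValueError("center concentrations must be positive")

    if startA is None:
        startA = fold ** ((n_levels - 1) / 2.0) * centerA
    if startB is None:
        startB = fold ** ((n_levels - 1) / 2.0) * centerB
    ladderA = build_dilution_series(startA, fold, n_levels).concentrations
    ladderB = build_dilution_series(startB, fold, n_levels).concentrations

    n_block_cols = n_levels * duplicates + duplicates  # core + drug-A edge
    n_block_rows = n_levels + 1 + 1                    # core + drug-B edge + controls
    if n_block_cols > n_cols or n_block_rows > n_rows:
        raise ValueError(
            f"combination block {n_block_rows}x{n_block_cols} exceeds "
            f"{n_rows}x{n_cols} plate"
        )

    layout = PlateLayout(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols)
    A, B = drugA.drug_id, drugB.drug_id

    for i, concA in enumerate(ladderA):
        # core dose pairs
        for j, concB in enumerate(ladderB):
            for d in range(duplicates):
                layout.assign(
                    _well(i, j * duplicates + d + 1),
                    WellAssignment(
                        role=ROLE_TREATED,
                        drugs=(A, B),
                        concentrations=(concA, concB),
                        replicate_group=f"{A}|L{i}+{B}|L{j}",
                    ),
                )
        # drug-A single-agent edge, right of the core
        for d in range(duplicates):
            layout.assign(
                _well(i, n_levels * duplicates + d + 1),
                WellAssignment(
                    role=ROLE_TREATED,
                    drugs=(A,),
                    concentrations=(concA,),
                    replicate_group=f"{A}|L{i}",
                ),
            )
    # drug-B single-agent edge, below the core
    for j, concB in enumerate(ladderB):
        for d in range(duplicates):
            layout.assign(
                _well(n_levels, j * duplicates + d + 1),
                WellAssignment(
                    role=ROLE_TREATED,
                    drugs=(B,),
                    concentrations=(concB,),
                    replicate_group=f"{B}|L{j}",
                ),
            )
    for c in range(n_controls):
        layout.assign(
            _well(n_levels + 1, c + 1),
            WellAssignment(role=ROLE_CONTROL, replicate_group="control"),
        )
    layout.validate()
    return layout


def assemble_virtual_plate(
    well_scores: Mapping[WellAddress, float], layout: PlateLayout
) -> pd.DataFrame:
    """Re-key well scores to (condition, dose), averaging duplicates.

    Returns one row per replicate group with columns ``role, drug_1,
    conc_1, drug_2, conc_2, score, n_wells``; ``score`` is the
    arithmetic mean over the group's wells (order-invariant).
    """
    missing = [
        str(w) for w, a in sorted(layout.wells.items())
        if a.role != ROLE_EMPTY and w not in well_scores
    ]
    if missing:
        raise ValueError(f"missing scores for wells: {', '.join(missing)}")

    rows = []
    for group, wells in layout.replicate_groups().items():
        if not wells:
            raise ValueError(f"replicate group {group!r} has no wells")
        a = layout.wells[wells[0]]
        scores = [well_scores[w] for w in wells]
        rows.append(
            {
                "replicate_group": group,
                "role": a.role,
                "drug_1": a.drugs[0] if len(a.drugs) > 0 else "",
                "conc_1": a.concentrations[0] if len(a.drugs) > 0 else float("nan"),
                "drug_2": a.drugs[1] if len(a.drugs) > 1 else "",
                "conc_2": a.concentrations[1] if len(a.drugs) > 1 else float("nan"),
                "score": sum(scores) / len(scores),
                "n_wells": len(wells),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["role", "drug_1", "drug_2", "conc_1", "conc_2"]
    ).reset_index(drop=True)
    return frame
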