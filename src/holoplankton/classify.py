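"""Decision-tree classification of particle silhouettes into taxa.

Nine operational classes are used: seven plankton groups plus Marine
snow (sinking detrital aggregates) and Suspension (small non-living
sedimentary particles, the basis of the turbidity estimate).  The tree
tests three silhouette features: the presence of antennas, the length
``H`` of the circumscribed rectangle, and the morphological parameter
``M`` (width/length of that rectangle).

Boundary conventions (the printed ranges touch without specifying
inclusion): ``H <= 200`` micrometres goes to the small-size branch; each
``M`` interval is half-open ``[lo, hi)`` except intervals ending at 1,
which are closed.  Two (antennas, H, M) cells are not covered by the
nine verbatim rows; the patched default table routes them to "Other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

H_SPLIT_UM = 200.0

TAXA = (
    "Chaetognatha",
    "Copepoda",
    "Copelata",
    "Cladocera",
    "Other",
    "Rotifera",
    "Phytoplankton chain",
    "Marine snow",
    "Suspension",
)

PLANKTON_TAXA = TAXA[:7]


class DecisionTableError(ValueError):
    """Raised for malformed or internally overlapping decision tables."""


@dataclass(frozen=True)
class DecisionRow:
    taxon: str
    antennas: bool
    h_rule: str  # ">200", "<=200" or "ANY"
    m_lo: float
    m_hi: float

    def __post_init__(self) -> None:
        if self.h_rule not in (">200", "<=200", "ANY"):
            raise DecisionTableError(f"bad H rule: {self.h_rule!r}")
        if not (0 <= self.m_lo < self.m_hi <= 1):
            raise DecisionTableError(f"bad M interval [{self.m_lo}, {self.m_hi}]")

    def matches(self, h_um: float, m: float, antennas: bool) -> bool:
        if antennas != self.antennas:
            return False
        if self.h_rule == ">200" and not h_um > H_SPLIT_UM:
            return False
        if self.h_rule == "<=200" and not h_um <= H_SPLIT_UM:
            return False
        if self.m_hi >= 1.0:  # topmost interval is closed
            return self.m_lo <= m <= self.m_hi
        return self.m_lo <= m < self.m_hi


_DEFAULT_ROWS = (
    DecisionRow("Chaetognatha", True, ">200", 0.0, 0.2),
    DecisionRow("Copepoda", True, ">200", 0.2, 0.5),
    DecisionRow("Copelata", True, ">200", 0.5, 0.66),
    DecisionRow("Cladocera", True, ">200", 0.66, 0.9),
    DecisionRow("Other", True, ">200", 0.9, 1.0),
    DecisionRow("Rotifera", True, "<=200", 0.0, 0.9),
    DecisionRow("Phytoplankton chain", False, "ANY", 0.0, 0.25),
    DecisionRow("Marine snow", False, "ANY", 0.25, 0.9),
    DecisionRow("Suspension", False, "<=200", 0.9, 1.0),
)

_PATCH_ROWS = (
    DecisionRow("Other", True, "<=200", 0.9, 1.0),
    DecisionRow("Other", False, ">200", 0.9, 1.0),
)


@dataclass(frozen=True)
class DecisionTable:
    rows: tuple[DecisionRow, ...]

    @classmethod
    def default(cls, patched: bool = True) -> "DecisionTable":
        """The shipped nine-row tree; ``patched`` adds the two catch-all rows."""
        rows = _DEFAULT_ROWS + (_PATCH_ROWS if patched else ())
        return cls(rows)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DecisionTable":
        df = pd.read_csv(path_or_buf)
        rows = tuple(
            DecisionRow(
                str(r.taxon),
                str(r.antennas).strip().upper() in ("YES", "TRUE", "1"),
                str(r.h_rule).strip(),
                float(r.m_lo),
                float(r.m_hi),
            )
            for r in df.itertuples()
        )
        return cls(rows)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "taxon": r.taxon,
                    "antennas": "YES" if r.antennas else "NO",
                    "h_rule": r.h_rule,
                    "m_lo": r.m_lo,
                    "m_hi": r.m_hi,
                }
                for r in self.rows
            ]
        ).to_csv(path, index=False)


@dataclass
class CoverageReport:
    """Coverage of the (antennas, H-side, M) feature space by a table."""

    uncovered: list[tuple[bool, str, float, float]] = field(default_factory=list)
    overlaps: list[tuple[str, str, bool, str, float, float]] = field(default_factory=list)

    @property
    def n_uncovered(self) -> int:
        return len(self.uncovered)


def _branch_rows(table: DecisionTable, antennas: bool, h_side: str):
    return [
        r
        for r in table.rows
        if r.antennas == antennas and r.h_rule in (h_side, "ANY")
    ]


def validate_decision_table(table: DecisionTable, strict: bool = True) -> CoverageReport:
    """Enumerate uncovered cells and overlapping rows of a decision table.

    The M axis is cut at every interval endpoint; each atomic interval in
    each (antennas, H-side) branch must be claimed by exactly one row.
    With ``strict`` an overlap raises :class:`DecisionTableError` naming
    the offending pair.
    """
    if not table.rows:
        raise DecisionTableError("empty decision table")
    report = CoverageReport()
    for antennas in (True, False):
        for h_side in (">200", "<=200"):
            rows = _branch_rows(table, antennas, h_side)
            cuts = sorted({0.0, 1.0} | {r.m_lo for r in rows} | {r.m_hi for r in rows})
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                mid = (lo + hi) / 2
                owners = [r for r in rows if r.m_lo <= mid < r.m_hi]
                if not owners:
                    # merge with previous uncovered atom in the same branch
                    if (
                        report.uncovered
                        and report.uncovered[-1][:2] == (antennas, h_side)
                        and report.uncovered[-1][3] == lo
                    ):
                        a, h, plo, _ = report.uncovered[-1]
                        report.uncovered[-1] = (a, h, plo, hi)
                    else:
                        report.uncovered.append((antennas, h_side, lo, hi))
                elif len(owners) > 1:
                    report.overlaps.append(
                        (owners[0].taxon, owners[1].taxon, antennas, h_side, lo, hi)
                    )
    if strict and report.overlaps:
        pairs = "; ".join(f"{a} / {b} on ({lo}, {hi})" for a, b, _, _, lo, hi in report.overlaps)
        raise DecisionTableError(f"overlapping rows: {pairs}")
    return report


def classify(
    h_um: float,
    m: float,
    antennas: bool,
    table: DecisionTable | None = None,
) -> str:
    """Assign a taxon label to one measured particle."""
    label, _ = classify_detailed(h_um, m, antennas, table)
    return label


def classify_detailed(
    h_um: float,
    m: float,
    antennas: bool,
    table: DecisionTable | None = None,
) -> tuple[str, bool]:
    """Classify and report whether the point fell outside the table.

    Returns ``(label, out_of_table)``.  Points in a cell that no row
    covers are labelled "Other" with ``out_of_table=True``.
    """
    if not 0 <= m <= 1:
        raise ValueError(f"M={m} outside [0, 1]")
    if h_um <= 0:
        raise ValueError(f"H={h_um} must be positive")
    if table is None:
        table = DecisionTable.default(patched=True)
    for row in table.rows:
        if row.matches(h_um, m, bool(antennas)):
            return row.taxon, False
    return "Other", True


def classify_table(df: pd.DataFrame, table: DecisionTable | None = None) -> pd.DataFrame:
    """Classify every row of a particle measurement table.

    Expects columns ``H_um``, ``M``, ``antennas``; adds ``taxon`` and
    ``out_of_table``.
    """
    out = df.copy()
    labels, flags = [], []
    for h, m, a in zip(out["H_um"], out["M"], out["antennas"]):
        t, f = classify_detailed(float(h), float(min(max(m, 0.0), 1.0)), bool(a), table)
        labels.append(t)
        flags.append(f)
    out["taxon"] = labels
    out["out_of_table"] = flags
    return out
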