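"""Sample-level data model for detection/non-detection water-sample tables.

A *sample* is one 1-L water grab from a pond, taken on a given study day at
a known transect (1-9, three per pond section) and water-column position
(surface / middle / bottom), scored 0/1 for a positive eDNA qPCR assay.
Tables of such samples are the input to every downstream stage: model
fitting, model selection, false-positive estimation and survey design.

The module also ships :func:`builtin_pond_study`, a deterministic
reconstruction of a four-pond mesocosm experiment (4 ponds x 3 days x 27
samples = 324 records) from its published per-stratum detection counts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "POSITIONS",
    "CSV_COLUMNS",
    "SampleRecord",
    "SampleTable",
    "load_samples",
    "builtin_pond_study",
    "subset",
]

#: Water-column strata, in fixed order (surface is the regression baseline).
POSITIONS = ("surface", "middle", "bottom")

#: Canonical CSV schema (header names, column order).
CSV_COLUMNS = [
    "pond_id",
    "day",
    "section",
    "transect",
    "position",
    "density_fish_per_m3",
    "temperature_c",
    "detection",
]


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One 1-L water sample with design coordinates, covariates and outcome."""

    pond_id: int
    day: int
    section: int
    transect: int
    position: str
    density_fish_per_m3: float
    temperature_c: float
    detection: int


def _section_for_transect(transect: int) -> int:
    return (int(transect) - 1) // 3 + 1


class SampleTable:
    """Ordered collection of samples backed by a :class:`pandas.DataFrame`.

    Parameters
    ----------
    df
        Frame with the :data:`CSV_COLUMNS` columns (extra columns rejected
        on write, ignored on validation). Row order is preserved.
    provenance
        Free-text tag: ``"fixture"``, ``"file"`` or ``"simulated"``.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "file") -> None:
        self.df = self._validate(df)
        self.provenance = provenance

    # -- construction ----------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[SampleRecord], provenance: str = "file"
    ) -> "SampleTable":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CSV_COLUMNS)
        return cls(df, provenance=provenance)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        df = df[CSV_COLUMNS].copy()
        for col in ("pond_id", "day", "section", "transect"):
            df[col] = df[col].astype(int)
        df["density_fish_per_m3"] = df["density_fish_per_m3"].astype(float)
        df["temperature_c"] = df["temperature_c"].astype(float)
        df["position"] = df["position"].astype(str).str.lower()

        for i, pos in enumerate(df["position"]):
            if pos not in POSITIONS:
                raise ValueError(
                    f"row {i}: unknown position label {pos!r} "
                    f"(column 'position'; expected one of {POSITIONS})"
                )
        det = df["detection"]
        for i, val in enumerate(det):
            if val not in (0, 1):
                raise ValueError(
                    f"row {i}: detection value {val!r} is not binary "
                    "(column 'detection'; expected 0 or 1)"
                )
        df["detection"] = det.astype(int)
        for i, dens in enumerate(df["density_fish_per_m3"]):
            if not dens >= 0:
                raise ValueError(
                    f"row {i}: density {dens!r} is negative "
                    "(column 'density_fish_per_m3')"
                )
        for i, (sec, tr) in enumerate(zip(df["section"], df["transect"])):
            if _section_for_transect(tr) != sec:
                raise ValueError(
                    f"row {i}: transect {tr} lies in section "
                    f"{_section_for_transect(tr)}, not section {sec} "
                    "(columns 'section'/'transect')"
                )
        return df.reset_index(drop=True)

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield SampleRecord(*row)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return (
            f"SampleTable({len(self)} samples, "
            f"{self.n_detections} detections, provenance={self.provenance!r})"
        )

    # -- summaries -------------------------------------------------------

    @property
    def n_detections(self) -> int:
        return int(self.df["detection"].sum())

    # -- I/O -------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        """Write the canonical CSV (header row, lowercase positions)."""
        self.df.to_csv(path, index=False)


def load_samples(path: str | Path, **read_csv_kwargs) -> SampleTable:
    """Read and validate a sample table from CSV.

    Extra keyword arguments are passed to :func:`pandas.read_csv` (dialect
    options). Raises ``ValueError`` naming the offending row and column on
    any validation failure.
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    return SampleTable(df, provenance="file")


# ---------------------------------------------------------------------------
# Built-in pond study fixture
# ---------------------------------------------------------------------------

# Pond-day design and per-stratum detection counts of the four-pond mesocosm
# study: (pond, day, fish density /m^3, water temperature C,
#         (surface, middle, bottom) detection counts out of 9 samples each).
# Pond 1 is the fishless control.
_POND_DAYS: tuple[tuple[int, int, float, float, tuple[int, int, int]], ...] = (
    (1, 1, 0.0, 30.20, (0, 0, 0)),
    (1, 5, 0.0, 30.17, (0, 0, 0)),
    (1, 10, 0.0, 28.30, (0, 0, 0)),
    (2, 1, 0.32, 30.77, (0, 0, 0)),
    (2, 5, 0.32, 29.77, (0, 0, 0)),
    (2, 10, 0.32, 28.23, (0, 1, 0)),
    (3, 1, 1.75, 30.70, (1, 1, 0)),
    (3, 5, 1.75, 29.87, (0, 0, 0)),
    (3, 10, 1.75, 28.23, (0, 0, 0)),
    (4, 1, 5.24, 30.77, (2, 2, 3)),
    (4, 5, 5.24, 29.77, (2, 0, 1)),
    (4, 10, 5.24, 28.30, (6, 2, 7)),
)


def builtin_pond_study() -> SampleTable:
    """Reconstruct the 324-sample pond study from its published cell counts.

    Each pond-day contributes 27 samples: one sample per transect (1-9) per
    water-column position, so every pond-day-position cell holds 9 samples.
    Which of the 9 samples in a cell were the detections is not recorded at
    sample level; detections are assigned deterministically to the lowest
    transect indices. This choice is inferentially neutral for any model
    without section/transect random intercepts, whose likelihood depends on
    the data only through per-cell counts; random-intercept fits on this
    fixture are approximate in that one respect.

    The published per-pond-day temperature is applied to all 27 samples of
    that pond-day (per-stratum temperature readings were not published).
    """
    records = []
    for pond, day, density, temp, counts in _POND_DAYS:
        for position, n_det in zip(POSITIONS, counts):
            for transect in range(1, 10):
                records.append(
                    SampleRecord(
                        pond_id=pond,
                        day=day,
                        section=_section_for_transect(transect),
                        transect=transect,
                        position=position,
                        density_fish_per_m3=density,
                        temperature_c=temp,
                        detection=1 if transect <= n_det else 0,
                    )
                )
    return SampleTable.from_records(records, provenance="fixture")


def subset(
    table: SampleTable,
    predicate: Callable[[pd.DataFrame], "pd.Series"] | None = None,
    **field_filters,
) -> SampleTable:
    """Return the samples matching a predicate and/or field equality filters.

    ``predicate`` receives the underlying frame and must return a boolean
    mask; keyword filters select rows where the named field equals (or, for
    list/tuple/set values, is contained in) the given value. An empty match
    is a valid empty table.

    >>> stocked = subset(builtin_pond_study(), predicate=lambda d: d.pond_id != 1)
    >>> len(stocked)
    243
    """
    mask = pd.Series(True, index=table.df.index)
    if predicate is not None:
        mask &= predicate(table.df).astype(bool)
    for field, value in field_filters.items():
        if field not in table.df.columns:
            raise ValueError(
                f"unknown field {field!r}; known fields: {', '.join(CSV_COLUMNS)}"
            )
        if isinstance(value, (list, tuple, set, frozenset)):
            mask &= table.df[field].isin(list(value))
        else:
            mask &= table.df[field] == value
    out = SampleTable(table.df[mask], provenance=table.provenance)
    return out
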