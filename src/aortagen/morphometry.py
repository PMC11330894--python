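"""Cohort-weighted aortic morphometry.

This module ships a transcription of the literature survey behind the
idealized models: per-study morphometric records (with per-sex sub-cohorts
and missing cells kept as reported) for arch-type prevalence, thoracic
diameters, arch height/width/bend radius, branch diameters, spacings and
takeoff angles, and coronary diameters.  The single statistic the model
construction relies on is the cohort-size-weighted mean

    mean = sum(n_i * v_i) / sum(n_i)

over sub-cohorts that report a value.  Male/female sub-cohorts count as
independent entries; a study that does not report a column contributes
nothing to that column's mean or cumulative cohort size N.

A handful of printed summary cells cannot be reproduced from the printed
per-study rows under any defensible counting rule (transcription metadata
marks these ``mean_verified``/``n_verified`` false); downstream checks only
assert the reproducible cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import NoDataError, ParameterError
from .params import AortaParameterSet, ArchType

__all__ = [
    "Modality", "SubCohort", "StudyRecord", "MorphoTable",
    "weighted_mean", "cumulative_n", "prevalences",
    "load_table", "load_all_tables", "aggregate_all", "aggregate_metadata",
    "default_parameters",
]

TABLE_NAMES = ("table1", "table2", "table3", "table4", "table5",
               "table6", "table7", "table8", "table9")

_TABLE_TITLES = {
    "table1": "Prevalence of aortic arch branch types",
    "table2": "Thoracic aorta diameters",
    "table3": "Height, width, and curvature of the aortic arch",
    "table4": "Distance from sinotubular junction to start of the arch",
    "table5": "Angles of the descending aorta and aortic arch",
    "table6": "Diameters of the aortic arch vessels",
    "table7": "Distances between the aortic arch vessels",
    "table8": "Takeoff angles of the aortic arch vessels",
    "table9": "Diameters of the coronary arteries",
}


class Modality(str, Enum):
    """Imaging/measurement modality of a literature study."""

    CT = "CT"
    CTA = "CTA"
    MRI = "MRI"
    CMR = "CMR"
    ECHO = "Echo"
    TTE = "TTE"
    DSA = "DSA"
    MSCTA = "MSCTA"
    QCA = "QCA"
    CADAVER = "Cadaver"
    REVIEW = "Review"


@dataclass(frozen=True)
class SubCohort:
    """One weighted entry of a study column: ``n`` subjects with mean ``value``.

    ``value`` is ``None`` when the study did not report the column; such
    entries are excluded from both the weighted mean and the cumulative N.
    """

    label: str          # "male", "female" or "all"
    n: int
    value: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("male", "female", "all"):
            raise ParameterError(f"sub-cohort label must be male/female/all, got {self.label!r}")
        if self.n < 1:
            raise ParameterError(f"sub-cohort size must be >= 1, got {self.n}")


@dataclass(frozen=True)
class StudyRecord:
    """One literature row: a study with per-symbol sub-cohort lists."""

    study_id: str
    modality: Modality
    age_note: str
    columns: dict[str, tuple[SubCohort, ...]]


@dataclass(frozen=True)
class MorphoTable:
    """A named collection of study records sharing a unit."""

    name: str
    unit: str
    records: tuple[StudyRecord, ...]

    @property
    def title(self) -> str:
        return _TABLE_TITLES.get(self.name, self.name)

    @property
    def symbols(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for sym in rec.columns:
                seen.setdefault(sym)
        return tuple(seen)

    def column(self, symbol: str) -> list[SubCohort]:
        """All sub-cohorts of ``symbol`` across studies (reported or not)."""
        out: list[SubCohort] = []
        for rec in self.records:
            out.extend(rec.columns.get(symbol, ()))
        return out


# ---------------------------------------------------------------------------
# aggregation primitives
# ---------------------------------------------------------------------------

def weighted_mean(column: list[SubCohort] | tuple[SubCohort, ...]) -> float:
    """Cohort-size-weighted mean over sub-cohorts that report a value."""
    num = den = 0.0
    for sc in column:
        if sc.value is not None:
            num += sc.n * sc.value
            den += sc.n
    if den == 0:
        raise NoDataError("no sub-cohort in this column reports a value")
    return num / den


def cumulative_n(column: list[SubCohort] | tuple[SubCohort, ...]) -> int:
    """Total number of subjects behind a column's weighted mean.

    Male/female sub-cohorts are counted separately; sub-cohorts with a
    missing value contribute nothing.  Empty columns give 0.
    """
    return sum(sc.n for sc in column if sc.value is not None)


def prevalences(table: MorphoTable) -> tuple[float, float, float]:
    """Weighted prevalence (%) of the Normal, Bovine and Isolated arch types.

    The three need not sum to 100: rare variants are excluded from the
    source surveys.
    """
    return (weighted_mean(table.column("type_i")),
            weighted_mean(table.column("type_ii")),
            weighted_mean(table.column("type_iii")))


# ---------------------------------------------------------------------------
# packaged data
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("aortagen").joinpath("data").joinpath(name)))


def load_table(name: str) -> MorphoTable:
    """Load one packaged morphometry table (``table1`` .. ``table9``)."""
    if name not in TABLE_NAMES:
        raise ParameterError(f"unknown table {name!r}; expected one of {TABLE_NAMES}")
    df = pd.read_csv(_data_path(f"{name}.csv"), dtype={"value": float},
                     keep_default_na=False, na_values=[""])
    records: list[StudyRecord] = []
    units = set(df["unit"])
    for study_id, g in df.groupby("study_id", sort=False):
        columns: dict[str, list[SubCohort]] = {}
        for row in g.itertuples():
            val = None if pd.isna(row.value) else float(row.value)
            columns.setdefault(row.symbol, []).append(
                SubCohort(label=row.label, n=int(row.n), value=val))
        records.append(StudyRecord(
            study_id=str(study_id),
            modality=Modality(g["modality"].iloc[0]),
            age_note=str(g["age_note"].iloc[0]),
            columns={k: tuple(v) for k, v in columns.items()},
        ))
    unit = units.pop() if len(units) == 1 else "mixed"
    return MorphoTable(name=name, unit=unit, records=tuple(records))


def load_all_tables() -> dict[str, MorphoTable]:
    return {name: load_table(name) for name in TABLE_NAMES}


def aggregate_metadata() -> pd.DataFrame:
    """Per-symbol printed summary cells with reproducibility flags.

    Columns: table, symbol, unit, printed_mean, decimals, printed_n,
    mean_verified, n_verified.  ``mean_verified`` is true when the direct
    weighted mean, rounded to the printed precision, matches the printed
    cell within one unit in the last place.
    """
    return pd.read_csv(_data_path("aggregates.csv"))


def aggregate_all() -> dict[str, tuple[float, int]]:
    """Recompute every column: symbol -> (weighted mean, cumulative N)."""
    out: dict[str, tuple[float, int]] = {}
    for table in load_all_tables().values():
        for sym in table.symbols:
            col = table.column(sym)
            out[sym] = (weighted_mean(col), cumulative_n(col))
    return out


def default_parameters(arch_type: ArchType | str) -> AortaParameterSet:
    """The packaged summary parameter set for Type I or Type II."""
    at = ArchType.coerce(arch_type)
    data = yaml.safe_load(_data_path("table10_defaults.yaml").read_text())
    key = "type_i" if at is ArchType.TYPE_I else "type_ii"
    return AortaParameterSet.from_dict(data[key])
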