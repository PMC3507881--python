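"""Reading, validation and assembly of mushroom-census inputs.

Three delimited text tables drive the analysis:

* a species table (``species_id, genus, family, guild, hypogeous``) assigning
  every species to a trophic guild — ectomycorrhizal (ECM), litter-decomposing,
  wood-decomposing, or unclassified — and flagging below-ground fruiters;
* a long detections table (``survey_id, date, species_id``), one row per
  species recorded in a monthly survey;
* a daily climate table (``date, temp_mean_c, rain_mm``).

From these we build the model's data objects: a :class:`DetectionMatrix` of
per-survey, per-group species counts and a :class:`CovariateTable` of
survey-anchored climate covariates (trailing-window temperature and rainfall,
and elapsed years), z-standardized over the analyzed surveys.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Guild",
    "SpeciesRecord",
    "SurveyEvent",
    "DetectionMatrix",
    "CovariateTable",
    "CovariateWindows",
    "COVARIATE_NAMES",
    "DEFAULT_GENERA",
    "read_species_table",
    "read_detections",
    "read_climate",
    "write_species_table",
    "write_detections",
    "filter_species",
    "build_detection_matrix",
    "build_covariates",
]

COVARIATE_NAMES = ("T", "MR", "WR", "Y")


class Guild(str, Enum):
    """Trophic guild of a mushroom-forming species."""

    ECM = "ECM"
    LITTER = "LITTER"
    WOOD = "WOOD"
    OTHER = "OTHER"


#: Accepted guild spellings in input files -> canonical guild.  Field sheets
#: commonly abbreviate litter/wood decomposers as "L"/"W" and mark species of
#: unresolved guild as "NA".
GUILD_DIALECT = {
    "ECM": Guild.ECM,
    "L": Guild.LITTER,
    "LITTER": Guild.LITTER,
    "W": Guild.WOOD,
    "WOOD": Guild.WOOD,
    "NA": Guild.OTHER,
    "OTHER": Guild.OTHER,
}

#: The 21 most frequently recorded genera, seven per guild, used for the
#: genus-level model fits and the concordance analysis.
DEFAULT_GENERA: dict[str, Guild] = {
    "Amanita": Guild.ECM,
    "Boletus": Guild.ECM,
    "Tylopilus": Guild.ECM,
    "Cortinarius": Guild.ECM,
    "Inocybe": Guild.ECM,
    "Lactarius": Guild.ECM,
    "Russula": Guild.ECM,
    "Agaricus": Guild.LITTER,
    "Lepiota": Guild.LITTER,
    "Lycoperdon": Guild.LITTER,
    "Entoloma": Guild.LITTER,
    "Hygrocybe": Guild.LITTER,
    "Marasmius": Guild.LITTER,
    "Collybia": Guild.LITTER,
    "Crepidotus": Guild.WOOD,
    "Mycena": Guild.WOOD,
    "Pluteus": Guild.WOOD,
    "Psathyrella": Guild.WOOD,
    "Pholiota": Guild.WOOD,
    "Tremella": Guild.WOOD,
    "Polyporus": Guild.WOOD,
}

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


@dataclass(frozen=True)
class SpeciesRecord:
    """One fungal species with its taxonomy and guild attributes."""

    species_id: str
    genus: str
    family: str
    guild: Guild
    hypogeous: bool = False


@dataclass(frozen=True)
class SurveyEvent:
    """One monthly census: the set of species detected on one date."""

    survey_id: int
    date: _dt.date
    detections: frozenset[str]


@dataclass
class DetectionMatrix:
    """Per-survey, per-group detected species counts.

    ``D[i, j]`` is the number of distinct species of group ``j`` detected in
    survey ``i``; ``N[j]`` is the number of distinct species of group ``j``
    observed at least once across all surveys (the binomial denominator of the
    presence/detection model).
    """

    D: np.ndarray
    N: np.ndarray
    groups: list[str]
    dates: list[_dt.date]
    survey_ids: list[int]
    group_guilds: dict[str, Guild] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        if self.D.shape != (len(self.dates), len(self.groups)):
            raise ValueError("D shape does not match surveys x groups")
        if np.any(self.D > self.N[None, :]) or np.any(self.D < 0):
            raise ValueError("detection counts must satisfy 0 <= D[i,j] <= N[j]")

    @property
    def n_surveys(self) -> int:
        return self.D.shape[0]

    def column(self, group: str) -> np.ndarray:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return self.D[:, self.groups.index(group)]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.D, columns=self.groups)
        out.insert(0, "survey_id", self.survey_ids)
        out.insert(1, "date", [d.isoformat() for d in self.dates])
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CovariateTable:
    """Raw and z-standardized covariates per survey.

    Columns are T (mean temperature over the monthly window, degC), MR
    (accumulated rainfall over the monthly window, mm), WR (accumulated
    rainfall over the weekly window, mm) and Y (years elapsed since the first
    survey).  ``x`` holds the standardized values used in the regression;
    ``x_raw`` the untransformed ones; ``means``/``sds`` the constants so new
    surveys can be projected onto the same scale.
    """

    x: np.ndarray
    x_raw: np.ndarray
    names: tuple[str, ...]
    dates: list[_dt.date]
    survey_ids: list[int]
    means: np.ndarray
    sds: np.ndarray
    windows: "CovariateWindows"

    @property
    def n_surveys(self) -> int:
        return self.x.shape[0]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"survey_id": self.survey_ids,
                            "date": [d.isoformat() for d in self.dates]})
        for k, name in enumerate(self.names):
            out[f"{name}_raw"] = self.x_raw[:, k]
            out[name] = self.x[:, k]
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def meta(self) -> dict:
        return {
            "covariates": list(self.names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "sd_ddof": 1,
            "windows": {
                "monthly_days": self.windows.monthly_days,
                "weekly_days": self.windows.weekly_days,
                "calendar_month": self.windows.calendar_month,
            },
        }

    def write_meta(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.meta(), indent=2) + "\n")


@dataclass(frozen=True)
class CovariateWindows:
    """Window policy for the climate covariates.

    Trailing windows end on the survey date and are closed at both ends, so a
    ``monthly_days=30`` window spans the survey date and the 29 days before
    it.  ``calendar_month=True`` switches T and MR to the calendar month
    containing the survey; WR always uses the trailing weekly window.
    """

    monthly_days: int = 30
    weekly_days: int = 7
    calendar_month: bool = False


# ---------------------------------------------------------------------------
# readers / writers

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse hypogeous flag {value!r}")


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read the species table, mapping guild codes through the dialect table.

    Raises ``ValueError`` on a duplicate ``species_id`` (naming it) or an
    unrecognised guild code (naming the row).
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                     keep_default_na=False)
    required = {"species_id", "genus", "family", "guild", "hypogeous"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        sid = str(rec.species_id)
        if sid in seen:
            raise ValueError(f"duplicate species_id {sid!r}")
        seen.add(sid)
        code = str(rec.guild).strip().upper()
        if code not in GUILD_DIALECT:
            raise ValueError(f"row {row}: unknown guild code {rec.guild!r}")
        records.append(SpeciesRecord(
            species_id=sid,
            genus=str(rec.genus),
            family=str(rec.family),
            guild=GUILD_DIALECT[code],
            hypogeous=_parse_bool(rec.hypogeous, row),
        ))
    return records


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    df = pd.DataFrame([
        {"species_id": r.species_id, "genus": r.genus, "family": r.family,
         "guild": r.guild.value, "hypogeous": str(r.hypogeous).lower()}
        for r in records
    ])
    df.to_csv(path, index=False, sep=_sep_for(path))


def read_detections(path: str | Path) -> list[SurveyEvent]:
    """Read the long detections table into per-survey events.

    Validates that survey dates strictly increase with ``survey_id`` and that
    no calendar month holds more than one survey (the census is monthly;
    skipped months are simply absent).
    """
    df = pd.read_csv(path, sep=_sep_for(path),
                     dtype={"survey_id": np.int64, "species_id": str})
    required = {"survey_id", "date", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detections table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    events: list[SurveyEvent] = []
    for sid, grp in df.groupby("survey_id", sort=True):
        dates = grp["date"].unique()
        if len(dates) != 1:
            raise ValueError(f"survey {sid} has multiple dates: {sorted(dates)}")
        events.append(SurveyEvent(int(sid), dates[0], frozenset(grp["species_id"])))
    validate_surveys(events)
    return events


def validate_surveys(events: Sequence[SurveyEvent]) -> None:
    months: set[tuple[int, int]] = set()
    prev: _dt.date | None = None
    for ev in events:
        if prev is not None and ev.date <= prev:
            raise ValueError(
                f"survey dates must strictly increase with survey_id; "
                f"survey {ev.survey_id} dated {ev.date} follows {prev}")
        prev = ev.date
        key = (ev.date.year, ev.date.month)
        if key in months:
            raise ValueError(f"more than one survey in {key[0]}-{key[1]:02d}")
        months.add(key)


def write_detections(events: Iterable[SurveyEvent], path: str | Path) -> None:
    rows = [
        {"survey_id": ev.survey_id, "date": ev.date.isoformat(), "species_id": sp}
        for ev in events for sp in sorted(ev.detections)
    ]
    pd.DataFrame(rows, columns=["survey_id", "date", "species_id"]).to_csv(
        path, index=False, sep=_sep_for(path))


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read daily climate into a date-indexed frame (temp_mean_c, rain_mm)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"date", "temp_mean_c", "rain_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate climate date {dup.date()}")
    if (df["rain_mm"] < 0).any():
        raise ValueError("rain_mm must be non-negative")
    return df.set_index("date").sort_index()


# ---------------------------------------------------------------------------
# filtering and matrix assembly

def filter_species(records: Sequence[SpeciesRecord],
                   exclude_hypogeous: bool = True) -> list[SpeciesRecord]:
    """Drop hypogeous (below-ground fruiting) species, preserving order.

    Hypogeous species are census-biased — finding them depends heavily on
    collector expertise — so the analysis excludes them.
    """
    if not exclude_hypogeous:
        return list(records)
    return [r for r in records if not r.hypogeous]


def build_detection_matrix(surveys: Sequence[SurveyEvent],
                           species: Sequence[SpeciesRecord],
                           grouping: str = "by_guild",
                           genera: dict[str, Guild] | None = None,
                           guilds: Sequence[Guild] = (Guild.ECM, Guild.LITTER,
                                                      Guild.WOOD),
                           ) -> DetectionMatrix:
    """Count distinct detected species per survey and group.

    ``grouping="by_guild"`` groups species by trophic guild (default the three
    modelled guilds; unclassified species are dropped).
    ``grouping="by_genus_within_guild"`` restricts to an explicit genus list
    (default the 21 most frequent genera) with one group per genus.

    ``N[j]`` counts only species actually observed in at least one survey;
    species never detected do not enter the binomial denominator.
    """
    by_id = {r.species_id: r for r in species}
    for ev in surveys:
        unknown = ev.detections - by_id.keys()
        if unknown:
            raise ValueError(
                f"survey {ev.survey_id} detects unknown species "
                f"{sorted(unknown)[:5]}")

    if grouping == "by_guild":
        labels = [g.value for g in guilds]

        def group_of(rec: SpeciesRecord) -> str | None:
            return rec.guild.value if rec.guild in guilds else None

        guild_map = {g.value: g for g in guilds}
    elif grouping == "by_genus_within_guild":
        genera = dict(DEFAULT_GENERA) if genera is None else dict(genera)
        labels = list(genera)

        def group_of(rec: SpeciesRecord) -> str | None:
            if rec.genus in genera and rec.guild == genera[rec.genus]:
                return rec.genus
            return None

        guild_map = dict(genera)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    col = {lab: j for j, lab in enumerate(labels)}
    D = np.zeros((len(surveys), len(labels)), dtype=np.int64)
    observed: list[set[str]] = [set() for _ in labels]
    for i, ev in enumerate(surveys):
        for sp in ev.detections:
            g = group_of(by_id[sp])
            if g is None:
                continue
            D[i, col[g]] += 1
            observed[col[g]].add(sp)
    N = np.array([len(s) for s in observed], dtype=np.int64)
    return DetectionMatrix(
        D=D, N=N, groups=labels,
        dates=[ev.date for ev in surveys],
        survey_ids=[ev.survey_id for ev in surveys],
        group_guilds=guild_map,
    )


def build_covariates(surveys: Sequence[SurveyEvent],
                     climate: pd.DataFrame,
                     windows: CovariateWindows = CovariateWindows(),
                     ) -> CovariateTable:
    """Build the four survey-anchored covariates and z-standardize them.

    Defaults: T = mean daily temperature and MR = accumulated rainfall over
    the trailing 30-day window ending on the survey date (both ends
    inclusive); WR = accumulated rainfall over the trailing 7-day window;
    Y = years elapsed since the first survey (365.25-day years).
    Standardization uses the sample sd (ddof=1) over the analyzed surveys.

    Raises ``ValueError`` naming the first missing climate date inside any
    window.
    """
    if not surveys:
        raise ValueError("no surveys")
    temp = climate["temp_mean_c"]
    rain = climate["rain_mm"]

    def window(series: pd.Series, end: _dt.date, days: int) -> pd.Series:
        lo = pd.Timestamp(end) - pd.Timedelta(days=days - 1)
        hi = pd.Timestamp(end)
        idx = pd.date_range(lo, hi, freq="D")
        got = series.reindex(idx)
        if got.isna().any():
            missing = got.index[got.isna()][0].date()
            raise ValueError(f"missing climate data for {missing}")
        return got

    first = surveys[0].date
    rows = []
    for ev in surveys:
        if windows.calendar_month:
            month_start = ev.date.replace(day=1)
            span = (ev.date - month_start).days + 1
            t = window(temp, ev.date, span).mean()
            mr = window(rain, ev.date, span).sum()
        else:
            t = window(temp, ev.date, windows.monthly_days).mean()
            mr = window(rain, ev.date, windows.monthly_days).sum()
        wr = window(rain, ev.date, windows.weekly_days).sum()
        y = (ev.date - first).days / 365.25
        rows.append((t, mr, wr, y))

    x_raw = np.asarray(rows, dtype=float)
    means = x_raw.mean(axis=0)
    sds = x_raw.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(4)
    constant = sds <= 0
    if np.any(constant):
        names = [COVARIATE_NAMES[k] for k in np.flatnonzero(constant)]
        warnings.warn(f"constant covariate(s) {names} standardized to zero",
                      stacklevel=2)
    safe = np.where(constant, 1.0, sds)
    x = np.where(constant[None, :], 0.0, (x_raw - means) / safe)
    return CovariateTable(
        x=x, x_raw=x_raw, names=COVARIATE_NAMES,
        dates=[ev.date for ev in surveys],
        survey_ids=[ev.survey_id for ev in surveys],
        means=means, sds=sds, windows=windows,
    )
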