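"""Scan-table data model, readers/validators, season assignment and focal
individual selection.

The central container is :class:`ScanTable`, a thin wrapper around a tidy
:class:`pandas.DataFrame` with one row per individual sighting.  Sightings
recorded at the same instant under the same subgroup label form a *subgroup
scan* — the sampling unit of the whole analysis.  Field protocols record one
shared location per subgroup, so all rows of a subgroup scan carry identical
coordinates and timestamps.

Seasons follow the wet/dry alternation typical of seasonal tropical forest
sites: the wet season opens mid-May and the dry season mid-November, with the
dry season conventionally labelled by the calendar year in which it *ends*
(so November 2013 – May 2014 is ``dry-2014``).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fisofus.errors import ConfigurationError, InsufficientDataError, ValidationError

#: canonical scan-table column names
SCAN_COLUMNS = ["date", "time", "subgroup_id", "x", "y", "individual_id"]

VALID_SEXES = {"female", "male", "unknown"}


@dataclass(frozen=True)
class ScanRecord:
    """A single individual sighting within a subgroup scan."""

    timestamp: _dt.datetime
    subgroup_id: str
    x: float
    y: float
    individual_id: str
    sex: str = "unknown"


class ScanTable:
    """Tidy table of individual sightings grouped into subgroup scans.

    Parameters
    ----------
    df
        DataFrame with columns ``date`` (datetime.date), ``time``
        (datetime.time), ``subgroup_id``, ``x``, ``y``, ``individual_id``.
        A combined ``timestamp`` column is derived on construction.
    roster
        Mapping ``individual_id -> sex`` for every known adult.  When omitted
        it is built from the data with sex ``"unknown"``.
    validate
        Run invariant checks (finite coordinates, one timestamp per subgroup
        scan, no duplicated individual within a scan, no individual in two
        subgroups at one instant).
    """

    def __init__(self, df: pd.DataFrame, roster: dict[str, str] | None = None,
                 validate: bool = True):
        df = df.copy().reset_index(drop=True)
        missing = [c for c in SCAN_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"scan table missing required columns: {missing}")
        if len(df):
            df["timestamp"] = pd.to_datetime(
                df["date"].astype(str) + " " + df["time"].astype(str)
            )
        else:
            df["timestamp"] = pd.Series([], dtype="datetime64[ns]")
        self.df = df
        if roster is None:
            roster = {i: "unknown" for i in df["individual_id"].unique()}
        self.roster = dict(roster)
        if validate:
            self._validate()

    # -- invariants ------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        problems: list[str] = []
        bad_rows: list[int] = []

        xy = df[["x", "y"]].to_numpy(dtype=float, na_value=np.nan)
        nonfinite = ~np.isfinite(xy).all(axis=1)
        if nonfinite.any():
            rows = df.index[nonfinite].tolist()
            bad_rows += rows
            problems.append(f"non-finite coordinates in rows {rows}")

        unknown = set(df["individual_id"]) - set(self.roster)
        if unknown:
            problems.append(f"individuals absent from roster: {sorted(unknown)}")

        # one timestamp per subgroup scan (subgroup_id is unique within a day)
        key = ["date", "subgroup_id"]
        if len(df):
            nts = df.groupby(key)["timestamp"].nunique()
            split = nts[nts > 1]
            if len(split):
                problems.append(
                    f"subgroup scans with multiple timestamps: {list(split.index)}"
                )
            dup = df.duplicated(subset=key + ["individual_id"], keep=False)
            if dup.any():
                dups = df.loc[dup, ["date", "subgroup_id", "individual_id"]]
                names = sorted(dups["individual_id"].unique())
                bad_rows += df.index[dup].tolist()
                problems.append(
                    f"individual(s) {names} duplicated within a subgroup scan"
                )
            twice = df.duplicated(subset=["timestamp", "individual_id"], keep=False)
            both = twice & ~dup
            if both.any():
                names = sorted(df.loc[both, "individual_id"].unique())
                problems.append(
                    f"individual(s) {names} recorded in two subgroups at one instant"
                )
        if problems:
            raise ValidationError("; ".join(problems), rows=bad_rows)

    # -- views -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["individual_id"].unique())

    def scan_keys(self) -> pd.DataFrame:
        """Unique subgroup scans as (date, subgroup_id, timestamp) rows."""
        if not len(self.df):
            return pd.DataFrame(columns=["date", "subgroup_id", "timestamp"])
        return (self.df[["date", "subgroup_id", "timestamp"]]
                .drop_duplicates()
                .reset_index(drop=True))

    @property
    def n_scans(self) -> int:
        return len(self.scan_keys())

    def with_seasons(self, cal: "SeasonCalendar") -> "ScanTable":
        """Return a copy with a ``season`` column assigned from *cal*."""
        out = ScanTable(self.df.drop(columns=["timestamp"]), roster=self.roster,
                        validate=False)
        dates = pd.to_datetime(out.df["date"]).dt.date
        out.df["season"] = [cal.assign(d) for d in dates]
        return out

    def restrict(self, individuals=None, season: str | None = None) -> "ScanTable":
        """Subset rows by roster membership and/or season label."""
        df = self.df
        if individuals is not None:
            df = df[df["individual_id"].isin(set(individuals))]
        if season is not None:
            if "season" not in df.columns:
                raise ConfigurationError("seasons not assigned; call with_seasons first")
            df = df[df["season"] == season]
        out = ScanTable(df.drop(columns=["timestamp"]), roster=self.roster,
                        validate=False)
        if "season" in df.columns:
            out.df["season"] = df["season"].to_numpy()
        return out

    def records(self) -> list[ScanRecord]:
        return [
            ScanRecord(row.timestamp.to_pydatetime(), str(row.subgroup_id),
                       float(row.x), float(row.y), str(row.individual_id),
                       self.roster.get(row.individual_id, "unknown"))
            for row in self.df.itertuples()
        ]


@dataclass
class SeasonCalendar:
    """Alternating wet/dry season calendar.

    ``dry_start``/``wet_start`` are (month, day) pairs; the default dry
    season opens November 15 and the wet season May 15.  ``dry_year_label``
    selects whether a dry season spanning a year boundary is labelled by the
    year it ends in (``"end"``, the default) or begins in (``"start"``).
    ``coverage`` optionally clips the calendar to the observed study window;
    dates outside it raise.
    """

    dry_start: tuple[int, int] = (11, 15)
    wet_start: tuple[int, int] = (5, 15)
    dry_year_label: str = "end"
    coverage: tuple[_dt.date, _dt.date] | None = None

    def __post_init__(self):
        if self.dry_year_label not in ("end", "start"):
            raise ConfigurationError("dry_year_label must be 'end' or 'start'")
        if not (self.wet_start < self.dry_start):
            raise ConfigurationError("wet season must begin before dry within the year")

    def assign(self, d: _dt.date) -> str:
        """Season label for calendar date *d*; boundary dates open a season."""
        if self.coverage is not None:
            lo, hi = self.coverage
            if not (lo <= d <= hi):
                raise ValueError(f"date {d} outside calendar coverage {lo}..{hi}")
        wet = _dt.date(d.year, *self.wet_start)
        dry = _dt.date(d.year, *self.dry_start)
        if d < wet:
            # tail of the dry season that began the previous November
            year = d.year if self.dry_year_label == "end" else d.year - 1
            return f"dry-{year}"
        if d < dry:
            return f"wet-{d.year}"
        year = d.year + 1 if self.dry_year_label == "end" else d.year
        return f"dry-{year}"

    def season_bounds(self, start: _dt.date, end: _dt.date) -> list[tuple[str, _dt.date, _dt.date]]:
        """Seasons intersecting [start, end], clipped to that window.

        The first and last seasons are truncated rather than rejected, which
        matches studies whose observation window opens mid-season.
        """
        out = []
        d = start
        while d <= end:
            label = self.assign(d) if self.coverage is None else \
                SeasonCalendar(self.dry_start, self.wet_start, self.dry_year_label).assign(d)
            # advance to next boundary
            nxt = min(b for b in self._boundaries(d.year) if b > d)
            s_end = min(nxt - _dt.timedelta(days=1), end)
            out.append((label, d, s_end))
            d = s_end + _dt.timedelta(days=1)
        return out

    def _boundaries(self, year: int) -> list[_dt.date]:
        return [
            _dt.date(y, *ms)
            for y in (year, year + 1)
            for ms in (self.wet_start, self.dry_start)
        ]


def assign_season(d: _dt.date, cal: SeasonCalendar) -> str:
    """Functional alias for :meth:`SeasonCalendar.assign`."""
    return cal.assign(d)


@dataclass
class FocalRoster:
    """Individuals retained for dyadic analyses plus their per-season
    sighting fractions and sexes."""

    individuals: list[str]
    fractions: pd.DataFrame  # index individual_id, columns season labels
    sexes: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self):
        return len(self.individuals)

    def __contains__(self, ind):
        return ind in set(self.individuals)


def select_focal_individuals(t: ScanTable, cal: SeasonCalendar,
                             min_fraction: float = 0.10) -> FocalRoster:
    """Select individuals sighted in at least ``min_fraction`` of the
    subgroup scans of *every* season.

    The denominator for a season is the number of distinct subgroup scans
    recorded in that season; the numerator counts scans in which the
    individual appears.  The threshold is inclusive ("at least").
    """
    if not len(t):
        raise InsufficientDataError("empty scan table")
    st = t if "season" in t.df.columns else t.with_seasons(cal)
    scans = st.df.drop_duplicates(subset=["date", "subgroup_id"])
    totals = scans.groupby("season").size()
    empty = totals[totals == 0]
    if len(empty):
        raise InsufficientDataError(f"seasons with zero scans: {list(empty.index)}")
    seen = (st.df.drop_duplicates(subset=["date", "subgroup_id", "individual_id"])
            .groupby(["individual_id", "season"]).size().unstack(fill_value=0))
    seen = seen.reindex(columns=totals.index, fill_value=0)
    frac = seen.div(totals, axis=1)
    keep = frac.index[(frac >= min_fraction).all(axis=1)].tolist()
    sexes = {i: t.roster.get(i, "unknown") for i in keep}
    return FocalRoster(sorted(keep), frac, sexes)


# ---------------------------------------------------------------------------
# readers / writers

DEFAULT_DIALECT = {c: c for c in SCAN_COLUMNS}


def read_scan_table(path, dialect: dict[str, str] | None = None,
                    roster_path=None) -> ScanTable:
    """Read a scan CSV into a validated :class:`ScanTable`.

    ``dialect`` maps canonical column names (``date``, ``time``,
    ``subgroup_id``, ``x``, ``y``, ``individual_id``) to the file's column
    headers.  Malformed rows are reported with 1-based file line numbers
    (header = line 1).  ``roster_path`` optionally points to a CSV with
    columns ``individual_id, sex``.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, dtype=str)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    df = pd.DataFrame({canon: raw[col] for canon, col in dialect.items()})

    bad: list[str] = []
    dates, times = [], []
    for idx, (ds, ts) in enumerate(zip(df["date"], df["time"])):
        line = idx + 2
        try:
            dates.append(_dt.date.fromisoformat(str(ds)))
        except ValueError:
            bad.append(f"line {line}: unparseable date {ds!r}")
            dates.append(None)
        try:
            times.append(_parse_time(str(ts)))
        except ValueError:
            bad.append(f"line {line}: unparseable time {ts!r}")
            times.append(None)
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna()]:
            bad.append(f"line {idx + 2}: non-numeric {col} value {df.loc[idx, col]!r}")
        df[col] = vals
    if bad:
        raise ValidationError("; ".join(bad), rows=bad)
    df["date"], df["time"] = dates, times

    roster = None
    if roster_path is not None:
        rdf = pd.read_csv(roster_path, dtype=str)
        if not {"individual_id", "sex"} <= set(rdf.columns):
            raise ConfigurationError(f"{roster_path}: roster needs individual_id, sex")
        bad_sex = set(rdf["sex"]) - VALID_SEXES
        if bad_sex:
            raise ValidationError(f"invalid sex value(s) {sorted(bad_sex)}")
        roster = dict(zip(rdf["individual_id"], rdf["sex"]))
    return ScanTable(df, roster=roster)


def _parse_time(s: str) -> _dt.time:
    for fmt in ("%H:%M", "%H:%M:%S"):
        try:
            return _dt.datetime.strptime(s, fmt).time()
        except ValueError:
            continue
    raise ValueError(s)


def write_scan_table(t: ScanTable, path) -> None:
    """Write the canonical scan CSV dialect (round-trips with
    :func:`read_scan_table`)."""
    out = t.df[SCAN_COLUMNS].copy()
    out["time"] = [x.strftime("%H:%M") if hasattr(x, "strftime") else x
                   for x in out["time"]]
    out.to_csv(path, index=False)


PHENOLOGY_COLUMNS = ["species", "fortnight_start", "fruiting_fraction",
                     "density_per_ha", "dbh_sum_cm_per_ha"]


def read_phenology_table(path) -> list:
    """Read a fortnightly phenology CSV into FruitSpeciesRecord rows.

    Expected columns: species, fortnight_start, fruiting_fraction (in
    [0, 1]), density_per_ha (trees/ha), dbh_sum_cm_per_ha (cm/ha).
    """
    from fisofus.seasonal_framework import FruitSpeciesRecord  # avoid cycle

    df = pd.read_csv(path)
    missing = [c for c in PHENOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing phenology column(s) {missing}")
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2
        if not (0.0 <= row["fruiting_fraction"] <= 1.0):
            problems.append(f"line {line}: fruiting_fraction outside [0,1]")
        if row["density_per_ha"] < 0 or row["dbh_sum_cm_per_ha"] < 0:
            problems.append(f"line {line}: negative density or DBH sum")
    if problems:
        raise ValidationError("; ".join(problems), rows=problems)
    return [
        FruitSpeciesRecord(str(r["species"]), str(r["fortnight_start"]),
                           float(r["fruiting_fraction"]), float(r["density_per_ha"]),
                           float(r["dbh_sum_cm_per_ha"]))
        for _, r in df.iterrows()
    ]
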