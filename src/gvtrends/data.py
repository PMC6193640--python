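"""Domain types, file readers/writers and derived-covariate construction.

All pipeline stages exchange three tabular objects:

* an ordered incident series (:class:`IncidentRecord`),
* a 50-state covariate panel plus its neighbourhood graph (:class:`StatePanel`),
* the sequence of inter-incident intervals with media covariates
  (:class:`IntervalRecord`).

Files are plain CSV (comma-separated, UTF-8, ISO-8601 dates, mandatory
header); the adjacency file is a whitespace-separated edge list with one
``ST1 ST2`` pair per line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "IncidentRecord",
    "StatePanel",
    "IntervalRecord",
    "FormatError",
    "RowError",
    "MIN_FATALITIES",
    "US_STATES",
    "read_incidents",
    "write_incidents",
    "read_state_panel",
    "write_state_panel",
    "read_adjacency",
    "write_adjacency",
    "read_media",
    "write_media",
    "compute_fss_ratio",
    "build_intervals",
    "incident_counts_by_state",
    "us_state_adjacency",
]

logger = logging.getLogger(__name__)

#: Study inclusion threshold: at least four victims killed (perpetrator excluded).
MIN_FATALITIES = 4

#: The 50 U.S. states (no DC / territories), two-letter USPS codes.
US_STATES = (
    "AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY LA ME MD "
    "MA MI MN MS MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC "
    "SD TN TX UT VT VA WA WV WI WY"
).split()

_US_STATE_SET = frozenset(US_STATES)


class FormatError(ValueError):
    """A file is structurally malformed (missing column, bad header...)."""


class RowError(ValueError):
    """A specific row violates a contract; the message names the row."""


@dataclass(frozen=True)
class IncidentRecord:
    """One mass-shooting event.

    Events qualify with at least :data:`MIN_FATALITIES` victim fatalities,
    perpetrator excluded.
    """

    event_id: str
    date: Date
    state_code: str
    fatalities: int
    injuries: int

    def __post_init__(self) -> None:
        if self.fatalities < 0 or self.injuries < 0:
            raise ValueError(f"negative casualty count on event {self.event_id}")


@dataclass
class StatePanel:
    """Per-state covariates, incident counts and the neighbour graph.

    ``table`` columns: state, population, fss_ratio, mental_illness_rate,
    poverty_rate, permissiveness, incident_count.  ``adjacency`` is an
    undirected :class:`networkx.Graph` over the same state codes (no
    self-loops; symmetric by construction).
    """

    table: pd.DataFrame
    adjacency: nx.Graph

    def __post_init__(self) -> None:
        t = self.table
        required = {
            "state",
            "population",
            "fss_ratio",
            "mental_illness_rate",
            "poverty_rate",
            "permissiveness",
        }
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"state panel missing columns: {sorted(missing)}")
        if (t["population"] <= 0).any():
            raise ValueError("population must be positive for every state")
        if ((t["fss_ratio"] < 0) | (t["fss_ratio"] > 1)).any():
            raise ValueError("fss_ratio must lie in [0, 1]")
        if "incident_count" in t.columns and (t["incident_count"] < 0).any():
            raise ValueError("incident_count must be non-negative")
        if any(u == v for u, v in self.adjacency.edges):
            raise ValueError("adjacency graph contains a self-loop")
        extra = set(self.adjacency.nodes) - set(t["state"])
        if extra:
            raise ValueError(f"adjacency names states absent from the panel: {sorted(extra)}")

    @property
    def states(self) -> list[str]:
        return list(self.table["state"])

    def validate_counts(self, incidents: Sequence[IncidentRecord]) -> None:
        """Check per-state incident counts against the incident table."""
        expected = incident_counts_by_state(incidents, self.states)
        got = self.table.set_index("state")["incident_count"]
        if not (expected == got.reindex(expected.index)).all():
            raise ValueError("panel incident_count disagrees with the incident table")


@dataclass(frozen=True)
class IntervalRecord:
    """The gap between two consecutive incidents, with media covariates.

    ``media_density`` is articles per day over the interval; ``search_interest``
    is relative search volume, scaled so the period maximum is 100.
    """

    index: int
    start_event: str
    end_event: str
    interval_days: float
    media_article_count: float = np.nan
    media_density: float = np.nan
    search_interest: float = np.nan

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValueError(f"interval {self.index}: non-positive duration")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


def read_incidents(
    path: str | Path,
    *,
    min_fatalities: int = MIN_FATALITIES,
    strict: bool = True,
    start: Date | None = None,
    end: Date | None = None,
) -> list[IncidentRecord]:
    """Read an incident CSV and return records sorted ascending by date.

    Ties in date keep file order.  Rows with fewer than ``min_fatalities``
    fatalities raise :class:`RowError` when ``strict`` (the default) and are
    dropped with a warning otherwise.  ``start``/``end`` bound the study
    window; out-of-window rows are an error.
    """
    df = pd.read_csv(path, dtype={"state": str})
    _require_columns(df, ["date", "state", "fatalities", "injuries"], str(path))
    if df.empty:
        logger.warning("incident file %s contains no data rows", path)
        return []
    records: list[IncidentRecord] = []
    for i, row in df.iterrows():
        try:
            d = pd.Timestamp(row["date"]).date()
        except (ValueError, TypeError) as exc:
            raise RowError(f"row {i}: unparseable date {row['date']!r}") from exc
        fat = int(row["fatalities"])
        if fat < min_fatalities:
            msg = f"row {i}: fatalities={fat} below the inclusion threshold {min_fatalities}"
            if strict:
                raise RowError(msg)
            logger.warning("%s; dropping", msg)
            continue
        if (start is not None and d < start) or (end is not None and d > end):
            raise RowError(f"row {i}: date {d} outside the study window")
        event_id = str(row["event_id"]) if "event_id" in df.columns else f"E{i:04d}"
        records.append(
            IncidentRecord(
                event_id=event_id,
                date=d,
                state_code=str(row["state"]),
                fatalities=fat,
                injuries=int(row["injuries"]),
            )
        )
    records.sort(key=lambda r: r.date)  # stable: ties keep file order
    return records


def write_incidents(records: Sequence[IncidentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "state": [r.state_code for r in records],
            "fatalities": [r.fatalities for r in records],
            "injuries": [r.injuries for r in records],
        }
    ).to_csv(path, index=False)


def read_state_panel(path: str | Path, adjacency: nx.Graph | None = None) -> StatePanel:
    """Read a state covariate CSV into a :class:`StatePanel`.

    ``adjacency`` defaults to the contiguous-U.S. border graph
    (:func:`us_state_adjacency`) restricted to the panel's states.
    """
    df = pd.read_csv(path, dtype={"state": str})
    _require_columns(
        df,
        ["state", "population", "fss_ratio", "mental_illness_rate", "poverty_rate", "permissiveness"],
        str(path),
    )
    unknown = set(df["state"]) - _US_STATE_SET
    if unknown:
        raise FormatError(f"unknown state codes in panel: {sorted(unknown)}")
    if adjacency is None:
        adjacency = us_state_adjacency().subgraph(df["state"]).copy()
    return StatePanel(table=df.reset_index(drop=True), adjacency=adjacency)


def write_state_panel(panel: StatePanel, path: str | Path) -> None:
    panel.table.to_csv(path, index=False, float_format="%.12g")


def read_adjacency(path: str | Path, valid_states: Iterable[str] | None = None) -> nx.Graph:
    """Read a two-column edge list into an undirected graph.

    Duplicate edges are merged with a warning; self-loops are an error;
    unknown state codes (when ``valid_states`` given) are an error.  Isolated
    states listed on their own line (single token) are added as nodes and
    logged — an isolated node carries no spatial smoothing under a CAR prior.
    """
    valid = frozenset(valid_states) if valid_states is not None else _US_STATE_SET
    g: nx.Graph = nx.Graph()
    seen: set[frozenset[str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) == 1:
                (a,) = tokens
                if a not in valid:
                    raise FormatError(f"{path}:{lineno}: unknown state {a!r}")
                g.add_node(a)
                logger.info("isolated state %s (no neighbours; CAR prior degenerates)", a)
                continue
            if len(tokens) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'ST1 ST2', got {line!r}")
            a, b = tokens
            for s in (a, b):
                if s not in valid:
                    raise FormatError(f"{path}:{lineno}: unknown state {s!r}")
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-loop {a!r}")
            key = frozenset((a, b))
            if key in seen:
                logger.warning("%s:%d: duplicate edge %s-%s ignored", path, lineno, a, b)
                continue
            seen.add(key)
            g.add_edge(a, b)
    return g


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a} {b}\n")
        for node in sorted(graph.nodes):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def read_media(path: str | Path) -> pd.DataFrame:
    """Read the per-interval media table (interval_index, article_count, search_interest)."""
    df = pd.read_csv(path)
    _require_columns(df, ["interval_index", "article_count", "search_interest"], str(path))
    return df.sort_values("interval_index").reset_index(drop=True)


def write_media(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def compute_fss_ratio(
    firearm_suicides: Sequence[float], all_suicides: Sequence[float]
) -> float:
    """Household gun-ownership proxy: mean firearm suicides / mean all suicides.

    Both series are yearly counts over the same years.  The ratio of the
    multi-year averages (not the average of yearly ratios) is returned.
    """
    f = np.asarray(firearm_suicides, dtype=float)
    a = np.asarray(all_suicides, dtype=float)
    if f.shape != a.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("firearm and all-suicide series must be equal-length 1-D")
    if (a <= 0).any():
        raise ValueError("all-suicide counts must be positive every year")
    if (f > a).any():
        raise ValueError("firearm suicides exceed all suicides in some year")
    if (f < 0).any():
        raise ValueError("negative suicide count")
    return float(f.mean() / a.mean())


def build_intervals(
    incidents: Sequence[IncidentRecord],
    media_counts: Sequence[float] | None = None,
    search_interest: Sequence[float] | None = None,
    *,
    floor_same_day: bool = False,
) -> list[IntervalRecord]:
    """Pair consecutive incidents into inter-arrival intervals.

    ``media_counts`` and ``search_interest``, when given, must have one entry
    per interval (``len(incidents) - 1``).  Two incidents on the same calendar
    day raise an error unless ``floor_same_day`` floors the gap at one day.
    """
    if len(incidents) < 2:
        raise ValueError("need at least two incidents to form an interval")
    n_int = len(incidents) - 1
    for name, series in (("media_counts", media_counts), ("search_interest", search_interest)):
        if series is not None and len(series) != n_int:
            raise ValueError(f"{name} must have {n_int} entries (one per interval)")
    out: list[IntervalRecord] = []
    for k in range(n_int):
        a, b = incidents[k], incidents[k + 1]
        days = float((b.date - a.date).days)
        if days < 0:
            raise ValueError("incidents must be ordered by date")
        if days == 0:
            if not floor_same_day:
                raise ValueError(
                    f"incidents {a.event_id} and {b.event_id} share date {a.date}; "
                    "pass floor_same_day=True to floor the interval at 1 day"
                )
            days = 1.0
        count = float(media_counts[k]) if media_counts is not None else np.nan
        if count == count and count < 0:
            raise ValueError(f"interval {k}: negative article count")
        out.append(
            IntervalRecord(
                index=k,
                start_event=a.event_id,
                end_event=b.event_id,
                interval_days=days,
                media_article_count=count,
                media_density=count / days if count == count else np.nan,
                search_interest=float(search_interest[k]) if search_interest is not None else np.nan,
            )
        )
    return out


def incident_counts_by_state(
    incidents: Sequence[IncidentRecord], states: Sequence[str]
) -> pd.Series:
    """Per-state incident totals over ``states`` (zero-filled)."""
    counts = pd.Series(0, index=pd.Index(states, name="state"), dtype=int)
    for r in incidents:
        if r.state_code in counts.index:
            counts[r.state_code] += 1
    return counts


# Contiguous-U.S. state border pairs (AK and HI are isolated nodes).
_US_BORDERS = """
AL FL; AL GA; AL MS; AL TN; AR LA; AR MO; AR MS; AR OK; AR TN; AR TX;
AZ CA; AZ CO; AZ NM; AZ NV; AZ UT; CA NV; CA OR; CO KS; CO NE; CO NM;
CO OK; CO UT; CO WY; CT MA; CT NY; CT RI; DE MD; DE NJ; DE PA; FL GA;
GA NC; GA SC; GA TN; IA IL; IA MN; IA MO; IA NE; IA SD; IA WI; ID MT;
ID NV; ID OR; ID UT; ID WA; ID WY; IL IN; IL KY; IL MO; IL WI; IN KY;
IN MI; IN OH; KS MO; KS NE; KS OK; KY MO; KY OH; KY TN; KY VA; KY WV;
LA MS; LA TX; MA NH; MA NY; MA RI; MA VT; MD PA; MD VA; MD WV; ME NH;
MI OH; MI WI; MN ND; MN SD; MN WI; MO NE; MO OK; MO TN; MS TN; MT ND;
MT SD; MT WY; NC SC; NC TN; NC VA; ND SD; NE SD; NE WY; NH VT; NJ NY;
NJ PA; NM OK; NM TX; NV OR; NV UT; NY PA; NY VT; OH PA; OH WV; OK TX;
OR WA; PA WV; SD WY; TN VA; UT WY; VA WV
"""


def us_state_adjacency() -> nx.Graph:
    """Border graph of the 50 states: contiguous-48 land borders; AK and HI isolated."""
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(US_STATES)
    for pair in _US_BORDERS.replace("\n", " ").split(";"):
        a, b = pair.split()
        g.add_edge(a, b)
    return g
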