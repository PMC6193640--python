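"""Synthetic-data generators for every pipeline input.

The study's compiled dataset (incident series, state covariate panel, media
table) is not redistributable, so each input is emulated with the statistical
structure the downstream models assume:

* state-level counts from a zero-inflated Poisson with an intrinsic CAR
  (spatially structured) plus exchangeable random effect and a population
  offset, calibrated so that roughly 19 of 50 states record no incident and
  about 100 incidents accrue nationally over 1982–2018;
* national event dates from a non-homogeneous Poisson process whose two-year
  expected count is log-linear in time;
* casualty marks with fatality counts floored at four (the study's inclusion
  rule) and overdispersed severity;
* per-interval media coverage coupled to the following inter-incident
  interval through a Gaussian copula with a target Spearman correlation.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    US_STATES,
    IncidentRecord,
    StatePanel,
    build_intervals,
    us_state_adjacency,
    write_adjacency,
    write_incidents,
    write_media,
    write_state_panel,
)

__all__ = [
    "SimTruth",
    "DEFAULT_SEED",
    "simulate_state_panel",
    "simulate_nhpp_events",
    "attach_casualties",
    "simulate_media",
    "simulate_dataset",
    "sample_icar",
]

#: Shipped default seed (start of the final study month, 2018-05-01, as yyyymmdd).
DEFAULT_SEED = 20180501

# Mid-2010s resident population by state, millions (census estimates, rounded).
_STATE_POP_M = {
    "AL": 4.86, "AK": 0.74, "AZ": 6.93, "AR": 2.99, "CA": 39.25, "CO": 5.54,
    "CT": 3.58, "DE": 0.95, "FL": 20.61, "GA": 10.31, "HI": 1.43, "ID": 1.68,
    "IL": 12.80, "IN": 6.63, "IA": 3.13, "KS": 2.91, "KY": 4.44, "LA": 4.68,
    "ME": 1.33, "MD": 6.02, "MA": 6.81, "MI": 9.93, "MN": 5.52, "MS": 2.99,
    "MO": 6.09, "MT": 1.04, "NE": 1.91, "NV": 2.94, "NH": 1.33, "NJ": 8.94,
    "NM": 2.08, "NY": 19.75, "NC": 10.15, "ND": 0.76, "OH": 11.61, "OK": 3.92,
    "OR": 4.09, "PA": 12.78, "RI": 1.06, "SC": 4.96, "SD": 0.87, "TN": 6.65,
    "TX": 27.86, "UT": 3.05, "VT": 0.62, "VA": 8.41, "WA": 7.29, "WV": 1.83,
    "WI": 5.78, "WY": 0.59,
}

# "May-issue" concealed-carry states (officials hold permit discretion).
_MAY_ISSUE = ("CA", "CT", "DE", "HI", "MD", "MA", "NJ", "NY", "RI")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters recorded alongside every generated dataset.

    ``beta`` is (intercept, FS/S, mental-illness, poverty, permissiveness) on
    the log-rate scale with the raw covariate scales; the intercept applies to
    a per-person exposure.  ``zero_model`` holds the logit coefficients of the
    structural-zero model over the same design.  ``intensity_a``/``intensity_b``
    are the national trend's log two-year expected count at 1982 and its
    yearly slope.  ``rho_target`` is the Spearman correlation aimed at between
    media density and the following interval.
    """

    beta: tuple[float, ...] = (-14.85, -0.35, 0.02, -0.02, -0.26)
    sigma_v: float = 0.5
    sigma_u: float = 0.3
    zero_model: tuple[float, ...] = (-1.95, 0.0, 0.0, 0.0, 0.0)
    intensity_a: float = 0.55683
    intensity_b: float = 0.05033
    rho_target: float = -0.70
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.sigma_v <= 0 or self.sigma_u <= 0:
            raise ValueError("random-effect scales must be positive")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _check_symmetric(adjacency: nx.Graph) -> None:
    if adjacency.is_directed():
        a = nx.to_numpy_array(adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")


def sample_icar(adjacency: nx.Graph, sigma: float, rng: np.random.Generator,
                nodelist: Sequence[str] | None = None) -> np.ndarray:
    """Draw from the intrinsic CAR (zero-sum constrained) Gaussian.

    The improper ICAR density has precision ``Q/sigma²`` with ``Q`` the graph
    Laplacian; the draw lives in the subspace orthogonal to each connected
    component's constant vector (zero-sum per component), sampled through the
    Laplacian eigendecomposition.  Singleton components get exactly 0.
    """
    _check_symmetric(adjacency)
    nodes = list(nodelist) if nodelist is not None else list(adjacency.nodes)
    q = nx.laplacian_matrix(adjacency, nodelist=nodes).toarray().astype(float)
    w, vec = np.linalg.eigh(q)
    v = np.zeros(len(nodes))
    tol = 1e-9 * max(1.0, w.max() if len(w) else 1.0)
    pos = w > tol
    if pos.any():
        z = rng.standard_normal(pos.sum())
        v = vec[:, pos] @ (z * sigma / np.sqrt(w[pos]))
    # numerical zero-sum per component
    comp_label = _component_labels(adjacency, nodes)
    for c in np.unique(comp_label):
        m = comp_label == c
        if m.sum() > 1:
            v[m] -= v[m].mean()
        else:
            v[m] = 0.0
    return v


def _component_labels(adjacency: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(nodes)}
    labels = np.empty(len(nodes), dtype=int)
    for c, comp in enumerate(nx.connected_components(adjacency)):
        for s in comp:
            labels[idx[s]] = c
    return labels


def _random_adjacency(n: int, rng: np.random.Generator) -> nx.Graph:
    """Connected synthetic border graph for non-US panel sizes."""
    g = nx.path_graph(n)
    extra = rng.integers(0, n, size=(max(n // 2, 1), 2))
    for a, b in extra:
        if a != b:
            g.add_edge(int(a), int(b))
    return nx.relabel_nodes(g, {i: f"S{i:02d}" for i in range(n)})


def simulate_state_panel(
    n_states: int = 50,
    adjacency: nx.Graph | None = None,
    truth: SimTruth | None = None,
    *,
    seed: int | None = None,
) -> tuple[StatePanel, SimTruth]:
    """Simulate covariates, random effects and ZIP incident counts per state.

    With the defaults (50 states, U.S. border graph, U.S. populations) the
    panel is calibrated to the study regime: ≈100 incidents nationally and
    ≈19 zero-count states, with covariate effects matching the magnitudes the
    spatial model reports.  For other ``n_states`` a synthetic connected
    adjacency and log-normal populations are used.
    """
    if n_states < 3:
        raise ValueError("need at least 3 states")
    truth = truth or SimTruth()
    if seed is not None:
        truth = dataclasses.replace(truth, seed=seed)
    rng = np.random.default_rng(truth.seed)

    if n_states == 50 and adjacency is None:
        states = list(US_STATES)
        adjacency = us_state_adjacency()
        population = np.array([_STATE_POP_M[s] for s in states]) * 1e6
        permissive = np.array([1 if s in _MAY_ISSUE else 0 for s in states])
    else:
        if adjacency is None:
            adjacency = _random_adjacency(n_states, rng)
        _check_symmetric(adjacency)
        states = list(adjacency.nodes)
        if len(states) != n_states:
            raise ValueError("adjacency size disagrees with n_states")
        population = np.exp(rng.normal(np.log(4e6), 1.0, size=n_states))
        permissive = (rng.random(n_states) < 0.18).astype(int)

    fss = rng.uniform(0.2, 0.7, size=n_states)
    mental = rng.uniform(13.0, 25.0, size=n_states)
    poverty = rng.uniform(8.0, 20.0, size=n_states)

    x = np.column_stack([np.ones(n_states), fss, mental, poverty, permissive])
    v = sample_icar(adjacency, truth.sigma_v, rng, nodelist=states)
    u = rng.normal(0.0, truth.sigma_u, size=n_states)

    beta = np.asarray(truth.beta, dtype=float)
    gamma = np.asarray(truth.zero_model, dtype=float)
    log_mu = np.log(population) + x @ beta + v + u
    mu = np.exp(log_mu)
    pi = 1.0 / (1.0 + np.exp(-(x @ gamma)))
    structural = rng.random(n_states) < pi
    counts = np.where(structural, 0, rng.poisson(mu))

    table = pd.DataFrame(
        {
            "state": states,
            "population": population,
            "fss_ratio": fss,
            "mental_illness_rate": mental,
            "poverty_rate": poverty,
            "permissiveness": permissive,
            "incident_count": counts.astype(int),
        }
    )
    return StatePanel(table=table, adjacency=adjacency), truth


def _year_float(d: Date | float) -> float:
    if isinstance(d, Date):
        start = Date(d.year, 1, 1)
        return d.year + (d - start).days / (366.0 if _leap(d.year) else 365.0)
    return float(d)


def _leap(y: int) -> bool:
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)


def _date_from_year(tau: float) -> Date:
    y = int(math.floor(tau))
    frac = tau - y
    days = int(round(frac * (366 if _leap(y) else 365)))
    return Date(y, 1, 1) + timedelta(days=days)


def nhpp_expected_count(a: float, b: float, t_start: float, t_end: float,
                        bin_width_years: float = 2.0, origin: float = 1982.0) -> float:
    """∫ λ(τ) dτ for log two-year count a + b·(τ−origin), exact closed form."""
    s0, s1 = t_start - origin, t_end - origin
    if abs(b) < 1e-12:
        return math.exp(a) * (s1 - s0) / bin_width_years
    return (math.exp(a + b * s1) - math.exp(a + b * s0)) / (b * bin_width_years)


def simulate_nhpp_events(
    a: float,
    b: float,
    t_start: Date | float = 1982.0,
    t_end: Date | float = 2018.37,
    seed: int | None = None,
    *,
    bin_width_years: float = 2.0,
    origin: float = 1982.0,
    as_dates: bool = True,
) -> list[Date] | np.ndarray:
    """Simulate event times from a log-linear-intensity Poisson process.

    The instantaneous intensity (events per year) is
    ``exp(a + b·(τ − origin)) / bin_width_years`` so that the expected count
    in a ``bin_width_years``-wide bin starting at offset ``t`` is close to
    ``exp(a + b·t)``.  Sampling is by thinning against the window's maximal
    intensity.  Returns ordered dates (or year floats with ``as_dates=False``).
    """
    t0, t1 = _year_float(t_start), _year_float(t_end)
    if t1 < t0:
        raise ValueError("t_end must not precede t_start")
    span_exponent = a + b * max(t0 - origin, t1 - origin)
    if span_exponent > 50:
        raise ValueError("intensity overflow: a + b·span too large to sample")
    rng = np.random.default_rng(seed)
    if t1 == t0:
        return [] if as_dates else np.array([])
    lam_max = max(
        math.exp(a + b * (t0 - origin)), math.exp(a + b * (t1 - origin))
    ) / bin_width_years
    n_prop = rng.poisson(lam_max * (t1 - t0))
    taus = np.sort(rng.uniform(t0, t1, size=n_prop))
    lam = np.exp(a + b * (taus - origin)) / bin_width_years
    keep = rng.random(n_prop) < lam / lam_max
    taus = taus[keep]
    if not as_dates:
        return taus
    return [_date_from_year(t) for t in taus]


def _nhpp_conditional_times(
    n: int, a: float, b: float, t0: float, t1: float, rng: np.random.Generator,
    origin: float = 1982.0,
) -> np.ndarray:
    """Given the total count, NHPP times are i.i.d. with density ∝ λ; inverse CDF."""
    u = np.sort(rng.random(n))
    if abs(b) < 1e-12:
        return t0 + u * (t1 - t0)
    e0, e1 = math.exp(b * (t0 - origin)), math.exp(b * (t1 - origin))
    return origin + np.log(e0 + u * (e1 - e0)) / b


def attach_casualties(
    dates: Sequence[Date],
    seed: int | None = None,
    *,
    states: Sequence[str] | None = None,
    dispersion: float = 1.0,
    mean_fatalities: float = 8.33,
    mean_injuries: float = 12.92,
) -> list[IncidentRecord]:
    """Mark event dates with states and overdispersed casualty counts.

    Fatalities are 4 plus a negative-binomial excess whose mean is
    ``dispersion·(mean_fatalities − 4)``; ``dispersion=0`` collapses severity
    to the minimal qualifying event (exactly 4 fatalities, 0 injuries).  The
    defaults match the study period's printed totals (means 8.33 and 12.92
    per event).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(dates)
    if states is None:
        pops = np.array([_STATE_POP_M[s] for s in US_STATES])
        states = list(rng.choice(US_STATES, size=n, p=pops / pops.sum()))
    if dispersion == 0:
        excess_f = np.zeros(n, dtype=int)
        injuries = np.zeros(n, dtype=int)
    else:
        mf = dispersion * (mean_fatalities - 4.0)
        mi = dispersion * mean_injuries
        rf, ri = 0.8, 0.35  # NB sizes: heavy-tailed severity
        excess_f = rng.negative_binomial(rf, rf / (rf + mf), size=n)
        injuries = rng.negative_binomial(ri, ri / (ri + mi), size=n)
    return [
        IncidentRecord(
            event_id=f"E{i:04d}",
            date=d,
            state_code=states[i],
            fatalities=4 + int(excess_f[i]),
            injuries=int(injuries[i]),
        )
        for i, d in enumerate(dates)
    ]


def simulate_media(
    interval_days: Sequence[float],
    rho_target: float = -0.70,
    seed: int | None = None,
    *,
    density_log_mean: float = 3.0,
    density_log_sd: float = 1.0,
    interest_noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Couple media coverage to the following inter-incident interval.

    A Gaussian copula links the normal scores of the intervals to a latent
    log-density at correlation ``r = 2·sin(π·ρ/6)`` (the bivariate-normal
    value whose Spearman correlation is ``ρ``).  Article counts are Poisson
    with mean density×days, so the realised density ``count/days`` inherits
    the target rank correlation.  Search interest is a noisy monotone
    transform of density rescaled so its maximum is exactly 100.
    Returns columns interval_index, article_count, search_interest.
    """
    d = np.asarray(interval_days, dtype=float)
    if (d <= 0).any():
        raise ValueError("interval durations must be positive")
    if abs(rho_target) == 1.0:
        raise ValueError("|rho_target| = 1 is unattainable with count and interest noise")
    n = len(d)
    rng = np.random.default_rng(seed)
    r = 2.0 * math.sin(math.pi * rho_target / 6.0)
    ranks = stats.rankdata(d, method="average")
    z1 = stats.norm.ppf((ranks - 0.5) / n)
    z2 = r * z1 + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    density = np.exp(density_log_mean + density_log_sd * z2)
    counts = rng.poisson(density * d)
    log_dens = np.log(np.maximum(counts, 0.5) / d)
    interest = np.exp(log_dens + interest_noise_sd * rng.standard_normal(n))
    interest = 100.0 * interest / interest.max()
    return pd.DataFrame(
        {
            "interval_index": np.arange(n),
            "article_count": counts,
            "search_interest": interest,
        }
    )


def simulate_dataset(
    outdir: str | Path,
    truth: SimTruth | None = None,
    *,
    seed: int | None = None,
    t_start: float = 1982.08,
    t_end: float = 2018.37,
    media_from: Date = Date(2005, 1, 1),
) -> dict[str, Path]:
    """Generate the four pipeline input files plus a ground-truth sidecar.

    The state panel fixes the per-state incident totals (zero-inflated
    spatial model); event dates are then placed by the national trend's
    conditional arrival-time distribution so the incident table and the panel
    agree exactly.  Media covariates are generated for the intervals between
    incidents on/after ``media_from`` (search-interest data only exist from
    2004 on).  Returns a name→path mapping of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = truth or SimTruth()
    if seed is not None:
        truth = dataclasses.replace(truth, seed=seed)
    panel, truth = simulate_state_panel(truth=truth)
    rng = np.random.default_rng(truth.seed + 1)

    counts = panel.table["incident_count"].to_numpy()
    n_events = int(counts.sum())
    taus = _nhpp_conditional_times(
        n_events, truth.intensity_a, truth.intensity_b, t_start, t_end, rng
    )
    dates = [_date_from_year(t) for t in np.sort(taus)]
    # distribute state labels to match the panel's counts exactly
    labels = np.repeat(panel.table["state"].to_numpy(), counts)
    rng.shuffle(labels)
    incidents = attach_casualties(dates, seed=truth.seed + 2, states=list(labels))

    recent = [r for r in incidents if r.date >= media_from]
    media = simulate_media(
        [iv.interval_days for iv in build_intervals(recent, floor_same_day=True)],
        rho_target=truth.rho_target,
        seed=truth.seed + 3,
    ) if len(recent) >= 2 else pd.DataFrame(
        columns=["interval_index", "article_count", "search_interest"]
    )

    paths = {
        "incidents": outdir / "incidents.csv",
        "states": outdir / "states.csv",
        "adjacency": outdir / "adjacency.txt",
        "media": outdir / "media.csv",
        "truth": outdir / "truth.json",
    }
    write_incidents(incidents, paths["incidents"])
    write_state_panel(panel, paths["states"])
    write_adjacency(panel.adjacency, paths["adjacency"])
    write_media(media, paths["media"])
    truth.to_json(paths["truth"])
    return paths
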