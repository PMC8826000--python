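"""Agent population synthesis.

Agents are simulated residents aged 16-75 at 1/10 scale of the zone
populations.  Each agent carries a socio-economic grade, a home location,
dog ownership, a homophily or heterophily tolerance threshold, an initial
daily visit probability and an ordered list of accessible green spaces.

The population is stored struct-of-arrays (:class:`AgentPopulation`) so the
daily engine can operate on whole-population numpy vectors; a per-agent
DataFrame view is available for inspection and CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .city import AGE_MAX, AGE_MIN, GRADES, CityLayout, N_AGES

#: grade indices of the higher-SES pair (homophilic by assumption)
HIGH_GRADES = (0, 1)  # AB, C1
LOW_GRADES = (2, 3)   # C2, DE


class PopulationError(ValueError):
    """Invalid population inputs."""


@dataclass
class DemogConfig:
    """Demographic parameters of the synthetic population.

    ``p0_mean = 0.07`` corresponds to one visit roughly every 14 days, the
    population-average rate; the draw is truncated to ``p0_bounds``.  The
    initial probability declines linearly with age to ``age_decline_at_max``
    at 75, is halved beyond ``far_threshold_m`` from the nearest green space
    (~20-minute walk), and dog owners are floored at ``dog_floor``.
    """

    scale: float = 0.1
    dog_rate_by_ses: dict[str, float] = field(
        default_factory=lambda: {g: 0.24 for g in GRADES}
    )
    age_decline_at_max: float = 0.5
    p0_mean: float = 0.07
    p0_sd: float = 0.025
    p0_bounds: tuple[float, float] = (0.001, 0.5)
    far_threshold_m: float = 1600.0
    dog_floor: float = 0.33
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.scale <= 1):
            raise PopulationError("scale must be in (0, 1]")
        for g, r in self.dog_rate_by_ses.items():
            if not (0 <= r <= 1):
                raise PopulationError(f"dog rate for {g} outside [0, 1]")


def age_factor(age: int, demog: DemogConfig) -> float:
    """Multiplier on the initial visit probability, declining linearly with
    age from 1.0 at 16 to ``age_decline_at_max`` at 75."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise PopulationError(f"age must be in [{AGE_MIN}, {AGE_MAX}], got {age}")
    frac = (age - AGE_MIN) / (AGE_MAX - AGE_MIN)
    return 1.0 - (1.0 - demog.age_decline_at_max) * frac


def draw_initial_probability(
    age: int,
    dist_to_nearest_ugs_m: float,
    dog_owner: bool,
    demog: DemogConfig,
    rng,
) -> float:
    """Initial daily probability p0 of visiting a green space.

    A Normal(0.07, 0.025) draw truncated to ``p0_bounds``, scaled by the age
    factor, halved when the nearest green space is beyond walking distance,
    then floored at ``dog_floor`` for dog owners.
    """
    lo, hi = demog.p0_bounds
    p = float(np.clip(rng.normal(demog.p0_mean, demog.p0_sd), lo, hi))
    p *= age_factor(age, demog)
    if dist_to_nearest_ugs_m > demog.far_threshold_m:
        p *= 0.5
    if dog_owner:
        p = max(p, demog.dog_floor)
    return p


@dataclass
class AgentPopulation:
    """Struct-of-arrays container for all agents of one city."""

    ses: np.ndarray            # int codes into GRADES
    age: np.ndarray            # int, 16..75
    home: np.ndarray           # (n, 2) planar metres
    zone_index: np.ndarray     # int index into layout.zones
    zone_id: np.ndarray        # object array of zone ids
    dog_owner: np.ndarray      # bool
    heterophilic: np.ndarray   # bool (only C2/DE can be True)
    t_threshold: np.ndarray    # float, NaN where heterophilic
    ht_threshold: np.ndarray   # float, NaN where homophilic
    p0: np.ndarray             # initial daily visit probability
    park_lists: np.ndarray     # (n, Lmax) int park indices, -1 padding
    park_list_len: np.ndarray  # int
    dog_floor: float = 0.33

    @property
    def n(self) -> int:
        return len(self.ses)

    @property
    def is_high(self) -> np.ndarray:
        return self.ses <= 1

    def threshold(self) -> np.ndarray:
        """The active threshold per agent (t for homophilic, ht otherwise)."""
        return np.where(self.heterophilic, self.ht_threshold, self.t_threshold)

    def park_list_ids(self, i: int, park_ids: list[str]) -> list[str]:
        row = self.park_lists[i, : self.park_list_len[i]]
        return [park_ids[j] for j in row]

    def to_dataframe(self, visits: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n),
                "zone": self.zone_id,
                "ses": [GRADES[s] for s in self.ses],
                "age": self.age,
                "dg": self.dog_owner.astype(int),
                "HA": self.heterophilic.astype(int),
                "t": self.t_threshold,
                "ht": self.ht_threshold,
                "p0": self.p0,
            }
        )
        if visits is not None:
            df["v"] = visits
        return df


def accessible_spaces(home: tuple[float, float], layout: CityLayout) -> list[str]:
    """Ordered ids of green spaces whose catchment covers ``home``.

    Parks are sorted by ascending distance, ties broken by ascending park id.
    If no catchment reaches the home, the single nearest park is returned so
    the list is never empty.
    """
    parks = sorted(layout.green_spaces, key=lambda p: p.id)
    d = np.array([np.hypot(home[0] - p.centroid[0], home[1] - p.centroid[1]) for p in parks])
    within = np.flatnonzero(d <= np.array([p.catchment_radius_m for p in parks]))
    if len(within) == 0:
        within = np.array([int(np.argmin(d))])
    order = within[np.argsort(d[within], kind="stable")]
    return [parks[i].id for i in order]


def assign_preferences(
    pop: AgentPopulation, t_mu: float, ht_mu: float, sigma: float, h: float, rng
) -> AgentPopulation:
    """Assign tolerance thresholds and heterophily flags in place.

    AB/C1 agents are homophilic with threshold t ~ N(t_mu, sigma) truncated
    to [0, 1].  Each C2/DE agent is heterophilic with probability h and then
    holds ht ~ N(ht_mu, sigma); otherwise it is homophilic with its own t.
    Exactly one of t/ht is active per agent.
    """
    if not (0 <= t_mu <= 1 and 0 <= ht_mu <= 1 and 0 <= h <= 1):
        raise PopulationError("t_mu, ht_mu and h must be in [0, 1]")
    n = pop.n
    low = ~pop.is_high
    pop.heterophilic = low & (rng.random(n) < h)
    t = np.clip(rng.normal(t_mu, sigma, n), 0.0, 1.0)
    ht = np.clip(rng.normal(ht_mu, sigma, n), 0.0, 1.0)
    pop.t_threshold = np.where(pop.heterophilic, np.nan, t)
    pop.ht_threshold = np.where(pop.heterophilic, ht, np.nan)
    return pop


def _sample_points_in_polygon(geom, n: int, rng) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    minx, miny, maxx, maxy = geom.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        keep = [c for c in cand if geom.contains(Point(c[0], c[1]))]
        take = min(len(keep), n - got)
        if take:
            pts[got : got + take] = np.asarray(keep)[:take]
            got += take
    return pts


def generate_population(layout: CityLayout, demog: DemogConfig, params) -> AgentPopulation:
    """Synthesize the agent population of a city, deterministic given seeds.

    Each zone contributes ``round(resident_count * scale)`` agents (a
    5000-resident zone at the default 1/10 scale yields 500 agents).  SES
    and age are drawn from the zone's distributions, homes uniformly within
    the zone polygon.  Preference thresholds come from ``params``
    (t_mu/ht_mu/threshold_sigma/h); initial probabilities and park lists are
    derived per agent.
    """
    layout.validate()
    demog.validate()
    rng = np.random.default_rng(demog.seed)

    parks = sorted(layout.green_spaces, key=lambda p: p.id)
    park_xy = np.array([p.centroid for p in parks])
    park_catch = np.array([p.catchment_radius_m for p in parks])

    ses_l, age_l, home_l, zidx_l, zid_l = [], [], [], [], []
    for zi, zone in enumerate(layout.zones):
        n_z = int(round(zone.resident_count * demog.scale))
        if n_z == 0:
            continue
        ses_l.append(rng.choice(4, size=n_z, p=np.asarray(zone.ses_shares, dtype=float)))
        if zone.age_distribution is not None:
            ages = rng.choice(N_AGES, size=n_z, p=zone.age_distribution) + AGE_MIN
        else:
            ages = rng.integers(AGE_MIN, AGE_MAX + 1, size=n_z)
        age_l.append(ages)
        home_l.append(_sample_points_in_polygon(zone.geometry, n_z, rng))
        zidx_l.append(np.full(n_z, zi))
        zid_l.append(np.full(n_z, zone.id, dtype=object))
    if not ses_l:
        raise PopulationError("layout yields an empty population")

    ses = np.concatenate(ses_l)
    age = np.concatenate(age_l)
    home = np.vstack(home_l)
    n = len(ses)

    dog_rates = np.array([demog.dog_rate_by_ses[g] for g in GRADES])
    dog = rng.random(n) < dog_rates[ses]

    # ordered accessible-park lists (vectorised over agents)
    d = np.hypot(home[:, 0, None] - park_xy[None, :, 0], home[:, 1, None] - park_xy[None, :, 1])
    within = d <= park_catch[None, :]
    nearest = np.argmin(d, axis=1)
    none_within = ~within.any(axis=1)
    within[none_within, nearest[none_within]] = True
    order = np.argsort(np.where(within, d, np.inf), axis=1, kind="stable")
    lens = within.sum(axis=1)
    lmax = int(lens.max())
    park_lists = np.where(np.arange(lmax)[None, :] < lens[:, None], order[:, :lmax], -1)

    pop = AgentPopulation(
        ses=ses,
        age=age,
        home=home,
        zone_index=np.concatenate(zidx_l),
        zone_id=np.concatenate(zid_l),
        dog_owner=dog,
        heterophilic=np.zeros(n, dtype=bool),
        t_threshold=np.full(n, np.nan),
        ht_threshold=np.full(n, np.nan),
        p0=np.zeros(n),
        park_lists=park_lists.astype(np.int64),
        park_list_len=lens.astype(np.int64),
        dog_floor=demog.dog_floor,
    )
    assign_preferences(pop, params.t_mu, params.ht_mu, params.threshold_sigma, params.h, rng)

    lo, hi = demog.p0_bounds
    raw = np.clip(rng.normal(demog.p0_mean, demog.p0_sd, n), lo, hi)
    afac = 1.0 - (1.0 - demog.age_decline_at_max) * (age - AGE_MIN) / (AGE_MAX - AGE_MIN)
    dist_near = d[np.arange(n), nearest]
    p0 = raw * afac * np.where(dist_near > demog.far_threshold_m, 0.5, 1.0)
    pop.p0 = np.where(dog, np.maximum(p0, demog.dog_floor), p0)
    return pop
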