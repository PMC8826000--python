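"""Daily visiting simulation.

Each simulated day every agent decides to visit with probability
``p * w * s`` (p: current propensity, w: zone walkability factor, s:
city-wide weather factor), walks the first non-avoided park on its ordered
accessibility list, and — after all visits of the day are resolved —
evaluates a sample of co-visitors against its tolerance threshold.
Satisfaction multiplies the propensity by (1+a) and keeps the park at the
head of the list; dissatisfaction multiplies by (1-a) and demotes the park
to the tail.  An empty park leaves the agent neutral.  Periodically, agents
whose visiting rate deviates strongly from the median of a local reference
group (same zone and grade, similar age) are nudged toward the group norm.

The default run is 1460 days (four years), the theoretical maximum number
of visits per agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .city import GRADES, CityLayout
from .population import AgentPopulation

SCENARIOS = ("social_only", "walkability", "quality")

P_FLOOR = 1e-4  # hard floor on the propensity; keeps dissatisfied agents recoverable

SATISFIED, DISSATISFIED, NEUTRAL = "satisfied", "dissatisfied", "neutral"


class EngineError(ValueError):
    """Invalid simulation inputs or state."""


@dataclass
class SimParams:
    """Model-wide constants of one simulation run.

    ``a`` is the multiplicative probability adjustment applied on every
    evaluated visit.  ``scenario`` switches the environmental modifiers:
    ``social_only`` forces walkability w = 1 everywhere and ignores park
    quality; ``walkability`` applies the zone's w; ``quality`` additionally
    lets agents skip low-quality parks with a per-grade probability
    (higher-SES agents avoid more).  Threshold means (t_mu, ht_mu), their
    spread and the heterophilic fraction h parameterise the preference
    assignment.
    """

    days: int = 1460
    a: float = 0.25
    scenario: str = "social_only"
    sunshine_factor: float | None = None  # None -> use the layout's s
    t_mu: float = 0.5
    ht_mu: float = 0.5
    threshold_sigma: float = 0.05
    h: float = 0.5
    social_influence_period_days: int = 90
    social_influence_nudge: float = 0.1
    covisitor_sample_max: int = 30
    avoid_low_quality_prob_by_ses: dict[str, float] = field(
        default_factory=lambda: {"AB": 0.5, "C1": 0.5, "C2": 0.2, "DE": 0.2}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.days < 0:
            raise EngineError("days must be >= 0")
        if not (0 <= self.a < 1):
            raise EngineError("a must be in [0, 1)")
        if self.scenario not in SCENARIOS:
            raise EngineError(f"unknown scenario {self.scenario!r}")
        if self.sunshine_factor is not None and not (0 < self.sunshine_factor <= 1):
            raise EngineError("sunshine_factor must be in (0, 1]")


@dataclass
class VisitLog:
    """Output of a run: per-agent totals and per-day park rosters."""

    visits: np.ndarray        # (n_agents,) cumulative visit counts
    roster: np.ndarray        # (days, n_parks, 4) visitor tallies by grade
    daily_totals: np.ndarray  # (days,)
    park_ids: list[str]

    @property
    def total_visits(self) -> int:
        return int(self.visits.sum())

    def agent_frame(self, pop: AgentPopulation) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(pop.n),
                "ses": [GRADES[s] for s in pop.ses],
                "zone": pop.zone_id,
                "visits": self.visits,
            }
        )

    def roster_frame(self) -> pd.DataFrame:
        days, n_parks, _ = self.roster.shape
        rows = {
            "day": np.repeat(np.arange(days), n_parks),
            "park": self.park_ids * days,
        }
        flat = self.roster.reshape(days * n_parks, 4)
        for k, g in enumerate(GRADES):
            rows[f"n_{g}"] = flat[:, k]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-agent rules (scalar form; the vectorised kernel applies the same maths)
# ---------------------------------------------------------------------------

def daily_visit_probability(p_visit: float, zone_walkability: float, params: SimParams,
                            sunshine_factor: float | None = None) -> float:
    """Effective probability of visiting today: min(1, p * w * s)."""
    w = 1.0 if params.scenario == "social_only" else zone_walkability
    s = sunshine_factor if sunshine_factor is not None else (params.sunshine_factor or 1.0)
    return min(1.0, p_visit * w * s)


def evaluate_satisfaction(
    is_high: bool,
    heterophilic: bool,
    threshold: float,
    covisitor_tally: np.ndarray,
    rng=None,
    sample_max: int = 30,
) -> str:
    """Evaluate a park's co-visitor composition against a tolerance threshold.

    ``covisitor_tally`` counts co-visitors by grade (AB, C1, C2, DE), the
    focal agent excluded.  A homophilic agent is dissatisfied iff the
    proportion of the *other* pair of grades strictly exceeds t; a
    heterophilic agent is satisfied iff the proportion of AB+C1 reaches ht.
    With no co-visitors the outcome is neutral.  When more than
    ``sample_max`` co-visitors are present, a uniform subset is evaluated.
    """
    tally = np.asarray(covisitor_tally)
    total = int(tally.sum())
    if total == 0:
        return NEUTRAL
    n_high = int(tally[0] + tally[1])
    if total > sample_max and rng is not None:
        n_high = int(rng.hypergeometric(n_high, total - n_high, sample_max))
        total = sample_max
    prop_high = n_high / total
    if heterophilic:
        return SATISFIED if prop_high >= threshold else DISSATISFIED
    prop_other = prop_high if not is_high else 1.0 - prop_high
    return DISSATISFIED if prop_other > threshold else SATISFIED


def update_probability(p: float, outcome: str, a: float, dog_owner: bool,
                       floor: float = 0.33) -> float:
    """Multiplicative propensity update: +a when satisfied, -a otherwise."""
    if outcome == SATISFIED:
        p = p * (1.0 + a)
    elif outcome == DISSATISFIED:
        p = p * (1.0 - a)
    p = min(p, 1.0)
    if dog_owner:
        p = max(p, floor)
    return float(np.clip(p, P_FLOOR, 1.0))


def reorder_park_list(park_list: list, park_id, outcome: str) -> list:
    """Demote an unsatisfying park to the tail; promote a satisfying one to
    the head (so the agent returns to the same space); neutral leaves the
    list unchanged."""
    if park_id not in park_list:
        raise EngineError(f"park {park_id!r} not in agent's list")
    rest = [p for p in park_list if p != park_id]
    if outcome == DISSATISFIED:
        return rest + [park_id]
    if outcome == SATISFIED:
        return [park_id] + rest
    return list(park_list)


def social_influence_update(p: float, own_rate: float, reference_median_rate: float,
                            nudge: float) -> float:
    """Nudge the propensity toward a local norm when far from it.

    If the agent's own visit rate r over the last period is below half or
    above double the reference-group median m, p moves toward m by the
    nudge fraction: p + nudge * (m - p).  Otherwise p is unchanged.
    """
    m = reference_median_rate
    if own_rate < m / 2.0 or own_rate > 2.0 * m:
        return p + nudge * (m - p)
    return p


# ---------------------------------------------------------------------------
# Vectorised simulation
# ---------------------------------------------------------------------------

class Simulation:
    """Mutable simulation state over one city; advanced one day at a time."""

    def __init__(self, layout: CityLayout, pop: AgentPopulation, params: SimParams):
        params.validate()
        layout.validate()
        if (pop.park_list_len < 1).any():
            raise EngineError("every agent needs a non-empty park list")
        self.layout = layout
        self.pop = pop
        self.params = params
        self.rng = np.random.default_rng(params.seed)

        parks = sorted(layout.green_spaces, key=lambda g: g.id)
        self.park_ids = [g.id for g in parks]
        self.n_parks = len(parks)
        self.park_low = np.array([g.quality == "low" for g in parks])

        n = pop.n
        s = params.sunshine_factor if params.sunshine_factor is not None else layout.sunshine_factor
        if params.scenario == "social_only":
            w = np.ones(n)
        else:
            zone_w = np.array([z.walkability_factor for z in layout.zones])
            w = zone_w[pop.zone_index]
        self.p_eff_factor = w * s  # per-agent w*s multiplier
        self.avoid_prob = np.array(
            [params.avoid_low_quality_prob_by_ses[GRADES[g]] for g in range(4)]
        )[pop.ses]
        self.is_high = pop.is_high
        self.threshold = pop.threshold()
        self.hetero = pop.heterophilic

        self.p = pop.p0.copy()
        self.park_lists = pop.park_lists.copy()
        self.list_len = pop.park_list_len.copy()
        self.visits = np.zeros(n, dtype=np.int64)
        self.day = 0
        self._period_start_visits = self.visits.copy()
        self._roster_rows: list[np.ndarray] = []
        self._daily_totals: list[int] = []

    # -- daily step ---------------------------------------------------------

    def step_day(self) -> None:
        """One simulated day: visit draws, park selection, end-of-day
        evaluation, propensity updates and list reordering (two-phase, so
        evaluation order cannot bias rosters)."""
        rng = self.rng
        pop = self.pop
        params = self.params
        n = pop.n

        p_eff = np.minimum(self.p * self.p_eff_factor, 1.0)
        visiting = rng.random(n) < p_eff
        vis = np.flatnonzero(visiting)

        sel, sel_col = self._select_parks(vis)
        ok = sel >= 0
        vis, sel, sel_col = vis[ok], sel[ok], sel_col[ok]

        self.visits[vis] += 1
        tally = np.zeros((self.n_parks, 4), dtype=np.int64)
        if len(vis):
            np.add.at(tally, (sel, pop.ses[vis]), 1)
        self._roster_rows.append(tally)
        self._daily_totals.append(len(vis))

        if len(vis):
            outcome = self._evaluate(vis, sel, tally)
            self._apply_updates(vis, sel, sel_col, outcome)

        self.day += 1
        if (
            params.social_influence_period_days > 0
            and params.social_influence_nudge > 0
            and self.day % params.social_influence_period_days == 0
        ):
            self._apply_social_influence()
            self._period_start_visits = self.visits.copy()

    def _select_parks(self, vis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """First non-avoided park per visitor; (-1, -1) if all avoided."""
        if self.params.scenario != "quality" or not self.park_low.any():
            return self.park_lists[vis, 0], np.zeros(len(vis), dtype=np.int64)
        sel = np.full(len(vis), -1, dtype=np.int64)
        col = np.full(len(vis), -1, dtype=np.int64)
        undecided = np.ones(len(vis), dtype=bool)
        lmax = self.park_lists.shape[1]
        for c in range(lmax):
            live = undecided & (self.list_len[vis] > c)
            if not live.any():
                break
            cand = self.park_lists[vis[live], c]
            skip = self.park_low[cand] & (self.rng.random(live.sum()) < self.avoid_prob[vis[live]])
            chosen = np.flatnonzero(live)[~skip]
            sel[chosen] = self.park_lists[vis[chosen], c]
            col[chosen] = c
            undecided[chosen] = False
        return sel, col

    def _evaluate(self, vis: np.ndarray, sel: np.ndarray, tally: np.ndarray) -> np.ndarray:
        """Outcome codes per visitor: +1 satisfied, -1 dissatisfied, 0 neutral."""
        pop = self.pop
        park_total = tally.sum(axis=1)
        park_high = tally[:, 0] + tally[:, 1]
        n_tot = park_total[sel] - 1
        n_high = park_high[sel] - self.is_high[vis].astype(np.int64)

        out = np.zeros(len(vis), dtype=np.int8)
        occupied = n_tot > 0
        if not occupied.any():
            return out
        idx = np.flatnonzero(occupied)
        tot = n_tot[idx]
        hi = n_high[idx]
        m = self.params.covisitor_sample_max
        big = tot > m
        if big.any():
            hi = hi.copy()
            hi[big] = self.rng.hypergeometric(hi[big], tot[big] - hi[big], m)
            tot = np.where(big, m, tot)
        prop_high = hi / tot

        thr = self.threshold[vis[idx]]
        het = self.hetero[vis[idx]]
        high = self.is_high[vis[idx]]
        prop_other = np.where(high, 1.0 - prop_high, prop_high)
        dissat = np.where(het, prop_high < thr, prop_other > thr)
        out[idx] = np.where(dissat, -1, 1)
        return out

    def _apply_updates(self, vis, sel, sel_col, outcome) -> None:
        a = self.params.a
        factor = np.where(outcome > 0, 1.0 + a, np.where(outcome < 0, 1.0 - a, 1.0))
        self.p[vis] = np.minimum(self.p[vis] * factor, 1.0)
        dogs = self.pop.dog_owner[vis]
        self.p[vis[dogs]] = np.maximum(self.p[vis[dogs]], self.pop.dog_floor)
        self.p[vis] = np.clip(self.p[vis], P_FLOOR, 1.0)

        # list reordering, grouped by (column, list length) for vector rolls
        to_tail = outcome < 0
        to_head = (outcome > 0) & (sel_col > 0)
        for rows_mask, to_end in ((to_tail, True), (to_head, False)):
            rows = vis[rows_mask]
            cols = sel_col[rows_mask]
            if not len(rows):
                continue
            lens = self.list_len[rows]
            keys = cols * 10000 + lens
            for key in np.unique(keys):
                grp = keys == key
                c, length = int(key // 10000), int(key % 10000)
                if length <= 1:
                    continue
                r = rows[grp]
                if to_end:
                    block = self.park_lists[r, c:length]
                    self.park_lists[r, c:length] = np.roll(block, -1, axis=1)
                else:
                    block = self.park_lists[r, : c + 1]
                    self.park_lists[r, : c + 1] = np.roll(block, 1, axis=1)

    def _apply_social_influence(self) -> None:
        """Nudge outliers toward the median visit rate of their reference
        group (same zone, same grade, age within ±10 years, >= 5 members)."""
        params = self.params
        period = params.social_influence_period_days
        rate = (self.visits - self._period_start_visits) / period
        pop = self.pop
        group_key = pop.zone_index * 4 + pop.ses
        order = np.argsort(group_key, kind="stable")
        bounds = np.searchsorted(group_key[order], np.arange(group_key.max() + 2))
        for gi in range(len(bounds) - 1):
            members = order[bounds[gi] : bounds[gi + 1]]
            if len(members) < 5:
                continue
            ages = pop.age[members]
            rates = rate[members]
            for k, i in enumerate(members):
                mask = np.abs(ages - ages[k]) <= 10
                if mask.sum() < 5:
                    continue
                m = float(np.median(rates[mask]))
                r = rates[k]
                if r < m / 2.0 or r > 2.0 * m:
                    self.p[i] = self.p[i] + params.social_influence_nudge * (m - self.p[i])
        self.p = np.clip(self.p, P_FLOOR, 1.0)
        dogs = pop.dog_owner
        self.p[dogs] = np.maximum(self.p[dogs], pop.dog_floor)

    # -- full run -----------------------------------------------------------

    def run(self) -> VisitLog:
        for _ in range(self.params.days):
            self.step_day()
        roster = (
            np.stack(self._roster_rows)
            if self._roster_rows
            else np.zeros((0, self.n_parks, 4), dtype=np.int64)
        )
        return VisitLog(
            visits=self.visits.copy(),
            roster=roster,
            daily_totals=np.asarray(self._daily_totals, dtype=np.int64),
            park_ids=self.park_ids,
        )


def run_simulation(layout: CityLayout, pop: AgentPopulation, params: SimParams) -> VisitLog:
    """Run the full daily simulation and return the visit log."""
    return Simulation(layout, pop, params).run()
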