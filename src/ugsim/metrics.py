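"""Outcome metrics, emergence conditions, parameter sweep and quasi-null.

The three emergence conditions compare a reference city against every other
city: (1) in every city the median visit count of grade AB exceeds that of
DE; (2) the reference city has the highest total visit count V; (3) the
reference city's AB/DE inequality ratio is strictly the smallest.  The
sweep runs the simulation over the Cartesian grid of threshold means
(t_mu, ht_mu) and the heterophilic fraction h, with seeded replicates, and
flags the cells where all three conditions hold on replicate-averaged
medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .city import GRADES, CityGenConfig, CityLayout, generate_city
from .engine import SCENARIOS, SimParams, VisitLog, run_simulation
from .population import AgentPopulation, DemogConfig, generate_population


class MetricsError(ValueError):
    """Invalid metric inputs."""


@dataclass
class CityResult:
    """Summary of one simulation run of one city."""

    city: str
    median_visits_by_ses: dict[str, float]
    total_visits: int
    inequality_ab_de: float


def median_visits_by_ses(log: VisitLog, pop: AgentPopulation) -> dict[str, float]:
    """Per-grade median of per-agent visit totals (zero-visit agents
    included).  Grades with no agents are omitted."""
    out = {}
    for gi, g in enumerate(GRADES):
        mask = pop.ses == gi
        if mask.any():
            out[g] = float(np.median(log.visits[mask]))
    return out


def inequality_ratio(medians: dict[str, float]) -> float:
    """AB/DE median-visit ratio; +inf when the DE median is zero."""
    if "AB" not in medians or "DE" not in medians:
        raise MetricsError("inequality ratio needs both AB and DE medians")
    ab, de = medians["AB"], medians["DE"]
    if de == 0:
        return math.inf if ab > 0 else math.nan
    return ab / de


def city_result(city: str, log: VisitLog, pop: AgentPopulation) -> CityResult:
    med = median_visits_by_ses(log, pop)
    return CityResult(
        city=city,
        median_visits_by_ses=med,
        total_visits=log.total_visits,
        inequality_ab_de=inequality_ratio(med),
    )


def check_emergence(results: dict[str, CityResult], reference_city: str
                    ) -> tuple[bool, dict[str, bool]]:
    """Evaluate the three emergence conditions.

    Returns the conjunction plus per-condition flags
    (``gradient``, ``reference_total``, ``reference_inequality``).  An
    infinite inequality in a comparison city counts in the reference's
    favour; an infinite (or undefined) reference inequality fails.
    """
    if reference_city not in results:
        raise MetricsError(f"missing reference city {reference_city!r}")
    others = [c for c in results if c != reference_city]
    if not others:
        raise MetricsError("need at least one comparison city")
    ref = results[reference_city]

    gradient = all(
        r.median_visits_by_ses.get("AB", math.nan) > r.median_visits_by_ses.get("DE", math.nan)
        for r in results.values()
    )
    ref_total = all(ref.total_visits > results[c].total_visits for c in others)
    ref_ineq = (
        math.isfinite(ref.inequality_ab_de)
        and all(ref.inequality_ab_de < results[c].inequality_ab_de for c in others)
    )
    flags = {
        "gradient": bool(gradient),
        "reference_total": bool(ref_total),
        "reference_inequality": bool(ref_ineq),
    }
    return all(flags.values()), flags


def dissimilarity_index(pop: AgentPopulation, n_zones: int,
                        group_a=(0, 1), group_b=(2, 3)) -> float:
    """Duncan dissimilarity index D between two grade groups over zones.

    D = 0.5 * sum_z |a_z/A - b_z/B|, in [0, 1]; 0 means identical spatial
    distributions, 1 perfect segregation.
    """
    in_a = np.isin(pop.ses, group_a)
    in_b = np.isin(pop.ses, group_b)
    A, B = in_a.sum(), in_b.sum()
    if A == 0 or B == 0:
        raise MetricsError("both groups must be non-empty")
    a_z = np.bincount(pop.zone_index[in_a], minlength=n_zones)
    b_z = np.bincount(pop.zone_index[in_b], minlength=n_zones)
    return float(0.5 * np.abs(a_z / A - b_z / B).sum())


def randomize_residences(pop: AgentPopulation, layout: CityLayout, rng) -> AgentPopulation:
    """Quasi-null transform: permute homes (and zones) uniformly across all
    agents, breaking the SES-location link while conserving every agent's
    attributes and the per-zone head counts.  Park lists are recomputed."""
    perm = rng.permutation(pop.n)
    new = AgentPopulation(
        ses=pop.ses.copy(),
        age=pop.age.copy(),
        home=pop.home[perm].copy(),
        zone_index=pop.zone_index[perm].copy(),
        zone_id=pop.zone_id[perm].copy(),
        dog_owner=pop.dog_owner.copy(),
        heterophilic=pop.heterophilic.copy(),
        t_threshold=pop.t_threshold.copy(),
        ht_threshold=pop.ht_threshold.copy(),
        p0=pop.p0.copy(),
        park_lists=pop.park_lists[perm].copy(),
        park_list_len=pop.park_list_len[perm].copy(),
        dog_floor=pop.dog_floor,
    )
    return new


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepGrid:
    """Grid of preference parameters; defaults give the 5x5x4 = 100-cell
    design (t_mu, ht_mu in 0.3..0.7 at 0.1 steps; h in {0.33, 0.5, 0.66, 1})."""

    t_mus: tuple = (0.3, 0.4, 0.5, 0.6, 0.7)
    ht_mus: tuple = (0.3, 0.4, 0.5, 0.6, 0.7)
    hs: tuple = (0.33, 0.5, 0.66, 1.0)

    @property
    def n_cells(self) -> int:
        return len(self.t_mus) * len(self.ht_mus) * len(self.hs)

    def cells(self):
        for t in self.t_mus:
            for ht in self.ht_mus:
                for h in self.hs:
                    yield t, ht, h


@dataclass
class SweepCell:
    t_mu: float
    ht_mu: float
    h: float
    scenario: str
    replicate_results: list[dict[str, CityResult]]
    averaged: dict[str, CityResult]
    emergence: bool
    flags: dict[str, bool]


def _cell_seed(base_seed: int, t_mu: float, ht_mu: float, h: float,
               scenario: str, replicate: int, city_index: int) -> int:
    """Order-independent deterministic seed for one (cell, replicate, city)."""
    ss = np.random.SeedSequence(
        [
            int(base_seed),
            int(round(t_mu * 1000)),
            int(round(ht_mu * 1000)),
            int(round(h * 1000)),
            SCENARIOS.index(scenario),
            int(replicate),
            int(city_index),
        ]
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_city(
    layout: CityLayout,
    demog: DemogConfig,
    params: SimParams,
    seed: int,
    randomized_residences: bool = False,
) -> tuple[CityResult, AgentPopulation, VisitLog]:
    """Generate a population for ``layout`` and simulate one run."""
    demog = replace(demog, seed=seed)
    params = replace(params, seed=seed + 1)
    pop = generate_population(layout, demog, params)
    if randomized_residences:
        pop = randomize_residences(pop, layout, np.random.default_rng(seed + 2))
    log = run_simulation(layout, pop, params)
    return city_result(layout.name, log, pop), pop, log


def _average_results(reps: list[dict[str, CityResult]]) -> dict[str, CityResult]:
    """Replicate-average the per-grade medians and totals city by city,
    then recompute the inequality ratio from the averaged medians."""
    out = {}
    for city in reps[0]:
        grades = set().union(*(r[city].median_visits_by_ses.keys() for r in reps))
        med = {
            g: float(np.mean([r[city].median_visits_by_ses.get(g, np.nan) for r in reps]))
            for g in grades
        }
        out[city] = CityResult(
            city=city,
            median_visits_by_ses=med,
            total_visits=int(np.mean([r[city].total_visits for r in reps])),
            inequality_ab_de=inequality_ratio(med) if {"AB", "DE"} <= grades else math.nan,
        )
    return out


def sweep(
    layouts: dict[str, CityLayout],
    grid: SweepGrid,
    replicates: int,
    base_seed: int,
    reference_city: str,
    demog: DemogConfig | None = None,
    base_params: SimParams | None = None,
    scenarios: tuple[str, ...] = ("social_only",),
    randomized_residences: bool = False,
) -> list[SweepCell]:
    """Run the full parameter sweep.

    Every (t_mu, ht_mu, h, scenario) cell is simulated ``replicates`` times
    per city with seeds derived from (base_seed, cell, replicate, city), so
    cells are independent and the result does not depend on execution order.
    Emergence is evaluated on replicate-averaged medians.
    """
    demog = demog or DemogConfig()
    base_params = base_params or SimParams()
    city_names = sorted(layouts)
    cells = []
    for scenario in scenarios:
        for t_mu, ht_mu, h in grid.cells():
            reps = []
            for rep in range(replicates):
                results = {}
                for ci, city in enumerate(city_names):
                    seed = _cell_seed(base_seed, t_mu, ht_mu, h, scenario, rep, ci)
                    params = replace(
                        base_params, t_mu=t_mu, ht_mu=ht_mu, h=h, scenario=scenario
                    )
                    res, _, _ = run_city(
                        layouts[city], demog, params, seed,
                        randomized_residences=randomized_residences,
                    )
                    results[city] = res
                reps.append(results)
            avg = _average_results(reps)
            emerged, flags = check_emergence(avg, reference_city)
            cells.append(
                SweepCell(
                    t_mu=t_mu, ht_mu=ht_mu, h=h, scenario=scenario,
                    replicate_results=reps, averaged=avg,
                    emergence=emerged, flags=flags,
                )
            )
    return cells


def count_emergent_cells(cells: list[SweepCell]) -> int:
    return sum(c.emergence for c in cells)


def sweep_frame(cells: list[SweepCell]) -> pd.DataFrame:
    """Long-format sweep table: one row per (cell, replicate, city)."""
    rows = []
    for cell in cells:
        for rep_i, rep in enumerate(cell.replicate_results):
            for city, res in rep.items():
                row = {
                    "city": city,
                    "scenario": cell.scenario,
                    "t_mu": cell.t_mu,
                    "ht_mu": cell.ht_mu,
                    "h": cell.h,
                    "replicate": rep_i,
                    "V": res.total_visits,
                    "inequality": res.inequality_ab_de,
                    "emergence": cell.emergence,
                }
                for g in GRADES:
                    row[f"med_{g}"] = res.median_visits_by_ses.get(g, np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def emergence_map_frame(cells: list[SweepCell]) -> pd.DataFrame:
    """One row per (scenario, t_mu, ht_mu, h) with the emergence flag and
    per-condition flags."""
    rows = []
    for cell in cells:
        rows.append(
            {
                "scenario": cell.scenario,
                "t_mu": cell.t_mu,
                "ht_mu": cell.ht_mu,
                "h": cell.h,
                "emergence": cell.emergence,
                **{f"cond_{k}": v for k, v in cell.flags.items()},
            }
        )
    return pd.DataFrame(rows)


def build_suite_layouts(configs: dict[str, CityGenConfig]) -> dict[str, CityLayout]:
    return {name: generate_city(cfg) for name, cfg in configs.items()}
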