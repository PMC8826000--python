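"""Spatial microsimulation baseline.

Builds a zone-allocated individual-level synthetic population by iterative
proportional fitting (IPF): survey respondents (four categorical attributes
plus a visits-per-year behaviour variable) are reweighted zone by zone so
that the weighted marginals match the zone's census-style marginal counts
for age band, gender, ethnicity and SES.  Weights are integerised by
truncate-replicate-sample, zone medians of the behaviour variable are
computed, and the result is compared with ABM zone medians by Pearson
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONSTRAINT_ORDER = ("age_band", "gender", "ethnicity", "ses")


class MsmError(ValueError):
    """Infeasible or malformed microsimulation inputs."""


class IpfWarning(UserWarning):
    """Raised-as-warning diagnostics from the IPF fit."""


def ipf_weights(
    survey: pd.DataFrame,
    zone_marginals: dict[str, dict[str, float]],
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Per-record IPF (raking) weights fitting a survey to zone marginals.

    ``zone_marginals`` maps each constraint variable to ``{level: count}``.
    Starting from unit weights, the weights are scaled constraint by
    constraint (age -> gender -> ethnicity -> ses each sweep) until every
    fitted marginal deviates from its target by less than ``tol``.  A
    positive target for a level absent from the survey is a structural zero
    and raises an error naming the cell; non-convergence warns with the
    achieved error.
    """
    variables = [v for v in CONSTRAINT_ORDER if v in zone_marginals]
    variables += [v for v in zone_marginals if v not in variables]
    if not variables:
        raise MsmError("no constraint variables supplied")

    n = len(survey)
    w = np.ones(n)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for var in variables:
        if var not in survey.columns:
            raise MsmError(f"survey lacks constraint column {var!r}")
        masks[var] = {}
        for level, target in zone_marginals[var].items():
            mask = (survey[var] == level).to_numpy()
            if target > 0 and not mask.any():
                raise MsmError(
                    f"structural zero: target {target} for {var}={level!r} "
                    "but no survey records in that category"
                )
            masks[var][level] = mask

    def max_dev() -> float:
        dev = 0.0
        for var in variables:
            for level, target in zone_marginals[var].items():
                dev = max(dev, abs(w[masks[var][level]].sum() - target))
        return dev

    for _ in range(max_iter):
        for var in variables:
            for level, target in zone_marginals[var].items():
                mask = masks[var][level]
                current = w[mask].sum()
                if current > 0:
                    w[mask] *= target / current
                elif target == 0:
                    w[mask] = 0.0
        if max_dev() < tol:
            break
    else:
        warnings.warn(
            f"IPF did not converge in {max_iter} iterations; "
            f"max marginal deviation {max_dev():.3g}",
            IpfWarning,
        )
    return w


def integerise(weights: np.ndarray, rng) -> np.ndarray:
    """Truncate-replicate-sample integerisation.

    Each weight is floored; the remaining ``round(sum) - sum(floors)``
    replicates are drawn by systematic sampling over the fractional parts
    (random order, random start), so a record's inclusion probability equals
    its fractional part and the expected count equals the weight.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise MsmError("weights must be non-negative")
    base = np.floor(w).astype(int)
    total = int(round(w.sum()))
    extra = total - base.sum()
    counts = base.copy()
    if extra > 0:
        frac = w - base
        if frac.sum() <= 0:
            idx = rng.choice(len(w), size=extra, replace=False)
        else:
            order = rng.permutation(len(w))
            f = frac[order]
            step = f.sum() / extra
            points = rng.uniform(0, step) + step * np.arange(extra)
            picks = np.searchsorted(np.cumsum(f), points, side="right")
            idx = order[np.clip(picks, 0, len(w) - 1)]
        np.add.at(counts, idx, 1)
    return counts


def synthesize_zone(survey: pd.DataFrame, zone_marginals, rng,
                    tol: float = 1e-6, max_iter: int = 200) -> pd.DataFrame:
    """IPF + integerisation for one zone: returns replicated survey rows."""
    w = ipf_weights(survey, zone_marginals, tol=tol, max_iter=max_iter)
    counts = integerise(w, rng)
    return survey.loc[survey.index.repeat(counts)].reset_index(drop=True)


def zone_behaviour_median(synthetic_population: pd.DataFrame,
                          behaviour_col: str = "visits_per_year",
                          zone_col: str = "zone") -> pd.Series:
    """Median behaviour value per zone of the integerised population."""
    return synthetic_population.groupby(zone_col)[behaviour_col].median()


def msm_zone_medians(
    survey: pd.DataFrame,
    marginals_by_zone: dict[str, dict[str, dict[str, float]]],
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    behaviour_col: str = "visits_per_year",
) -> pd.Series:
    """Full MSM pipeline: fit every zone and return per-zone behaviour
    medians."""
    rng = np.random.default_rng(seed)
    frames = []
    for zone, marg in marginals_by_zone.items():
        zp = synthesize_zone(survey, marg, rng, tol=tol, max_iter=max_iter)
        zp = zp.assign(zone=zone)
        frames.append(zp)
    pop = pd.concat(frames, ignore_index=True)
    return zone_behaviour_median(pop, behaviour_col=behaviour_col)


def compare_abm_msm(abm_zone_medians: pd.Series, msm_zone_medians: pd.Series
                    ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between ABM and MSM zone medians.

    Returns (r, paired table over common zones).  With fewer than three
    common zones an error is raised; a zero-variance vector yields NaN with
    a warning.
    """
    abm = pd.Series(abm_zone_medians)
    msm = pd.Series(msm_zone_medians)
    common = abm.index.intersection(msm.index)
    if len(common) < 3:
        raise MsmError(f"need >= 3 common zones, got {len(common)}")
    paired = pd.DataFrame({"abm": abm.loc[common], "msm": msm.loc[common]})
    if paired["abm"].nunique() < 2 or paired["msm"].nunique() < 2:
        warnings.warn("zero variance in one vector; correlation undefined", IpfWarning)
        return float("nan"), paired
    r, _ = stats.pearsonr(paired["abm"], paired["msm"])
    return float(r), paired


# ---------------------------------------------------------------------------
# Synthetic survey / marginals scenario (SPANS-like structure)
# ---------------------------------------------------------------------------

AGE_BANDS = ("16-29", "30-44", "45-59", "60-75")
GENDERS = ("female", "male")
ETHNICITIES = ("white", "minority")
SES_LEVELS = ("AB", "C1", "C2", "DE")

#: mean annual visit counts by SES grade used by the synthetic behaviour
#: model; higher grades visit more, mirroring the survey gradient.
DEFAULT_BEHAVIOUR_MEANS = {"AB": 60.0, "C1": 45.0, "C2": 25.0, "DE": 15.0}


@dataclass
class MsmScenario:
    """A generated ground truth + survey + marginals bundle for testing and
    demonstration (the real census/survey inputs are not required)."""

    ground_truth: pd.DataFrame
    survey: pd.DataFrame
    marginals_by_zone: dict[str, dict[str, dict[str, float]]]

    @property
    def truth_zone_medians(self) -> pd.Series:
        return zone_behaviour_median(self.ground_truth)


def generate_msm_scenario(
    n_zones: int = 50,
    zone_size: int = 500,
    survey_size: int = 1000,
    seed: int = 0,
    behaviour_means: dict[str, float] | None = None,
) -> MsmScenario:
    """Generate a feasible synthetic MSM problem.

    A ground-truth population with zone-varying SES/age/gender/ethnicity
    composition and an SES-driven (gamma-distributed) visits-per-year
    behaviour; the survey is a uniform sample of the whole population and
    marginals are the true zone category counts, so IPF problems are
    feasible by construction.
    """
    rng = np.random.default_rng(seed)
    means = behaviour_means or DEFAULT_BEHAVIOUR_MEANS
    rows = []
    for z in range(n_zones):
        # zone-level SES tilt creates spatial variation in behaviour
        tilt = rng.beta(2, 2)
        p_ses = np.array([tilt * 0.3 + 0.05, tilt * 0.3 + 0.1,
                          (1 - tilt) * 0.25 + 0.1, (1 - tilt) * 0.35 + 0.05])
        p_ses /= p_ses.sum()
        ses = rng.choice(4, size=zone_size, p=p_ses)
        age = rng.choice(4, size=zone_size, p=(0.25, 0.3, 0.25, 0.2))
        gender = rng.choice(2, size=zone_size)
        eth = rng.choice(2, size=zone_size, p=(0.9, 0.1))
        mu = np.array([means[g] for g in SES_LEVELS])[ses]
        visits = rng.gamma(shape=2.0, scale=mu / 2.0)
        rows.append(
            pd.DataFrame(
                {
                    "zone": f"z{z:03d}",
                    "age_band": np.array(AGE_BANDS)[age],
                    "gender": np.array(GENDERS)[gender],
                    "ethnicity": np.array(ETHNICITIES)[eth],
                    "ses": np.array(SES_LEVELS)[ses],
                    "visits_per_year": visits,
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)

    survey = truth.sample(n=survey_size, random_state=int(seed) % (2**32 - 1)).drop(
        columns="zone"
    ).reset_index(drop=True)

    marginals: dict[str, dict[str, dict[str, float]]] = {}
    for zone, zdf in truth.groupby("zone"):
        marginals[zone] = {
            var: zdf[var].value_counts().reindex(levels, fill_value=0).astype(float).to_dict()
            for var, levels in (
                ("age_band", AGE_BANDS),
                ("gender", GENDERS),
                ("ethnicity", ETHNICITIES),
                ("ses", SES_LEVELS),
            )
        }
    return MsmScenario(ground_truth=truth, survey=survey, marginals_by_zone=marginals)
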