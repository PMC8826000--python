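"""Synthetic city generation and layout I/O.

A :class:`CityLayout` is the simulation arena: polygonal residential zones
(postcode-sector analogues) carrying population counts, socio-economic
composition and a walkability quartile, plus point green spaces with a size,
a quality label and a size-derived catchment radius.

Layouts are either generated synthetically from a :class:`CityGenConfig`
(controllable SES composition, residential segregation, walkability-SES
correlation and park placement) or loaded from a planar-coordinate GeoJSON
FeatureCollection.  All coordinates are abstract planar metres; distances are
Euclidean and no CRS handling is performed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon, box, mapping, shape

#: Socio-economic grades, highest (AB) to lowest (DE).
GRADES = ("AB", "C1", "C2", "DE")
GRADE_INDEX = {g: i for i, g in enumerate(GRADES)}

#: Quartile -> walkability multiplier w on the daily visit probability.
WALKABILITY_FACTORS = {1: 0.5, 2: 0.66, 3: 1.0, 4: 2.0}

QUALITY_LEVELS = ("low", "medium", "high")

AGE_MIN, AGE_MAX = 16, 75
N_AGES = AGE_MAX - AGE_MIN + 1


class LayoutError(ValueError):
    """Invalid city layout or generation config."""


def walkability_factor(quartile: int) -> float:
    """Map a walkability quartile (1-4) to its multiplier w.

    Q1 (least walkable) halves the daily visit probability, Q4 doubles it.
    """
    try:
        return WALKABILITY_FACTORS[int(quartile)]
    except (KeyError, TypeError, ValueError) as exc:
        raise LayoutError(f"walkability quartile must be in 1..4, got {quartile!r}") from exc


def catchment_radius(size_ha: float, base_radius_m: float, mean_size_ha: float) -> float:
    """Catchment radius of a park, proportional to the square root of its area.

    A park of mean size has the base radius (default 1600 m, roughly a
    20-minute walk); the radius scales with sqrt(size/mean) so doubling the
    linear dimension doubles the reach, and is floored at half the base
    radius so tiny parks keep a non-degenerate catchment.
    """
    if size_ha <= 0:
        raise LayoutError(f"park size must be positive, got {size_ha}")
    if base_radius_m <= 0 or mean_size_ha <= 0:
        raise LayoutError("base radius and mean size must be positive")
    return max(base_radius_m * math.sqrt(size_ha / mean_size_ha), base_radius_m / 2.0)


@dataclass
class GreenSpace:
    """One urban green space: a point location with size, quality and reach."""

    id: str
    centroid: tuple[float, float]
    size_ha: float
    quality: str = "medium"
    catchment_radius_m: float = 0.0

    def validate(self) -> None:
        if self.size_ha <= 0:
            raise LayoutError(f"green space {self.id}: size must be positive")
        if self.quality not in QUALITY_LEVELS:
            raise LayoutError(f"green space {self.id}: unknown quality {self.quality!r}")
        if self.catchment_radius_m <= 0:
            raise LayoutError(f"green space {self.id}: catchment radius not set")


@dataclass
class Zone:
    """A residential zone (postcode-sector analogue)."""

    id: str
    geometry: Polygon
    resident_count: int
    ses_shares: np.ndarray  # proportions over GRADES, sums to 1
    walkability_quartile: int
    deprived: bool = False
    age_distribution: np.ndarray | None = None  # over ages 16..75; None = uniform

    @property
    def walkability_factor(self) -> float:
        return walkability_factor(self.walkability_quartile)

    def validate(self) -> None:
        shares = np.asarray(self.ses_shares, dtype=float)
        if shares.shape != (4,):
            raise LayoutError(f"zone {self.id}: ses_shares must have 4 entries")
        if abs(shares.sum() - 1.0) > 1e-9 or (shares < 0).any():
            raise LayoutError(
                f"zone {self.id}: ses_shares must be non-negative and sum to 1 "
                f"(sum={shares.sum():.6f})"
            )
        if self.resident_count < 0:
            raise LayoutError(f"zone {self.id}: resident_count must be >= 0")
        walkability_factor(self.walkability_quartile)
        if self.age_distribution is not None:
            ad = np.asarray(self.age_distribution, dtype=float)
            if ad.shape != (N_AGES,) or abs(ad.sum() - 1.0) > 1e-9 or (ad < 0).any():
                raise LayoutError(f"zone {self.id}: invalid age distribution")


@dataclass
class CityLayout:
    """Zones plus green spaces plus the city-wide weather factor s."""

    name: str
    zones: list[Zone]
    green_spaces: list[GreenSpace]
    sunshine_factor: float = 1.0

    @property
    def mean_park_size(self) -> float:
        return float(np.mean([g.size_ha for g in self.green_spaces]))

    @property
    def total_residents(self) -> int:
        return int(sum(z.resident_count for z in self.zones))

    def validate(self) -> None:
        if not self.zones or not self.green_spaces:
            raise LayoutError(f"layout {self.name}: needs at least one zone and one green space")
        if not (0 < self.sunshine_factor <= 1):
            raise LayoutError(f"layout {self.name}: sunshine_factor must be in (0, 1]")
        for z in self.zones:
            z.validate()
        for g in self.green_spaces:
            g.validate()

    def zone_of_point(self, x: float, y: float) -> int:
        """Index of the zone containing (x, y); nearest centroid as fallback."""
        pt = Point(x, y)
        for i, z in enumerate(self.zones):
            if z.geometry.contains(pt) or z.geometry.touches(pt):
                return i
        d = [z.geometry.centroid.distance(pt) for z in self.zones]
        return int(np.argmin(d))


@dataclass
class CityGenConfig:
    """Parameters of the synthetic city generator.

    ``segregation_strength`` g mixes each zone's SES composition between the
    city-wide shares and a one-hot dominant grade:
    ``zone_shares = (1-g)*city_shares + g*one_hot(dominant)``.  Dominant
    grades are allocated to contiguous blocks of zones (serpentine order over
    the grid) in proportion to the city shares, so g moves a *spatial*
    dissimilarity index, not only zone compositions.
    """

    name: str = "synthetic"
    n_zones: int = 16
    residents_per_zone: int = 1250
    ses_shares_city: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    segregation_strength: float = 0.3
    n_parks: int = 12
    park_size_log_mu: float = 1.6   # log-hectares; median ~5 ha
    park_size_log_sigma: float = 0.8
    grid_extent_m: float = 6000.0
    walkability_ses_correlation: float = 0.7
    sunshine_factor: float = 1.0
    deprived_threshold: float = 0.6  # deprived iff share(C2)+share(DE) exceeds this
    p_low_given_small_deprived: float = 0.5
    base_catchment_m: float = 1600.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_zones <= 0 or self.residents_per_zone <= 0 or self.n_parks <= 0:
            raise LayoutError("counts must be positive")
        if not (0 <= self.segregation_strength <= 1):
            raise LayoutError("segregation_strength must be in [0, 1]")
        shares = np.asarray(self.ses_shares_city, dtype=float)
        if abs(shares.sum() - 1.0) > 1e-9 or (shares < 0).any():
            raise LayoutError("ses_shares_city must be non-negative and sum to 1")
        if not (0 <= self.p_low_given_small_deprived <= 1):
            raise LayoutError("p_low_given_small_deprived must be in [0, 1]")
        if not (0 < self.sunshine_factor <= 1):
            raise LayoutError("sunshine_factor must be in (0, 1]")


def _largest_remainder_counts(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of `total` items proportional to `shares`."""
    raw = shares * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _serpentine_order(side_r: int, side_c: int) -> list[tuple[int, int]]:
    order = []
    for r in range(side_r):
        cols = range(side_c) if r % 2 == 0 else range(side_c - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return order


def generate_city(config: CityGenConfig) -> CityLayout:
    """Generate a synthetic city layout, deterministic given ``config.seed``.

    Zones form a square grid over the extent.  Each grade receives a
    contiguous block of zones (its dominant region) sized by its city share;
    zone shares blend city shares with the dominant one-hot vector by the
    segregation strength.  Walkability quartiles are assigned so that zones
    with higher mean SES get higher quartiles with probability increasing in
    ``walkability_ses_correlation``.  Parks are placed uniformly at random,
    with log-normal sizes and quality assigned by :func:`assign_quality`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shares_city = np.asarray(config.ses_shares_city, dtype=float)

    side = math.ceil(math.sqrt(config.n_zones))
    rows = math.ceil(config.n_zones / side)
    cell_w = config.grid_extent_m / side
    cell_h = config.grid_extent_m / rows

    order = _serpentine_order(rows, side)[: config.n_zones]
    dominant_counts = _largest_remainder_counts(shares_city, config.n_zones)
    dominants = np.repeat(np.arange(4), dominant_counts)

    g = config.segregation_strength
    zones: list[Zone] = []
    ses_score = np.empty(config.n_zones)
    for k, (r, c) in enumerate(order):
        one_hot = np.zeros(4)
        one_hot[dominants[k]] = 1.0
        shares = (1 - g) * shares_city + g * one_hot
        geom = box(c * cell_w, r * cell_h, (c + 1) * cell_w, (r + 1) * cell_h)
        # mean SES score, AB highest
        ses_score[k] = float(shares @ np.array([4.0, 3.0, 2.0, 1.0]))
        zones.append(
            Zone(
                id=f"z{k:03d}",
                geometry=geom,
                resident_count=config.residents_per_zone,
                ses_shares=shares,
                walkability_quartile=1,  # assigned below
                deprived=bool(shares[2] + shares[3] > config.deprived_threshold),
            )
        )

    # walkability: blend SES rank with a random rank, split into quartiles
    rho = config.walkability_ses_correlation
    ses_rank = np.argsort(np.argsort(ses_score, kind="stable"), kind="stable").astype(float)
    noise_rank = rng.permutation(config.n_zones).astype(float)
    score = rho * ses_rank + (1 - rho) * noise_rank
    sorted_idx = np.argsort(score, kind="stable")
    for pos, zi in enumerate(sorted_idx):
        zones[zi].walkability_quartile = 1 + min(3, (4 * pos) // config.n_zones)

    xy = rng.uniform(0, config.grid_extent_m, size=(config.n_parks, 2))
    sizes = rng.lognormal(config.park_size_log_mu, config.park_size_log_sigma, config.n_parks)
    mean_size = float(sizes.mean())
    parks = [
        GreenSpace(
            id=f"p{j:03d}",
            centroid=(float(xy[j, 0]), float(xy[j, 1])),
            size_ha=float(sizes[j]),
            catchment_radius_m=catchment_radius(float(sizes[j]), config.base_catchment_m, mean_size),
        )
        for j in range(config.n_parks)
    ]

    layout = CityLayout(
        name=config.name,
        zones=zones,
        green_spaces=parks,
        sunshine_factor=config.sunshine_factor,
    )
    assign_quality(layout, config.p_low_given_small_deprived, rng)
    layout.validate()
    return layout


def assign_quality(layout: CityLayout, p_low_given_small_deprived: float, rng) -> CityLayout:
    """Assign park quality labels in place.

    Parks smaller than the city mean located in a deprived zone are labelled
    low with probability ``p_low_given_small_deprived``; every other park is
    medium or high uniformly.  Only the low label changes behaviour in the
    engine (higher-SES avoidance); medium and high are kept distinct labels.
    """
    if not (0 <= p_low_given_small_deprived <= 1):
        raise LayoutError("p_low_given_small_deprived must be in [0, 1]")
    mean_size = layout.mean_park_size
    for park in layout.green_spaces:
        zi = layout.zone_of_point(*park.centroid)
        small_deprived = park.size_ha < mean_size and layout.zones[zi].deprived
        if small_deprived and rng.random() < p_low_given_small_deprived:
            park.quality = "low"
        else:
            park.quality = "medium" if rng.random() < 0.5 else "high"
    return layout


# ---------------------------------------------------------------------------
# GeoJSON I/O (planar coordinates, RFC 7946 structure)
# ---------------------------------------------------------------------------

def write_city_geojson(layout: CityLayout, path) -> None:
    """Write a layout as a GeoJSON FeatureCollection.

    Zones are Polygon features with ``properties.kind == "zone"``; green
    spaces are Point features with ``properties.kind == "green_space"``.
    """
    features = []
    for z in layout.zones:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(z.geometry),
                "properties": {
                    "kind": "zone",
                    "id": z.id,
                    "resident_count": z.resident_count,
                    "ses_shares": {g: float(s) for g, s in zip(GRADES, z.ses_shares)},
                    "walkability_quartile": int(z.walkability_quartile),
                    "deprived": bool(z.deprived),
                },
            }
        )
    for p in layout.green_spaces:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(p.centroid)},
                "properties": {
                    "kind": "green_space",
                    "id": p.id,
                    "size_ha": p.size_ha,
                    "quality": p.quality,
                    "catchment_radius_m": p.catchment_radius_m,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "name": layout.name,
        "sunshine_factor": layout.sunshine_factor,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_city_geojson(path) -> CityLayout:
    """Load a layout from GeoJSON written in the dialect above.

    Coordinates are taken as planar metres; no CRS transformation.  Missing
    required properties raise a schema error naming the feature; invariant
    breaches (e.g. SES shares not summing to 1) raise a validation error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise LayoutError(f"{path}: not a GeoJSON FeatureCollection")
    zones, parks = [], []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        kind = props.get("kind")
        fid = props.get("id", "<missing id>")
        if kind == "zone":
            required = ("id", "resident_count", "ses_shares", "walkability_quartile")
            missing = [k for k in required if k not in props]
            if missing:
                raise LayoutError(f"zone feature {fid}: missing properties {missing}")
            shares = np.array([props["ses_shares"].get(g, 0.0) for g in GRADES], dtype=float)
            zones.append(
                Zone(
                    id=props["id"],
                    geometry=shape(feat["geometry"]),
                    resident_count=int(props["resident_count"]),
                    ses_shares=shares,
                    walkability_quartile=int(props["walkability_quartile"]),
                    deprived=bool(props.get("deprived", False)),
                )
            )
        elif kind == "green_space":
            required = ("id", "size_ha", "quality")
            missing = [k for k in required if k not in props]
            if missing:
                raise LayoutError(f"green_space feature {fid}: missing properties {missing}")
            coords = feat["geometry"]["coordinates"]
            parks.append(
                GreenSpace(
                    id=props["id"],
                    centroid=(float(coords[0]), float(coords[1])),
                    size_ha=float(props["size_ha"]),
                    quality=props["quality"],
                    catchment_radius_m=float(props.get("catchment_radius_m", 0.0)),
                )
            )
        else:
            raise LayoutError(f"feature {fid}: unknown kind {kind!r}")
    layout = CityLayout(
        name=doc.get("name", "loaded"),
        zones=zones,
        green_spaces=parks,
        sunshine_factor=float(doc.get("sunshine_factor", 1.0)),
    )
    if layout.green_spaces:
        mean_size = layout.mean_park_size
        for p in layout.green_spaces:
            if p.catchment_radius_m <= 0:
                p.catchment_radius_m = catchment_radius(p.size_ha, 1600.0, mean_size)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Default synthetic city suites
# ---------------------------------------------------------------------------

def default_city_suite(residents_per_zone: int = 1250, seed: int = 0) -> dict[str, CityGenConfig]:
    """Four synthetic cities emulating the statistical structure of the four
    Scottish study cities: SES composition (share of AB+C1), residential
    segregation, walkability-SES correlation and annual-sunshine factor.

    The reference city ("edleith") has the largest high-SES share and the
    lowest segregation; "glasfork" the opposite.  Weather factors follow the
    published annual-sunshine ordering (Dundee-like highest at s=1).
    """
    base = dict(
        n_zones=16,
        residents_per_zone=residents_per_zone,
        n_parks=12,
        grid_extent_m=6000.0,
        walkability_ses_correlation=0.7,
    )
    return {
        "edleith": CityGenConfig(
            name="edleith",
            ses_shares_city=(0.25, 0.30, 0.20, 0.25),
            segregation_strength=0.2,
            sunshine_factor=0.88,
            seed=seed,
            **base,
        ),
        "glasfork": CityGenConfig(
            name="glasfork",
            ses_shares_city=(0.15, 0.20, 0.30, 0.35),
            segregation_strength=0.6,
            sunshine_factor=0.80,
            seed=seed + 1,
            **base,
        ),
        "aberdon": CityGenConfig(
            name="aberdon",
            ses_shares_city=(0.26, 0.27, 0.23, 0.24),
            segregation_strength=0.55,
            sunshine_factor=0.88,
            seed=seed + 2,
            **base,
        ),
        "dunlaw": CityGenConfig(
            name="dunlaw",
            ses_shares_city=(0.17, 0.23, 0.30, 0.30),
            segregation_strength=0.4,
            sunshine_factor=1.0,
            seed=seed + 3,
            **base,
        ),
    }


def two_city_suite(residents_per_zone: int = 1250, seed: int = 0) -> dict[str, CityGenConfig]:
    """The reference-vs-comparison pair used for mechanism checks: an
    Edinburgh-like city (AB+C1 share 0.55, segregation 0.2) and a
    Glasgow-like one (AB+C1 share 0.35, segregation 0.6)."""
    suite = default_city_suite(residents_per_zone=residents_per_zone, seed=seed)
    return {k: suite[k] for k in ("edleith", "glasfork")}
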