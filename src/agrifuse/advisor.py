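"""Attention-point detection and GA-optimised tractor routing.

Cells whose kriged soil moisture falls below an irrigation threshold,
or whose canopy NDVI falls below a fertilisation threshold, become
attention points with a severity equal to the summed fractional
shortfall below each violated threshold.  A permutation-encoded
genetic algorithm then orders the visit: order crossover (OX), swap
mutation, tournament selection of size 3 and single-individual elitism
minimise a weighted sum of route length (closed tour from a depot) and
severity-weighted visit rank, so severe cells are reached early without
driving an absurd detour.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRouteWarning, GridMismatchError
from .geodata import NDVIMap
from .kriging import local_xy


@dataclass(frozen=True)
class AlertRules:
    """Thresholds triggering attention points.

    ``moisture_min`` (VWC) flags irrigation need; ``ndvi_min`` flags
    fertilisation need on the canopy NDVI layer.  Defaults are
    documented package choices, not field-calibrated values.
    """

    moisture_min: float = 0.25
    ndvi_min: float = 0.45


@dataclass
class AttentionPoint:
    lat: float
    lon: float
    reasons: frozenset[str]
    severity: float
    cell: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("an attention point needs at least one reason")
        if self.severity < 0:
            raise ValueError("severity must be non-negative")


@dataclass
class RoutePlan:
    waypoints: list[tuple[float, float]]  # depot, points in visit order, depot
    order: list[int]  # permutation of input point indices
    total_length_m: float
    objective_value: float
    seed: int
    generations: int
    history: np.ndarray = field(repr=False, default=None)  # best objective per generation


def detect_attention_points(
    ndvi_vin: NDVIMap,
    moisture: np.ndarray,
    rules: AlertRules = AlertRules(),
    moisture_nodata: np.ndarray | None = None,
) -> list[AttentionPoint]:
    """Flag cells needing irrigation (low moisture) or fertilisation (low canopy NDVI).

    ``moisture`` is a VWC plane on the same grid as ``ndvi_vin``.
    Severity is the sum over triggered reasons of the fractional
    shortfall (threshold - value)/threshold.  Nodata cells are never
    flagged.
    """
    moisture = np.asarray(moisture, dtype=float)
    if moisture.shape != ndvi_vin.grid.shape:
        raise GridMismatchError("moisture plane shape does not match the NDVI grid")
    m_bad = ~np.isfinite(moisture)
    if moisture_nodata is not None:
        m_bad |= np.asarray(moisture_nodata, dtype=bool)

    points: list[AttentionPoint] = []
    valid = ndvi_vin.valid & ~m_bad
    irrigation = valid & (moisture < rules.moisture_min)
    fertilisation = valid & (ndvi_vin.values < rules.ndvi_min)
    flagged = irrigation | fertilisation
    for u, v in zip(*np.nonzero(flagged)):
        reasons = set()
        severity = 0.0
        if irrigation[u, v]:
            reasons.add("irrigation")
            severity += (rules.moisture_min - moisture[u, v]) / rules.moisture_min
        if fertilisation[u, v]:
            reasons.add("fertilisation")
            severity += (rules.ndvi_min - ndvi_vin.values[u, v]) / rules.ndvi_min
        lat, lon = ndvi_vin.grid.pixel_center(int(u), int(v))
        points.append(
            AttentionPoint(
                lat=lat,
                lon=lon,
                reasons=frozenset(reasons),
                severity=float(severity),
                cell=(int(u), int(v)),
            )
        )
    return points


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 100
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float = 0.8
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 42


def route_objective(
    order: np.ndarray,
    dist: np.ndarray,
    severities: np.ndarray,
    w_dist: float,
    w_priority: float,
) -> float:
    """Objective of one visiting order.

    ``dist`` is the (n+1, n+1) matrix with the depot at index 0 and
    point k at index k+1.  Length is the closed tour
    depot -> order -> depot; priority term is sum(rank * severity) with
    rank starting at 1, so high-severity points want early ranks.
    """
    idx = np.asarray(order) + 1
    length = dist[0, idx[0]] + dist[idx[-1], 0] + dist[idx[:-1], idx[1:]].sum()
    ranks = np.arange(1, len(idx) + 1)
    priority = float((ranks * severities[np.asarray(order)]).sum())
    return w_dist * length + w_priority * priority


def _order_crossover(p1: np.ndarray, p2: np.ndarray, rng) -> np.ndarray:
    """OX: copy a slice from p1, fill the rest in p2's cyclic order."""
    n = len(p1)
    a, b = sorted(rng.choice(n, size=2, replace=False))
    child = np.full(n, -1)
    child[a : b + 1] = p1[a : b + 1]
    used = set(child[a : b + 1].tolist())
    fill = [g for g in itertools.chain(p2[b + 1 :], p2[: b + 1]) if g not in used]
    pos = [i for i in itertools.chain(range(b + 1, n), range(a))]
    for i, g in zip(pos, fill):
        child[i] = g
    return child


def plan_route(
    points: list[AttentionPoint],
    depot: tuple[float, float],
    ga: GAConfig = GAConfig(),
    weights: tuple[float, float] = (1.0, 0.0),
) -> RoutePlan:
    """Order attention points into a closed tour from the depot with a GA.

    Deterministic given ``ga.seed``.  ``weights`` = (w_dist, w_priority)
    scalarise route length (metres) against severity-weighted visit
    rank.  With no points, a depot-only route is returned with a
    warning.
    """
    w_dist, w_priority = weights
    if not points:
        warnings.warn("no attention points; returning depot-only route", EmptyRouteWarning)
        return RoutePlan(
            waypoints=[depot, depot],
            order=[],
            total_length_m=0.0,
            objective_value=0.0,
            seed=ga.seed,
            generations=0,
            history=np.zeros(0),
        )

    n = len(points)
    lats = np.array([depot[0]] + [p.lat for p in points])
    lons = np.array([depot[1]] + [p.lon for p in points])
    xy = local_xy(lats, lons, float(lats.mean()), float(lons.mean()))
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    severities = np.array([p.severity for p in points])

    rng = np.random.default_rng(ga.seed)

    def score(order):
        return route_objective(order, dist, severities, w_dist, w_priority)

    pop = np.array([rng.permutation(n) for _ in range(ga.pop_size)])
    fitness = np.array([score(ind) for ind in pop])
    history = np.empty(ga.generations + 1)
    history[0] = fitness.min()

    for gen in range(ga.generations):
        best_idx = int(np.argmin(fitness))
        new_pop = [pop[best_idx].copy()]  # elitism of 1
        while len(new_pop) < ga.pop_size:
            # tournament selection, size 3
            contenders = rng.integers(0, ga.pop_size, size=ga.tournament_size)
            p1 = pop[contenders[np.argmin(fitness[contenders])]]
            contenders = rng.integers(0, ga.pop_size, size=ga.tournament_size)
            p2 = pop[contenders[np.argmin(fitness[contenders])]]
            if n >= 2 and rng.random() < ga.crossover_rate:
                child = _order_crossover(p1, p2, rng)
            else:
                child = p1.copy()
            if n >= 2 and rng.random() < ga.mutation_rate:
                i, j = rng.choice(n, size=2, replace=False)
                child[i], child[j] = child[j], child[i]
            new_pop.append(child)
        pop = np.array(new_pop)
        fitness = np.array([score(ind) for ind in pop])
        history[gen + 1] = fitness.min()

    best = pop[int(np.argmin(fitness))]
    idx = best + 1
    length = float(dist[0, idx[0]] + dist[idx[-1], 0] + dist[idx[:-1], idx[1:]].sum())
    ordered = [(points[k].lat, points[k].lon) for k in best]
    return RoutePlan(
        waypoints=[depot] + ordered + [depot],
        order=best.tolist(),
        total_length_m=length,
        objective_value=float(fitness.min()),
        seed=ga.seed,
        generations=ga.generations,
        history=history,
    )


def brute_force_route(
    points: list[AttentionPoint],
    depot: tuple[float, float],
    weights: tuple[float, float] = (1.0, 0.0),
) -> tuple[list[int], float]:
    """Exhaustive-permutation optimum (small n only); oracle for the GA."""
    n = len(points)
    lats = np.array([depot[0]] + [p.lat for p in points])
    lons = np.array([depot[1]] + [p.lon for p in points])
    xy = local_xy(lats, lons, float(lats.mean()), float(lons.mean()))
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    severities = np.array([p.severity for p in points])
    w_dist, w_priority = weights
    best_order, best_val = None, math.inf
    for perm in itertools.permutations(range(n)):
        val = route_objective(np.array(perm), dist, severities, w_dist, w_priority)
        if val < best_val:
            best_order, best_val = list(perm), val
    return best_order, best_val


def attention_points_geojson(points: list[AttentionPoint]) -> dict:
    """GeoJSON FeatureCollection of attention points."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {
                    "reasons": sorted(p.reasons),
                    "severity": p.severity,
                    "cell": list(p.cell) if p.cell else None,
                },
            }
            for p in points
        ],
    }


def route_geojson(plan: RoutePlan) -> dict:
    """GeoJSON LineString of the planned route (lon, lat order)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[lon, lat] for lat, lon in plan.waypoints],
                },
                "properties": {
                    "total_length_m": plan.total_length_m,
                    "objective_value": plan.objective_value,
                    "seed": plan.seed,
                    "generations": plan.generations,
                },
            }
        ],
    }
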