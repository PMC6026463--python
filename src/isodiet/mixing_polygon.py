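"""Monte Carlo mixing-polygon validation of consumers.

Before fitting a mixing model, each consumer must be explainable as a
convex combination of the TEF-corrected sources.  Convex hulls (mixing
polygons) are iterated by resampling every source position from
Normal(mean + TEF mean, sqrt(SD² + TEF SD²)) per tracer; the fraction of
iterated polygons containing a consumer is its inclusion probability.
Consumers below the probability threshold in any pairwise tracer
projection fall outside the 95% mixing region and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .isotope_prep import ConsumerSample, SourceGroup, TEFSet, TRACERS

#: The three pairwise tracer projections in which polygons are built.
ISOTOPE_PAIRS: tuple[tuple[str, str], ...] = (
    ("d13c", "d15n"),
    ("d13c", "d34s"),
    ("d15n", "d34s"),
)

DEFAULT_N_ITER = 1500
DEFAULT_THRESHOLD = 0.05


@dataclass(frozen=True)
class PolygonIterations:
    """Iterated convex hulls for one tracer pair."""

    isotope_pair: tuple[str, str]
    hulls: tuple[np.ndarray, ...]  # each (m, 2), vertices in hull order
    n_iter: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class InclusionReport:
    """Per-consumer, per-pair inclusion probabilities and the joint decision.

    ``table`` has columns ``bird_id, pair, probability``; ``decisions`` maps
    bird_id to ``"retained"`` or ``"excluded"``.  A consumer is retained iff
    its probability is at least ``threshold`` in every tracer pair.
    """

    table: pd.DataFrame
    decisions: dict[str, str]
    threshold: float

    def retained_ids(self) -> list[str]:
        return [b for b, d in self.decisions.items() if d == "retained"]

    def excluded_ids(self) -> list[str]:
        return [b for b, d in self.decisions.items() if d == "excluded"]


def point_in_polygon(
    point: Sequence[float],
    vertices: np.ndarray,
    tol: float = 1e-9,
) -> bool:
    """Inclusive point-in-convex-polygon test.

    ``vertices`` must be ordered along the hull (either orientation).
    Boundary points count as inside.  A degenerate (collinear) hull is
    treated as a zero-area region: only points on the segment are inside.
    """
    v = np.asarray(vertices, dtype=float)
    p = np.asarray(point, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("vertices must be an (m, 2) array with m >= 2")
    edges = np.roll(v, -1, axis=0) - v
    rel = p[None, :] - v
    cross = edges[:, 0] * rel[:, 1] - edges[:, 1] * rel[:, 0]
    scale = max(1.0, float(np.abs(v).max()))
    eps = tol * scale
    # signed area (shoelace); ~0 means collinear vertices
    area2 = float(np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]))
    if abs(area2) <= eps:
        return _on_segment(p, v, eps)
    sign = 1.0 if area2 > 0 else -1.0
    return bool(np.all(sign * cross >= -eps))


def _on_segment(p: np.ndarray, v: np.ndarray, eps: float) -> bool:
    lo, hi = v[np.argmin(v[:, 0] + v[:, 1])], v[np.argmax(v[:, 0] + v[:, 1])]
    d = hi - lo
    if np.allclose(d, 0):
        return bool(np.linalg.norm(p - lo) <= eps)
    t = float(np.dot(p - lo, d) / np.dot(d, d))
    if t < -eps or t > 1 + eps:
        return False
    return bool(np.linalg.norm(p - (lo + t * d)) <= eps)


def simulate_polygons(
    groups: Sequence[SourceGroup],
    tefs: TEFSet,
    isotope_pair: tuple[str, str],
    n_iter: int = DEFAULT_N_ITER,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PolygonIterations:
    """Iterate mixing polygons for one tracer pair.

    Each iteration draws every source's position per tracer from
    ``Normal(mean + tef_mean, sqrt(sd² + tef_sd²))`` and takes the convex
    hull of the K drawn points.  Requires K >= 3 sources for a 2-D polygon.
    """
    if len(groups) < 3:
        raise ValueError("a 2-D mixing polygon needs at least 3 sources")
    for t in isotope_pair:
        if t not in TRACERS:
            raise ValueError(f"unknown tracer {t!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(groups)
    loc = np.empty((k, 2))
    scale = np.empty((k, 2))
    for i, g in enumerate(groups):
        for j, t in enumerate(isotope_pair):
            sd = g.sd_of(t)
            if math.isnan(sd):
                raise ValueError(f"group {g.group_id}: missing SD for {t}")
            loc[i, j] = g.mean_of(t) + tefs.mean(g.group_id, t)
            scale[i, j] = math.sqrt(sd**2 + tefs.sd(g.group_id, t) ** 2)
    draws = rng.normal(loc, scale, size=(n_iter, k, 2))
    hulls = []
    for it in range(n_iter):
        pts = draws[it]
        try:
            hull = ConvexHull(pts)
            hulls.append(pts[hull.vertices])
        except QhullError:  # collinear draw: keep the extreme points
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            hulls.append(pts[order[[0, -1]]])
    return PolygonIterations(
        isotope_pair=tuple(isotope_pair),
        hulls=tuple(hulls),
        n_iter=n_iter,
        seed=seed,
    )


def inclusion_probability(
    point: Sequence[float], polygons: PolygonIterations
) -> float:
    """Fraction of iterated polygons containing the point."""
    hits = sum(point_in_polygon(point, h) for h in polygons.hulls)
    return hits / polygons.n_iter


def validate_consumers(
    consumers: Sequence[ConsumerSample],
    groups: Sequence[SourceGroup],
    tefs: TEFSet,
    n_iter: int = DEFAULT_N_ITER,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int | None = None,
) -> InclusionReport:
    """Gate consumers on their mixing-polygon inclusion probabilities.

    Polygons are simulated independently in the three pairwise tracer
    projections (one seeded RNG stream per pair, derived from ``seed``); a
    consumer is retained iff its inclusion probability is >= ``threshold``
    in all three.
    """
    if not consumers:
        raise ValueError("no consumers supplied")
    child_rngs = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(len(ISOTOPE_PAIRS))
    ]
    rows = []
    probs: dict[str, list[float]] = {c.bird_id: [] for c in consumers}
    for pair, rng in zip(ISOTOPE_PAIRS, child_rngs):
        polys = simulate_polygons(
            groups, tefs, pair, n_iter=n_iter, seed=seed, rng=rng
        )
        for c in consumers:
            pt = (c.triplet.get(pair[0]), c.triplet.get(pair[1]))
            p = inclusion_probability(pt, polys)
            probs[c.bird_id].append(p)
            rows.append(
                {"bird_id": c.bird_id, "pair": "-".join(pair), "probability": p}
            )
    decisions = {
        b: "retained" if all(p >= threshold for p in ps) else "excluded"
        for b, ps in probs.items()
    }
    return InclusionReport(
        table=pd.DataFrame(rows), decisions=decisions, threshold=threshold
    )
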