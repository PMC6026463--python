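"""Gut-content diet composition and Dirichlet prior construction.

Per-bird prey-item records (wet weight, ash-free dry weight) are summarized
into the classic composition table — WW%, AFDW%, frequency of occurrence —
and those proportions are converted into Dirichlet concentration vectors
that act as informative priors for the mixing model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("isodiet")


@dataclass(frozen=True)
class GutRecord:
    """One prey item found in one bird's oesophagus/gizzard.

    ``afdw_g`` (organic-matter weight) may be missing; it can be derived
    from wet weight with a taxon-specific conversion via
    :func:`afdw_from_ww`.  Pebbles and other non-food material are assumed
    to have been excluded upstream.
    """

    bird_id: str
    taxon: str
    ww_g: float
    afdw_g: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ww_g) and self.ww_g >= 0):
            raise ValueError(f"ww_g must be finite and >= 0, got {self.ww_g}")
        if self.afdw_g is not None:
            if not (math.isfinite(self.afdw_g) and self.afdw_g >= 0):
                raise ValueError(f"afdw_g must be finite and >= 0")
            if self.afdw_g > self.ww_g + 1e-12:
                raise ValueError(
                    f"afdw_g ({self.afdw_g}) cannot exceed ww_g ({self.ww_g})"
                )


@dataclass(frozen=True)
class DietComposition:
    """Per-taxon composition table plus the number of birds analysed.

    ``table`` is indexed by taxon with columns ``ww_g, ww_pct, afdw_g,
    afdw_pct, fo_n, fo_pct`` (full precision; round only for reports).
    """

    table: pd.DataFrame
    n_birds: int

    def __post_init__(self) -> None:
        for col in ("ww_pct", "afdw_pct"):
            total = self.table[col].sum()
            if total > 0 and abs(total - 100.0) > 0.05:
                raise ValueError(f"{col} sums to {total}, expected 100")
        if (self.table["fo_n"] > self.n_birds).any():
            raise ValueError("fo_n cannot exceed n_birds")

    @classmethod
    def from_totals(
        cls,
        totals: Mapping[str, tuple[float, float, int]],
        n_birds: int,
    ) -> "DietComposition":
        """Build a composition from per-taxon totals.

        ``totals[taxon] == (ww_g, afdw_g, fo_n)``.  Used to ingest published
        summary tables where the per-bird records are not available.
        """
        df = pd.DataFrame.from_dict(
            totals, orient="index", columns=["ww_g", "afdw_g", "fo_n"]
        )
        return cls(table=_add_percent_columns(df, n_birds), n_birds=n_birds)

    def weights(self, mode: str) -> pd.Series:
        if mode not in ("ww", "afdw"):
            raise ValueError(f"mode must be 'ww' or 'afdw', got {mode!r}")
        return self.table[f"{mode}_g"]

    def report(self, decimals: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("ww_g", "ww_pct", "afdw_g", "afdw_pct", "fo_pct"):
            out[col] = out[col].round(decimals)
        return out


@dataclass(frozen=True)
class PriorSpec:
    """A Dirichlet prior on the source-proportion simplex.

    ``alpha`` is ordered as ``source_ids``; components are floored at a
    small ``floor`` so that zero-weight sources (e.g. soft-bodied prey that
    digest away before gut inspection) keep non-zero prior mass, then the
    vector is rescaled to total concentration ``concentration``.
    """

    mode: str
    source_ids: tuple[str, ...]
    alpha: np.ndarray
    concentration: float
    floor: float
    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (len(self.source_ids),):
            raise ValueError("alpha length must match source_ids")
        if not (a > 0).all():
            raise ValueError("all alpha components must be > 0")
        object.__setattr__(self, "alpha", a)


def diet_composition(
    records: Sequence[GutRecord], n_birds: int
) -> DietComposition:
    """Summarize per-bird gut records into a composition table.

    WW% and AFDW% are taxon totals over the grand totals; frequency of
    occurrence counts distinct birds containing the taxon, expressed
    against ``n_birds`` (which may exceed the number of birds with records
    — birds whose guts held nothing still count in the denominator).
    """
    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    if not records:
        raise ValueError("no gut records supplied")
    df = pd.DataFrame(
        {
            "bird_id": [r.bird_id for r in records],
            "taxon": [r.taxon for r in records],
            "ww_g": [r.ww_g for r in records],
            "afdw_g": [r.afdw_g if r.afdw_g is not None else 0.0 for r in records],
        }
    )
    agg = df.groupby("taxon").agg(
        ww_g=("ww_g", "sum"),
        afdw_g=("afdw_g", "sum"),
        fo_n=("bird_id", "nunique"),
    )
    if agg["ww_g"].sum() <= 0:
        raise ValueError("total wet weight is zero")
    return DietComposition(
        table=_add_percent_columns(agg, n_birds), n_birds=n_birds
    )


def _add_percent_columns(df: pd.DataFrame, n_birds: int) -> pd.DataFrame:
    df = df.copy()
    ww_tot = df["ww_g"].sum()
    afdw_tot = df["afdw_g"].sum()
    if ww_tot <= 0:
        raise ValueError("total wet weight is zero")
    df["ww_pct"] = 100.0 * df["ww_g"] / ww_tot
    df["afdw_pct"] = (
        100.0 * df["afdw_g"] / afdw_tot if afdw_tot > 0 else 0.0
    )
    df["fo_pct"] = 100.0 * df["fo_n"] / n_birds
    return df[["ww_g", "ww_pct", "afdw_g", "afdw_pct", "fo_n", "fo_pct"]]


def afdw_from_ww(ww_g: float, conversion: float) -> float:
    """Ash-free dry weight from wet weight via a taxon-specific fraction."""
    if not (0 < conversion <= 1):
        raise ValueError(f"conversion must be in (0, 1], got {conversion}")
    return ww_g * conversion


def parse_mapping_value(value: str) -> str | tuple[str, tuple[str, ...]]:
    """Parse a taxon-mapping entry: a source id, ``"drop"``, or
    ``"redistribute:src1,src2"``."""
    if value.startswith("redistribute:"):
        targets = tuple(t.strip() for t in value.split(":", 1)[1].split(",") if t.strip())
        if not targets:
            raise ValueError("redistribute mapping needs at least one target")
        return ("redistribute", targets)
    return value


def gut_priors(
    comp: DietComposition,
    mapping: Mapping[str, str],
    source_ids: Sequence[str],
    mode: str = "ww",
    concentration: float | None = None,
    floor: float = 0.01,
) -> PriorSpec:
    """Convert gut-content proportions into a Dirichlet prior.

    Every taxon in the composition must appear in ``mapping``, whose values
    are a model source id, ``"drop"`` (excluded, e.g. trace or non-modelled
    prey), or ``"redistribute:<src1,src2,...>"`` (unidentifiable material
    split over the named sources proportionally to their identified
    weights).  The mapped proportions ``q`` are renormalized over the model
    sources, floored (``alpha_k = max(c*q_k, floor)``) and rescaled so the
    total concentration equals ``c`` (default: the number of sources, i.e.
    a uniform composition yields the uninformative all-ones vector).
    """
    source_ids = tuple(source_ids)
    k = len(source_ids)
    c = float(concentration) if concentration is not None else float(k)
    if c <= 0:
        raise ValueError("concentration must be > 0")
    if not 0 < floor:
        raise ValueError("floor must be > 0")
    weights = comp.weights(mode)

    direct = {s: 0.0 for s in source_ids}
    redistributed: list[tuple[float, tuple[str, ...]]] = []
    for taxon, w in weights.items():
        if taxon not in mapping:
            raise ValueError(f"taxon {taxon!r} missing from the source mapping")
        target = parse_mapping_value(mapping[taxon])
        if target == "drop":
            continue
        if isinstance(target, tuple):
            redistributed.append((float(w), target[1]))
            continue
        if target not in direct:
            raise ValueError(
                f"mapping sends {taxon!r} to unknown source {target!r}"
            )
        direct[target] += float(w)

    mass = dict(direct)
    for w, targets in redistributed:
        for t in targets:
            if t not in mass:
                raise ValueError(f"redistribute target {t!r} is not a source")
        base = sum(direct[t] for t in targets)
        if base > 0:
            for t in targets:
                mass[t] += w * direct[t] / base
        else:  # nothing identified among the targets: split evenly
            for t in targets:
                mass[t] += w / len(targets)

    total = sum(mass.values())
    if total <= 0:
        raise ValueError("all gut weight was dropped; cannot form a prior")
    q = np.array([mass[s] / total for s in source_ids])
    for s, qs in zip(source_ids, q):
        if qs == 0:
            logger.warning(
                "source %s has no gut-content weight; prior floored at %g",
                s,
                floor,
            )
    alpha = np.maximum(c * q, floor)
    alpha = alpha * (c / alpha.sum())
    return PriorSpec(
        mode=mode,
        source_ids=source_ids,
        alpha=alpha,
        concentration=c,
        floor=floor,
        mapping=dict(mapping),
    )
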