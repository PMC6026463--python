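"""Isotope sample containers, delta-notation helpers, lipid normalization
and trophic-enrichment-factor (TEF) construction.

All delta values are per-mil (‰) deviations of a heavy/light isotope ratio
from the conventional standard (VPDB for carbon, atmospheric N2 for
nitrogen, VCDT for sulphur).  Carbon values of prey tissue are lipid-
normalized arithmetically from the tissue C:N mass ratio before any use in
the mixing machinery; consumer blood is never corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("isodiet")

#: Ordered tracer names used throughout the package.
TRACERS: tuple[str, str, str] = ("d13c", "d15n", "d34s")

#: C:N mass-ratio gate above which aquatic tissue is lipid-normalized.
LIPID_CN_GATE = 3.5
_LIPID_OFFSET = -3.32
_LIPID_SLOPE = 0.99

#: Linear diet-dependent carbon TEF for whole blood: slope*d13c + intercept.
CAUT_SLOPE = -0.199
CAUT_INTERCEPT = -3.986

#: Blood nitrogen TEF (‰). Two uncertainty conventions are in circulation for
#: this value; 0.01 is the one used in the fitted models, 0.20 the one quoted
#: in running text.  Both are exposed.
NITROGEN_TEF = 2.25
NITROGEN_TEF_SD_DEFAULT = 0.01
NITROGEN_TEF_SD_ALT = 0.20

#: Fixed literature TEF sets (carbon mean, carbon sd, nitrogen mean,
#: nitrogen sd).  Sulphur TEF is zero in every named set: the mean reported
#: trophic shift for sulphur is not significantly different from zero.
_FIXED_TEFS = {
    "modelA": (1.0, 0.2, 4.5, 0.2),
    "modelB": (0.4, 0.17, 2.67, 0.7),
}

TEF_MODEL_IDS = ("model0", "modelA", "modelB", "modelC")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopeTriplet:
    """One (δ13C, δ15N, δ34S) measurement in ‰.

    ``nan`` marks a tracer that was not measured for this specimen (source
    tables routinely have unequal per-tracer sample sizes); infinities are
    rejected.  ``cn_ratio`` is the C:N mass ratio, required only when the
    carbon value is to be lipid-normalized.
    """

    d13c: float = math.nan
    d15n: float = math.nan
    d34s: float = math.nan
    cn_ratio: float | None = None

    def __post_init__(self) -> None:
        for name in TRACERS:
            v = getattr(self, name)
            if v is not None and math.isinf(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio must be > 0, got {self.cn_ratio}")

    def get(self, tracer: str) -> float:
        if tracer not in TRACERS:
            raise KeyError(f"unknown tracer {tracer!r}")
        return getattr(self, tracer)


@dataclass(frozen=True)
class SourceSample:
    """A single prey specimen assigned to an end-member group."""

    taxon: str
    group_id: str
    triplet: IsotopeTriplet
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.group_id:
            raise ValueError("group_id must be non-empty")


@dataclass(frozen=True)
class SourceGroup:
    """A prey end-member: per-tracer mean, SD and sample count.

    The carbon mean/SD refer to lipid-corrected values.  ``sd`` reuses the
    triplet container as a value holder; its ``cn_ratio`` slot is unused.
    """

    group_id: str
    mean: IsotopeTriplet
    sd: IsotopeTriplet
    n: Mapping[str, int]

    def __post_init__(self) -> None:
        for t in TRACERS:
            s = self.sd.get(t)
            if not math.isnan(s) and s < 0:
                raise ValueError(f"sd[{t}] must be >= 0")
            if t in self.n and self.n[t] < 1:
                raise ValueError(f"n[{t}] must be >= 1")

    def mean_of(self, tracer: str) -> float:
        return self.mean.get(tracer)

    def sd_of(self, tracer: str) -> float:
        return self.sd.get(tracer)


@dataclass(frozen=True)
class ConsumerSample:
    """A consumer (whole blood) measurement.  Never lipid-corrected."""

    bird_id: str
    triplet: IsotopeTriplet
    body_weight: float | None = None

    def __post_init__(self) -> None:
        for t in TRACERS:
            if math.isnan(self.triplet.get(t)):
                raise ValueError(
                    f"consumer {self.bird_id}: {t} must be a finite number"
                )


@dataclass(frozen=True)
class TEFSet:
    """Per-group, per-tracer trophic enrichment factors (mean ± SD, ‰).

    ``values[group_id][tracer] == (tef_mean, tef_sd)``.
    """

    model_id: str
    values: Mapping[str, Mapping[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        for gid, per_tracer in self.values.items():
            for t, (m, s) in per_tracer.items():
                if s < 0:
                    raise ValueError(f"tef_sd[{gid}][{t}] must be >= 0")

    def mean(self, group_id: str, tracer: str) -> float:
        return self.values[group_id][tracer][0]

    def sd(self, group_id: str, tracer: str) -> float:
        return self.values[group_id][tracer][1]


# ---------------------------------------------------------------------------
# delta notation and lipid normalization
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert a measured heavy/light isotope ratio to delta notation.

    δX = (R_sample / R_standard − 1) × 1000, in ‰.
    """
    if not r_standard > 0:
        raise ValueError(f"r_standard must be > 0, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"r_sample must be >= 0, got {r_sample}")
    return (r_sample / r_standard - 1.0) * 1000.0


def lipid_normalize(
    d13c_untreated: float,
    cn_ratio: float | None,
    gate: float = LIPID_CN_GATE,
) -> float:
    """Arithmetic lipid normalization of a tissue δ13C value.

    Lipids are depleted in 13C, so lipid-rich tissue (C:N above ``gate``,
    default 3.5 for aquatic organisms) is corrected as

        δ13C = δ13C_untreated − 3.32 + 0.99 × C:N.

    At or below the gate the value is returned unchanged.
    """
    if cn_ratio is None:
        raise ValueError("cn_ratio is required for lipid normalization")
    if not cn_ratio > 0:
        raise ValueError(f"cn_ratio must be > 0, got {cn_ratio}")
    if cn_ratio > gate:
        return d13c_untreated + _LIPID_OFFSET + _LIPID_SLOPE * cn_ratio
    return d13c_untreated


# ---------------------------------------------------------------------------
# group summarization and pooling
# ---------------------------------------------------------------------------

def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    """Arithmetic mean and n−1 sample SD; SD is 0 for a single value."""
    n = values.size
    if n == 0:
        return math.nan, math.nan, 0
    m = float(np.mean(values))
    if n == 1:
        return m, 0.0, 1
    return m, float(np.std(values, ddof=1)), n


def summarize_group(
    samples: Sequence[SourceSample],
    apply_lipid_correction: bool = True,
    gate: float = LIPID_CN_GATE,
) -> SourceGroup:
    """Summarize one end-member group from its individual samples.

    Per-tracer mean and sample SD (n−1 denominator); missing (nan) values are
    skipped so per-tracer counts may differ.  When ``apply_lipid_correction``
    is set, carbon is corrected per sample *before* averaging — the per-sample
    order matters at reporting precision even though the formula is linear.
    """
    if not samples:
        raise ValueError("summarize_group needs at least one sample")
    gids = {s.group_id for s in samples}
    if len(gids) != 1:
        raise ValueError(f"samples span multiple groups: {sorted(gids)}")
    group_id = samples[0].group_id

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ns: dict[str, int] = {}
    for tracer in TRACERS:
        vals = []
        for s in samples:
            v = s.triplet.get(tracer)
            if math.isnan(v):
                continue
            if tracer == "d13c" and apply_lipid_correction:
                v = lipid_normalize(v, s.triplet.cn_ratio, gate=gate)
            vals.append(v)
        m, sd, n = _mean_sd(np.asarray(vals, dtype=float))
        if n == 1:
            logger.warning(
                "group %s: single %s sample, SD set to 0", group_id, tracer
            )
        means[tracer], sds[tracer], ns[tracer] = m, sd, n
    if all(v == 0 for v in ns.values()):
        raise ValueError(f"group {group_id}: no usable measurements")

    cn_vals = np.asarray(
        [s.triplet.cn_ratio for s in samples if s.triplet.cn_ratio is not None],
        dtype=float,
    )
    cn_mean = float(np.mean(cn_vals)) if cn_vals.size else None
    return SourceGroup(
        group_id=group_id,
        mean=IsotopeTriplet(**means, cn_ratio=cn_mean),
        sd=IsotopeTriplet(**sds),
        n={t: n for t, n in ns.items() if n > 0},
    )


def pool_groups(
    groups: Sequence[SourceGroup],
    pooled_id: str,
    samples: Sequence[SourceSample],
    apply_lipid_correction: bool = True,
) -> SourceGroup:
    """Pool ≥2 end-member groups into one, recomputed from raw samples.

    Statistics are computed over the union of the underlying individual
    samples — not as a mean of group means — so the result equals
    ``summarize_group`` run on the concatenated sample list.
    """
    if len(groups) < 2:
        raise ValueError("pooling requires at least 2 groups")
    member_ids = {g.group_id for g in groups}
    pooled_samples = [
        replace(s, group_id=pooled_id)
        for s in samples
        if s.group_id in member_ids
    ]
    if not pooled_samples:
        raise ValueError("no samples belong to the groups being pooled")
    return summarize_group(pooled_samples, apply_lipid_correction)


def pool_summaries(
    groups: Sequence[SourceGroup], pooled_id: str
) -> SourceGroup:
    """Pool groups from summary statistics only (no raw samples).

    The pooled mean is the unweighted average of the group means and the
    pooled SD is the equal-weight Gaussian-mixture SD,
    ``sqrt(mean(sd_i²) + mean((m_i − m̄)²))``.  Used when only published
    mean ± SD rows are available.  Per-tracer counts are summed.
    """
    if len(groups) < 2:
        raise ValueError("pooling requires at least 2 groups")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ns: dict[str, int] = {}
    for t in TRACERS:
        m = np.array([g.mean_of(t) for g in groups])
        s = np.array([g.sd_of(t) for g in groups])
        means[t] = float(np.mean(m))
        sds[t] = float(np.sqrt(np.mean(s**2) + np.mean((m - means[t]) ** 2)))
        ns[t] = int(sum(g.n.get(t, 0) for g in groups))
    return SourceGroup(
        group_id=pooled_id,
        mean=IsotopeTriplet(**means),
        sd=IsotopeTriplet(**sds),
        n=ns,
    )


# ---------------------------------------------------------------------------
# trophic enrichment factors
# ---------------------------------------------------------------------------

def caut_carbon_tef(
    d13c_source: float,
    slope: float = CAUT_SLOPE,
    intercept: float = CAUT_INTERCEPT,
) -> float:
    """Diet-dependent carbon TEF for whole blood, linear in source δ13C."""
    if math.isnan(d13c_source) or math.isinf(d13c_source):
        raise ValueError("d13c_source must be finite")
    return slope * d13c_source + intercept


def propagate_tef_se(se_d13c_source: float, slope: float = CAUT_SLOPE) -> float:
    """First-order error propagation of a source-δ13C standard error through
    the linear TEF function: SE_tef = |slope| × SE_source."""
    if se_d13c_source < 0:
        raise ValueError("standard error must be >= 0")
    return abs(slope) * se_d13c_source


def build_tef_set(
    model_id: str,
    groups: Sequence[SourceGroup],
    nitrogen_sd: float = NITROGEN_TEF_SD_DEFAULT,
    custom: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> TEFSet:
    """Construct a named TEF set for the given end-member groups.

    * ``model0`` — per-group carbon TEF from the linear diet-dependence,
      SD from first-order propagation of the group-mean standard error;
      nitrogen 2.25 ± ``nitrogen_sd``.
    * ``modelA`` — carbon 1.0 ± 0.2, nitrogen 4.5 ± 0.2 (literature values
      for marine ducks).
    * ``modelB`` — carbon 0.4 ± 0.17, nitrogen 2.67 ± 0.7.
    * ``modelC`` — carbon fixed at the mean of the model0 per-group TEFs
      ± 0.01; nitrogen as model0.
    * ``custom`` — values supplied by the caller.

    Sulphur TEF is 0 ± 0 in all four named sets.
    """
    if custom is not None:
        return TEFSet(model_id=model_id, values={g: dict(v) for g, v in custom.items()})
    if model_id not in TEF_MODEL_IDS:
        raise ValueError(
            f"unknown TEF model {model_id!r}; expected one of {TEF_MODEL_IDS} "
            "or custom values"
        )
    values: dict[str, dict[str, tuple[float, float]]] = {}
    if model_id in _FIXED_TEFS:
        c_m, c_s, n_m, n_s = _FIXED_TEFS[model_id]
        for g in groups:
            values[g.group_id] = {
                "d13c": (c_m, c_s),
                "d15n": (n_m, n_s),
                "d34s": (0.0, 0.0),
            }
        return TEFSet(model_id=model_id, values=values)

    # model0 / modelC: carbon from the linear diet dependence
    per_group_c: dict[str, tuple[float, float]] = {}
    for g in groups:
        tef = caut_carbon_tef(g.mean_of("d13c"))
        n_c = g.n.get("d13c", 1)
        se = g.sd_of("d13c") / math.sqrt(n_c) if n_c > 0 else 0.0
        per_group_c[g.group_id] = (tef, propagate_tef_se(se))
    if model_id == "modelC":
        c_mean = float(np.mean([m for m, _ in per_group_c.values()]))
        per_group_c = {gid: (c_mean, 0.01) for gid in per_group_c}
    for g in groups:
        values[g.group_id] = {
            "d13c": per_group_c[g.group_id],
            "d15n": (NITROGEN_TEF, nitrogen_sd),
            "d34s": (0.0, 0.0),
        }
    return TEFSet(model_id=model_id, values=values)
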