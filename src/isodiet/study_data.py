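"""Published summary statistics of the Baltic Velvet Scoter winter-diet
study that this package's default configuration reproduces.

The raw per-specimen measurements were never deposited, so the study is
carried here at the level of its published summary rows: per-taxon source
statistics (sample sizes, C:N, untreated δ13C, δ15N, δ34S), the pooled
gut-content totals of 66 bycaught birds, and the per-tracer blood
statistics of the 8 live-caught consumers.  Builders turn these rows into
the package's domain objects; consumer *individuals* are emulated from the
summary statistics (truncated Normals) because only the summaries exist.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .gut_contents import DietComposition
from .isotope_prep import (
    ConsumerSample,
    IsotopeTriplet,
    SourceGroup,
    lipid_normalize,
    pool_summaries,
)

#: Per-taxon source statistics: (n for C&N, n for S, C:N mean, C:N sd,
#: untreated d13c mean, untreated d13c sd, corrected d13c sd (as published;
#: the corrected *mean* is recomputed from the untreated mean at full
#: precision), d15n mean, d15n sd, d34s mean, d34s sd).
SOURCE_STATS: dict[str, dict[str, float | int]] = {
    "Saduria entomon": dict(
        n_cn=6, n_s=6, cn=6.1, cn_sd=0.4, d13c_unt=-21.5, d13c_unt_sd=0.3,
        d13c_sd=0.3, d15n=13.1, d15n_sd=0.3, d34s=15.1, d34s_sd=0.9,
    ),
    "Crangon crangon": dict(
        n_cn=6, n_s=6, cn=3.4, cn_sd=0.0, d13c_unt=-20.1, d13c_unt_sd=0.1,
        d13c_sd=0.1, d15n=12.4, d15n_sd=0.2, d34s=13.5, d34s_sd=0.9,
    ),
    "Macoma balthica": dict(
        n_cn=6, n_s=6, cn=4.8, cn_sd=0.1, d13c_unt=-22.8, d13c_unt_sd=0.1,
        d13c_sd=0.2, d15n=7.8, d15n_sd=0.2, d34s=10.7, d34s_sd=0.2,
    ),
    "Mya arenaria": dict(
        n_cn=9, n_s=5, cn=4.1, cn_sd=0.1, d13c_unt=-22.6, d13c_unt_sd=0.3,
        d13c_sd=0.2, d15n=6.6, d15n_sd=0.2, d34s=16.6, d34s_sd=0.6,
    ),
    "Cerastoderma glaucum": dict(
        n_cn=12, n_s=12, cn=5.0, cn_sd=0.2, d13c_unt=-23.6, d13c_unt_sd=0.7,
        d13c_sd=0.8, d15n=5.7, d15n_sd=0.4, d34s=17.4, d34s_sd=0.7,
    ),
    "Polychaetes": dict(
        n_cn=9, n_s=4, cn=4.3, cn_sd=0.2, d13c_unt=-23.1, d13c_unt_sd=0.4,
        d13c_sd=0.5, d15n=11.0, d15n_sd=0.6, d34s=10.7, d34s_sd=1.0,
    ),
}

#: Taxon -> end-member group id. Mya and Cerastoderma are isotopically
#: indistinguishable and enter the model as one pooled end-member.
TAXON_TO_GROUP = {
    "Saduria entomon": "saduria",
    "Crangon crangon": "crangon",
    "Macoma balthica": "macoma",
    "Mya arenaria": "mya_cerastoderma",
    "Cerastoderma glaucum": "mya_cerastoderma",
    "Polychaetes": "polychaetes",
}

#: Model source order used in all study-replication runs.
SOURCE_ORDER = (
    "saduria",
    "crangon",
    "mya_cerastoderma",
    "macoma",
    "polychaetes",
)

#: Gut-content totals over 66 birds: taxon -> (WW g, AFDW g, FO n).
#: Trace items published as "<0.01 g" are entered as 0 (below reporting
#: precision).
GUT_TOTALS: dict[str, tuple[float, float, int]] = {
    "Mya arenaria": (57.48, 8.31, 33),
    "Macoma balthica": (59.01, 7.56, 32),
    "Cerastoderma glaucum": (117.56, 9.71, 61),
    "Rangia cuneata": (0.0, 0.0, 1),
    "Hydrobia ulvae": (0.0, 0.0, 1),
    "Unident. Mollusca": (232.90, 25.46, 31),
    "Crangon crangon": (0.79, 0.21, 2),
    "Saduria entomon": (175.82, 34.22, 23),
    "Ammodytes tobianus": (2.25, 2.19, 2),
}

GUT_N_BIRDS = 66

#: Default mapping of gut taxa onto model sources.  Unidentifiable mollusc
#: material is split over the bivalve end-members in proportion to their
#: identified weights; trace gastropods/bivalves and fish are dropped.
DEFAULT_TAXON_MAPPING = {
    "Mya arenaria": "mya_cerastoderma",
    "Cerastoderma glaucum": "mya_cerastoderma",
    "Macoma balthica": "macoma",
    "Unident. Mollusca": "redistribute:mya_cerastoderma,macoma",
    "Saduria entomon": "saduria",
    "Crangon crangon": "crangon",
    "Rangia cuneata": "drop",
    "Hydrobia ulvae": "drop",
    "Ammodytes tobianus": "drop",
}

#: Blood statistics of the 8 analysed consumers: per tracer
#: (mean, sd, min, max); plus body weight 1574 ± 128 g, C:N 3.5.
CONSUMER_STATS = {
    "d13c": (-21.4, 0.2, -21.6, -21.2),
    "d15n": (11.5, 0.8, 10.4, 13.0),
    "d34s": (16.3, 1.3, 14.9, 18.8),
}
CONSUMER_BODY_WEIGHT = (1574.0, 128.0)
CONSUMER_CN = 3.5


def corrected_d13c(taxon: str) -> float:
    """Full-precision lipid-corrected carbon mean for one source taxon."""
    row = SOURCE_STATS[taxon]
    return lipid_normalize(float(row["d13c_unt"]), float(row["cn"]))


def taxon_group(taxon: str) -> SourceGroup:
    """One taxon as an (unpooled) end-member group, carbon corrected."""
    row = SOURCE_STATS[taxon]
    return SourceGroup(
        group_id=TAXON_TO_GROUP[taxon],
        mean=IsotopeTriplet(
            d13c=corrected_d13c(taxon),
            d15n=float(row["d15n"]),
            d34s=float(row["d34s"]),
            cn_ratio=float(row["cn"]),
        ),
        sd=IsotopeTriplet(
            d13c=float(row["d13c_sd"]),
            d15n=float(row["d15n_sd"]),
            d34s=float(row["d34s_sd"]),
        ),
        n={"d13c": int(row["n_cn"]), "d15n": int(row["n_cn"]), "d34s": int(row["n_s"])},
    )


def study_source_groups(pool_bivalves: bool = True) -> list[SourceGroup]:
    """The study's end-member groups in :data:`SOURCE_ORDER`.

    With ``pool_bivalves`` (the published configuration) Mya and
    Cerastoderma are combined from their summary rows: unweighted average
    of means, equal-weight mixture SD.
    """
    per_taxon = {t: taxon_group(t) for t in SOURCE_STATS}
    if not pool_bivalves:
        return list(per_taxon.values())
    mya = per_taxon["Mya arenaria"]
    cer = per_taxon["Cerastoderma glaucum"]
    pooled = pool_summaries([mya, cer], "mya_cerastoderma")
    groups = {
        "saduria": per_taxon["Saduria entomon"],
        "crangon": per_taxon["Crangon crangon"],
        "mya_cerastoderma": pooled,
        "macoma": per_taxon["Macoma balthica"],
        "polychaetes": per_taxon["Polychaetes"],
    }
    return [groups[g] for g in SOURCE_ORDER]


def study_diet_composition() -> DietComposition:
    """The published gut-content composition (66 birds)."""
    return DietComposition.from_totals(GUT_TOTALS, n_birds=GUT_N_BIRDS)


def emulate_consumers(
    n: int = 7, seed: int | None = None
) -> list[ConsumerSample]:
    """Draw pseudo-consumers from the published blood statistics.

    Each tracer is an independent truncated Normal at the published
    mean/SD, truncated to the published min–max range.  These stand in for
    the real individuals, which were never deposited.
    """
    rng = np.random.default_rng(seed)
    vals = {}
    for tracer, (m, s, lo, hi) in CONSUMER_STATS.items():
        a, b = (lo - m) / s, (hi - m) / s
        vals[tracer] = truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng)
    bw = rng.normal(*CONSUMER_BODY_WEIGHT, size=n)
    return [
        ConsumerSample(
            bird_id=f"scoter_{i + 1:02d}",
            triplet=IsotopeTriplet(
                d13c=float(vals["d13c"][i]),
                d15n=float(vals["d15n"][i]),
                d34s=float(vals["d34s"][i]),
                cn_ratio=CONSUMER_CN,
            ),
            body_weight=float(bw[i]),
        )
        for i in range(n)
    ]
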