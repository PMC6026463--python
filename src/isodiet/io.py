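"""CSV schemas, configuration, and the end-to-end pipeline.

The pipeline chains the analysis stages in the order the method runs:
source summarization (with lipid normalization) → TEF construction →
Monte Carlo mixing-polygon gate → Bayesian mixing model per prior mode →
report bundle (CSV tables plus a YAML manifest recording the seed and the
gate decisions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, study_data
from .gut_contents import DietComposition, GutRecord, diet_composition, gut_priors
from .isotope_prep import (
    ConsumerSample,
    IsotopeTriplet,
    SourceGroup,
    SourceSample,
    TEFSet,
    build_tef_set,
    summarize_group,
)
from .mixing_model import (
    McmcConfig,
    MixingModelSpec,
    compare_prior_modes,
)
from .mixing_polygon import InclusionReport, validate_consumers

logger = logging.getLogger("isodiet")

SOURCES_COLUMNS = ["sample_id", "taxon", "group_id", "d13c", "d15n", "d34s", "cn_ratio"]
CONSUMERS_COLUMNS = ["bird_id", "d13c", "d15n", "d34s", "cn_ratio", "body_weight_g"]
GUT_COLUMNS = ["bird_id", "taxon", "ww_g", "afdw_g"]


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _cell_float(
    row: pd.Series, col: str, path: Path, line: int, allow_missing: bool
) -> float:
    raw = row[col]
    if pd.isna(raw):
        if allow_missing:
            return math.nan
        raise SchemaError(f"{path}, line {line}, column {col!r}: value required")
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"{path}, line {line}, column {col!r}: not a number ({raw!r})"
        ) from None


def read_sources(path: str | Path) -> list[SourceSample]:
    """Read source samples; per-tracer values may be blank (unequal n)."""
    path = Path(path)
    df = _read_table(path, ["taxon", "group_id", "d13c", "d15n", "d34s"])
    out = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        cn = _cell_float(row, "cn_ratio", path, line, True) if "cn_ratio" in df else math.nan
        try:
            out.append(
                SourceSample(
                    taxon=str(row["taxon"]),
                    group_id=str(row["group_id"]),
                    sample_id=str(row.get("sample_id", "")),
                    triplet=IsotopeTriplet(
                        d13c=_cell_float(row, "d13c", path, line, True),
                        d15n=_cell_float(row, "d15n", path, line, True),
                        d34s=_cell_float(row, "d34s", path, line, True),
                        cn_ratio=None if math.isnan(cn) else cn,
                    ),
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}, line {line}: {e}") from None
    return out


def read_consumers(path: str | Path) -> list[ConsumerSample]:
    """Read consumer blood samples; all three tracers are required,
    ``cn_ratio`` and ``body_weight_g`` are optional (blood is never
    lipid-corrected)."""
    path = Path(path)
    df = _read_table(path, ["bird_id", "d13c", "d15n", "d34s"])
    out = []
    for i, row in df.iterrows():
        line = int(i) + 2
        cn = _cell_float(row, "cn_ratio", path, line, True) if "cn_ratio" in df else math.nan
        bw = (
            _cell_float(row, "body_weight_g", path, line, True)
            if "body_weight_g" in df
            else math.nan
        )
        try:
            out.append(
                ConsumerSample(
                    bird_id=str(row["bird_id"]),
                    triplet=IsotopeTriplet(
                        d13c=_cell_float(row, "d13c", path, line, False),
                        d15n=_cell_float(row, "d15n", path, line, False),
                        d34s=_cell_float(row, "d34s", path, line, False),
                        cn_ratio=None if math.isnan(cn) else cn,
                    ),
                    body_weight=None if math.isnan(bw) else bw,
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}, line {line}: {e}") from None
    return out


def read_gut(path: str | Path) -> list[GutRecord]:
    path = Path(path)
    df = _read_table(path, ["bird_id", "taxon", "ww_g"])
    out = []
    for i, row in df.iterrows():
        line = int(i) + 2
        afdw = _cell_float(row, "afdw_g", path, line, True) if "afdw_g" in df else math.nan
        try:
            out.append(
                GutRecord(
                    bird_id=str(row["bird_id"]),
                    taxon=str(row["taxon"]),
                    ww_g=_cell_float(row, "ww_g", path, line, False),
                    afdw_g=None if math.isnan(afdw) else afdw,
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}, line {line}: {e}") from None
    return out


def write_sources(samples: Sequence[SourceSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "taxon": s.taxon,
            "group_id": s.group_id,
            "d13c": s.triplet.d13c,
            "d15n": s.triplet.d15n,
            "d34s": s.triplet.d34s,
            "cn_ratio": s.triplet.cn_ratio,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SOURCES_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_consumers(consumers: Sequence[ConsumerSample], path: str | Path) -> None:
    rows = [
        {
            "bird_id": c.bird_id,
            "d13c": c.triplet.d13c,
            "d15n": c.triplet.d15n,
            "d34s": c.triplet.d34s,
            "cn_ratio": c.triplet.cn_ratio,
            "body_weight_g": c.body_weight,
        }
        for c in consumers
    ]
    pd.DataFrame(rows, columns=CONSUMERS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_gut(records: Sequence[GutRecord], path: str | Path) -> None:
    rows = [
        {"bird_id": r.bird_id, "taxon": r.taxon, "ww_g": r.ww_g, "afdw_g": r.afdw_g}
        for r in records
    ]
    pd.DataFrame(rows, columns=GUT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def tef_table(tefs: TEFSet) -> pd.DataFrame:
    rows = []
    for gid, per_tracer in tefs.values.items():
        for tracer, (m, s) in per_tracer.items():
            rows.append(
                {"model_id": tefs.model_id, "group_id": gid, "tracer": tracer,
                 "tef_mean": m, "tef_sd": s}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run."""

    sources_csv: str
    consumers_csv: str
    gut_csv: str | None = None
    model_id: str = "model0"
    prior_modes: tuple[str, ...] = ("none",)
    taxon_mapping: Mapping[str, str] = field(
        default_factory=lambda: dict(study_data.DEFAULT_TAXON_MAPPING)
    )
    nitrogen_tef_sd: float = 0.01
    gate_n_iter: int = 1500
    gate_threshold: float = 0.05
    mcmc_iterations: int = 40_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 10
    prior_concentration: float | None = None
    prior_floor: float = 0.01
    residual_scale: float = 1.0
    n_birds: int | None = None
    seed: int = 0
    out_dir: str = "isodiet_out"
    round_pct_decimals: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "prior_modes" in raw:
            raw["prior_modes"] = tuple(raw["prior_modes"])
        return cls(**raw)


@dataclass
class PipelineResult:
    groups: list[SourceGroup]
    tefs: TEFSet
    inclusion: InclusionReport
    composition: DietComposition | None
    summaries: pd.DataFrame
    manifest: dict
    out_dir: Path


def _group_order(samples: Sequence[SourceSample]) -> list[str]:
    seen: list[str] = []
    for s in samples:
        if s.group_id not in seen:
            seen.append(s.group_id)
    return seen


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute prep → TEFs → polygon gate → mixing models → reports."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    gate_seed, mcmc_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))

    sources = read_sources(cfg.sources_csv)
    consumers = read_consumers(cfg.consumers_csv)
    groups = [
        summarize_group([s for s in sources if s.group_id == gid])
        for gid in _group_order(sources)
    ]
    tefs = build_tef_set(cfg.model_id, groups, nitrogen_sd=cfg.nitrogen_tef_sd)

    inclusion = validate_consumers(
        consumers,
        groups,
        tefs,
        n_iter=cfg.gate_n_iter,
        threshold=cfg.gate_threshold,
        seed=gate_seed,
    )
    retained = [c for c in consumers if inclusion.decisions[c.bird_id] == "retained"]
    if not retained:
        raise RuntimeError(
            "all consumers fall outside the 95% mixing region; the chosen "
            "TEF model cannot explain their isotopic signatures and "
            "alternative models are required"
        )
    logger.info(
        "polygon gate: %d retained, %d excluded",
        len(retained),
        len(consumers) - len(retained),
    )

    composition: DietComposition | None = None
    priors: dict[str, object] = {}
    source_ids = [g.group_id for g in groups]
    for mode in cfg.prior_modes:
        if mode == "none":
            priors["none"] = None
            continue
        if cfg.gut_csv is None:
            raise ValueError(f"prior mode {mode!r} requires a gut-content CSV")
        if composition is None:
            records = read_gut(cfg.gut_csv)
            n_birds = cfg.n_birds or len({r.bird_id for r in records})
            composition = diet_composition(records, n_birds=n_birds)
        priors[mode] = gut_priors(
            composition,
            cfg.taxon_mapping,
            source_ids,
            mode=mode,
            concentration=cfg.prior_concentration,
            floor=cfg.prior_floor,
        )

    spec = MixingModelSpec(
        groups=tuple(groups), tefs=tefs, residual_scale=cfg.residual_scale
    )
    mcmc = McmcConfig(
        iterations=cfg.mcmc_iterations,
        burn_in=cfg.mcmc_burn_in,
        thin=cfg.mcmc_thin,
        seed=mcmc_seed,
    )
    summaries = compare_prior_modes(retained, spec, priors, mcmc)

    # reports
    tef_table(tefs).to_csv(out_dir / "tef_table.csv", index=False)
    inclusion.table.assign(
        decision=inclusion.table["bird_id"].map(inclusion.decisions)
    ).to_csv(out_dir / "inclusion.csv", index=False)
    summaries.to_csv(out_dir / "posterior_summaries.csv", index=False)
    if composition is not None:
        composition.report().to_csv(out_dir / "composition.csv")

    failed_pairs = {
        b: inclusion.table.loc[
            (inclusion.table.bird_id == b)
            & (inclusion.table.probability < cfg.gate_threshold),
            "pair",
        ].tolist()
        for b in inclusion.excluded_ids()
    }
    manifest = {
        "isodiet_version": __version__,
        "seed": cfg.seed,
        "model_id": cfg.model_id,
        "prior_modes": list(cfg.prior_modes),
        "n_sources": len(sources),
        "n_groups": len(groups),
        "n_consumers": len(consumers),
        "n_retained": len(retained),
        "n_excluded": len(consumers) - len(retained),
        "excluded_by_pair": failed_pairs,
        "gate": {"n_iter": cfg.gate_n_iter, "threshold": cfg.gate_threshold},
        "mcmc": {
            "iterations": cfg.mcmc_iterations,
            "burn_in": cfg.mcmc_burn_in,
            "thin": cfg.mcmc_thin,
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return PipelineResult(
        groups=groups,
        tefs=tefs,
        inclusion=inclusion,
        composition=composition,
        summaries=summaries,
        manifest=manifest,
        out_dir=out_dir,
    )
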