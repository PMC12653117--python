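"""End-to-end orchestration: simulate or ingest a community, stratify by
guild, then run alpha diversity, zeta decline, Beals dark diversity and the
gated treatment comparison, writing a reproducible report bundle.

Given the same configuration and seed, every CSV/JSON output is
byte-identical between runs; the manifest records the configuration echo,
seeds and analysis decisions (quantile, reference-pool scope, unit levels)
so a run can be reproduced from the bundle alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_table
from .community import (
    GUILD_CODES,
    CommunityMatrix,
    GuildTable,
    aggregate_units,
    read_community,
    read_guilds,
    subset_by_guild,
    to_incidence,
    write_community,
    write_guilds,
)
from .dark import dark_diversity
from .inference import compare_groups
from .synthetic import SyntheticDesign, simulate_community
from .zeta import zeta_decline, zeta_ratios

log = logging.getLogger("meadowdiv")

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    # either explicit inputs ...
    matrix_path: str | None = None
    metadata_path: str | None = None
    guilds_path: str | None = None
    # ... or a synthetic design
    design: SyntheticDesign | None = None

    guilds: list[str] = field(default_factory=lambda: list(GUILD_CODES))
    unit_level_alpha: str = "transect"
    unit_level_zeta: str = "transect"
    unit_level_dark: str = "plot"
    zeta_max_order: int = 10
    zeta_mode: str = "exact"
    n_perm: int = 0
    dark_q: float = 0.01
    reference_scope: str = "pooled"  # "pooled" | "treatment"
    gate_alpha: float = 0.05
    alpha: float = 0.05
    outdir: str = "meadowdiv_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.matrix_path is not None and self.metadata_path is not None
        if not has_files and self.design is None:
            raise ValueError("config needs input paths or a synthetic design")
        if self.reference_scope not in ("pooled", "treatment"):
            raise ValueError("reference_scope must be 'pooled' or 'treatment'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        design = raw.pop("design", None)
        if design is not None:
            design = SyntheticDesign(**design)
        return cls(design=design, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def composition_summary(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-treatment abundance totals and percentage shares.

    Shares are 100 * total / grand total, rounded half-up to two
    decimals for presentation.
    """
    totals = (
        pd.Series(cm.counts.sum(axis=1), index=cm.unit_ids)
        .groupby(cm.metadata["treatment"], sort=False)
        .sum()
    )
    grand = int(totals.sum())
    shares = [
        float(Decimal(100 * int(t)) / Decimal(grand)) if grand else float("nan") for t in totals
    ]
    rounded = [
        float(Decimal(str(s)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) if grand else s
        for s in shares
    ]
    return pd.DataFrame(
        {"treatment": totals.index, "total": totals.to_numpy(), "share_pct": rounded}
    )


def _zeta_bundle(cm: CommunityMatrix, gt: GuildTable, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    agg = aggregate_units(cm, cfg.unit_level_zeta)
    for treat in agg.treatments:
        units = [u for u in agg.unit_ids if agg.metadata.loc[u, "treatment"] == treat]
        block = agg.select_units(units)
        for g in cfg.guilds:
            sub = subset_by_guild(block, gt, g)
            inc = to_incidence(sub)
            if inc.presence.sum() == 0:
                log.warning("empty stratum %s x %s; skipped", treat, g)
                continue
            max_order = min(cfg.zeta_max_order, inc.n_units)
            dec = zeta_decline(inc, max_order=max_order, mode="exact", seed=cfg.seed)
            ratios = np.append(zeta_ratios(dec), np.nan)
            for o, z, s, r in zip(dec.orders, dec.zeta, dec.sd, ratios):
                rows.append(
                    {"treatment": treat, "guild": g, "order": int(o), "zeta": z, "sd": s, "ratio": r}
                )
    return pd.DataFrame(rows)


def _dark_bundle(cm: CommunityMatrix, gt: GuildTable, cfg: PipelineConfig):
    pdd_rows, cci_rows, beals_rows = [], [], []
    dark_json: dict[str, dict[str, list[str]]] = {}
    scopes = (
        [("all", cm)]
        if cfg.reference_scope == "pooled"
        else [
            (t, cm.select_units([u for u in cm.unit_ids if cm.metadata.loc[u, "treatment"] == t]))
            for t in cm.treatments
        ]
    )
    for scope_label, scoped in scopes:
        for g in cfg.guilds:
            sub = subset_by_guild(scoped, gt, g)
            if sub.counts.sum() == 0:
                log.warning("guild %s empty in scope %s; flagged as missing", g, scope_label)
                continue
            res = dark_diversity(sub, level=cfg.unit_level_dark, q=cfg.dark_q)
            key = g if scope_label == "all" else f"{scope_label}:{g}"
            dark_json[key] = {u: sorted(s) for u, s in res.dark_sets.items() if s}
            p = res.pdd.assign(guild=g, scope=scope_label)
            pdd_rows.append(p)
            cci_rows.append(res.cci.assign(guild=g, scope=scope_label))
            bf = res.beals.to_frame()
            beals_rows.append(
                bf.rename_axis("unit")
                .reset_index()
                .melt(id_vars="unit", var_name="species", value_name="beals_p")
                .assign(guild=g, scope=scope_label)
            )
    cols = lambda frames: pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return cols(pdd_rows), cols(cci_rows), cols(beals_rows), dark_json


def _comparisons(alpha_df: pd.DataFrame, cci_df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    jobs = []
    for g, sub in alpha_df.groupby("guild", sort=False):
        for idx in ("MR", "H", "J", "D", "S"):
            jobs.append((f"alpha_{idx}", g, sub[idx].to_numpy(), sub["treatment"].to_numpy()))
    if not cci_df.empty:
        for g, sub in cci_df.groupby("guild", sort=False):
            jobs.append(("CCI", g, sub["CCI"].to_numpy(), sub["treatment"].to_numpy()))
    for response, g, vals, labels in jobs:
        try:
            res = compare_groups(
                vals, labels, alpha=cfg.alpha, gate_alpha=cfg.gate_alpha, response=response
            )
        except ValueError as exc:
            log.warning("comparison %s/%s skipped: %s", response, g, exc)
            continue
        rows.append(
            {
                "response": response,
                "guild": g,
                "route": res.route,
                "homogeneity_p": res.homogeneity_p,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "letters": ";".join(f"{k}:{v}" for k, v in res.letters.items()),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig):
    """Execute every stage and write the report bundle to ``config.outdir``.

    Any stage failure aborts the run with the stage named and removes the
    partial outputs already written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)

    def save_json(obj, name: str) -> None:
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(path)

    stage = "input"
    try:
        truth = None
        if config.design is not None:
            cm, gt, truth = simulate_community(config.design)
            write_community(cm, outdir / "matrix.csv", outdir / "metadata.csv")
            write_guilds(gt, outdir / "guilds.csv")
            written += [outdir / "matrix.csv", outdir / "metadata.csv", outdir / "guilds.csv"]
            save_json(
                {
                    "withheld": sorted(map(list, truth.withheld)),
                    "pools": {t: sorted(p) for t, p in truth.pools.items()},
                    "occupancy_class": truth.occupancy_class,
                },
                "truth.json",
            )
        else:
            cm = read_community(config.matrix_path, config.metadata_path)
            gt = read_guilds(config.guilds_path)
        gt.check_covers(cm.species_ids)

        stage = "composition"
        comp = composition_summary(cm)
        save_csv(comp, "composition.csv")

        stage = "alpha"
        adf = alpha_table(aggregate_units(cm, config.unit_level_alpha), gt, config.guilds)
        save_csv(adf, "alpha_table.csv")

        stage = "zeta"
        zdf = _zeta_bundle(cm, gt, config)
        save_csv(zdf, "zeta_decline.csv")

        stage = "dark"
        pdd_df, cci_df, beals_df, dark_json = _dark_bundle(cm, gt, config)
        save_csv(pdd_df, "pdd.csv")
        save_csv(cci_df, "cci.csv")
        save_csv(beals_df, "beals.csv")
        save_json(dark_json, "dark_sets.json")

        stage = "compare"
        cdf = _comparisons(adf, cci_df, config)
        save_csv(cdf, "comparisons.csv")

        stage = "manifest"
        manifest = {
            "package": "meadowdiv",
            "version": __version__,
            "config": config.to_dict(),
            "decisions": {
                "dark_quantile_q": config.dark_q,
                "reference_scope": config.reference_scope,
                "unit_levels": {
                    "alpha": config.unit_level_alpha,
                    "zeta": config.unit_level_zeta,
                    "dark": config.unit_level_dark,
                },
                "gate_alpha": config.gate_alpha,
            },
            "seed": config.seed,
        }
        save_json(manifest, "manifest.json")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("pipeline complete: %d artifacts in %s", len(written), outdir)
    return {
        "outdir": outdir,
        "community": cm,
        "guilds": gt,
        "truth": truth,
        "composition": comp,
        "alpha": adf,
        "zeta": zdf,
        "pdd": pdd_df,
        "cci": cci_df,
        "comparisons": cdf,
    }
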