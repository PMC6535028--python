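"""CSV readers/writers, run configuration and the end-to-end pipeline.

Sample CSV schema (one row per observation, ISO-8601 dates, UTF-8):

    river,date,analyte,delta14c_permil,delta13c_permil,flux_mgC_per_s

Seasons are always derived from the date, never trusted from a file. Rows
with a missing Δ¹⁴C are skipped (the count is logged); rows with an unknown
river, unparseable date, out-of-range Δ¹⁴C or unknown analyte are reported
per row, and the whole file is rejected when more than 10% of rows are bad.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apportionment import (
    MCMCConfig,
    PosteriorFraction,
    RiverSample,
    apportion,
    apportion_each,
    combine_posteriors,
)
from .endmembers import (
    RIVERS,
    default_pools,
    load_pools,
    recent_pool,
    scenario_endmember,
)
from .flux_partition import FluxTable, carrier_and_season_shares, ppc_flux
from .sensitivity import minimum_resolvable_change, sensitivity_table

logger = logging.getLogger("fluvial14c")

__all__ = [
    "SAMPLE_COLUMNS",
    "read_samples",
    "write_samples",
    "RunConfig",
    "run_pipeline",
    "PipelineResult",
]

SAMPLE_COLUMNS = [
    "river", "date", "analyte", "delta14c_permil", "delta13c_permil",
    "flux_mgC_per_s",
]

MAX_BAD_ROW_FRACTION = 0.10


def read_samples(path: "str | Path") -> list[RiverSample]:
    """Read and validate a sample CSV; see the module docstring for rules."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(SAMPLE_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {sorted(missing_cols)}")
    samples: list[RiverSample] = []
    errors: list[str] = []
    skipped_missing = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        d14_raw = getattr(row, "delta14c_permil", "").strip()
        if d14_raw == "":
            skipped_missing += 1
            continue
        try:
            river = row.river.strip()
            if river not in RIVERS:
                raise ValueError(f"unknown river {river!r}")
            date = _dt.date.fromisoformat(row.date.strip())
            analyte = row.analyte.strip()
            delta14c = float(d14_raw)
            if not delta14c > -1000.0:
                raise ValueError(f"delta14c {delta14c}‰ at or below the -1000‰ bound")
            d13_raw = str(getattr(row, "delta13c_permil", "")).strip()
            delta13c = float(d13_raw) if d13_raw else None
            w_raw = str(getattr(row, "flux_mgC_per_s", "")).strip()
            weight = float(w_raw) if w_raw else 1.0
            samples.append(RiverSample(river, date, analyte, delta14c,
                                       delta13c, weight))
        except (ValueError, TypeError) as err:
            errors.append(f"row {idx}: {err}")
    if skipped_missing:
        logger.info("%s: skipped %d rows with missing delta14c", path, skipped_missing)
    if errors:
        n_considered = len(df) - skipped_missing
        if n_considered and len(errors) / n_considered > MAX_BAD_ROW_FRACTION:
            raise ValueError(
                f"{path}: {len(errors)}/{n_considered} rows invalid "
                f"(> {MAX_BAD_ROW_FRACTION:.0%}):\n" + "\n".join(errors)
            )
        for msg in errors:
            logger.warning("%s: %s (row dropped)", path, msg)
    return samples


def write_samples(samples: "list[RiverSample]", path: "str | Path") -> None:
    rows = [
        {
            "river": s.river,
            "date": s.date.isoformat(),
            "analyte": s.analyte,
            "delta14c_permil": s.delta14c,
            "delta13c_permil": "" if s.delta13c is None else s.delta13c,
            "flux_mgC_per_s": s.flux_weight,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    samples_csv: str
    output_dir: str
    flux_table_csv: str | None = None
    endmember_db: str | None = None  # YAML; defaults to the built-in pools
    scenario: str = "best_estimate"
    seed: int = 0
    obs_sd: float = 10.0
    scaled_down: bool = False
    granularity: str = "sample"  # "sample" or "group"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    endmember_draws: int = 100_000
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        if self.granularity not in ("sample", "group"):
            raise ValueError("granularity must be 'sample' or 'group'")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "mcmc"}
        d["mcmc"] = {
            "iterations": self.mcmc.iterations, "burn_in": self.mcmc.burn_in,
            "thinning": self.mcmc.thinning, "seed": self.mcmc.seed,
            "proposal_sd": self.mcmc.proposal_sd,
        }
        return d

    def effective_mcmc(self) -> MCMCConfig:
        cfg = self.mcmc.scaled_down() if self.scaled_down else self.mcmc
        return MCMCConfig(cfg.iterations, cfg.burn_in, cfg.thinning,
                          self.seed, cfg.proposal_sd)


@dataclass
class PipelineResult:
    posteriors: pd.DataFrame
    group_fractions: pd.DataFrame
    ppc_fluxes: pd.DataFrame | None
    shares: pd.DataFrame | None
    sensitivity: pd.DataFrame | None
    manifest: dict


def _manifest(config: RunConfig) -> dict:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "package": "fluvial14c",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(payload).hexdigest(),
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Endmembers → apportionment → flux partition → sensitivity, with all
    outputs written as CSV plus a machine-readable run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)

    try:
        samples = read_samples(config.samples_csv)
    except Exception as err:
        raise RuntimeError(f"stage read_samples failed: {err}") from err
    if not samples:
        raise RuntimeError("stage read_samples failed: no usable samples")

    pools = load_pools(config.endmember_db) if config.endmember_db else default_pools()
    recent = recent_pool(pools)
    rivers = sorted({s.river for s in samples})
    rng = np.random.default_rng(config.seed)
    ppc_by_river = {
        river: scenario_endmember(river, config.scenario,
                                  n_draws=config.endmember_draws, pools=pools, rng=rng)
        for river in rivers
    }

    mcmc = config.effective_mcmc()
    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault((s.river, s.season, s.analyte), []).append(i)

    post_rows = []
    group_rows = []
    group_posteriors: dict[tuple[str, str, str], PosteriorFraction] = {}
    sample_posteriors: list[PosteriorFraction | None] = [None] * len(samples)
    try:
        for key in sorted(groups):
            river, season, analyte = key
            members = [samples[i] for i in groups[key]]
            weights = [s.flux_weight for s in members]
            label = f"{river}/{season}/{analyte}"
            if config.granularity == "group":
                gp = apportion(members, recent, ppc_by_river[river], mcmc,
                               config.obs_sd, target_id=label)
            else:
                posts = apportion_each(members, recent, ppc_by_river[river],
                                       mcmc, config.obs_sd)
                for i, p in zip(groups[key], posts):
                    sample_posteriors[i] = p
                    s = samples[i]
                    lo, hi = p.credible_interval()
                    post_rows.append({
                        "river": s.river, "date": s.date.isoformat(),
                        "season": s.season, "analyte": s.analyte,
                        "delta14c_permil": s.delta14c,
                        "flux_mgC_per_s": s.flux_weight,
                        "f_mean": p.mean, "f_sd": p.sd,
                        "f_ci_low": lo, "f_ci_high": hi,
                        "acceptance_rate": p.acceptance_rate,
                    })
                gp = combine_posteriors(posts, weights, label,
                                        seed=int(rng.integers(2**31)))
            group_posteriors[key] = gp
            lo, hi = gp.credible_interval()
            group_rows.append({
                "river": river, "season": season, "analyte": analyte,
                "n_samples": len(members), "f_mean": gp.mean, "f_sd": gp.sd,
                "f_ci_low": lo, "f_ci_high": hi,
            })
    except Exception as err:
        raise RuntimeError(f"stage apportion failed: {err}") from err

    posteriors_df = pd.DataFrame(post_rows)
    group_df = pd.DataFrame(group_rows)

    flux_df = shares_df = None
    if config.flux_table_csv:
        try:
            fluxes = FluxTable.from_csv(config.flux_table_csv)
            estimates = ppc_flux(group_posteriors, fluxes,
                                 seed=int(rng.integers(2**31)))
            flux_df = estimates.by_river()
            shares = carrier_and_season_shares(estimates)
            shares_df = pd.DataFrame(
                [{"kind": "carrier_ppc", "scope": k, "share_pct": v[0], "share_sd_pct": v[1]}
                 for k, v in shares.carrier.items()]
                + [{"kind": "seasonal_ppc", "scope": k, "share_pct": v[0], "share_sd_pct": v[1]}
                   for k, v in shares.ppc_seasonal.items()]
                + [{"kind": "seasonal_recent", "scope": k, "share_pct": v[0], "share_sd_pct": v[1]}
                   for k, v in shares.recent_seasonal.items()]
            )
        except Exception as err:
            raise RuntimeError(f"stage flux_partition failed: {err}") from err

    sens_df = None
    if config.run_sensitivity:
        try:
            rows = []
            for river in rivers:
                ppc_mean = ppc_by_river[river].summary_mean
                for analyte in ("DOC", "POC"):
                    members = [s for s in samples
                               if s.river == river and s.analyte == analyte]
                    if len(members) < 2:
                        continue
                    if config.granularity == "sample":
                        posts = [sample_posteriors[i] for i, s in enumerate(samples)
                                 if s.river == river and s.analyte == analyte]
                    else:
                        posts = [group_posteriors[(s.river, s.season, s.analyte)]
                                 for s in members]
                    mrc = minimum_resolvable_change(
                        members, posts, recent.delta14c_mean, ppc_mean)
                    rows.append({
                        "river": river, "analyte": analyte,
                        "n_samples": len(members),
                        "min_resolvable_increase_pct":
                            np.nan if mrc is None else mrc,
                        "resolvable": mrc is not None,
                    })
            sens_df = pd.DataFrame(rows)
            table = sensitivity_table(
                [0.5, 0.75, 1.25, 1.5, 2.0], recent.delta14c_mean,
                ppc_by_river[rivers[0]].summary_mean)
            table.to_csv(outdir / "sensitivity_curves.csv", index=False)
        except Exception as err:
            raise RuntimeError(f"stage sensitivity failed: {err}") from err

    if not posteriors_df.empty:
        posteriors_df.to_csv(outdir / "posteriors.csv", index=False)
    group_df.to_csv(outdir / "group_fractions.csv", index=False)
    if flux_df is not None:
        flux_df.to_csv(outdir / "ppc_fluxes.csv", index=False)
        shares_df.to_csv(outdir / "shares.csv", index=False)
    if sens_df is not None:
        sens_df.to_csv(outdir / "sensitivity.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(posteriors_df, group_df, flux_df, shares_df,
                          sens_df, manifest)
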