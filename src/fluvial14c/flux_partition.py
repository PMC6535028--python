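"""Partition total DOC/POC export fluxes into PP-C and recent components.

Total seasonal carbon fluxes per river (regression-based load estimates,
consumed as inputs with mean ± SD) are combined with the posterior PP-C
fractions by Monte Carlo: in each replicate a fraction is drawn from the
posterior and a flux from a zero-truncated Normal, and their product gives
the PP-C flux of that river × season × analyte cell. Sums, shares by
carrier phase (DOC vs POC) and shares by season are formed within each
replicate, so every replicate's shares sum to exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .apportionment import SEASONS, PosteriorFraction

__all__ = [
    "FluxTable",
    "PPCFluxEstimate",
    "PPCFluxEstimates",
    "SharesSummary",
    "ppc_flux",
    "carrier_and_season_shares",
    "TABLE1_PUBLISHED",
]

CellKey = tuple[str, str, str]  # (river, season, analyte)

#: Published four-river benchmark (Tg C y⁻¹): total organic carbon flux and
#: PP-C flux under the three scenarios, as (mean, sd). Reference values for
#: comparison with new runs of the pipeline.
TABLE1_PUBLISHED: dict[str, dict[str, tuple[float, float]]] = {
    "Ob": {"total": (4.7, 0.7), "best_estimate": (1.2, 0.2), "minimum": (0.9, 0.1), "maximum": (1.8, 0.3)},
    "Yenisey": {"total": (4.9, 0.4), "best_estimate": (0.7, 0.2), "minimum": (0.5, 0.1), "maximum": (1.1, 0.2)},
    "Lena": {"total": (6.5, 1.0), "best_estimate": (0.9, 0.2), "minimum": (0.5, 0.1), "maximum": (1.7, 0.3)},
    "Kolyma": {"total": (0.9, 0.2), "best_estimate": (0.2, 0.0), "minimum": (0.1, 0.0), "maximum": (0.3, 0.1)},
    "All rivers": {"total": (17.0, 1.3), "best_estimate": (3.0, 0.3), "minimum": (2.0, 0.2), "maximum": (5.0, 0.5)},
}


@dataclass
class FluxTable:
    """Total carbon fluxes by river × season × analyte, mean ± SD in Tg C."""

    entries: dict[CellKey, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (mean, sd) in self.entries.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"negative flux mean/sd for cell {key}")

    @property
    def cells(self) -> list[CellKey]:
        return list(self.entries)

    def mean(self, key: CellKey) -> float:
        return self.entries[key][0]

    def total_mean(self) -> float:
        return sum(m for m, _ in self.entries.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FluxTable":
        required = {"river", "season", "analyte", "flux_Tg", "flux_sd_Tg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"flux table missing columns: {sorted(missing)}")
        entries = {
            (str(r.river), str(r.season), str(r.analyte)): (float(r.flux_Tg), float(r.flux_sd_Tg))
            for r in df.itertuples()
        }
        if len(entries) != len(df):
            raise ValueError("duplicate river/season/analyte cells in flux table")
        return cls(entries)

    @classmethod
    def from_csv(cls, path: "str | Path") -> "FluxTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"river": k[0], "season": k[1], "analyte": k[2],
             "flux_Tg": v[0], "flux_sd_Tg": v[1]}
            for k, v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: "str | Path") -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PPCFluxEstimate:
    """PP-C flux summary for one scope (cell, river, analyte or aggregate)."""

    scope: str
    ppc_flux_mean: float  # Tg C y⁻¹ (or per season, per the scope)
    ppc_flux_sd: float
    share_of_total: float  # % of the total organic carbon flux in scope


@dataclass
class PPCFluxEstimates:
    """Replicate-level PP-C flux partition for a set of flux cells."""

    replicates: dict[CellKey, np.ndarray] = field(repr=False)  # PP-C Tg per replicate
    flux_replicates: dict[CellKey, np.ndarray] = field(repr=False)  # total Tg
    n_mc: int

    def _select(self, river=None, season=None, analyte=None) -> list[CellKey]:
        keys = [
            k for k in self.replicates
            if (river is None or k[0] == river)
            and (season is None or k[1] == season)
            and (analyte is None or k[2] == analyte)
        ]
        if not keys:
            raise KeyError(
                f"no flux cells match river={river!r} season={season!r} analyte={analyte!r}"
            )
        return keys

    def _sum(self, keys: Sequence[CellKey], which: str = "ppc") -> np.ndarray:
        source = self.replicates if which == "ppc" else self.flux_replicates
        return np.sum([source[k] for k in keys], axis=0)

    def estimate(self, river=None, season=None, analyte=None) -> PPCFluxEstimate:
        """Summed PP-C flux (mean ± SD over replicates) for a scope."""
        keys = self._select(river, season, analyte)
        ppc = self._sum(keys, "ppc")
        tot = self._sum(keys, "total")
        scope = ",".join(x or "all" for x in (river, season, analyte))
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot > 0, ppc / tot, 0.0)
        return PPCFluxEstimate(
            scope, float(ppc.mean()), float(ppc.std(ddof=1)),
            float(share.mean() * 100.0),
        )

    def by_river(self) -> pd.DataFrame:
        """Annual per-river and all-rivers PP-C fluxes (Table-1-style)."""
        rivers = sorted({k[0] for k in self.replicates})
        rows = []
        for river in rivers:
            est = self.estimate(river=river)
            rows.append({"river": river, "ppc_flux_Tg": est.ppc_flux_mean,
                         "ppc_flux_sd_Tg": est.ppc_flux_sd,
                         "share_of_total_pct": est.share_of_total})
        total = self.estimate()
        rows.append({"river": "All rivers", "ppc_flux_Tg": total.ppc_flux_mean,
                     "ppc_flux_sd_Tg": total.ppc_flux_sd,
                     "share_of_total_pct": total.share_of_total})
        return pd.DataFrame(rows)


def ppc_flux(
    fractions: Mapping[CellKey, PosteriorFraction],
    fluxes: FluxTable,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> PPCFluxEstimates:
    """Monte-Carlo PP-C flux partition.

    For every flux cell a posterior fraction draw and a zero-truncated
    Normal flux draw are multiplied per replicate. Raises if any flux cell
    lacks a matching posterior.
    """
    missing = [k for k in fluxes.cells if k not in fractions]
    if missing:
        raise KeyError(f"no posterior fraction for flux cells: {missing}")
    rng = np.random.default_rng(seed)
    reps: dict[CellKey, np.ndarray] = {}
    flux_reps: dict[CellKey, np.ndarray] = {}
    for key in fluxes.cells:
        mean, sd = fluxes.entries[key]
        if sd == 0.0:
            flux = np.full(n_mc, mean)
        else:
            a = (0.0 - mean) / sd
            flux = _sstats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                         size=n_mc, random_state=rng)
        post = fractions[key]
        f = post.draws[rng.integers(0, post.draws.size, n_mc)]
        reps[key] = f * flux
        flux_reps[key] = flux
    return PPCFluxEstimates(reps, flux_reps, n_mc)


@dataclass(frozen=True)
class SharesSummary:
    """Carrier-phase and seasonal shares of PP-C and recent carbon, in %."""

    carrier: dict[str, tuple[float, float]]  # analyte -> (mean, sd) % of PP-C
    ppc_seasonal: dict[str, tuple[float, float]]  # season -> (mean, sd) %
    recent_seasonal: dict[str, tuple[float, float]]


def carrier_and_season_shares(estimates: PPCFluxEstimates) -> SharesSummary:
    """Shares of PP-C export by carrier phase and season (replicate-wise).

    Shares are computed inside each Monte-Carlo replicate (so they sum to
    100% exactly) and then summarised as mean ± SD across replicates. The
    recent-carbon flux of a cell is its total flux minus its PP-C flux.
    """
    keys = list(estimates.replicates)
    analytes = sorted({k[2] for k in keys})
    seasons = [s for s in SEASONS if any(k[1] == s for k in keys)]
    if len(analytes) < 2:
        raise ValueError("carrier shares need both DOC and POC flux cells")
    if len(seasons) < len(SEASONS):
        raise ValueError(f"seasonal shares need all seasons; found {seasons}")

    total_ppc = estimates._sum(keys, "ppc")
    total_recent = estimates._sum(keys, "total") - total_ppc

    def _share(sub_keys, denom, which):
        num = estimates._sum(sub_keys, "ppc")
        if which == "recent":
            num = estimates._sum(sub_keys, "total") - num
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(denom > 0, num / denom * 100.0, 0.0)
        return float(s.mean()), float(s.std(ddof=1))

    carrier = {
        a: _share([k for k in keys if k[2] == a], total_ppc, "ppc") for a in analytes
    }
    ppc_seasonal = {
        s: _share([k for k in keys if k[1] == s], total_ppc, "ppc") for s in seasons
    }
    recent_seasonal = {
        s: _share([k for k in keys if k[1] == s], total_recent, "recent")
        for s in seasons
    }
    return SharesSummary(carrier, ppc_seasonal, recent_seasonal)
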