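"""Organic-carbon source pools and composite permafrost/peat (PP-C) endmembers.

Four terrestrial source pools supply organic carbon to the large Siberian
rivers: recent primary production (litter and organic layers), the
seasonally thawed active layer, Holocene permafrost/peat/thermokarst
deposits, and Pleistocene Ice Complex (Yedoma) deposits. Each pool carries
a literature-constrained Δ¹⁴C mean ± SD.

Apportionment distinguishes two endmembers only: recent carbon versus the
combined PP-C pool. The PP-C endmember distribution is built per scenario:

* ``best_estimate`` — all plausible PP-C compartments contribute, with all
  fractional combinations equally likely (flat Dirichlet weights on the
  simplex). This keeps the mean at the arithmetic mean of the pool means
  while inflating the spread with compositional uncertainty. Pleistocene
  deposits enter only for the Lena and Kolyma, where Ice Complex deposits
  are abundant.
* ``maximum`` — only the youngest compartment (active layer) contributes,
  maximising the inferred PP-C fraction.
* ``minimum`` — only the oldest compartment contributes (Holocene deposits
  for Ob/Yenisey, Pleistocene deposits for Lena/Kolyma).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SourcePool",
    "ScenarioSpec",
    "CompositeEndmember",
    "RIVERS",
    "RECENT_POOL_NAME",
    "default_pools",
    "recent_pool",
    "pools_by_name",
    "default_scenarios",
    "composite_ppc_endmember",
    "composite_moments",
    "scenario_endmember",
    "load_pools",
    "write_pools",
]

RIVERS: tuple[str, ...] = ("Ob", "Yenisey", "Lena", "Kolyma")

RECENT_POOL_NAME = "recent_production"
PPC_POOL_NAMES = ("active_layer", "holocene_deposits", "pleistocene_deposits")

#: Physical lower bound of the Δ¹⁴C scale: −1000‰ means no ¹⁴C left.
DELTA14C_FLOOR = -1000.0


@dataclass(frozen=True)
class SourcePool:
    """One endmember carbon source with its Δ¹⁴C (and optional δ¹³C) signature."""

    name: str
    delta14c_mean: float  # ‰
    delta14c_sd: float  # ‰
    n: int
    delta13c_mean: float | None = None  # ‰ (stored, not used in apportionment)
    delta13c_sd: float | None = None

    def __post_init__(self) -> None:
        if self.delta14c_sd <= 0:
            raise ValueError(f"pool {self.name!r}: delta14c_sd must be > 0")
        if self.n < 1:
            raise ValueError(f"pool {self.name!r}: n must be >= 1")
        if self.delta14c_mean <= DELTA14C_FLOOR:
            raise ValueError(f"pool {self.name!r}: delta14c_mean must exceed -1000‰")

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Normal Δ¹⁴C draws.

        The Normal is left untruncated: truncating the Pleistocene pool at
        the −1000‰ floor would raise its mean by ≈27‰ and break the defining
        property that the composite mean equals the arithmetic mean of the
        pool means. A small tail of draws below −1000‰ (<25% of the
        Pleistocene pool, far less after compositing) is accepted as part of
        the endmember uncertainty model.
        """
        return rng.normal(self.delta14c_mean, self.delta14c_sd, n_draws)


def default_pools() -> list[SourcePool]:
    """The four literature-constrained source pools."""
    return [
        SourcePool(RECENT_POOL_NAME, 97.0, 124.8, 58, -27.7, 1.3),
        SourcePool("active_layer", -197.5, 148.4, 60, -26.4, 0.8),
        SourcePool("holocene_deposits", -567.5, 156.7, 138),
        SourcePool("pleistocene_deposits", -954.8, 65.8, 329, -26.3, 0.7),
    ]


def pools_by_name(pools: Iterable[SourcePool] | None = None) -> dict[str, SourcePool]:
    return {p.name: p for p in (pools if pools is not None else default_pools())}


def recent_pool(pools: Iterable[SourcePool] | None = None) -> SourcePool:
    return pools_by_name(pools)[RECENT_POOL_NAME]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which PP-C pools contribute to the composite endmember, per river."""

    name: str
    pools_by_river: Mapping[str, tuple[str, ...]]

    def pools_for(self, river: str) -> tuple[str, ...]:
        try:
            return tuple(self.pools_by_river[river])
        except KeyError:
            raise KeyError(
                f"unknown river {river!r}; expected one of {RIVERS}"
            ) from None


def default_scenarios() -> dict[str, ScenarioSpec]:
    west = ("Ob", "Yenisey")
    east = ("Lena", "Kolyma")
    best = {r: ("active_layer", "holocene_deposits") for r in west}
    best |= {r: ("active_layer", "holocene_deposits", "pleistocene_deposits") for r in east}
    minimum = {r: ("holocene_deposits",) for r in west}
    minimum |= {r: ("pleistocene_deposits",) for r in east}
    maximum = {r: ("active_layer",) for r in RIVERS}
    return {
        "best_estimate": ScenarioSpec("best_estimate", best),
        "minimum": ScenarioSpec("minimum", minimum),
        "maximum": ScenarioSpec("maximum", maximum),
    }


@dataclass
class CompositeEndmember:
    """Monte-Carlo sample of the combined PP-C Δ¹⁴C distribution."""

    draws: np.ndarray
    pools: tuple[str, ...]
    summary_mean: float
    summary_sd: float

    @classmethod
    def from_draws(cls, draws: np.ndarray, pools: Sequence[str]) -> "CompositeEndmember":
        draws = np.asarray(draws, dtype=float)
        return cls(draws, tuple(pools), float(draws.mean()), float(draws.std(ddof=1)))


def composite_moments(pools: Sequence[SourcePool]) -> tuple[float, float]:
    """Closed-form mean and SD of the flat-Dirichlet composite (no truncation).

    With weights φ ~ Dirichlet(1,…,1) over k pools and independent pool draws
    Xₖ ~ N(μₖ, σₖ), the composite Σφₖ Xₖ has mean μ̄ = (Σμₖ)/k and variance
    E[Σφₖ²(σₖ²+μₖ²) + Σ_{j≠k} φⱼφₖ μⱼμₖ] − μ̄², using E[φₖ²] = 2/(k(k+1))
    and E[φⱼφₖ] = 1/(k(k+1)).
    """
    k = len(pools)
    mu = np.array([p.delta14c_mean for p in pools])
    sig = np.array([p.delta14c_sd for p in pools])
    mean = float(mu.mean())
    c = 1.0 / (k * (k + 1.0))
    second = 2.0 * c * np.sum(sig**2 + mu**2) + c * (np.sum(mu) ** 2 - np.sum(mu**2))
    var = float(second - mean**2)
    return mean, float(np.sqrt(var))


def composite_ppc_endmember(
    pools: Sequence[SourcePool],
    n_draws: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CompositeEndmember:
    """Monte-Carlo composite PP-C endmember under equally likely compositions.

    Each draw takes fractional pool contributions φ uniform on the simplex
    (flat Dirichlet) and pool Δ¹⁴C realisations from the Normal pool
    distributions, returning Σφₖ·Xₖ. A single pool reduces to that pool's
    own distribution.
    """
    pools = list(pools)
    if not 1 <= len(pools) <= 3:
        raise ValueError("composite endmember needs between 1 and 3 pools")
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10,000")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.column_stack([p.sample(n_draws, rng) for p in pools])
    if len(pools) == 1:
        draws = x[:, 0]
    else:
        phi = rng.dirichlet(np.ones(len(pools)), size=n_draws)
        draws = np.sum(phi * x, axis=1)
    return CompositeEndmember.from_draws(draws, [p.name for p in pools])


def scenario_endmember(
    river: str,
    scenario: "str | ScenarioSpec" = "best_estimate",
    n_draws: int = 100_000,
    seed: int | None = None,
    pools: Iterable[SourcePool] | None = None,
    rng: np.random.Generator | None = None,
) -> CompositeEndmember:
    """Composite PP-C endmember for a river under a named scenario."""
    if isinstance(scenario, str):
        try:
            scenario = default_scenarios()[scenario]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario!r}; expected one of "
                f"{sorted(default_scenarios())}"
            ) from None
    by_name = pools_by_name(pools)
    members = [by_name[name] for name in scenario.pools_for(river)]
    return composite_ppc_endmember(members, n_draws=n_draws, seed=seed, rng=rng)


# ---------------------------------------------------------------------------
# Endmember database I/O (user-editable YAML)
# ---------------------------------------------------------------------------

def load_pools(path: "str | Path") -> list[SourcePool]:
    """Load an endmember database from YAML.

    Schema: a list of mappings with keys ``name``, ``delta14c_mean``,
    ``delta14c_sd``, ``n`` and optional ``delta13c_mean``, ``delta13c_sd``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError("endmember database must be a YAML list of pools")
    pools = [SourcePool(**entry) for entry in raw]
    names = {p.name for p in pools}
    if RECENT_POOL_NAME not in names:
        raise ValueError(f"endmember database must include {RECENT_POOL_NAME!r}")
    return pools


def write_pools(pools: Sequence[SourcePool], path: "str | Path") -> None:
    rows = []
    for p in pools:
        row = {
            "name": p.name,
            "delta14c_mean": p.delta14c_mean,
            "delta14c_sd": p.delta14c_sd,
            "n": p.n,
        }
        if p.delta13c_mean is not None:
            row["delta13c_mean"] = p.delta13c_mean
            row["delta13c_sd"] = p.delta13c_sd
        rows.append(row)
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)
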