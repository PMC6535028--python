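"""Bayesian MCMC apportionment of the permafrost/peat fraction f.

Each river observation mixes two endmembers on the Δ¹⁴C scale:

    Δ_obs ~ Normal(f·Δ_pp + (1 − f)·Δ_rec, σ_obs),   f ~ Uniform(0, 1)

where Δ_rec is the recent-production endmember and Δ_pp the composite PP-C
endmember. Endmember variability is marginalised by redrawing both
endmember values from their distributions at every Metropolis–Hastings
iteration; f is updated with a Gaussian random walk reflected at the [0,1]
boundaries. With degenerate (fixed) endmembers the sampler reduces to exact
MH on f alone.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .endmembers import CompositeEndmember, SourcePool

logger = logging.getLogger("fluvial14c")

__all__ = [
    "RiverSample",
    "MCMCConfig",
    "PosteriorFraction",
    "SEASONS",
    "assign_season",
    "apportion",
    "apportion_each",
    "aggregate_fractions",
    "combine_posteriors",
]

SEASONS: tuple[str, ...] = ("spring", "summer_fall", "winter")

#: Default observation (AMS measurement) uncertainty on Δ¹⁴C, ‰.
DEFAULT_OBS_SD = 10.0


def assign_season(date: _dt.date) -> str:
    """Season of a sampling date: May–Jun spring (ice breakup), Jul–Oct
    summer/fall (ice-free), Nov–Apr winter (ice-covered)."""
    if date.month in (5, 6):
        return "spring"
    if 7 <= date.month <= 10:
        return "summer_fall"
    return "winter"


@dataclass(frozen=True)
class RiverSample:
    """One DOC or POC observation with isotopes and its flux weight."""

    river: str
    date: _dt.date
    analyte: str  # "DOC" or "POC"
    delta14c: float  # ‰
    delta13c: float | None = None  # ‰
    flux_weight: float = 1.0  # carbon flux at sampling, e.g. mg C s⁻¹

    def __post_init__(self) -> None:
        if self.analyte not in ("DOC", "POC"):
            raise ValueError(f"analyte must be DOC or POC, got {self.analyte!r}")
        if not self.delta14c > -1000.0:
            raise ValueError("delta14c must exceed the physical bound of -1000‰")
        if self.flux_weight < 0:
            raise ValueError("flux_weight must be nonnegative")

    @property
    def season(self) -> str:
        return assign_season(self.date)

    @property
    def collection_year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis–Hastings settings (defaults follow the full-scale run)."""

    iterations: int = 1_000_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int | None = None
    proposal_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")

    def scaled_down(self, iterations: int = 100_000) -> "MCMCConfig":
        """A desk-scale variant with fewer iterations (same burn-in/thinning)."""
        iterations = min(iterations, self.iterations)
        return MCMCConfig(
            iterations=iterations,
            burn_in=min(self.burn_in, iterations // 10),
            thinning=self.thinning,
            seed=self.seed,
            proposal_sd=self.proposal_sd,
        )


@dataclass
class PosteriorFraction:
    """Retained MCMC draws of the PP-C fraction f for one target."""

    target: str
    draws: np.ndarray
    acceptance_rate: float = math.nan

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size == 0:
            raise ValueError("posterior must contain at least one draw")
        if np.any((self.draws < 0) | (self.draws > 1)):
            raise ValueError("fraction draws must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1)) if self.draws.size > 1 else 0.0

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.draws, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    @classmethod
    def point_mass(cls, target: str, f: float, size: int = 1000) -> "PosteriorFraction":
        """Degenerate posterior concentrated at a single fraction (for toys)."""
        return cls(target, np.full(size, float(f)))


def _reflect(f: float) -> float:
    # fold a random-walk proposal back into [0, 1]
    while f < 0.0 or f > 1.0:
        if f < 0.0:
            f = -f
        if f > 1.0:
            f = 2.0 - f
    return f


def apportion(
    target: "RiverSample | Sequence[RiverSample] | float | Sequence[float]",
    recent: SourcePool,
    ppc: CompositeEndmember,
    config: MCMCConfig = MCMCConfig(),
    obs_sd: float = DEFAULT_OBS_SD,
    target_id: str | None = None,
) -> PosteriorFraction:
    """Posterior PP-C fraction for one observation or a pooled group.

    ``target`` may be a single :class:`RiverSample`, a list of samples that
    share an endmember context (pooled in one likelihood with a common f),
    or raw Δ¹⁴C value(s) in ‰.
    """
    if obs_sd <= 0:
        raise ValueError("obs_sd must be > 0")
    obs, label = _extract_observations(target, target_id)
    if obs.size == 0:
        raise ValueError("no observations to apportion")
    if not np.all(np.isfinite(obs)):
        raise ValueError(f"non-finite Δ¹⁴C observation for target {label!r}")

    rng = np.random.default_rng(config.seed)
    it = config.iterations
    # pre-generate all randomness; the MH loop is scalar arithmetic only
    rec_draws = rng.normal(recent.delta14c_mean, recent.delta14c_sd, it).tolist()
    ppc_draws = ppc.draws[rng.integers(0, ppc.draws.size, it)].tolist()
    steps = rng.normal(0.0, config.proposal_sd, it).tolist()
    logu = np.log(rng.random(it)).tolist()

    n = obs.size
    s1 = float(obs.sum())
    s2 = float(np.sum(obs * obs))
    inv2 = 1.0 / (2.0 * obs_sd * obs_sd)

    f = float(rng.random())
    out: list[float] = []
    burn, thin = config.burn_in, config.thinning
    accepted = 0
    for i in range(it):
        r = rec_draws[i]
        p = ppc_draws[i]
        m = f * p + (1.0 - f) * r
        ll_cur = -(s2 - 2.0 * m * s1 + n * m * m) * inv2
        fp = _reflect(f + steps[i])
        mp = fp * p + (1.0 - fp) * r
        ll_prop = -(s2 - 2.0 * mp * s1 + n * mp * mp) * inv2
        if logu[i] < ll_prop - ll_cur:
            f = fp
            accepted += 1
        if i >= burn and (i - burn) % thin == 0:
            out.append(f)

    rate = accepted / it
    if not 0.05 <= rate <= 0.95:
        logger.warning(
            "MCMC acceptance rate %.3f outside [0.05, 0.95] for target %s",
            rate, label,
        )
    return PosteriorFraction(label, np.array(out), acceptance_rate=rate)


def _extract_observations(target, target_id) -> tuple[np.ndarray, str]:
    if isinstance(target, RiverSample):
        obs = np.array([target.delta14c])
        label = target_id or f"{target.river}/{target.date}/{target.analyte}"
    elif isinstance(target, (int, float)):
        obs = np.array([float(target)])
        label = target_id or f"delta14c={float(target):g}"
    else:
        seq = list(target)
        if seq and isinstance(seq[0], RiverSample):
            obs = np.array([s.delta14c for s in seq])
            label = target_id or _group_label(seq)
        else:
            obs = np.asarray(seq, dtype=float)
            label = target_id or f"group(n={obs.size})"
    return obs, label


def _group_label(samples: Sequence[RiverSample]) -> str:
    rivers = sorted({s.river for s in samples})
    seasons = sorted({s.season for s in samples})
    analytes = sorted({s.analyte for s in samples})
    return "/".join(["+".join(rivers), "+".join(seasons), "+".join(analytes)])


def apportion_each(
    samples: Sequence[RiverSample],
    recent: SourcePool,
    ppc: CompositeEndmember,
    config: MCMCConfig = MCMCConfig(),
    obs_sd: float = DEFAULT_OBS_SD,
) -> list[PosteriorFraction]:
    """Per-sample apportionment; seeds are derived per sample for determinism."""
    seq = np.random.SeedSequence(config.seed).spawn(len(samples))
    out = []
    for sample, ss in zip(samples, seq):
        sub = MCMCConfig(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thinning=config.thinning,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            proposal_sd=config.proposal_sd,
        )
        out.append(apportion(sample, recent, ppc, sub, obs_sd))
    return out


def aggregate_fractions(
    posteriors: Sequence[PosteriorFraction],
    weights: Sequence[float],
    n_mc: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Flux-weighted roll-up of posterior fractions across targets.

    Per Monte-Carlo replicate one draw is taken from each posterior and the
    flux-weighted mean formed; the mean and SD over replicates are returned
    in percent.
    """
    if len(posteriors) == 0:
        raise ValueError("no posteriors to aggregate")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(posteriors),):
        raise ValueError("weights must align one-to-one with posteriors")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative with at least one positive")
    rng = np.random.default_rng(seed)
    cols = [
        p.draws[rng.integers(0, p.draws.size, n_mc)] for p in posteriors
    ]
    mat = np.column_stack(cols)  # (n_mc, n_targets)
    reps = mat @ (w / w.sum())
    return float(reps.mean() * 100.0), float(reps.std(ddof=1) * 100.0)


def combine_posteriors(
    posteriors: Sequence[PosteriorFraction],
    weights: Sequence[float],
    target: str,
    size: int = 10_000,
    seed: int | None = None,
) -> PosteriorFraction:
    """Flux-weighted group-level posterior built from per-sample posteriors.

    Each retained draw is the flux-weighted mean of one random draw per
    member posterior — the distribution of the group's PP-C fraction.
    """
    if len(posteriors) == 0:
        raise ValueError("no posteriors to combine")
    w = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    mat = np.column_stack(
        [p.draws[rng.integers(0, p.draws.size, size)] for p in posteriors]
    )
    return PosteriorFraction(target, mat @ (w / w.sum()))
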