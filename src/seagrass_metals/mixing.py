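"""Two-source Bayesian stable-isotope mixing model for the epiphyte weight ratio.

Initial leaves (IL) placed in decomposition bags are a physical mixture of
eelgrass leaf tissue and its epiphytes (mainly crustose coralline algae).  The
mass fraction of epiphytes, the weight ratio of epiphytes (WRE, ``r``), is not
directly measurable on the bagged material, so it is inferred from elemental
tracers (C %, δ13C, and optionally N %, δ15N) measured on the mixture and on
the two end-member sources.

Model
-----
For tracer ``t`` with source means ``μ_eel,t``, ``μ_epi,t`` and SDs
``σ_eel,t``, ``σ_epi,t``, an IL replicate is normal with

    mean      m_t(r) = (1 − r)·μ_eel,t + r·μ_epi,t
    variance  v_t(r) = (1 − r)²·σ²_eel,t + r²·σ²_epi,t

i.e. linear mass-fraction mixing with source variability propagated by
squared-fraction weighting.  The prior on ``r`` is uniform(0, 1); the
posterior is sampled by a reflective random-walk Metropolis sampler, and can
be cross-checked against deterministic grid integration (`wre_grid_posterior`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACERS = ("c_content", "d13c", "n_content", "d15n")
#: tracers expressed as % dry weight, physically bounded to [0, 100]
CONTENT_TRACERS = ("c_content", "n_content")

_LOG_2PI = math.log(2.0 * math.pi)


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Isotope ratio to δ-notation (‰): (R_sample/R_standard − 1) × 10³."""
    if r_standard <= 0:
        raise ValueError("isotope standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1.0e3


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Invert δ-notation back to the raw isotope ratio."""
    if r_standard <= 0:
        raise ValueError("isotope standard ratio must be positive")
    return (delta / 1.0e3 + 1.0) * r_standard


@dataclass(frozen=True)
class SourceSummary:
    """Per-source tracer summaries (mean, SD, n) used as plug-in mixing priors."""

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        for t, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"SD for tracer {t!r} must be >= 0")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same tracer set")

    def tracers(self) -> tuple[str, ...]:
        return tuple(t for t in TRACERS if t in self.means)


def summarize_sources(
    samples: pd.DataFrame, tracers: tuple[str, ...] = TRACERS
) -> dict[str, SourceSummary]:
    """Build per-source `SourceSummary` objects from a tracer-sample table.

    ``samples`` needs a ``source`` column plus one column per tracer; SD is the
    sample standard deviation (ddof=1).
    """
    out: dict[str, SourceSummary] = {}
    for label, grp in samples.groupby("source"):
        avail = [t for t in tracers if t in grp.columns and grp[t].notna().all()]
        means = {t: float(grp[t].mean()) for t in avail}
        sds = {t: float(grp[t].std(ddof=1)) if len(grp) > 1 else 0.0 for t in avail}
        out[str(label)] = SourceSummary(str(label), means, sds, len(grp))
    return out


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule. ``iterations`` is the total per chain, burn-in included."""

    iterations: int = 200_000
    burn_in: int = 50_000
    thinning: int = 15
    chains: int = 1
    seed: int = 0
    proposal_scale: float = 0.05
    adapt: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("require 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if (self.iterations - self.burn_in) // self.thinning < 1:
            raise ValueError("schedule retains no draws")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")


#: reference schedule for the weight-ratio fit: 200k iterations, 50k burn-in,
#: every 15th retained -> exactly 10,000 draws.
WRE_SCHEDULE = MCMCConfig(iterations=200_000, burn_in=50_000, thinning=15, chains=1)


@dataclass
class WREPosterior:
    """Retained MCMC draws of the epiphyte weight fraction plus summaries."""

    draws: np.ndarray
    summary: dict[str, float]
    acceptance_rate: float
    n_retained: int
    non_identifiable: bool = False
    tracers: tuple[str, ...] = field(default_factory=tuple)


class _MixSuffStats:
    """Per-tracer sufficient statistics of the IL replicates.

    The Gaussian log-likelihood over replicates j and tracers t reduces to
    Σ_t [ −n/2·log(2π v_t) − (SS_t + n·(x̄_t − m_t)²) / (2 v_t) ], which makes
    each Metropolis step O(#tracers) instead of O(n × #tracers).
    """

    def __init__(self, il: pd.DataFrame, sources: tuple[SourceSummary, SourceSummary],
                 tracers: tuple[str, ...]):
        eel, epi = sources
        for t in tracers:
            for s in sources:
                if t not in s.means:
                    raise ValueError(f"tracer {t!r} missing from source {s.label!r}")
            if t not in il.columns or il[t].isna().any():
                raise ValueError(f"tracer {t!r} missing from IL replicates")
        x = il.loc[:, list(tracers)].to_numpy(dtype=float)
        self.n = x.shape[0]
        if self.n < 1:
            raise ValueError("need at least one IL replicate")
        self.xbar = x.mean(axis=0)
        self.ss = ((x - self.xbar) ** 2).sum(axis=0)
        self.mu_eel = np.array([eel.means[t] for t in tracers])
        self.mu_epi = np.array([epi.means[t] for t in tracers])
        self.var_eel = np.array([eel.sds[t] for t in tracers]) ** 2
        self.var_epi = np.array([epi.sds[t] for t in tracers]) ** 2
        self.x = x

    def loglik(self, r: float) -> float:
        m = (1.0 - r) * self.mu_eel + r * self.mu_epi
        v = (1.0 - r) ** 2 * self.var_eel + r**2 * self.var_epi
        zero = v == 0.0
        if zero.any():
            # degenerate tracer: point mass at m; -inf unless every obs sits on
            # it (within floating tolerance)
            if not np.allclose(self.x[:, zero], m[zero], rtol=1e-9, atol=1e-9):
                return -math.inf
            if zero.all():
                return 0.0
            m, v = m[~zero], v[~zero]
            xbar, ss, n = self.xbar[~zero], self.ss[~zero], self.n
        else:
            xbar, ss, n = self.xbar, self.ss, self.n
        quad = ss + n * (xbar - m) ** 2
        return float(np.sum(-0.5 * n * (_LOG_2PI + np.log(v)) - quad / (2.0 * v)))


def mixing_loglik(
    r: float,
    sources: tuple[SourceSummary, SourceSummary],
    il: pd.DataFrame,
    tracers: tuple[str, ...] = ("c_content", "d13c"),
) -> float:
    """Log-likelihood of mixing fraction ``r`` given IL replicates and sources."""
    if not 0.0 <= r <= 1.0:
        return -math.inf
    return _MixSuffStats(il, sources, tracers).loglik(r)


def _reflect(x: float) -> float:
    """Fold a real proposal back into [0, 1] (reflecting boundaries)."""
    x = math.fmod(x, 2.0)
    if x < 0.0:
        x += 2.0
    return 2.0 - x if x > 1.0 else x


def fit_wre(
    il: pd.DataFrame,
    sources: tuple[SourceSummary, SourceSummary],
    tracers: tuple[str, ...] = ("c_content", "d13c"),
    mcmc: MCMCConfig = WRE_SCHEDULE,
) -> WREPosterior:
    """Sample the posterior of the epiphyte weight fraction by random-walk MCMC.

    Uniform(0, 1) prior, normal random-walk proposals reflected at the
    boundaries.  During burn-in the proposal scale is optionally adapted toward
    a 20–50 % acceptance rate; adaptation stops at the end of burn-in so the
    retained chain is a valid Metropolis sample.
    """
    stats = _MixSuffStats(il, sources, tracers)
    eel, epi = sources
    non_ident = all(
        eel.means[t] == epi.means[t] and eel.sds[t] == epi.sds[t] for t in tracers
    )

    rng = np.random.default_rng(mcmc.seed)
    scale = mcmc.proposal_scale
    r = 0.5
    ll = stats.loglik(r)
    n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thinning
    draws = np.empty(n_keep)
    kept = 0
    accepted = 0
    post_burn = 0
    window_acc = 0

    steps = rng.standard_normal(mcmc.iterations)
    log_u = np.log(rng.random(mcmc.iterations))
    for i in range(mcmc.iterations):
        prop = _reflect(r + scale * steps[i])
        ll_prop = stats.loglik(prop)
        if ll_prop - ll > log_u[i]:
            r, ll = prop, ll_prop
            if i >= mcmc.burn_in:
                accepted += 1
            window_acc += 1
        if i >= mcmc.burn_in:
            post_burn += 1
            if post_burn % mcmc.thinning == 0 and kept < n_keep:
                draws[kept] = r
                kept += 1
        elif mcmc.adapt and (i + 1) % 1000 == 0:
            rate = window_acc / 1000.0
            if rate < 0.20:
                scale = max(scale * 0.7, 1e-4)
            elif rate > 0.50:
                scale = min(scale * 1.4, 1.0)
            window_acc = 0

    draws = draws[:kept]
    return WREPosterior(
        draws=draws,
        summary=summarize_posterior(draws),
        acceptance_rate=accepted / max(mcmc.iterations - mcmc.burn_in, 1),
        n_retained=kept,
        non_identifiable=non_ident,
        tracers=tracers,
    )


def wre_grid_posterior(
    il: pd.DataFrame,
    sources: tuple[SourceSummary, SourceSummary],
    tracers: tuple[str, ...] = ("c_content", "d13c"),
    n_grid: int = 10_000,
) -> dict[str, np.ndarray | float]:
    """Deterministic quadrature posterior of ``r`` on a uniform grid.

    Serves as the numerical-integration route against which the MCMC route is
    validated; both share the likelihood but nothing of the sampling machinery.
    """
    stats = _MixSuffStats(il, sources, tracers)
    grid = np.linspace(0.0, 1.0, n_grid)
    logp = np.array([stats.loglik(r) for r in grid])
    logp -= logp.max()
    w = np.exp(logp)
    z = np.trapezoid(w, grid)
    dens = w / z
    mean = np.trapezoid(grid * dens, grid)
    var = np.trapezoid((grid - mean) ** 2 * dens, grid)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return {
        "grid": grid,
        "density": dens,
        "mean": float(mean),
        "sd": float(math.sqrt(max(var, 0.0))),
        "ci_low": lo,
        "ci_high": hi,
    }


def summarize_posterior(draws: np.ndarray) -> dict[str, float]:
    """Mean, SD and equal-tailed 95% credible interval of a draw vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws to summarize")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }
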