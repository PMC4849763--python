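"""Posterior summaries: KDE modes, credible ranges, ICC, CoV and % repeatability.

Every reported quantity is summarised the same way: transform the posterior
chain *per draw* (e.g. form the ICC chain ``sigma_a^2 / (sigma_a^2 +
sigma_ab^2)`` from the joint draws), then report the kernel-density mode of
the transformed chain together with its empirical 2.5–97.5 % range.  The mode
of the transformed chain is reported, never the transform of a mode.

The mode estimator evaluates a Gaussian-kernel density with Silverman's
bandwidth ``h = 0.9 * min(sd, IQR / 1.34) * n**(-1/5)`` on a 1000-point
uniform grid over the sample range, after uniformly downsampling chains
longer than 10,000 draws.  Percentiles use linear interpolation between order
statistics (the numpy default) — this interpolation convention is part of the
contract.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SummaryStat",
    "RepeatabilityReport",
    "PCT_REPEATABILITY_FACTOR",
    "kde_mode",
    "credible_interval",
    "icc_inter",
    "icc_intra",
    "cov",
    "pct_repeatability",
    "summarize_report",
]

#: % repeatability per unit CoV: 100 * 1.96 * sqrt(2), the smallest relative
#: change declarable significant (p < 0.05, two-tailed) for a single patient.
PCT_REPEATABILITY_FACTOR = 100.0 * 1.96 * math.sqrt(2.0)

KDE_GRID_SIZE = 1000
KDE_MAX_DRAWS = 10_000


@dataclass(frozen=True)
class SummaryStat:
    """Posterior mode with 2.5–97.5 % range."""

    mode: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    def to_dict(self) -> dict:
        return {"mode": self.mode, "ci_low": self.ci_low, "ci_high": self.ci_high}

    @classmethod
    def from_dict(cls, d: dict) -> "SummaryStat":
        return cls(d["mode"], d["ci_low"], d["ci_high"])


def kde_mode(draws, grid_size: int = KDE_GRID_SIZE, max_draws: int = KDE_MAX_DRAWS,
             seed: int = 0) -> float:
    """Kernel-density mode of a sample.

    Chains longer than ``max_draws`` are first downsampled uniformly without
    replacement (seeded).  A Gaussian-kernel density with Silverman bandwidth
    is evaluated on a ``grid_size``-point uniform grid spanning the sample
    range; the grid point of maximal density is returned, ties broken toward
    the lower grid point.  A constant sample is returned as-is.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least one draw")
    if np.all(x == x[0]):
        return float(x[0])
    if x.size > max_draws:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(x.size, size=max_draws, replace=False)]
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    h = 0.9 * min(spread_candidates) * n ** (-0.2)
    grid = np.linspace(x.min(), x.max(), grid_size)
    density = np.empty(grid_size)
    chunk = max(1, int(2e6 // n))
    for start in range(0, grid_size, chunk):
        g = grid[start:start + chunk]
        z = (g[:, None] - x[None, :]) / h
        density[start:start + chunk] = np.exp(-0.5 * z**2).sum(axis=1)
    return float(grid[int(np.argmax(density))])


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Central empirical credible interval (linear-interpolation percentiles)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least one draw")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(x, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def icc_inter(sigma_a, sigma_ab):
    """Inter-observer ICC per draw: sigma_a^2 / (sigma_a^2 + sigma_ab^2)."""
    sa2 = np.asarray(sigma_a, dtype=float) ** 2
    sab2 = np.asarray(sigma_ab, dtype=float) ** 2
    denom = sa2 + sab2
    if np.any(denom == 0):
        raise ValueError("ICC undefined: sigma_a and sigma_ab both zero")
    return sa2 / denom


def icc_intra(sigma_a, sigma_eps_j):
    """Intra-observer ICC for reader j per draw: sigma_a^2 / (sigma_a^2 + sigma_eps_j^2)."""
    sa2 = np.asarray(sigma_a, dtype=float) ** 2
    se2 = np.asarray(sigma_eps_j, dtype=float) ** 2
    denom = sa2 + se2
    if np.any(denom == 0):
        raise ValueError("ICC undefined: sigma_a and sigma_eps both zero")
    return sa2 / denom


def cov(sigma, mu):
    """Coefficient of variation |sigma / mu| per draw.

    Draws with mu == 0 are excluded with a warning reporting the count;
    a negative mean triggers a flag warning (the absolute CoV is reported).
    """
    s = np.atleast_1d(np.asarray(sigma, dtype=float))
    m = np.atleast_1d(np.asarray(mu, dtype=float))
    s, m = np.broadcast_arrays(s, m)
    keep = m != 0
    n_excluded = int((~keep).sum())
    if n_excluded == s.size:
        raise ValueError("CoV undefined: all mu draws are zero")
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} draw(s) with mu == 0 from CoV", stacklevel=2)
    if np.any(m[keep] < 0):
        warnings.warn("negative-mean draws encountered; reporting |CoV|", stacklevel=2)
    out = np.abs(s[keep] / m[keep])
    if np.isscalar(sigma) and np.isscalar(mu):
        return float(out[0])
    return out


def pct_repeatability(cov_value):
    """Percentage repeatability 100 * 1.96 * sqrt(2) * CoV."""
    c = np.asarray(cov_value, dtype=float)
    if np.any(c < 0):
        raise ValueError("CoV must be non-negative")
    out = PCT_REPEATABILITY_FACTOR * c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RepeatabilityReport:
    """Repeatability summaries for one metric, mirroring the reporting tables.

    Inter-observer quantities derive from the reader-bias spread sigma_ab;
    intra-observer quantities (one per reader j) from sigma_eps_j.  Each entry
    is a posterior mode with its 2.5–97.5 % range.  All values are on the
    metric's native scale; any x100 display scaling is applied only in
    :meth:`to_dict` with explicitly flagged keys.
    """

    metric: str
    sigma_ab: SummaryStat
    cov_inter: SummaryStat
    pct_rep_inter: SummaryStat
    icc_inter: SummaryStat
    sigma_eps: tuple
    cov_intra: tuple
    pct_rep_intra: tuple
    icc_intra: tuple
    n_draws: int = 0
    seed: int = 0

    def to_dict(self, display_scale_100: bool = False) -> dict:
        """JSON-ready dict.  ``display_scale_100`` multiplies sigma and CoV
        entries by 100 (presentation only), flagging the keys with ``_x100``."""
        f = 100.0 if display_scale_100 else 1.0
        tag = "_x100" if display_scale_100 else ""

        def scaled(s: SummaryStat) -> dict:
            return {"mode": s.mode * f, "ci_low": s.ci_low * f, "ci_high": s.ci_high * f}

        out = {
            "metric": self.metric,
            "n_draws": self.n_draws,
            "seed": self.seed,
            f"sigma_ab{tag}": scaled(self.sigma_ab),
            f"cov_inter{tag}": scaled(self.cov_inter),
            "pct_rep_inter": self.pct_rep_inter.to_dict(),
            "icc_inter": self.icc_inter.to_dict(),
        }
        for j in (1, 2):
            out[f"sigma_eps_{j}{tag}"] = scaled(self.sigma_eps[j - 1])
            out[f"cov_intra_{j}{tag}"] = scaled(self.cov_intra[j - 1])
            out[f"pct_rep_intra_{j}"] = self.pct_rep_intra[j - 1].to_dict()
            out[f"icc_intra_{j}"] = self.icc_intra[j - 1].to_dict()
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RepeatabilityReport":
        return cls(
            metric=d["metric"],
            sigma_ab=SummaryStat.from_dict(d["sigma_ab"]),
            cov_inter=SummaryStat.from_dict(d["cov_inter"]),
            pct_rep_inter=SummaryStat.from_dict(d["pct_rep_inter"]),
            icc_inter=SummaryStat.from_dict(d["icc_inter"]),
            sigma_eps=tuple(SummaryStat.from_dict(d[f"sigma_eps_{j}"]) for j in (1, 2)),
            cov_intra=tuple(SummaryStat.from_dict(d[f"cov_intra_{j}"]) for j in (1, 2)),
            pct_rep_intra=tuple(SummaryStat.from_dict(d[f"pct_rep_intra_{j}"]) for j in (1, 2)),
            icc_intra=tuple(SummaryStat.from_dict(d[f"icc_intra_{j}"]) for j in (1, 2)),
            n_draws=d.get("n_draws", 0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, s: str) -> "RepeatabilityReport":
        return cls.from_dict(json.loads(s))


def _summary(draws, level: float, seed: int) -> SummaryStat:
    lo, hi = credible_interval(draws, level=level)
    return SummaryStat(kde_mode(draws, seed=seed), lo, hi)


def summarize_report(chain, level: float = 0.95, seed: int | None = None) -> "RepeatabilityReport":
    """Full repeatability report from a posterior chain.

    All derived chains (CoV, % repeatability, ICC) are formed per draw from
    the joint posterior — in particular CoV divides each sigma draw by the
    concurrent mu draw of the same iteration — and then summarised by KDE mode
    and 2.5–97.5 % range.
    """
    if seed is None:
        seed = chain.config.seed
    mu = chain.array("mu")
    sigma_a = chain.array("sigma_a")
    sigma_ab_d = chain.array("sigma_ab")
    sigma_eps_d = [chain.array("sigma_eps_1"), chain.array("sigma_eps_2")]

    cov_inter_d = cov(sigma_ab_d, mu)
    report = RepeatabilityReport(
        metric=chain.metric or "metric",
        sigma_ab=_summary(sigma_ab_d, level, seed),
        cov_inter=_summary(cov_inter_d, level, seed),
        pct_rep_inter=_summary(pct_repeatability(cov_inter_d), level, seed),
        icc_inter=_summary(icc_inter(sigma_a, sigma_ab_d), level, seed),
        sigma_eps=tuple(_summary(se, level, seed) for se in sigma_eps_d),
        cov_intra=tuple(_summary(cov(se, mu), level, seed) for se in sigma_eps_d),
        pct_rep_intra=tuple(
            _summary(pct_repeatability(cov(se, mu)), level, seed) for se in sigma_eps_d
        ),
        icc_intra=tuple(_summary(icc_intra(sigma_a, se), level, seed) for se in sigma_eps_d),
        n_draws=len(chain),
        seed=seed,
    )
    return report
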