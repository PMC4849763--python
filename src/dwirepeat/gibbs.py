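"""Gibbs sampler for the constrained two-observer mixed-effects model.

Each biomarker is modelled as

    Y_ijk = mu + a_i + ab_ij + eps_ijk,

where i = 1..P indexes patients, j in {1, 2} the observer and k in {1, 2} the
repeat reading.  ``a_i ~ N(0, sigma_a^2)`` is the true patient deviation,
``ab_ij ~ N(0, sigma_ab^2)`` the bias of observer j on patient i, and
``eps_ijk ~ N(0, sigma_eps_j^2)`` the within-observer measurement error.
With only two observers no observer-population statistics are identifiable,
so the biases are constrained to cancel within each patient:

    ab_i1 + ab_i2 = 0,

leaving the 2P + 5 unknowns mu, a_1..P, b_1..P (= ab_i1) and the standard
deviations sigma_a, sigma_ab, sigma_eps_1, sigma_eps_2.

With a normal prior on mu and conjugate inverse-gamma priors on all
variances, every full conditional is available in closed form (normal for the
location blocks, inverse-gamma for the variances) and the posterior is
explored by a systematic-scan Gibbs sampler.  The update order is fixed —
mu, {a_i}, {b_i}, sigma_a^2, sigma_ab^2, sigma_eps_1^2, sigma_eps_2^2 — and a
single seeded generator drives each chain, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurements import MeasurementTable

__all__ = [
    "Priors",
    "ChainConfig",
    "ModelState",
    "PosteriorChain",
    "NumericalError",
    "default_priors",
    "init_state",
    "conditional_mu",
    "conditional_patient_effects",
    "conditional_reader_bias",
    "conditional_variance",
    "sample_invgamma",
    "gibbs_step",
    "run_chain",
    "split_rhat",
    "write_chain",
]

#: Observer sign in the constrained parameterisation: ab_i1 = +b_i, ab_i2 = -b_i.
OBSERVER_SIGN = np.array([1.0, -1.0])

_K = 2  # replicates per (patient, observer)

#: Relative floor applied to drawn variances, as a fraction of Var(Y).
#: Prevents division underflow on degenerate (zero-noise) data while keeping
#: the sampler exactly scale-equivariant.
VAR_FLOOR_REL = 1e-12

CHAIN_COLUMNS = ("chain", "iteration", "mu", "sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2")


class NumericalError(RuntimeError):
    """A full conditional produced a non-finite parameter."""

    def __init__(self, block: str, detail: str = ""):
        self.block = block
        super().__init__(f"non-finite conditional parameters in block {block!r} {detail}")


@dataclass(frozen=True)
class Priors:
    """Hyperparameters: mu ~ N(mu_mean, mu_sd^2); variances ~ InvGamma(ig_shape, ig_scale).

    Defaults are vague: use :func:`default_priors` to scale ``mu_sd`` to the
    data (10^6 x data scale), keeping the prior effectively flat while the
    conjugate structure yields a pure Gibbs sampler.
    """

    mu_mean: float = 0.0
    mu_sd: float = 1e6
    ig_shape: float = 1e-3
    ig_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.mu_sd <= 0 or self.ig_shape <= 0 or self.ig_scale <= 0:
            raise ValueError("mu_sd, ig_shape and ig_scale must all be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ChainConfig:
    """Chain schedule.  Defaults retain (60000 - 10000) / 5 = 10000 draws."""

    n_iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.thin <= 0 or self.n_chains <= 0:
            raise ValueError("n_iterations, thin and n_chains must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain after burn-in and thinning."""
        return (self.n_iterations - self.burn_in + self.thin - 1) // self.thin

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ModelState:
    """One Gibbs draw of the 2P + 5 parameters (b_i stores ab_i1; ab_i2 = -b_i)."""

    mu: float
    a: np.ndarray
    b: np.ndarray
    sigma_a: float
    sigma_ab: float
    sigma_eps: np.ndarray  # (sigma_eps_1, sigma_eps_2)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.sigma_eps = np.asarray(self.sigma_eps, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be length-P vectors")
        if self.sigma_eps.shape != (2,):
            raise ValueError("sigma_eps must have length 2")
        if min(self.sigma_a, self.sigma_ab, *self.sigma_eps) < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def P(self) -> int:
        return self.a.size

    def copy(self) -> "ModelState":
        return ModelState(
            self.mu, self.a.copy(), self.b.copy(),
            self.sigma_a, self.sigma_ab, self.sigma_eps.copy(),
        )


@dataclass
class PosteriorChain:
    """Retained posterior draws of (mu, sigma_a, sigma_ab, sigma_eps_1, sigma_eps_2)."""

    draws: pd.DataFrame
    config: ChainConfig
    priors: Priors
    metric: str | None = None

    def __len__(self) -> int:
        return len(self.draws)

    def array(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def rhat(self) -> dict:
        """Split-chain potential-scale-reduction diagnostic (advisory).

        Requires at least two chains; computed per parameter.
        """
        if self.config.n_chains < 2:
            raise ValueError("rhat requires n_chains >= 2")
        out = {}
        for name in ("mu", "sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"):
            stacked = np.stack(
                [g[name].to_numpy() for _, g in self.draws.groupby("chain", sort=True)]
            )
            out[name] = split_rhat(stacked)
        return out


def _as_array(table) -> np.ndarray:
    if isinstance(table, MeasurementTable):
        return table.to_array()
    Y = np.asarray(table, dtype=float)
    if Y.ndim != 3 or Y.shape[1:] != (2, 2):
        raise ValueError(f"expected MeasurementTable or (P, 2, 2) array, got shape {Y.shape}")
    return Y


def _data_scale(Y: np.ndarray) -> float:
    scale = float(np.std(Y))
    if scale == 0.0:
        scale = max(abs(float(np.mean(Y))), 1.0)
    return scale


def default_priors(table) -> Priors:
    """Vague data-scaled priors.

    mu ~ N(0, (1e6 * scale)^2) and variances ~ InvGamma(1e-3, 1e-3 * Var(Y)),
    where scale = sd(Y).  Both hyperparameters scale with the data: a fixed
    inverse-gamma scale is not vague for variance components far from unit
    magnitude (it would inflate small components), and scaling it keeps the
    whole posterior exactly equivariant under rescaling of the measurements.
    """
    Y = _as_array(table)
    scale = _data_scale(Y)
    return Priors(mu_mean=0.0, mu_sd=1e6 * scale, ig_scale=1e-3 * scale**2)


def init_state(table) -> ModelState:
    """Method-of-moments starting point for the sampler.

    mu starts at the grand mean, a_i at centred patient means, b_i at half the
    between-observer patient-mean difference.  The variance components are
    moment estimates (replicate differences for sigma_eps_j; excess variance
    of the patient means / observer contrasts for sigma_a / sigma_ab), floored
    at 1e-6 of the data scale so no conditional starts degenerate.
    """
    Y = _as_array(table)
    P = Y.shape[0]
    floor = 1e-6 * _data_scale(Y)
    grand = float(Y.mean())
    patient_means = Y.mean(axis=(1, 2))
    a = patient_means - grand
    b = (Y[:, 0, :].mean(axis=1) - Y[:, 1, :].mean(axis=1)) / 2.0
    diffs = Y[:, :, 1] - Y[:, :, 0]  # (P, 2) replicate differences per observer
    se2 = (diffs**2).sum(axis=0) / (2.0 * P)
    # Var(patient mean) = sigma_a^2 + (se1^2 + se2^2)/8; Var(b_hat) likewise.
    noise = se2.sum() / 8.0
    var_pm = float(np.var(patient_means, ddof=1)) if P > 1 else 0.0
    sigma_a = np.sqrt(max(var_pm - noise, floor**2))
    sigma_ab = np.sqrt(max(float(np.mean(b**2)) - noise, floor**2))
    sigma_eps = np.sqrt(np.maximum(se2, floor**2))
    return ModelState(grand, a, b, float(sigma_a), float(sigma_ab), sigma_eps)


# -- full conditionals ------------------------------------------------------


def conditional_mu(Y: np.ndarray, a: np.ndarray, b: np.ndarray,
                   sigma_eps: np.ndarray, priors: Priors) -> tuple[float, float]:
    """Normal full conditional of mu: returns (mean, sd)."""
    P = Y.shape[0]
    inv = 1.0 / sigma_eps**2
    precision = 1.0 / priors.mu_sd**2 + _K * P * inv.sum()
    resid = Y - a[:, None, None] - (OBSERVER_SIGN * b[:, None])[:, :, None]
    num = priors.mu_mean / priors.mu_sd**2 + float((resid.sum(axis=2) * inv).sum())
    return num / precision, float(np.sqrt(1.0 / precision))


def conditional_patient_effects(Y: np.ndarray, mu: float, b: np.ndarray,
                                sigma_a: float, sigma_eps: np.ndarray
                                ) -> tuple[np.ndarray, float]:
    """Normal full conditionals of a_1..P: returns (means, common sd)."""
    inv = 1.0 / sigma_eps**2
    precision = 1.0 / sigma_a**2 + _K * inv.sum()
    partial = (Y - mu).sum(axis=2) - _K * OBSERVER_SIGN * b[:, None]  # (P, 2)
    means = (partial * inv).sum(axis=1) / precision
    return means, float(np.sqrt(1.0 / precision))


def conditional_reader_bias(Y: np.ndarray, mu: float, a: np.ndarray,
                            sigma_ab: float, sigma_eps: np.ndarray
                            ) -> tuple[np.ndarray, float]:
    """Normal full conditionals of b_1..P: returns (means, common sd)."""
    inv = 1.0 / sigma_eps**2
    precision = 1.0 / sigma_ab**2 + _K * inv.sum()
    partial = (Y - mu - a[:, None, None]).sum(axis=2)  # (P, 2)
    means = (partial * OBSERVER_SIGN * inv).sum(axis=1) / precision
    return means, float(np.sqrt(1.0 / precision))


def conditional_variance(block: str, state: ModelState, Y: np.ndarray,
                         priors: Priors) -> tuple[float, float]:
    """Inverse-gamma full conditional (shape, scale) for one variance block.

    ``block`` is one of ``"a"``, ``"ab"``, ``"eps1"``, ``"eps2"``.
    """
    P = Y.shape[0]
    if block == "a":
        return priors.ig_shape + P / 2.0, priors.ig_scale + 0.5 * float(state.a @ state.a)
    if block == "ab":
        return priors.ig_shape + P / 2.0, priors.ig_scale + 0.5 * float(state.b @ state.b)
    if block in ("eps1", "eps2"):
        j = 0 if block == "eps1" else 1
        resid = (
            Y[:, j, :]
            - state.mu
            - state.a[:, None]
            - OBSERVER_SIGN[j] * state.b[:, None]
        )
        ss = float((resid**2).sum())
        return priors.ig_shape + P * _K / 2.0, priors.ig_scale + 0.5 * ss
    raise ValueError(f"unknown variance block {block!r}")


def sample_invgamma(shape: float, scale: float, rng: np.random.Generator, size=None):
    """Draw from InverseGamma(shape, scale): scale / Gamma(shape, 1)."""
    return scale / rng.gamma(shape, size=size)


def gibbs_step(state: ModelState, table, priors: Priors,
               rng: np.random.Generator, var_floor: float | None = None) -> ModelState:
    """One systematic-scan sweep over all blocks; returns a new state.

    Update order: mu, {a_i}, {b_i}, sigma_a^2, sigma_ab^2, sigma_eps_1^2,
    sigma_eps_2^2.  The draw order within a sweep is part of the public
    contract (bit-reproducibility under a fixed seed).
    """
    Y = _as_array(table)
    if state.P != Y.shape[0]:
        raise ValueError("state dimension does not match table")
    if var_floor is None:
        var_floor = VAR_FLOOR_REL * max(float(np.var(Y)), np.finfo(float).tiny)

    m, s = conditional_mu(Y, state.a, state.b, state.sigma_eps, priors)
    _check(m, s, "mu")
    mu = m + s * rng.standard_normal()

    means, sd = conditional_patient_effects(Y, mu, state.b, state.sigma_a, state.sigma_eps)
    _check(means, sd, "a")
    a = means + sd * rng.standard_normal(state.P)

    means, sd = conditional_reader_bias(Y, mu, a, state.sigma_ab, state.sigma_eps)
    _check(means, sd, "b")
    b = means + sd * rng.standard_normal(state.P)

    new = ModelState(mu, a, b, state.sigma_a, state.sigma_ab, state.sigma_eps.copy())

    shape, scale = conditional_variance("a", new, Y, priors)
    _check(shape, scale, "sigma_a")
    new.sigma_a = float(np.sqrt(max(sample_invgamma(shape, scale, rng), var_floor)))

    shape, scale = conditional_variance("ab", new, Y, priors)
    _check(shape, scale, "sigma_ab")
    new.sigma_ab = float(np.sqrt(max(sample_invgamma(shape, scale, rng), var_floor)))

    for idx, block in enumerate(("eps1", "eps2")):
        shape, scale = conditional_variance(block, new, Y, priors)
        _check(shape, scale, f"sigma_{block}")
        new.sigma_eps[idx] = np.sqrt(max(sample_invgamma(shape, scale, rng), var_floor))

    return new


def _check(*values_and_block) -> None:
    *values, block = values_and_block
    for v in values:
        if not np.all(np.isfinite(v)):
            raise NumericalError(block)


def run_chain(table, priors: Priors | None = None,
              config: ChainConfig | None = None,
              metric: str | None = None) -> PosteriorChain:
    """Run the Gibbs sampler and return retained draws.

    ``config.n_chains`` independent chains are run from the same
    method-of-moments start, each with its own generator seeded from
    ``(config.seed, chain_index)``.  Draws before ``burn_in`` are discarded
    and every ``thin``-th sweep thereafter is retained.  Identical inputs and
    seed give bitwise-identical chains.
    """
    Y = _as_array(table)
    if priors is None:
        priors = default_priors(Y)
    if config is None:
        config = ChainConfig()
    if metric is None and isinstance(table, MeasurementTable):
        metric = table.metric
    if config.n_retained * config.n_chains < 10_000:
        warnings.warn(
            f"only {config.n_retained * config.n_chains} retained draws "
            "(< 10000 recommended for stable density summaries)",
            stacklevel=2,
        )
    var_floor = VAR_FLOOR_REL * max(float(np.var(Y)), np.finfo(float).tiny)
    frames = []
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        state = init_state(Y)
        n_keep = config.n_retained
        out = np.empty((n_keep, 5))
        kept = 0
        for it in range(config.n_iterations):
            state = gibbs_step(state, Y, priors, rng, var_floor=var_floor)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                out[kept] = (state.mu, state.sigma_a, state.sigma_ab,
                             state.sigma_eps[0], state.sigma_eps[1])
                kept += 1
        frame = pd.DataFrame(
            out[:kept],
            columns=["mu", "sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"],
        )
        frame.insert(0, "iteration", np.arange(kept))
        frame.insert(0, "chain", c)
        frames.append(frame)
    draws = pd.concat(frames, ignore_index=True)
    return PosteriorChain(draws=draws, config=config, priors=priors, metric=metric)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain R-hat for a (n_chains, n_draws) array of one parameter."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    half = x.shape[1] // 2
    halves = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = halves.shape
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def write_chain(chain: PosteriorChain, csv_path, sidecar_path=None) -> None:
    """Serialize draws as CSV plus a JSON sidecar holding config and priors."""
    chain.draws.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "metric": chain.metric,
            "config": chain.config.to_dict(),
            "priors": chain.priors.to_dict(),
            "n_draws": len(chain),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
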