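"""scikit-learn style estimators over the repeatability machinery.

These are fit-only estimators in the spirit of sklearn's covariance and
mixture models: ``fit`` consumes a long-format measurement table (a
:class:`~dwirepeat.measurements.MeasurementTable`, a DataFrame with columns
``patient, observer, replicate, value``, or a dense ``(P, 2, 2)`` array) and
exposes results as trailing-underscore attributes.  They compose with sklearn
tooling (``clone``, ``get_params`` / ``set_params``) so prior/chain settings
can be swept with standard model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import classical as _classical
from . import gibbs as _gibbs
from . import summary as _summary
from .measurements import MeasurementTable

__all__ = ["GibbsRepeatability", "AnovaICC", "BlandAltman"]


def _coerce_table(X, metric: str | None = None) -> MeasurementTable:
    if isinstance(X, MeasurementTable):
        return X
    if isinstance(X, pd.DataFrame):
        return MeasurementTable.from_frame(X, metric=metric or "metric")
    Y = np.asarray(X, dtype=float)
    return MeasurementTable.from_array(Y, metric=metric or "metric")


class GibbsRepeatability(BaseEstimator):
    """Bayesian variance-components repeatability model (Gibbs-sampled).

    Fits the constrained two-observer mixed-effects model
    ``Y_ijk = mu + a_i + ab_ij + eps_ijk`` (with ``ab_i1 + ab_i2 = 0``) by
    systematic-scan Gibbs sampling and summarises the posterior into the
    repeatability quantities of interest: sigma_ab, sigma_eps_j, CoV,
    % repeatability and the inter-/intra-observer ICCs, each as a
    kernel-density mode with a 2.5–97.5 % credible range.

    Parameters
    ----------
    n_iterations, burn_in, thin, n_chains : int
        Chain schedule; the defaults retain 10,000 draws.
    mu_prior_mean : float
        Prior mean of mu.
    mu_prior_sd : float or None
        Prior SD of mu; ``None`` scales an effectively-flat prior to the data
        (1e6 x data scale).
    ig_shape, ig_scale : float
        Inverse-gamma hyperparameters shared by all variance components;
        ``ig_scale=None`` scales the vague default to the data
        (1e-3 x Var(Y)).
    random_state : int
        Master seed; also seeds the KDE downsampler.

    Attributes
    ----------
    chain_ : PosteriorChain
        Retained posterior draws.
    report_ : RepeatabilityReport
        Posterior modes and credible ranges for every reported quantity.
    priors_ : Priors
    n_patients_ : int
    metric_ : str
    rhat_ : dict or None
        Split-chain R-hat per parameter when ``n_chains >= 2`` (advisory).
    """

    def __init__(
        self,
        n_iterations: int = 60_000,
        burn_in: int = 10_000,
        thin: int = 5,
        n_chains: int = 1,
        mu_prior_mean: float = 0.0,
        mu_prior_sd: float | None = None,
        ig_shape: float = 1e-3,
        ig_scale: float | None = None,
        random_state: int = 0,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.mu_prior_mean = mu_prior_mean
        self.mu_prior_sd = mu_prior_sd
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale
        self.random_state = random_state

    def fit(self, X, y=None, metric: str | None = None):
        """Run the sampler on one metric's balanced table."""
        table = _coerce_table(X, metric=metric)
        auto = _gibbs.default_priors(table)
        priors = _gibbs.Priors(
            mu_mean=self.mu_prior_mean,
            mu_sd=auto.mu_sd if self.mu_prior_sd is None else self.mu_prior_sd,
            ig_shape=self.ig_shape,
            ig_scale=auto.ig_scale if self.ig_scale is None else self.ig_scale,
        )
        config = _gibbs.ChainConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            n_chains=self.n_chains,
        )
        self.chain_ = _gibbs.run_chain(table, priors=priors, config=config)
        self.report_ = _summary.summarize_report(self.chain_, seed=self.random_state)
        self.priors_ = priors
        self.n_patients_ = table.P
        self.metric_ = table.metric
        self.rhat_ = self.chain_.rhat() if self.n_chains >= 2 else None
        return self


class AnovaICC(BaseEstimator):
    """Classical method-of-moments variance components and plug-in ICCs.

    The frequentist counterpart of :class:`GibbsRepeatability`; useful as a
    fast point-estimate oracle.  Negative moment estimates are clamped at
    zero (names recorded in ``clamped_``).
    """

    def fit(self, X, y=None, metric: str | None = None):
        table = _coerce_table(X, metric=metric)
        res = _classical.anova_icc(table)
        self.sigma_a_ = res.sigma_a
        self.sigma_ab_ = res.sigma_ab
        self.sigma_eps_ = res.sigma_eps
        self.icc_inter_ = res.icc_inter
        self.icc_intra_ = res.icc_intra
        self.clamped_ = res.clamped
        self.n_patients_ = table.P
        return self


class BlandAltman(BaseEstimator):
    """Bland–Altman replicate-agreement analysis for one observer.

    Parameters
    ----------
    observer : int
        Which observer's pair of readings to analyse (1 or 2).

    Attributes
    ----------
    averages_, differences_ : ndarray, shape (P,)
    bias_ : float
        Mean replicate difference.
    sigma_ : float
        Classical per-measurement error SD from the differences.
    loa_low_, loa_high_ : float
        Zero-centred 95 % repeatability limits (+/- 1.96 * sqrt(2) * sigma_).
    """

    def __init__(self, observer: int = 1):
        self.observer = observer

    def fit(self, X, y=None, metric: str | None = None):
        table = _coerce_table(X, metric=metric)
        res = _classical.bland_altman(table, observer_j=self.observer)
        self.result_ = res
        self.averages_ = res.averages
        self.differences_ = res.differences
        self.bias_ = res.bias
        self.sigma_ = res.sigma
        self.loa_low_ = res.loa_low
        self.loa_high_ = res.loa_high
        return self
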