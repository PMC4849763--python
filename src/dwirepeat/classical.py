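"""Classical (non-Bayesian) agreement analysis.

Three cross-checks against the Bayesian machinery:

* Bland–Altman analysis of the two repeat readings by one observer —
  per-patient (average, difference) pairs with zero-bias repeatability limits;
* the classical replicate-difference estimate of the within-observer error
  sigma_eps_j (under the model, a replicate difference has variance
  ``2 * sigma_eps_j^2``, so ``sigma_eps_j = sqrt(sum d_i^2 / (2P))`` assuming
  zero-mean differences);
* method-of-moments (two-way ANOVA-type) variance components and the plug-in
  ICC point estimates, serving as an independent oracle for the posterior
  modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .measurements import MeasurementTable

__all__ = [
    "BlandAltmanResult",
    "AnovaComponents",
    "bland_altman",
    "classical_sigma",
    "anova_icc",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Per-patient replicate agreement for one observer.

    ``averages``/``differences`` hold (mean of the two replicates,
    replicate 2 - replicate 1) per patient.  ``sigma`` is the classical
    per-measurement error SD implied by the differences; the limits of
    agreement are drawn at ``+/- 1.96 * sqrt(2) * sigma`` about zero (the
    model assumes zero-mean differences), which equals 1.96 x the SD of a
    replicate difference.
    """

    patient_ids: tuple
    averages: np.ndarray
    differences: np.ndarray
    bias: float
    sigma: float
    loa_low: float
    loa_high: float
    observer: int

    def to_dict(self) -> dict:
        return {
            "observer": self.observer,
            "bias": self.bias,
            "sigma": self.sigma,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n_patients": len(self.patient_ids),
        }


@dataclass(frozen=True)
class AnovaComponents:
    """Method-of-moments variance components and plug-in ICCs.

    Components are clamped at zero (negative moment estimates are possible at
    small P); clamped component names are listed in ``clamped``.
    """

    sigma_a: float
    sigma_ab: float
    sigma_eps: np.ndarray
    icc_inter: float
    icc_intra: np.ndarray
    clamped: tuple = field(default_factory=tuple)


def classical_sigma(differences, normalization: str = "paired") -> float:
    """Within-observer error SD from replicate differences.

    With ``normalization="paired"`` (default) returns
    ``sqrt(sum(d_i^2) / (2P))`` — the per-measurement SD, since each
    difference of two independent readings has variance ``2 sigma^2``.
    ``normalization="plain"`` returns ``sqrt(sum(d_i^2) / P)`` (the SD of the
    differences themselves) for sensitivity analysis.
    """
    d = np.asarray(differences, dtype=float).ravel()
    if d.size < 1:
        raise ValueError("need at least one difference")
    ss = float(d @ d)
    if normalization == "paired":
        return float(np.sqrt(ss / (2.0 * d.size)))
    if normalization == "plain":
        return float(np.sqrt(ss / d.size))
    raise ValueError(f"unknown normalization {normalization!r}")


def bland_altman(table: MeasurementTable, observer_j: int) -> BlandAltmanResult:
    """Bland–Altman replicate analysis for one observer.

    Pairs the two repeat readings of observer ``observer_j`` per patient.
    """
    if observer_j not in (1, 2):
        raise ValueError(f"observer_j must be 1 or 2, got {observer_j}")
    Y = table.to_array()[:, observer_j - 1, :]  # (P, 2)
    averages = Y.mean(axis=1)
    differences = Y[:, 1] - Y[:, 0]
    sigma = classical_sigma(differences)
    half_width = 1.96 * np.sqrt(2.0) * sigma
    return BlandAltmanResult(
        patient_ids=table.patient_ids,
        averages=averages,
        differences=differences,
        bias=float(differences.mean()),
        sigma=sigma,
        loa_low=-half_width,
        loa_high=half_width,
        observer=observer_j,
    )


def anova_icc(table: MeasurementTable) -> AnovaComponents:
    """Method-of-moments variance components and plug-in ICC point estimates.

    For the balanced two-observer, two-replicate layout:

    * ``sigma_eps_j^2`` from within-cell replicate scatter (identical to the
      classical replicate-difference estimator);
    * ``sigma_ab^2`` from the patient-wise observer contrasts
      ``c_i = (mean_i1 - mean_i2) / 2``, whose second moment is
      ``sigma_ab^2 + (sigma_eps_1^2 + sigma_eps_2^2) / 8``;
    * ``sigma_a^2`` from the variance of patient means, which under the
      cancelling-bias constraint carry no observer-bias contribution and have
      excess variance ``(sigma_eps_1^2 + sigma_eps_2^2) / 8``.

    Negative component estimates are clamped at zero with a warning.
    """
    Y = table.to_array()
    P = Y.shape[0]
    diffs = Y[:, :, 1] - Y[:, :, 0]  # (P, 2)
    se2 = (diffs**2).sum(axis=0) / (2.0 * P)
    noise = float(se2.sum()) / 8.0

    contrasts = (Y[:, 0, :].mean(axis=1) - Y[:, 1, :].mean(axis=1)) / 2.0
    sab2 = float(np.mean(contrasts**2)) - noise

    patient_means = Y.mean(axis=(1, 2))
    sa2 = (float(np.var(patient_means, ddof=1)) if P > 1 else 0.0) - noise

    clamped = []
    if sab2 < 0:
        clamped.append("sigma_ab")
        sab2 = 0.0
    if sa2 < 0:
        clamped.append("sigma_a")
        sa2 = 0.0
    if clamped:
        warnings.warn(
            f"negative variance-component estimate(s) clamped at zero: {clamped}",
            stacklevel=2,
        )

    denom_inter = sa2 + sab2
    icc_inter_pt = sa2 / denom_inter if denom_inter > 0 else float("nan")
    icc_intra_pts = np.array(
        [sa2 / (sa2 + s2) if (sa2 + s2) > 0 else float("nan") for s2 in se2]
    )
    return AnovaComponents(
        sigma_a=float(np.sqrt(sa2)),
        sigma_ab=float(np.sqrt(sab2)),
        sigma_eps=np.sqrt(se2),
        icc_inter=float(icc_inter_pt),
        icc_intra=icc_intra_pts,
        clamped=tuple(clamped),
    )
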