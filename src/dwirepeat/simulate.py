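"""Synthetic study generators.

No patient images or measurement tables are publicly deposited for this kind
of two-radiologist whole-body DWI repeatability study, so everything the
pipeline consumes is generated here:

* balanced P x 2 x 2 measurement tables drawn from the constrained
  mixed-effects model (``Y_ijk = mu + a_i + ab_ij + eps_ijk`` with
  ``ab_i1 + ab_i2 = 0`` enforced exactly);
* voxel-level ADC sets with controlled high-ADC outlier contamination — the
  mechanism by which a handful of extra voxels destabilises higher-order
  gADC histogram statistics while leaving the median almost untouched;
* an end-to-end reader study in which each (patient, observer, replicate)
  reading perturbs the segmented voxel set (random inclusion of a
  higher-ADC lesion cluster, mimicking observer disagreement over an
  equivocal vertebral lesion) before the gADC metrics are computed.

All generators are bit-reproducible under their seed.  Default population
values per metric are back-calculated from published mode/CoV ratios at the
study's scale (ADC in mm^2/s); they are plausible fixtures, not measured
data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .measurements import MeasurementTable
from .metrics import (
    DEFAULT_VOXEL_VOLUME_ML,
    VoxelSet,
    apply_exclusion,
    summarize_gadc,
)

__all__ = [
    "SimulationSpec",
    "VoxelSimSpec",
    "DEFAULT_METRIC_SPECS",
    "metric_spec",
    "simulate_table",
    "simulate_voxels",
    "simulate_reader_study",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Population parameters of the mixed-effects model for one metric."""

    P: int = 9
    mu: float = 1.0
    sigma_a: float = 0.2
    sigma_ab: float = 0.05
    sigma_eps_1: float = 0.02
    sigma_eps_2: float = 0.02
    seed: int = 0
    metric: str = "metric"

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError(f"P must be >= 1, got {self.P}")
        if min(self.sigma_a, self.sigma_ab, self.sigma_eps_1, self.sigma_eps_2) < 0:
            raise ValueError("all standard deviations must be non-negative")


#: Study-scale fixture defaults per metric (P = 9 study; ADC statistics in
#: units of 1e-3 mm^2/s).  mu is back-calculated as sigma_ab / CoV from the
#: published inter-observer table; sigma_a from the published ICCs.  These
#: reproduce the *magnitudes* of a real study, not its data.
DEFAULT_METRIC_SPECS = {
    "median_gadc": SimulationSpec(9, 0.914, 0.180, 0.0181, 0.0179, 0.0190, metric="median_gadc"),
    "mean_gadc": SimulationSpec(9, 0.941, 0.136, 0.0239, 0.0216, 0.0199, metric="mean_gadc"),
    "log_tdv": SimulationSpec(9, 4.14, 1.85, 0.132, 0.182, 0.211, metric="log_tdv"),
    "var_gadc": SimulationSpec(9, 0.0699, 0.027, 0.0095, 0.0105, 0.0151, metric="var_gadc"),
    "skew_gadc": SimulationSpec(9, 0.695, 0.55, 0.0632, 0.108, 0.209, metric="skew_gadc"),
    "kurt_gadc": SimulationSpec(9, 3.825, 1.50, 0.337, 0.117, 0.541, metric="kurt_gadc"),
}


def metric_spec(metric: str, P: int = 9, seed: int = 0) -> SimulationSpec:
    """Study-scale fixture spec for one of the six canonical metrics."""
    if metric not in DEFAULT_METRIC_SPECS:
        raise KeyError(
            f"no default spec for metric {metric!r}; choose from "
            f"{sorted(DEFAULT_METRIC_SPECS)}"
        )
    return replace(DEFAULT_METRIC_SPECS[metric], P=P, seed=seed)


@dataclass(frozen=True)
class VoxelSimSpec:
    """Voxel-level ADC mixture: a Gaussian base component plus an optional
    high-ADC outlier component replacing ``round(n * outlier_fraction)``
    voxels (deterministic count, seeded positions).  Values are truncated at
    zero (a negligible correction at the defaults)."""

    n_voxels: int = 100_000
    mean: float = 0.8e-3
    sd: float = 0.1e-3
    outlier_fraction: float = 0.0
    outlier_mean: float = 1.9e-3
    outlier_sd: float = 0.0
    voxel_volume: float = DEFAULT_VOXEL_VOLUME_ML
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.sd < 0 or self.outlier_sd < 0 or self.voxel_volume <= 0:
            raise ValueError("sd, outlier_sd must be >= 0 and voxel_volume > 0")


def simulate_table(spec: SimulationSpec) -> MeasurementTable:
    """Draw one balanced measurement table from the mixed-effects model.

    ``a_i ~ N(0, sigma_a^2)``, ``b_i ~ N(0, sigma_ab^2)`` with
    ``ab_i1 = +b_i`` and ``ab_i2 = -b_i`` (the cancelling-bias constraint is
    enforced exactly), and ``eps_ijk ~ N(0, sigma_eps_j^2)``.
    """
    rng = np.random.default_rng(spec.seed)
    sign = np.array([1.0, -1.0])
    a = spec.sigma_a * rng.standard_normal(spec.P)
    b = spec.sigma_ab * rng.standard_normal(spec.P)
    sigma_eps = np.array([spec.sigma_eps_1, spec.sigma_eps_2])
    eps = rng.standard_normal((spec.P, 2, 2)) * sigma_eps[None, :, None]
    Y = spec.mu + a[:, None, None] + (sign * b[:, None])[:, :, None] + eps
    return MeasurementTable.from_array(Y, metric=spec.metric)


def simulate_voxels(spec: VoxelSimSpec) -> VoxelSet:
    """Draw a contaminated voxel ADC set.

    The base sample is drawn first, so two specs differing only in
    ``outlier_fraction`` share identical base draws under the same seed —
    contamination comparisons are exact, not confounded by resampling.
    """
    rng = np.random.default_rng(spec.seed)
    values = spec.mean + spec.sd * rng.standard_normal(spec.n_voxels)
    n_out = round(spec.n_voxels * spec.outlier_fraction)
    if n_out > 0:
        idx = rng.choice(spec.n_voxels, size=n_out, replace=False)
        values[idx] = spec.outlier_mean + spec.outlier_sd * rng.standard_normal(n_out)
    np.clip(values, 0.0, None, out=values)
    return VoxelSet(values, voxel_volume=spec.voxel_volume)


def simulate_reader_study(
    spec: SimulationSpec,
    voxel_spec: VoxelSimSpec | None = None,
    disagreement_prob: float = 0.25,
    cluster_fraction: float = 0.02,
    cluster_mean: float = 1.9e-3,
    cluster_sd: float = 0.05e-3,
    volume_jitter: float = 0.02,
    reading_noise_sd: float = 0.005e-3,
    size_log_sd: float = 0.8,
) -> dict:
    """End-to-end reader-study simulation; one MeasurementTable per metric.

    Per patient, a base lesion voxel set is drawn (patient mean ADC and
    lesion size vary across patients; the relative patient-mean spread is
    ``spec.sigma_a / spec.mu``) together with a fixed higher-ADC "equivocal
    lesion" cluster of ``cluster_fraction`` relative size.  Each of the four
    readings (observer x replicate) then sees the base set perturbed by:

    * inclusion of the cluster with probability ``disagreement_prob``
      (observers disagreeing whether an equivocal site is active disease);
    * per-voxel reading noise ``N(0, reading_noise_sd^2)``;
    * random sub-sampling of the segmentation by a relative amount
      ``~ |N(0, volume_jitter^2)|`` (boundary-tracing variability).

    The standard ADC > 2.0e-3 mm^2/s exclusion is applied before the gADC
    statistics.  With ``disagreement_prob = volume_jitter =
    reading_noise_sd = 0`` all four readings per patient are identical and
    downstream ICCs are 1 by construction.
    """
    if voxel_spec is None:
        voxel_spec = VoxelSimSpec()
    if not (0 <= disagreement_prob <= 1):
        raise ValueError("disagreement_prob must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    patient_cv = spec.sigma_a / spec.mu if spec.mu else 0.15
    metrics = ("median_gadc", "mean_gadc", "var_gadc", "skew_gadc", "kurt_gadc", "log_tdv")
    values = {m: np.empty((spec.P, 2, 2)) for m in metrics}

    for i in range(spec.P):
        mean_i = voxel_spec.mean * max(1.0 + patient_cv * rng.standard_normal(), 0.2)
        n_i = max(100, round(voxel_spec.n_voxels * rng.lognormal(0.0, size_log_sd)))
        base = mean_i + voxel_spec.sd * rng.standard_normal(n_i)
        n_cluster = max(1, round(cluster_fraction * n_i))
        cluster = cluster_mean + cluster_sd * rng.standard_normal(n_cluster)
        for j in (1, 2):
            for k in (1, 2):
                reading = base
                if reading_noise_sd > 0:
                    reading = reading + reading_noise_sd * rng.standard_normal(n_i)
                if volume_jitter > 0:
                    n_keep = round(n_i * (1.0 - abs(volume_jitter * rng.standard_normal())))
                    n_keep = int(np.clip(n_keep, min(100, n_i), n_i))
                    if n_keep < n_i:
                        reading = reading[rng.choice(n_i, size=n_keep, replace=False)]
                if rng.random() < disagreement_prob:
                    reading = np.concatenate([reading, cluster])
                voxels = apply_exclusion(
                    VoxelSet(np.clip(reading, 0.0, None), voxel_spec.voxel_volume)
                )
                summ = summarize_gadc(voxels)
                values["median_gadc"][i, j - 1, k - 1] = summ.median
                values["mean_gadc"][i, j - 1, k - 1] = summ.mean
                values["var_gadc"][i, j - 1, k - 1] = summ.variance
                values["skew_gadc"][i, j - 1, k - 1] = summ.skewness
                values["kurt_gadc"][i, j - 1, k - 1] = summ.kurtosis
                values["log_tdv"][i, j - 1, k - 1] = summ.log_tdv

    return {m: MeasurementTable.from_array(values[m], metric=m) for m in metrics}
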