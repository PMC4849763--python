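"""Long-format measurement tables for a balanced two-observer repeatability design.

A repeatability study records one numeric value per (patient, observer,
replicate) for each biomarker of interest: every patient is read by two
observers, and each observer repeats the reading once (typically after a
wash-out period to limit recall bias).  The resulting balanced ``P x 2 x 2``
grid is the unit of input for the variance-components model in
:mod:`dwirepeat.gibbs`.

Tables are exchanged as long-format CSV with columns
``patient, observer, replicate, value``.  Patient identifiers are opaque
strings mapped internally to ``1..P`` in order of first appearance; observers
and replicates are coded as the integers 1 and 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_METRICS",
    "DesignError",
    "IncompleteDesignError",
    "DuplicateRecordError",
    "Measurement",
    "MeasurementTable",
    "read_table",
    "write_table",
    "log_tdv",
]

#: Biomarkers produced by the whole-body DWI pipeline.  User-defined metric
#: names are also accepted everywhere.
CANONICAL_METRICS = (
    "median_gadc",
    "mean_gadc",
    "var_gadc",
    "skew_gadc",
    "kurt_gadc",
    "log_tdv",
)

_CSV_COLUMNS = ("patient", "observer", "replicate", "value")


class DesignError(ValueError):
    """The table violates the balanced P x 2 x 2 study design."""


class IncompleteDesignError(DesignError):
    """A (patient, observer, replicate) cell of the design is missing."""


class DuplicateRecordError(DesignError):
    """A (patient, observer, replicate) cell appears more than once."""


@dataclass(frozen=True)
class Measurement:
    """One observed biomarker value ``Y_ijk``.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier (index ``i`` after mapping).
    observer_id : int
        Reader identity ``j``, 1 or 2.
    replicate_id : int
        Repeat-reading index ``k``, 1 or 2.
    metric : str
        Biomarker name, e.g. ``"median_gadc"`` or ``"log_tdv"``.
    value : float
        Observed value in the metric's units.
    """

    patient_id: str
    observer_id: int
    replicate_id: int
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.observer_id not in (1, 2):
            raise ValueError(f"observer_id must be 1 or 2, got {self.observer_id!r}")
        if self.replicate_id not in (1, 2):
            raise ValueError(f"replicate_id must be 1 or 2, got {self.replicate_id!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")


@dataclass
class MeasurementTable:
    """Balanced table of 4P measurements of one metric.

    Validation enforces exactly one record per (patient, observer, replicate)
    triple over ``{1..P} x {1,2} x {1,2}``; records are stored sorted by
    (patient first-appearance order, observer, replicate).
    """

    metric: str
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.records:
            raise IncompleteDesignError("table contains no records")
        order: dict[str, int] = {}
        seen: dict[tuple, Measurement] = {}
        for rec in self.records:
            if rec.metric != self.metric:
                raise DesignError(
                    f"record metric {rec.metric!r} does not match table metric "
                    f"{self.metric!r}"
                )
            order.setdefault(rec.patient_id, len(order))
            key = (rec.patient_id, rec.observer_id, rec.replicate_id)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate record for (patient={key[0]!r}, observer={key[1]}, "
                    f"replicate={key[2]})"
                )
            seen[key] = rec
        for pid in order:
            for j in (1, 2):
                for k in (1, 2):
                    if (pid, j, k) not in seen:
                        raise IncompleteDesignError(
                            f"missing record for (patient={pid!r}, observer={j}, "
                            f"replicate={k})"
                        )
        self.records = sorted(
            self.records,
            key=lambda r: (order[r.patient_id], r.observer_id, r.replicate_id),
        )
        self._patient_ids = tuple(order)

    # -- accessors ----------------------------------------------------------

    @property
    def P(self) -> int:
        """Number of distinct patients."""
        return len(self._patient_ids)

    @property
    def patient_ids(self) -> tuple:
        """Patient identifiers in first-appearance (internal index) order."""
        return self._patient_ids

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns patient, observer, replicate, value."""
        return pd.DataFrame(
            {
                "patient": [r.patient_id for r in self.records],
                "observer": [r.observer_id for r in self.records],
                "replicate": [r.replicate_id for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    def to_array(self) -> np.ndarray:
        """Dense ``(P, 2, 2)`` array ``Y[i, j-1, k-1]`` of the observations."""
        values = np.array([r.value for r in self.records], dtype=float)
        return values.reshape(self.P, 2, 2)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metric: str) -> "MeasurementTable":
        """Build a validated table from a long-format DataFrame."""
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise DesignError(f"missing required column(s): {missing}")
        try:
            values = pd.to_numeric(frame["value"], errors="raise").astype(float)
            observers = pd.to_numeric(frame["observer"], errors="raise").astype(int)
            replicates = pd.to_numeric(frame["replicate"], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric entry in table: {exc}") from exc
        records = [
            Measurement(str(p), int(j), int(k), metric, float(v))
            for p, j, k, v in zip(frame["patient"], observers, replicates, values)
        ]
        return cls(metric=metric, records=records)

    @classmethod
    def from_array(
        cls, values, metric: str, patient_ids=None
    ) -> "MeasurementTable":
        """Build a table from a dense ``(P, 2, 2)`` array."""
        Y = np.asarray(values, dtype=float)
        if Y.ndim != 3 or Y.shape[1:] != (2, 2):
            raise DesignError(f"expected shape (P, 2, 2), got {Y.shape}")
        P = Y.shape[0]
        if patient_ids is None:
            width = len(str(P))
            patient_ids = [f"p{idx + 1:0{width}d}" for idx in range(P)]
        records = [
            Measurement(str(patient_ids[i]), j, k, metric, float(Y[i, j - 1, k - 1]))
            for i in range(P)
            for j in (1, 2)
            for k in (1, 2)
        ]
        return cls(metric=metric, records=records)


def read_table(source, metric: str) -> MeasurementTable:
    """Read a long-format CSV into a validated :class:`MeasurementTable`.

    ``source`` may be a path or an open text stream.  The file must have a
    header row with columns ``patient, observer, replicate, value``; a missing
    or duplicated design cell raises :class:`IncompleteDesignError` /
    :class:`DuplicateRecordError` naming the offending triple.
    """
    # round_trip parsing: the default float parser can be 1 ulp off
    frame = pd.read_csv(source, float_precision="round_trip")
    return MeasurementTable.from_frame(frame, metric=metric)


def write_table(table: MeasurementTable, dest) -> None:
    """Write a table as long-format CSV (the inverse of :func:`read_table`)."""
    # 17 significant digits guarantee exact float64 round-trips
    table.to_frame().to_csv(dest, index=False, float_format="%.17g")


def log_tdv(volume: float, base: float = math.e) -> float:
    """Log-transformed total diffusion volume.

    The total segmented disease volume (ml) is log-transformed to damp the
    scaling effect of segmentation errors on large tumour burdens.  Natural
    log by default; ``base`` is configurable.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume!r}")
    if base <= 0 or base == 1:
        raise ValueError(f"invalid log base {base!r}")
    return math.log(volume) / math.log(base)
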