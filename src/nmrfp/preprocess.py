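"""Probabilistic Quotient Normalization (PQN) of binned spectra.

PQN corrects sample-to-sample dilution differences: each row is first scaled
to a common total area, a reference spectrum is taken as the element-wise
median across (training) rows, and each row is then divided by the median of
its bin-wise quotients against that reference.

The fitted reference is reused when transforming new samples (projection of
held-out patients), which prevents information leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra_io import BinnedMatrix


@dataclass
class NormalizationReport:
    """Per-sample record of the normalization applied.

    ``quotient_factor`` is the median-quotient dilution estimate (step 4 of the
    PQN recipe); ``dilution_factor`` is the overall scalar each input row was
    divided by (area pre-normalization folded in), so that
    ``output_row = input_row / dilution_factor``.
    """

    reference: np.ndarray
    quotient_factor: np.ndarray
    dilution_factor: np.ndarray
    strategy: str = "median_all"


def pqn_reference(X: np.ndarray, total_area: bool = True) -> np.ndarray:
    """Element-wise median reference, optionally after unit-area row scaling."""
    X = np.asarray(X, dtype=float)
    if total_area:
        X = X / X.sum(axis=1, keepdims=True)
    return np.median(X, axis=0)


def pqn_quotient_factors(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Median quotient of each row against ``reference`` over positive-reference bins."""
    reference = np.asarray(reference, dtype=float)
    pos = reference > 0
    if not pos.any():
        raise ValueError("PQN reference has no positive bins")
    return np.median(np.asarray(X, dtype=float)[:, pos] / reference[pos], axis=1)


class PQNNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style PQN transformer.

    Parameters
    ----------
    total_area : bool
        Apply the total-area pre-normalization step (original PQN recipe).
    strategy : {"median_all", "median_reference_group"}
        Which rows define the reference; with ``median_reference_group`` a
        boolean row mask must be passed to :meth:`fit` as ``reference_rows``.

    Attributes
    ----------
    reference_ : ndarray
        Element-wise median reference spectrum (unit-area basis).
    area_scale_ : float
        Common-area basis of the output (fixed at 1: rows are expressed on
        the unit-total-area scale before quotient correction).
    """

    def __init__(self, total_area: bool = True, strategy: str = "median_all"):
        self.total_area = total_area
        self.strategy = strategy

    def _validate(self, X: np.ndarray, n_min: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bins)")
        zero = np.where(~np.any(X != 0, axis=1))[0]
        if zero.size:
            raise ValueError(f"all-zero row(s) at index {zero.tolist()}")
        if n_min is not None and X.shape[0] < n_min:
            raise ValueError(f"PQN needs at least {n_min} samples, got {X.shape[0]}")
        return X

    def fit(self, X, y=None, reference_rows: np.ndarray | None = None) -> "PQNNormalizer":
        X = self._validate(X, n_min=3)
        if self.strategy == "median_reference_group":
            if reference_rows is None:
                raise ValueError("strategy median_reference_group needs reference_rows")
            rows = X[np.asarray(reference_rows, dtype=bool)]
        elif self.strategy == "median_all":
            rows = X
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.reference_ = pqn_reference(rows, total_area=self.total_area)
        # outputs stay on the unit-area basis: any common rescale would break
        # exact scale invariance and idempotence of the transform
        self.area_scale_ = 1.0
        return self

    def _factors(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(quotient factors, overall per-row divisors)."""
        if self.total_area:
            areas = X.sum(axis=1)
            U = X / areas[:, None]
        else:
            areas = np.ones(X.shape[0])
            U = X
        q = pqn_quotient_factors(U, self.reference_)
        if np.any(q <= 0):
            raise ValueError("non-positive PQN quotient factor; check input signs")
        overall = areas * q / self.area_scale_
        return q, overall

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        _, overall = self._factors(X)
        return X / overall[:, None]

    def transform_report(self, X) -> tuple[np.ndarray, NormalizationReport]:
        X = self._validate(X)
        q, overall = self._factors(X)
        report = NormalizationReport(
            reference=self.reference_.copy(),
            quotient_factor=q,
            dilution_factor=overall,
            strategy=self.strategy,
        )
        return X / overall[:, None], report


def pqn_normalize(
    matrix: BinnedMatrix | np.ndarray,
    strategy: str = "median_all",
    total_area: bool = True,
    reference_rows: np.ndarray | None = None,
) -> tuple[BinnedMatrix | np.ndarray, NormalizationReport]:
    """Fit-and-apply PQN to a binned matrix (ndarray in, ndarray out)."""
    values = matrix.values if isinstance(matrix, BinnedMatrix) else matrix
    if isinstance(matrix, BinnedMatrix):
        ids = matrix.sample_ids
    norm = PQNNormalizer(total_area=total_area, strategy=strategy)
    try:
        norm.fit(values, reference_rows=reference_rows)
        out, report = norm.transform_report(values)
    except ValueError as exc:
        if isinstance(matrix, BinnedMatrix) and "all-zero row" in str(exc):
            import re

            m = re.search(r"\[([0-9, ]+)\]", str(exc))
            if m:
                bad = [ids[int(i)] for i in m.group(1).split(",")]
                raise ValueError(f"all-zero spectrum for sample(s) {bad}") from None
        raise
    if isinstance(matrix, BinnedMatrix):
        return (
            BinnedMatrix(
                values=out,
                bin_edges=list(matrix.bin_edges),
                sample_ids=list(matrix.sample_ids),
                pulse_seq=matrix.pulse_seq,
                calibration_shifts=matrix.calibration_shifts,
            ),
            report,
        )
    return out, report
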