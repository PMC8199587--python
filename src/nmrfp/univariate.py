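"""Univariate metabolite screen: quantification, Wilcoxon rank-sum tests,
Benjamini-Hochberg FDR control, Cliff's delta effect sizes and
median-threshold discrimination accuracies.

Effect sizes follow the convention that a positive Cliff's delta means lower
levels in the metastatic group (delta computed as early-vs-metastatic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import MetaboliteSignature, load_signatures
from .spectra_io import Spectrum, trapezoid_window_integral


def quantify_metabolites(
    spectra: Sequence[Spectrum],
    signatures: Sequence[MetaboliteSignature] | None = None,
    dilution_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrate each signature's quantification window in each spectrum.

    Spectra must be calibrated; dilution correction is applied by dividing each
    sample's row by its PQN dilution factor when ``dilution_factors`` is given.
    Returns a samples x metabolites table (one column per signature).
    """
    signatures = list(signatures) if signatures is not None else load_signatures()
    windows = [s.quant_window for s in signatures]
    rows = []
    for sp in spectra:
        for sig in signatures:
            lo, hi = sig.quant_window
            if lo < sp.ppm[0] or hi > sp.ppm[-1]:
                raise ValueError(
                    f"quantification window for {sig.name!r} ({lo}-{hi} ppm) outside "
                    f"spectral range [{sp.ppm[0]:.2f}, {sp.ppm[-1]:.2f}]"
                )
        rows.append(trapezoid_window_integral(sp, windows))
    table = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(signatures))),
        index=[sp.sample_id for sp in spectra],
        columns=[s.name for s in signatures],
    )
    if dilution_factors is not None:
        table = table.div(np.asarray(dilution_factors, dtype=float), axis=0)
    return table


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Normal approximation with mid-ranks, tie-corrected variance and continuity
    correction; degenerate input (all values identical) gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Signed Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y).

    Positive when x (early CRC) tends to exceed y (metastatic CRC).
    Computed via sorted-array rank counting, O((n+m) log m).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ys = np.sort(y)
    n_less = np.searchsorted(ys, x, side="left")  # y < x_i
    n_greater = y.size - np.searchsorted(ys, x, side="right")  # y > x_i
    return float((n_less.sum() - n_greater.sum()) / (x.size * y.size))


def median_threshold_accuracy(
    values: np.ndarray, labels: Sequence[str], positive_label: str = "metastatic"
) -> float:
    """Accuracy of the single-metabolite classifier thresholded at the pooled
    median.

    Direction follows the sign of Cliff's delta (early vs metastatic): with a
    positive delta (metabolite lower in metastatic serum) samples at or below
    the threshold are called metastatic, otherwise at or above.  Ties at the
    threshold side with the metastatic call.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("empty input")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    is_pos = labels == positive_label
    delta = cliffs_delta(values[~is_pos], values[is_pos])
    thr = float(np.median(values))
    if delta > 0:
        called_pos = values <= thr
    else:
        called_pos = values >= thr
    return float(np.mean(called_pos == is_pos))


@dataclass
class UnivariateResult:
    metabolite: str
    p_value: float
    p_adjusted: float
    effect_size: float
    median_threshold_accuracy: float
    significant: bool


def univariate_table(
    concentrations: pd.DataFrame,
    labels: Sequence[str],
    positive_label: str = "metastatic",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite screen: Wilcoxon p, BH-adjusted p (over all columns),
    signed Cliff's delta (early vs metastatic) and median-threshold accuracy;
    rows sorted by raw p-value."""
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    if is_pos.all() or not is_pos.any():
        raise ValueError("both groups must be present")
    raw_p, deltas, accs = [], [], []
    for col in concentrations.columns:
        v = concentrations[col].to_numpy(dtype=float)
        raw_p.append(wilcoxon_rank_sum(v[~is_pos], v[is_pos]))
        deltas.append(cliffs_delta(v[~is_pos], v[is_pos]))
        accs.append(median_threshold_accuracy(v, labels, positive_label))
    adj = bh_adjust(raw_p)
    table = pd.DataFrame(
        {
            "metabolite": list(concentrations.columns),
            "p_value": raw_p,
            "p_adjusted": adj,
            "effect_size": deltas,
            "median_threshold_accuracy": accs,
            "significant": adj < alpha,
        }
    )
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
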