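"""Willmott index of agreement between paired measurement series.

The index scores the correspondence of a series ``A`` against a reference
series ``B`` on a standardized 0-1 scale:

    d = 1 - sum_i (A_i - B_i)^2 / sum_i (|A'_i| + |B'_i|)^2,

with deviations taken about the reference mean, ``A'_i = A_i - Bbar`` and
``B'_i = B_i - Bbar``.  Identical series give d = 1 (including the
degenerate case where both series are constant and the denominator
vanishes); d = 0 indicates no agreement.  Term-wise,
``(A_i - B_i)^2 = (A'_i - B'_i)^2 <= (|A'_i| + |B'_i|)^2``, so d is always
in [0, 1], and it is invariant under a common additive shift of both
series.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["willmott_index", "pair_series", "monthly_willmott"]


def willmott_index(a, b, literal_printed_form: bool = False) -> float:
    """Index of agreement of series ``a`` against reference series ``b``.

    Parameters
    ----------
    a, b
        Paired numeric sequences of equal length >= 2 without missing
        values.  ``b`` is the reference: deviations are centered on its
        mean.
    literal_printed_form
        Off by default.  When set, evaluates the non-standard variant with
        denominator ``sum (|A_i| - |B_i|)^2`` (uncentered, differenced).
        That variant is undefined (NaN) whenever the denominator vanishes
        — e.g. for any pair of identical series — and is provided only for
        auditing against sources that print it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired observations")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not allowed after pairing")

    num = float(np.sum((a - b) ** 2))
    if literal_printed_form:
        den = float(np.sum((np.abs(a) - np.abs(b)) ** 2))
        return 1.0 - num / den if den > 0 else float("nan")

    b_bar = b.mean()
    den = float(np.sum((np.abs(a - b_bar) + np.abs(b - b_bar)) ** 2))
    if den == 0.0:
        # both series constant and equal to the reference mean: perfect match
        return 1.0
    return 1.0 - num / den


def pair_series(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two indexed series on their common index.

    Returns the paired arrays and the number of unpaired observations
    dropped from either side.
    """
    common = a.index.intersection(b.index)
    dropped = (len(a) - len(common)) + (len(b) - len(common))
    return a.loc[common].to_numpy(float), b.loc[common].to_numpy(float), dropped


def monthly_willmott(
    frame: pd.DataFrame,
    a_col: str,
    b_col: str,
    month_col: str = "month",
    pair_label: str | None = None,
) -> pd.DataFrame:
    """Willmott index per month for one pair of columns.

    ``b_col`` is the reference series.  Months with fewer than 2 complete
    pairs are omitted with a warning.  Returns columns
    month, pair_label, d, n.
    """
    label = pair_label or f"{a_col} vs {b_col}"
    rows = []
    for month, grp in frame.groupby(month_col, sort=True):
        paired = grp[[a_col, b_col]].dropna()
        if len(paired) < 2:
            warnings.warn(f"month {month}: fewer than 2 pairs for {label}; omitted")
            continue
        d = willmott_index(paired[a_col].to_numpy(), paired[b_col].to_numpy())
        rows.append({"month": month, "pair_label": label, "d": d, "n": len(paired)})
    return pd.DataFrame(rows, columns=["month", "pair_label", "d", "n"])
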