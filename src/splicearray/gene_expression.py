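"""Regulated-gene calling.

A gene is *expressed* in a condition if its mean expression index there
is >= 500 fluorescence units (inclusive). It is *regulated* if it is
expressed in at least one condition, its symmetric fold change between
condition means is >= 1.5, and an unpaired two-sided pooled-variance
(Student) t-test on the log2 indices gives p <= 0.05. No multiple-testing
correction is applied: the thresholds are raw cutoffs, used as such.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EXPRESSED_THRESHOLD = 500.0
DEFAULT_FC_MIN = 1.5
DEFAULT_ALPHA = 0.05

LOG_FLOOR = 1.0


def call_expressed(
    index: pd.DataFrame,
    condition_map: dict[str, str],
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene, per-condition expressed flags (condition mean >= threshold)."""
    out = {}
    for cond in ("control", "treated"):
        samples = [s for s in index.columns if condition_map[s] == cond]
        out[cond] = index[samples].mean(axis=1) >= threshold
    return pd.DataFrame(out, index=index.index)


def unpaired_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided unpaired t-test, vectorized over leading axes.

    ``a`` and ``b`` hold observations along the last axis (n >= 2 each).
    Default is the classical pooled-variance Student form with
    n_a + n_b - 2 degrees of freedom; ``equal_var=False`` gives Welch.

    Degenerate groups (zero pooled variance) are resolved explicitly:
    equal means -> t = 0, p = 1; unequal means -> p = 0 with a warning,
    since the difference is then infinitely many standard errors wide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("each group needs >= 2 observations")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = stats.ttest_ind(a, b, axis=-1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        mean_diff = a.mean(axis=-1) - b.mean(axis=-1)
        equal = degenerate & np.isclose(mean_diff, 0.0)
        unequal = degenerate & ~np.isclose(mean_diff, 0.0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        if np.any(unequal):
            warnings.warn(
                "zero within-group variance with unequal means: p set to 0",
                stacklevel=2,
            )
            t = np.where(unequal, np.sign(mean_diff) * np.inf, t)
            p = np.where(unequal, 0.0, p)
    if t.ndim == 0:
        return float(t), float(p)
    return t, p


def call_regulated_genes(
    index: pd.DataFrame,
    condition_map: dict[str, str],
    threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
    fc_min: float = DEFAULT_FC_MIN,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Apply the three-clause regulated-gene rule to a gene index table.

    Returns one row per gene: gene_id, mean_control, mean_treated,
    expressed_control, expressed_treated, fold_change (>= 1, symmetric),
    direction (sign of treated - control), t, p, regulated.
    """
    ctrl = [s for s in index.columns if condition_map[s] == "control"]
    trt = [s for s in index.columns if condition_map[s] == "treated"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per condition for the t-test")

    expressed = call_expressed(index, condition_map, threshold)
    m_c = index[ctrl].mean(axis=1).to_numpy()
    m_t = index[trt].mean(axis=1).to_numpy()
    # the 1.0-unit intensity floor upstream keeps means positive
    m_c = np.maximum(m_c, LOG_FLOOR)
    m_t = np.maximum(m_t, LOG_FLOOR)
    ratio = m_t / m_c
    fold_change = np.maximum(ratio, 1.0 / ratio)
    direction = np.sign(m_t - m_c).astype(int)

    log2_index = np.log2(np.maximum(index.to_numpy(dtype=float), LOG_FLOOR))
    cols = list(index.columns)
    a = log2_index[:, [cols.index(s) for s in trt]]
    b = log2_index[:, [cols.index(s) for s in ctrl]]
    t, p = unpaired_ttest(a, b, equal_var=equal_var)

    expressed_any = expressed["control"].to_numpy() | expressed["treated"].to_numpy()
    regulated = expressed_any & (fold_change >= fc_min) & (p <= alpha)

    return pd.DataFrame(
        {
            "gene_id": index.index,
            "mean_control": m_c,
            "mean_treated": m_t,
            "expressed_control": expressed["control"].to_numpy(),
            "expressed_treated": expressed["treated"].to_numpy(),
            "fold_change": fold_change,
            "direction": direction,
            "t": t,
            "p": p,
            "regulated": regulated,
        }
    ).reset_index(drop=True)
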