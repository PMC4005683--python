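"""Normalization and gene-level summarization.

Four stages, each taking and returning explicit state:

1. ``scale_arrays`` — per-array linear scaling so every sample's
   trimmed-mean intensity hits a common target (default 500, so the
   "expressed" cutoff of 500 sits at the array-wide trimmed mean).
2. ``correct_probe_effects`` — removes each probe's multiplicative
   affinity, estimated as the median log2 residual of the probe against
   its gene's per-sample median probe signal.
3. ``select_probes`` — per gene, drops constitutive probes whose
   cross-sample log2 profile correlates poorly with the gene's median
   constitutive profile (cross-hybridization filter); event probesets
   are never filtered, they carry the splicing signal.
4. ``gene_expression_index`` — arithmetic mean of the selected
   constitutive probes on the linear scale, per gene per sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import ArrayDesign, IntensityMatrix

logger = logging.getLogger(__name__)

LOG_FLOOR = 1.0  # intensities are floored before any log2


def scale_arrays(
    raw: IntensityMatrix, target: float = 500.0, trim: float = 0.02
) -> IntensityMatrix:
    """Scale each sample so its ``trim``-trimmed mean equals ``target``."""
    if raw.state != "raw":
        raise ValueError(f"expected state='raw', got {raw.state!r}")
    factors = {}
    scaled = raw.values.copy()
    for s in raw.values.columns:
        col = raw.values[s].to_numpy()
        tmean = float(stats.trim_mean(col, trim)) if trim > 0 else float(col.mean())
        if tmean <= 0:
            raise ValueError(f"sample {s!r} has non-positive trimmed mean; cannot scale")
        factors[s] = target / tmean
        scaled[s] = col * factors[s]
    logger.info("probe scaling factors: %s",
                ", ".join(f"{s}={f:.4g}" for s, f in factors.items()))
    return raw.with_values(scaled, state="scaled")


def correct_probe_effects(scaled: IntensityMatrix, design: ArrayDesign) -> IntensityMatrix:
    """Subtract per-probe affinity (median log2 residual) in log2 space.

    For each probe p of gene g:
        affinity(p) = median_s [ log2 x(p,s) - log2 ref(g,s) ]
    where ref(g,s) is the per-sample median signal of g's *constitutive*
    probes, and the corrected intensity is x(p,s) / 2**affinity(p).
    Referencing constitutive probes keeps the corrected scale at the
    gene's transcript-abundance level: junction probes run at an
    isoform-fraction of it and would drag a whole-gene median down by
    about half, which would defeat an absolute expressed threshold.
    A gene whose reference is a single flat probe gets affinity 0 for
    that probe (nothing to compare against).
    """
    if scaled.state != "scaled":
        raise ValueError(f"expected state='scaled', got {scaled.state!r}")
    frame = design.probe_frame().set_index("probe_id")
    log2x = np.log2(np.maximum(scaled.values, LOG_FLOOR))
    gene_of = frame.loc[log2x.index, "gene_id"]
    is_const = frame.loc[log2x.index, "group"] == "constitutive"
    gene_median = log2x[is_const.to_numpy()].groupby(gene_of[is_const]).median()
    resid = log2x.sub(gene_median.loc[gene_of].set_axis(log2x.index), axis=0)
    affinity = resid.median(axis=1)
    corrected = scaled.values / np.power(2.0, affinity.to_numpy())[:, None]
    return scaled.with_values(corrected, state="background_corrected")


def select_probes(
    corrected: IntensityMatrix,
    design: ArrayDesign,
    r_min: float = 0.7,
    min_keep: int = 3,
) -> pd.Series:
    """Boolean mask over probes: which are used for the gene index.

    Per gene, constitutive probes whose cross-sample log2 profile has
    Pearson r >= ``r_min`` against the gene's median constitutive profile
    are kept; if fewer than ``min_keep`` survive the filter, all of the
    gene's constitutive probes are kept instead (the filter is a guard
    against cross-hybridizing probes, not a way to empty a gene).
    Probes of event probesets are always False in the mask — they never
    enter the expression index.
    """
    if corrected.state != "background_corrected":
        raise ValueError(f"expected state='background_corrected', got {corrected.state!r}")
    frame = design.probe_frame().set_index("probe_id")
    is_const = frame.loc[corrected.values.index, "group"] == "constitutive"
    log2x = np.log2(np.maximum(corrected.values, LOG_FLOOR))
    mask = pd.Series(False, index=corrected.values.index)

    n_dropped = 0
    for gene, idx in frame.loc[is_const[is_const].index].groupby("gene_id").groups.items():
        profiles = log2x.loc[idx]
        ref = profiles.median(axis=0)
        keep = []
        for pid in idx:
            x = profiles.loc[pid].to_numpy()
            r = _pearson_or_zero(x, ref.to_numpy())
            keep.append(r >= r_min)
        keep = pd.Series(keep, index=idx)
        if int(keep.sum()) < min_keep:
            keep[:] = True  # fallback: too few survivors, keep everything
        else:
            n_dropped += int((~keep).sum())
        mask.loc[idx] = keep
    if n_dropped:
        logger.info("probe selection dropped %d constitutive probes (r < %.2f)",
                    n_dropped, r_min)
    return mask


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either profile has zero variance."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def gene_expression_index(
    corrected: IntensityMatrix, mask: pd.Series, design: ArrayDesign
) -> pd.DataFrame:
    """Gene x sample expression index: mean of selected constitutive probes."""
    frame = design.probe_frame().set_index("probe_id")
    sel = corrected.values.loc[mask[mask].index]
    gene_of = frame.loc[sel.index, "gene_id"]
    index = sel.groupby(gene_of).mean()
    index.index.name = "gene_id"
    # guaranteed by the min_keep fallback, but fail loudly if violated
    missing = set(g.gene_id for g in design.genes) - set(index.index)
    if missing:
        raise RuntimeError(f"genes with no selected probes: {sorted(missing)[:5]}")
    return index.loc[[g.gene_id for g in design.genes]]


def preprocess(
    raw: IntensityMatrix,
    design: ArrayDesign,
    target: float = 500.0,
    trim: float = 0.02,
    r_min: float = 0.7,
    min_keep: int = 3,
) -> tuple[IntensityMatrix, pd.Series, pd.DataFrame]:
    """Run all four stages; returns (corrected matrix, probe mask, gene index)."""
    scaled = scale_arrays(raw, target=target, trim=trim)
    corrected = correct_probe_effects(scaled, design)
    mask = select_probes(corrected, design, r_min=r_min, min_keep=min_keep)
    index = gene_expression_index(corrected, mask, design)
    return corrected, mask, index
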