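"""ChIP real-time-PCR relative quantification.

Enrichment of an immunoprecipitated chromatin fragment relative to
input DNA is estimated from threshold cycles as

    enrichment = 2 ** (Ct(reference) - Ct(sample))

with Ct(reference) from input DNA and Ct(sample) from the IP'd
chromatin. Only the cycle difference matters; no amplification-
efficiency correction is applied (the pure 2^dCt form). Replicates
(independent immunoprecipitations, at least three per experiment) are
aggregated as mean and sample standard deviation of the per-replicate
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import QpcrMeasurement

MIN_REPLICATES = 3


def relative_expression(m: QpcrMeasurement) -> float:
    """Relative enrichment 2**(ct_reference - ct_sample) for one replicate."""
    return 2.0 ** (m.ct_reference - m.ct_sample)


@dataclass(frozen=True)
class QpcrSummary:
    target_id: str
    mean: float
    sd: float
    n: int


def aggregate_replicates(ms: list[QpcrMeasurement]) -> QpcrSummary:
    """Mean, sample sd and n of per-replicate enrichment ratios for one target."""
    if not ms:
        raise ValueError("no measurements to aggregate")
    targets = {m.target_id for m in ms}
    if len(targets) > 1:
        raise ValueError(f"mixed targets in one aggregation: {sorted(targets)}")
    ratios = np.array([relative_expression(m) for m in ms])
    n = len(ratios)
    if n < MIN_REPLICATES:
        warnings.warn(
            f"target {ms[0].target_id!r}: only {n} replicate(s); "
            f"at least {MIN_REPLICATES} immunoprecipitations are expected",
            stacklevel=2,
        )
    sd = float(ratios.std(ddof=1)) if n > 1 else 0.0
    return QpcrSummary(target_id=ms[0].target_id, mean=float(ratios.mean()), sd=sd, n=n)


def enrichment_ratio(treated: QpcrSummary, control: QpcrSummary) -> tuple[float, float]:
    """Treated/control ratio of mean enrichments with propagated sd.

    First-order error propagation for a ratio r = a/b:
    sd_r = |r| * sqrt((sd_a/a)^2 + (sd_b/b)^2).
    """
    if control.mean == 0:
        raise ValueError("control mean enrichment is 0; ratio undefined")
    r = treated.mean / control.mean
    rel = 0.0
    if treated.mean != 0:
        rel += (treated.sd / treated.mean) ** 2
    rel += (control.sd / control.mean) ** 2
    return r, abs(r) * float(np.sqrt(rel))
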