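"""Splicing-index statistics and combinatorial event calling.

The pipeline per probe p and sample s:

    si(p, s) = log2( intensity(p, s) / index(gene(p), s) )

i.e. the probe signal normalized to its gene's expression index, so a
transcription change moves every probe of the gene equally and cancels,
while a splicing change moves inclusion and exclusion probes in
opposite directions. Per probe, the condition contrast is

    delta_si(p) = mean_treated si(p, .) - mean_control si(p, .)

and an unpaired two-sided t-test compares the si values between
conditions. Probe p-values within each probeset are combined with
Fisher's method (X = -2 sum ln p_i ~ chi-square, 2k df). A probeset is
significant when its combined p <= 0.01.

An event is called when at least one-third (ceiling) of its exclusion
probesets and one-third of its inclusion probesets are significant, and
every significant inclusion probeset moves opposite to the consensus
direction of the significant exclusion probesets. For a cassette exon
(1 exclusion junction, up to 3 inclusion probesets) this reduces to:
the exclusion junction plus at least one inclusion probeset significant,
with opposite splicing-index regulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import NO_EVENT, ArrayDesign, IntensityMatrix
from .gene_expression import unpaired_ttest

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_PS = 0.01
P_CLIP = 1e-300  # probe p-values are clipped to [P_CLIP, 1] before the log

LOG_FLOOR = 1.0


@dataclass
class SplicingIndexMatrix:
    """Per-probe splicing index (log2 probe/gene-index ratio) and contrast."""

    si: pd.DataFrame  # probe x sample
    delta_si: pd.Series  # per probe: mean treated - mean control
    condition_map: dict[str, str]


def splicing_index(
    corrected: IntensityMatrix, index: pd.DataFrame, design: ArrayDesign
) -> SplicingIndexMatrix:
    """Compute si and delta_si for every probe, constitutive included."""
    frame = design.probe_frame().set_index("probe_id")
    gene_of = frame.loc[corrected.values.index, "gene_id"]
    denom = index.loc[gene_of].set_axis(corrected.values.index)
    si = np.log2(np.maximum(corrected.values, LOG_FLOOR)) - np.log2(
        np.maximum(denom, LOG_FLOOR)
    )
    ctrl = corrected.samples("control")
    trt = corrected.samples("treated")
    delta = si[trt].mean(axis=1) - si[ctrl].mean(axis=1)
    return SplicingIndexMatrix(si=si, delta_si=delta, condition_map=dict(corrected.condition_map))


def probe_si_ttest(si: SplicingIndexMatrix, equal_var: bool = True) -> pd.Series:
    """Per-probe two-sided p-value, treated vs control si values."""
    ctrl = [s for s in si.si.columns if si.condition_map[s] == "control"]
    trt = [s for s in si.si.columns if si.condition_map[s] == "treated"]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per condition for probe t-tests")
    a = si.si[trt].to_numpy()
    b = si.si[ctrl].to_numpy()
    _, p = unpaired_ttest(a, b, equal_var=equal_var)
    return pd.Series(p, index=si.si.index, name="p")


def probe_pvalues(
    si: SplicingIndexMatrix,
    corrected: IntensityMatrix | None = None,
    on: str = "si",
    equal_var: bool = True,
) -> pd.Series:
    """Per-probe p-values on gene-normalized ('si') or raw probe signals.

    The gene-normalized test (default) contrasts splicing indices so
    expression changes cancel; ``on='raw'`` tests log2 probe intensities
    directly, in which case a transcription change alone can reach
    significance on every probe of the gene.
    """
    if on == "si":
        return probe_si_ttest(si, equal_var=equal_var)
    if on != "raw":
        raise ValueError(f"unknown test target {on!r} (use 'si' or 'raw')")
    if corrected is None:
        raise ValueError("raw-signal tests need the corrected intensity matrix")
    log2x = np.log2(np.maximum(corrected.values, LOG_FLOOR))
    ctrl = corrected.samples("control")
    trt = corrected.samples("treated")
    _, p = unpaired_ttest(log2x[trt].to_numpy(), log2x[ctrl].to_numpy(), equal_var=equal_var)
    return pd.Series(p, index=log2x.index, name="p")


def fisher_combine(p_values) -> float:
    """Fisher's method: combined p for k >= 1 independent p-values.

    X = -2 sum ln p_i is chi-square with 2k df under the global null;
    the combined p is its upper-tail probability. Inputs are clipped to
    [1e-300, 1] so the log is finite. For k = 1 the transform inverts
    exactly and the input p is returned unchanged.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    p = np.clip(p, P_CLIP, 1.0)
    x = -2.0 * np.log(p).sum()
    return float(sps.chi2.sf(x, df=2 * p.size))


def probeset_stats(
    si: SplicingIndexMatrix,
    probe_p: pd.Series,
    design: ArrayDesign,
    alpha_ps: float = DEFAULT_ALPHA_PS,
) -> pd.DataFrame:
    """Fisher-combined p, mean delta_si, direction and significance per probeset.

    Constitutive probesets are included in the output (their statistics
    are informative diagnostics) but event calling uses only inclusion
    and exclusion probesets.
    """
    frame = design.probe_frame().set_index("probe_id")
    meta = frame.loc[probe_p.index]
    clipped = np.clip(probe_p.to_numpy(dtype=float), P_CLIP, 1.0)
    df = pd.DataFrame(
        {
            "probeset_id": meta["probeset_id"].to_numpy(),
            "neg2logp": -2.0 * np.log(clipped),
            "delta_si": si.delta_si.loc[probe_p.index].to_numpy(),
        }
    )
    grouped = df.groupby("probeset_id", sort=False)
    agg = grouped.agg(
        x=("neg2logp", "sum"), k=("neg2logp", "size"), delta_si=("delta_si", "mean")
    )
    agg["fisher_p"] = sps.chi2.sf(agg["x"], df=2 * agg["k"])
    agg["direction"] = np.sign(agg["delta_si"]).astype(int)
    agg["significant"] = agg["fisher_p"] <= alpha_ps

    ps_meta = (
        meta[["probeset_id", "group", "event_id", "event_type", "gene_id"]]
        .drop_duplicates("probeset_id")
        .set_index("probeset_id")
    )
    out = agg.join(ps_meta).reset_index()
    return out[
        ["probeset_id", "gene_id", "event_id", "event_type", "group",
         "k", "fisher_p", "delta_si", "direction", "significant"]
    ]


@dataclass
class EventCall:
    event_id: str
    event_type: str
    n_incl: int
    n_excl: int
    n_sig_incl: int
    n_sig_excl: int
    called: bool
    direction: int  # +1 inclusion-up in treated, -1 inclusion-down, 0 not called


def call_event(members: pd.DataFrame, alpha_ps: float = DEFAULT_ALPHA_PS) -> EventCall:
    """Apply the one-third / opposite-direction rule to one event.

    ``members`` is the probeset_stats subset for a single event. The
    consensus direction is the sign of the summed delta_si over the
    significant exclusion probesets; all significant inclusion probesets
    must carry the opposite sign for the event to be called. A zero
    consensus (exactly cancelling exclusion shifts) leaves the event
    uncalled and is logged as indeterminate.
    """
    event_id = members["event_id"].iloc[0]
    event_type = members["event_type"].iloc[0]
    incl = members[members["group"] == "inclusion"]
    excl = members[members["group"] == "exclusion"]
    n_incl, n_excl = len(incl), len(excl)
    sig_incl = incl[incl["significant"]]
    sig_excl = excl[excl["significant"]]
    n_sig_incl, n_sig_excl = len(sig_incl), len(sig_excl)

    called = False
    direction = 0
    if (
        n_sig_excl >= math.ceil(n_excl / 3)
        and n_sig_incl >= math.ceil(n_incl / 3)
        and n_sig_incl > 0
        and n_sig_excl > 0
    ):
        consensus = int(np.sign(sig_excl["delta_si"].sum()))
        if consensus == 0:
            logger.info("event %s: indeterminate exclusion consensus, not called", event_id)
        elif (sig_incl["direction"] == -consensus).all():
            called = True
            direction = -consensus  # the inclusion side's direction
    return EventCall(
        event_id=event_id,
        event_type=event_type,
        n_incl=n_incl,
        n_excl=n_excl,
        n_sig_incl=n_sig_incl,
        n_sig_excl=n_sig_excl,
        called=called,
        direction=direction,
    )


def call_events(
    stats: pd.DataFrame, design: ArrayDesign, alpha_ps: float = DEFAULT_ALPHA_PS
) -> pd.DataFrame:
    """Run the event caller over every event in the design.

    Returns one row per event with the calling counts, decision and
    direction, plus the per-event minimum Fisher p and semicolon-joined
    per-probeset details for the report tables.
    """
    ev_stats = stats[stats["event_id"] != NO_EVENT]
    by_event = dict(tuple(ev_stats.groupby("event_id", sort=False)))
    rows = []
    for ev in design.events:
        members = by_event.get(ev.event_id)
        if members is None or members.empty:
            raise ValueError(f"no probeset statistics for event {ev.event_id!r}")
        call = call_event(members, alpha_ps=alpha_ps)
        rows.append(
            {
                "event_id": call.event_id,
                "event_type": call.event_type,
                "gene_id": ev.gene_id,
                "n_incl": call.n_incl,
                "n_excl": call.n_excl,
                "n_sig_incl": call.n_sig_incl,
                "n_sig_excl": call.n_sig_excl,
                "called": call.called,
                "direction": call.direction,
                "min_fisher_p": float(members["fisher_p"].min()),
                "probeset_p": ";".join(
                    f"{r.probeset_id}:{r.fisher_p:.3g}" for r in members.itertuples()
                ),
                "probeset_delta_si": ";".join(
                    f"{r.probeset_id}:{r.delta_si:.3g}" for r in members.itertuples()
                ),
            }
        )
    columns = [
        "event_id", "event_type", "gene_id", "n_incl", "n_excl",
        "n_sig_incl", "n_sig_excl", "called", "direction",
        "min_fisher_p", "probeset_p", "probeset_delta_si",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_events(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of called events: cassette, mutually exclusive, alt 5'/3' pooled.

    Alternative 5' and 3' splice sites are pooled into one category, the
    layout used for headline array summaries; ``total`` is their sum.
    """
    if calls.empty:
        n_cas = n_me = n_alt = 0
    else:
        called = calls[calls["called"]]
        n_cas = int((called["event_type"] == "cassette").sum())
        n_me = int((called["event_type"] == "mutually_exclusive").sum())
        n_alt = int(called["event_type"].isin(["alt5", "alt3"]).sum())
    return pd.DataFrame(
        [
            {"category": "cassette", "n_called": n_cas},
            {"category": "mutually_exclusive", "n_called": n_me},
            {"category": "alt_ss", "n_called": n_alt},
            {"category": "total", "n_called": n_cas + n_me + n_alt},
        ]
    )
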