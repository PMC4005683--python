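"""Synthetic junction-array generator with known ground truth.

Emulates, at reduced scale, a junction-array design in which each
alternative-splicing event is covered by inclusion and exclusion
probesets, and generates two-condition intensity data from a
two-isoform mixture model:

    constitutive probe mean = affinity * E_gene
    inclusion probe mean    = affinity * PSI * E_gene
    exclusion probe mean    = affinity * (1 - PSI) * E_gene

where E_gene is the gene's transcript abundance on the fluorescence
scale, PSI the fraction of transcripts containing the alternative
exon, and affinity a per-probe multiplicative response (log-normal
across probes). Replicate noise is multiplicative log-normal; an
intensity floor of 1.0 fluorescence unit keeps logs finite, mimicking
optical background on a scanner.

Injected effects (expression fold changes and PSI shifts in the
treated condition) are recorded in a :class:`TruthTable` so callers can
be scored for recovery. The default event-type mix follows the
composition of a human junction array: about 63% cassette exons, 31%
alternative 5'/3' splice sites and 6% mutually exclusive exon pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ArrayDesign,
    EventAnnot,
    GeneAnnot,
    IntensityMatrix,
    ProbeAnnot,
    ProbesetAnnot,
)

# event-type composition of the emulated array:
# 13150 cassette : 6517 alt 5'/3' : 1145 mutually exclusive (total 20812)
EVENT_MIX = {
    "cassette": 13150 / 20812,
    "alt5": 6517 / 2 / 20812,
    "alt3": 6517 / 2 / 20812,
    "mutually_exclusive": 1145 / 20812,
}


@dataclass
class SimulationParams:
    """Generator settings; defaults describe a typical two-condition run.

    Expression and noise scales are in log2 fluorescence units: baseline
    abundance log2(E) ~ Normal(mu_expr, sd_expr), per-probe affinity
    ~ Normal(0, sd_affinity), replicate noise ~ Normal(0, sd_noise).
    Baseline PSI is Uniform(psi_low, psi_high); injected splicing shifts
    move PSI by +/- delta_psi (clipped to [0, 1]) in the treated
    condition, and injected expression changes multiply E by
    2**expr_log2fc. ``fraction_unexpressed`` genes are drawn near the
    optical background (2**background_log2 ~ 128, below a 500-unit
    expressed threshold) rather than at zero.
    """

    seed: int = 0
    n_genes: int = 100
    events_per_gene: float = 1.0  # Poisson mean
    n_replicates: int = 3
    mu_expr: float = 10.0
    sd_expr: float = 1.5
    sd_affinity: float = 0.5
    sd_noise: float = 0.25
    psi_low: float = 0.2
    psi_high: float = 0.8
    fraction_regulated_splicing: float = 0.0
    delta_psi: float = 0.3
    fraction_regulated_expression: float = 0.0
    expr_log2fc: float = 1.0
    fraction_unexpressed: float = 0.1
    background_log2: float = 7.0
    n_constitutive_probesets: int = 2
    probes_per_probeset: tuple[int, int] = (3, 4)  # inclusive range
    intensity_floor: float = 1.0
    event_mix: dict[str, float] = field(default_factory=lambda: dict(EVENT_MIX))

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (t-tests need replication)")
        for name in (
            "fraction_regulated_splicing",
            "fraction_regulated_expression",
            "fraction_unexpressed",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.psi_low <= self.psi_high <= 1.0:
            raise ValueError("need 0 <= psi_low <= psi_high <= 1")
        if self.events_per_gene < 0:
            raise ValueError("events_per_gene must be >= 0")
        if self.n_constitutive_probesets < 1:
            raise ValueError("need >= 1 constitutive probeset per gene")

    def _streams(self) -> dict[str, np.random.Generator]:
        """Independent deterministic substreams, one per stage."""
        ss = np.random.SeedSequence(self.seed)
        names = ("design", "truth", "noise")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment.

    ``genes``: gene_id, expr_control/expr_treated (linear E), expressed
    (above-background draw), regulated, direction. ``events``: event_id,
    gene_id, event_type, psi_control, psi_treated, regulated, direction
    (sign of the treated-minus-control PSI shift).
    """

    genes: pd.DataFrame
    events: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.events.to_csv(out / "truth_events.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, out_dir: str | Path) -> "TruthTable":
        out = Path(out_dir)
        return cls(
            genes=pd.read_csv(out / "truth_genes.tsv", sep="\t"),
            events=pd.read_csv(out / "truth_events.tsv", sep="\t"),
        )


def _event_probesets(event_type: str, event_id: str) -> list[ProbesetAnnot]:
    """Probeset layout per event type.

    Cassette: one skipping (flank-flank) junction on the exclusion side;
    exon body plus two flank-exon junctions on the inclusion side.
    Alt 5'/3': distal junction = inclusion, proximal = exclusion.
    Mutually exclusive: exon A body+junction = inclusion group, exon B
    body+junction = exclusion group.
    """
    e = event_id
    if event_type == "cassette":
        return [
            ProbesetAnnot(f"{e}_excl_j", e, "exclusion", "junction"),
            ProbesetAnnot(f"{e}_incl_body", e, "inclusion", "exon_body"),
            ProbesetAnnot(f"{e}_incl_j5", e, "inclusion", "junction"),
            ProbesetAnnot(f"{e}_incl_j3", e, "inclusion", "junction"),
        ]
    if event_type in ("alt5", "alt3"):
        return [
            ProbesetAnnot(f"{e}_distal_j", e, "inclusion", "junction"),
            ProbesetAnnot(f"{e}_proximal_j", e, "exclusion", "junction"),
        ]
    if event_type == "mutually_exclusive":
        return [
            ProbesetAnnot(f"{e}_A_body", e, "inclusion", "exon_body"),
            ProbesetAnnot(f"{e}_A_j", e, "inclusion", "junction"),
            ProbesetAnnot(f"{e}_B_body", e, "exclusion", "exon_body"),
            ProbesetAnnot(f"{e}_B_j", e, "exclusion", "junction"),
        ]
    raise ValueError(f"unknown event type {event_type!r}")


def generate_design(params: SimulationParams) -> ArrayDesign:
    """Draw a junction-array design: genes, events, probesets, probes."""
    params.validate()
    rng = params._streams()["design"]
    types = list(params.event_mix)
    probs = np.asarray([params.event_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    lo, hi = params.probes_per_probeset

    genes: list[GeneAnnot] = []
    events: list[EventAnnot] = []
    probesets: list[ProbesetAnnot] = []
    probes: list[ProbeAnnot] = []
    constitutive_gene: dict[str, str] = {}

    gene_span = 10_000
    for i in range(params.n_genes):
        gid = f"g{i:05d}"
        start = 1 + i * gene_span
        end = start + gene_span - 1
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneAnnot(gid, "chr1", strand, start, end))

        gene_probesets: list[ProbesetAnnot] = []
        for k in range(params.n_constitutive_probesets):
            ps = ProbesetAnnot(f"{gid}_const{k}", None, "constitutive", "exon_body")
            gene_probesets.append(ps)
            constitutive_gene[ps.probeset_id] = gid

        n_events = int(rng.poisson(params.events_per_gene))
        for j in range(n_events):
            eid = f"{gid}_e{j}"
            etype = types[rng.choice(len(types), p=probs)]
            ev_start = start + 1000 + j * 500
            events.append(EventAnnot(eid, gid, etype, ev_start, ev_start + 199))
            gene_probesets.extend(_event_probesets(etype, eid))

        probesets.extend(gene_probesets)
        for ps in gene_probesets:
            n_probes = int(rng.integers(lo, hi + 1))
            probes.extend(
                ProbeAnnot(f"{ps.probeset_id}_p{k}", ps.probeset_id) for k in range(n_probes)
            )

    return ArrayDesign(
        genes=genes,
        events=events,
        probesets=probesets,
        probes=probes,
        constitutive_gene=constitutive_gene,
    )


def simulate_experiment(
    design: ArrayDesign, params: SimulationParams
) -> tuple[IntensityMatrix, TruthTable]:
    """Generate raw intensities for 2 x n_replicates arrays plus truth."""
    params.validate()
    streams = params._streams()
    rng_truth, rng_noise = streams["truth"], streams["noise"]

    # ---- gene-level truth -------------------------------------------
    gene_rows = []
    log2_e_control: dict[str, float] = {}
    log2_e_treated: dict[str, float] = {}
    for g in design.genes:
        unexpressed = rng_truth.random() < params.fraction_unexpressed
        if unexpressed:
            base = params.background_log2 + rng_truth.normal(0.0, 0.25)
        else:
            base = rng_truth.normal(params.mu_expr, params.sd_expr)
        regulated = (not unexpressed) and rng_truth.random() < params.fraction_regulated_expression
        direction = int(rng_truth.choice([-1, 1])) if regulated else 0
        log2_e_control[g.gene_id] = base
        log2_e_treated[g.gene_id] = base + direction * params.expr_log2fc
        gene_rows.append(
            (g.gene_id, 2.0 ** base, 2.0 ** log2_e_treated[g.gene_id],
             not unexpressed, regulated, direction)
        )
    genes_truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "expr_control", "expr_treated", "expressed", "regulated", "direction"],
    )

    # ---- event-level truth ------------------------------------------
    event_rows = []
    psi_control: dict[str, float] = {}
    psi_treated: dict[str, float] = {}
    for ev in design.events:
        psi0 = rng_truth.uniform(params.psi_low, params.psi_high)
        regulated = rng_truth.random() < params.fraction_regulated_splicing
        if regulated:
            shift = params.delta_psi * rng_truth.choice([-1.0, 1.0])
            psi1 = float(np.clip(psi0 + shift, 0.0, 1.0))
        else:
            psi1 = psi0
        psi_control[ev.event_id] = psi0
        psi_treated[ev.event_id] = psi1
        direction = int(np.sign(psi1 - psi0))
        event_rows.append(
            (ev.event_id, ev.gene_id, ev.event_type, psi0, psi1, regulated, direction)
        )
    events_truth = pd.DataFrame(
        event_rows,
        columns=["event_id", "gene_id", "event_type",
                 "psi_control", "psi_treated", "regulated", "direction"],
    )

    # ---- probe means and noisy replicates ---------------------------
    frame = design.probe_frame()
    n_probes = len(frame)
    affinity = rng_truth.normal(0.0, params.sd_affinity, size=n_probes)

    def _mean_matrix(log2_e: dict[str, float], psi: dict[str, float]) -> np.ndarray:
        e = np.array([2.0 ** log2_e[g] for g in frame["gene_id"]])
        frac = np.ones(n_probes)
        is_incl = (frame["group"] == "inclusion").to_numpy()
        is_excl = (frame["group"] == "exclusion").to_numpy()
        psi_vec = np.array(
            [psi.get(e_id, 0.0) for e_id in frame["event_id"]]
        )
        frac[is_incl] = psi_vec[is_incl]
        frac[is_excl] = 1.0 - psi_vec[is_excl]
        return (2.0 ** affinity) * frac * e

    mean_c = _mean_matrix(log2_e_control, psi_control)
    mean_t = _mean_matrix(log2_e_treated, psi_treated)

    n_rep = params.n_replicates
    sample_ids = [f"control_{r + 1}" for r in range(n_rep)] + [
        f"treated_{r + 1}" for r in range(n_rep)
    ]
    condition_map = {s: ("control" if s.startswith("control") else "treated") for s in sample_ids}

    values = np.empty((n_probes, 2 * n_rep))
    for r in range(n_rep):
        values[:, r] = mean_c
        values[:, n_rep + r] = mean_t
    if params.sd_noise > 0:
        values *= 2.0 ** rng_noise.normal(0.0, params.sd_noise, size=values.shape)
    values = np.maximum(values, params.intensity_floor)

    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=frame["probe_id"].tolist(), columns=sample_ids),
        condition_map=condition_map,
        state="raw",
    )
    return matrix, TruthTable(genes=genes_truth, events=events_truth)
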