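"""Domain types for exon-junction array analysis.

The object hierarchy mirrors the physical array design: genes carry
alternative-splicing *events* (cassette exons, alternative 5'/3' splice
sites, mutually exclusive exons); each event is interrogated by
*probesets* that support either the inclusion isoform (exon body and
flank-exon junctions) or the exclusion isoform (flank-flank junction);
each probeset contains several individual *probes*. Constitutive
probesets (not tied to any event) measure overall gene expression.

Every statistic downstream is aggregated over this hierarchy, so the
design is validated strictly on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

EventType = Literal["cassette", "alt5", "alt3", "mutually_exclusive"]
Group = Literal["inclusion", "exclusion", "constitutive"]
Role = Literal["exon_body", "junction"]

EVENT_TYPES = ("cassette", "alt5", "alt3", "mutually_exclusive")
GROUPS = ("inclusion", "exclusion", "constitutive")
ROLES = ("exon_body", "junction")

#: sentinel used in the design table for "no event" (constitutive probesets)
NO_EVENT = "."


class DesignError(ValueError):
    """Raised when an array design violates a structural invariant."""


@dataclass(frozen=True)
class GeneAnnot:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class EventAnnot:
    event_id: str
    gene_id: str
    event_type: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class ProbesetAnnot:
    probeset_id: str
    event_id: str | None  # None => constitutive
    group: str
    role: str


@dataclass(frozen=True)
class ProbeAnnot:
    probe_id: str
    probeset_id: str


@dataclass
class ArrayDesign:
    """Validated gene → event → probeset → probe hierarchy.

    Parameters
    ----------
    genes, events, probesets, probes
        Annotation records. ``probesets`` with ``event_id=None`` are
        constitutive and must carry ``group='constitutive'``.
    """

    genes: list[GeneAnnot]
    events: list[EventAnnot]
    probesets: list[ProbesetAnnot]
    probes: list[ProbeAnnot]
    #: probeset_id -> gene_id for constitutive probesets (no event to go through)
    constitutive_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def gene_of_probeset(self, probeset_id: str) -> str:
        ps = self._probeset_map[probeset_id]
        if ps.event_id is None:
            return self.constitutive_gene[probeset_id]
        return self._event_map[ps.event_id].gene_id

    def probesets_of_event(self, event_id: str) -> list[ProbesetAnnot]:
        return [ps for ps in self.probesets if ps.event_id == event_id]

    def probe_frame(self) -> pd.DataFrame:
        """Flat per-probe table (one row per probe) used by vectorized stats.

        Columns: probe_id, probeset_id, group, role, event_id, event_type,
        gene_id. ``event_id`` is ``NO_EVENT`` for constitutive probes.
        """
        rows = []
        for pr in self.probes:
            ps = self._probeset_map[pr.probeset_id]
            if ps.event_id is None:
                ev_id, ev_type = NO_EVENT, NO_EVENT
                gene_id = self.constitutive_gene[ps.probeset_id]
            else:
                ev = self._event_map[ps.event_id]
                ev_id, ev_type = ev.event_id, ev.event_type
                gene_id = ev.gene_id
            rows.append(
                (pr.probe_id, pr.probeset_id, ps.group, ps.role, ev_id, ev_type, gene_id)
            )
        return pd.DataFrame(
            rows,
            columns=[
                "probe_id", "probeset_id", "group", "role",
                "event_id", "event_type", "gene_id",
            ],
        )

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if not self.probes:
            raise DesignError("no probes in design")
        self._gene_map = {g.gene_id: g for g in self.genes}
        if len(self._gene_map) != len(self.genes):
            raise DesignError("duplicate gene_id in design")
        self._event_map = {e.event_id: e for e in self.events}
        if len(self._event_map) != len(self.events):
            raise DesignError("duplicate event_id in design")
        self._probeset_map = {ps.probeset_id: ps for ps in self.probesets}
        if len(self._probeset_map) != len(self.probesets):
            raise DesignError("duplicate probeset_id in design")
        seen_probes = set()
        for pr in self.probes:
            if pr.probe_id in seen_probes:
                raise DesignError(f"duplicate probe_id {pr.probe_id!r}")
            seen_probes.add(pr.probe_id)
            if pr.probeset_id not in self._probeset_map:
                raise DesignError(
                    f"probe {pr.probe_id!r} references unknown probeset {pr.probeset_id!r}"
                )
        for ev in self.events:
            if ev.gene_id not in self._gene_map:
                raise DesignError(f"event {ev.event_id!r} references unknown gene {ev.gene_id!r}")
            if ev.event_type not in EVENT_TYPES:
                raise DesignError(f"event {ev.event_id!r} has unknown type {ev.event_type!r}")
        for g in self.genes:
            if g.strand not in ("+", "-"):
                raise DesignError(f"gene {g.gene_id!r} has invalid strand {g.strand!r}")

        by_event: dict[str, list[ProbesetAnnot]] = {}
        const_genes: set[str] = set()
        for ps in self.probesets:
            if ps.group not in GROUPS:
                raise DesignError(f"probeset {ps.probeset_id!r} has unknown group {ps.group!r}")
            if ps.role not in ROLES:
                raise DesignError(f"probeset {ps.probeset_id!r} has unknown role {ps.role!r}")
            if ps.event_id is None:
                if ps.group != "constitutive":
                    raise DesignError(
                        f"probeset {ps.probeset_id!r} has no event but group {ps.group!r}"
                    )
                gene = self.constitutive_gene.get(ps.probeset_id)
                if gene is None or gene not in self._gene_map:
                    raise DesignError(
                        f"constitutive probeset {ps.probeset_id!r} maps to unknown gene {gene!r}"
                    )
                const_genes.add(gene)
            else:
                if ps.event_id not in self._event_map:
                    raise DesignError(
                        f"probeset {ps.probeset_id!r} references unknown event {ps.event_id!r}"
                    )
                if ps.group == "constitutive":
                    raise DesignError(
                        f"probeset {ps.probeset_id!r} is constitutive but attached to "
                        f"event {ps.event_id!r}"
                    )
                by_event.setdefault(ps.event_id, []).append(ps)

        probes_per_set: dict[str, int] = {}
        for pr in self.probes:
            probes_per_set[pr.probeset_id] = probes_per_set.get(pr.probeset_id, 0) + 1
        for ps in self.probesets:
            if probes_per_set.get(ps.probeset_id, 0) == 0:
                raise DesignError(f"probeset {ps.probeset_id!r} has no probes")

        for ev in self.events:
            members = by_event.get(ev.event_id, [])
            n_incl = sum(1 for ps in members if ps.group == "inclusion")
            n_excl = sum(1 for ps in members if ps.group == "exclusion")
            if n_incl < 1 or n_excl < 1:
                raise DesignError(
                    f"event {ev.event_id!r} lacks an inclusion or exclusion probeset "
                    f"(inclusion={n_incl}, exclusion={n_excl})"
                )
            if ev.event_type == "cassette":
                # one flank-flank skipping junction; up to 1 exon body + 2
                # inclusion junctions on the inclusion side
                if n_excl != 1:
                    raise DesignError(
                        f"cassette event {ev.event_id!r} must have exactly 1 exclusion "
                        f"probeset, found {n_excl}"
                    )
                if n_incl > 3:
                    raise DesignError(
                        f"cassette event {ev.event_id!r} has {n_incl} inclusion probesets "
                        "(max 3: one exon body + two junctions)"
                    )
        for g in self.genes:
            if g.gene_id not in const_genes:
                raise DesignError(f"gene {g.gene_id!r} has no constitutive probeset")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(n_genes, n_events, n_probesets, n_probes)."""
        return (len(self.genes), len(self.events), len(self.probesets), len(self.probes))


@dataclass
class IntensityMatrix:
    """Probe x sample fluorescence intensities with condition labels.

    ``values`` is a DataFrame indexed by probe_id with sample columns;
    intensities are linear-scale, non-negative. ``state`` tracks the
    preprocessing stage: raw -> scaled -> background_corrected.
    """

    values: pd.DataFrame
    condition_map: dict[str, str]  # sample_id -> {"control", "treated"}
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values.index.name = "probe_id"
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = [s for s in self.values.columns if s not in self.condition_map]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        bad = {c for c in self.condition_map.values()} - {"control", "treated"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_map[s] == condition]

    def with_values(self, values: pd.DataFrame, state: str) -> "IntensityMatrix":
        return IntensityMatrix(values=values, condition_map=dict(self.condition_map), state=state)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR replicate: threshold cycles of input DNA vs IP'd chromatin."""

    target_id: str
    ct_reference: float
    ct_sample: float
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        for name, ct in (("ct_reference", self.ct_reference), ("ct_sample", self.ct_sample)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {ct!r}")
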