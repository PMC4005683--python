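"""Readers and writers for the tab-delimited artifact formats.

All files are UTF-8, tab-delimited, with a header line; lines starting
with '#' are comments. Design coordinates are 1-based inclusive
(GFF-like); the BED export converts to 0-based half-open. Constitutive
probesets carry ``event_id = "."`` in the single design table.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import pandas as pd

from .model import (
    NO_EVENT,
    ArrayDesign,
    DesignError,
    EventAnnot,
    GeneAnnot,
    IntensityMatrix,
    ProbeAnnot,
    ProbesetAnnot,
    QpcrMeasurement,
)

DESIGN_COLUMNS = [
    "probe_id", "probeset_id", "group", "role",
    "event_id", "event_type", "gene_id", "chrom", "start", "end", "strand",
]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_design(path: str | Path) -> ArrayDesign:
    """Parse and validate a one-table array design.

    One row per probe; gene/event/probeset annotations are repeated on
    each of their probes' rows and must be internally consistent.
    """
    df = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"design file missing columns: {missing}")
    if df.empty:
        raise DesignError("no probes in design file")

    genes: dict[str, GeneAnnot] = {}
    events: dict[str, EventAnnot] = {}
    probesets: dict[str, ProbesetAnnot] = {}
    constitutive_gene: dict[str, str] = {}
    probes: list[ProbeAnnot] = []

    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if row.gene_id not in genes:
            genes[row.gene_id] = GeneAnnot(row.gene_id, row.chrom, row.strand, start, end)
        else:
            # widen the gene span to cover all of its features
            g = genes[row.gene_id]
            genes[row.gene_id] = GeneAnnot(
                g.gene_id, g.chrom, g.strand, min(g.start, start), max(g.end, end)
            )
        is_const = row.event_id == NO_EVENT or (
            isinstance(row.event_id, float) and math.isnan(row.event_id)
        )
        if not is_const and row.event_id not in events:
            events[row.event_id] = EventAnnot(
                row.event_id, row.gene_id, row.event_type, start, end
            )
        if row.probeset_id not in probesets:
            probesets[row.probeset_id] = ProbesetAnnot(
                row.probeset_id, None if is_const else row.event_id, row.group, row.role
            )
            if is_const:
                constitutive_gene[row.probeset_id] = row.gene_id
        probes.append(ProbeAnnot(row.probe_id, row.probeset_id))

    return ArrayDesign(
        genes=list(genes.values()),
        events=list(events.values()),
        probesets=list(probesets.values()),
        probes=probes,
        constitutive_gene=constitutive_gene,
    )


def write_design(design: ArrayDesign, path: str | Path) -> None:
    """Inverse of :func:`read_design` (row order follows probe order)."""
    gmap = {g.gene_id: g for g in design.genes}
    emap = {e.event_id: e for e in design.events}
    psmap = {ps.probeset_id: ps for ps in design.probesets}
    rows = []
    for pr in design.probes:
        ps = psmap[pr.probeset_id]
        if ps.event_id is None:
            gene = gmap[design.constitutive_gene[ps.probeset_id]]
            ev_id, ev_type, start, end = NO_EVENT, NO_EVENT, gene.start, gene.end
        else:
            ev = emap[ps.event_id]
            gene = gmap[ev.gene_id]
            ev_id, ev_type, start, end = ev.event_id, ev.event_type, ev.start, ev.end
        rows.append(
            (pr.probe_id, pr.probeset_id, ps.group, ps.role, ev_id, ev_type,
             gene.gene_id, gene.chrom, start, end, gene.strand)
        )
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_intensities(
    path: str | Path, design: ArrayDesign, conditions: dict[str, str]
) -> IntensityMatrix:
    """Read a probe x sample intensity table matched against a design."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    design_probes = design.probe_ids
    missing = [p for p in design_probes if p not in df.index]
    if missing:
        raise ValueError(f"intensity file missing probes: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    extra = [p for p in df.index if p not in set(design_probes)]
    if extra:
        raise ValueError(f"probe {extra[0]!r} in intensity file is absent from design")
    df = df.loc[design_probes].astype(float)
    neg = (df < 0)
    if neg.to_numpy().any():
        r, c = next(zip(*neg.to_numpy().nonzero()))
        raise ValueError(
            f"negative intensity at probe {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    for cond in ("control", "treated"):
        n = sum(1 for s in df.columns if conditions.get(s) == cond)
        if n < 2:
            warnings.warn(
                f"condition {cond!r} has {n} sample(s); t-tests require >= 2",
                stacklevel=2,
            )
    return IntensityMatrix(values=df, condition_map=dict(conditions), state="raw")


def write_intensities(mat: IntensityMatrix, path: str | Path) -> None:
    out = mat.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_cts(path: str | Path) -> list[QpcrMeasurement]:
    """Read qPCR Ct table: target_id, replicate_id, ct_reference, ct_sample.

    An optional ``condition`` column is carried through by the CLI but is
    not part of the measurement itself.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = ["target_id", "replicate_id", "ct_reference", "ct_sample"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"Ct file missing columns: {missing}")
    return [
        QpcrMeasurement(
            target_id=row.target_id,
            ct_reference=float(row.ct_reference),
            ct_sample=float(row.ct_sample),
            replicate_id=row.replicate_id,
        )
        for row in df.itertuples(index=False)
    ]


def write_results(
    genes: pd.DataFrame,
    events: pd.DataFrame,
    summary: pd.DataFrame,
    design: ArrayDesign,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write genes.tsv, events.tsv, summary.tsv and events.bed.

    ``events.bed`` contains only called events, converted from the design's
    1-based inclusive intervals to BED's 0-based half-open convention
    (start-1, end), on either strand.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "events": out / "events.tsv",
        "summary": out / "summary.tsv",
        "bed": out / "events.bed",
    }
    genes.to_csv(paths["genes"], sep="\t", index=False)
    events.to_csv(paths["events"], sep="\t", index=False)
    summary.to_csv(paths["summary"], sep="\t", index=False)

    emap = {e.event_id: e for e in design.events}
    gmap = {g.gene_id: g for g in design.genes}
    with open(paths["bed"], "w", encoding="utf-8") as fh:
        if not events.empty:
            for row in events.loc[events["called"]].itertuples(index=False):
                ev = emap[row.event_id]
                gene = gmap[ev.gene_id]
                min_p = getattr(row, "min_fisher_p", 1.0)
                score = min(1000, int(round(-10 * _log10(max(float(min_p), 1e-100)))))
                fh.write(
                    f"{gene.chrom}\t{ev.start - 1}\t{ev.end}\t"
                    f"{ev.event_id}\t{score}\t{gene.strand}\n"
                )
    return paths


def _log10(x: float) -> float:
    return math.log10(x)
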