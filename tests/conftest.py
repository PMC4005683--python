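"""Shared fixtures: a tiny hand-built cassette design and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicearray import (
    ArrayDesign,
    EventAnnot,
    GeneAnnot,
    IntensityMatrix,
    ProbeAnnot,
    ProbesetAnnot,
)

DESIGN_HEADER = (
    "probe_id\tprobeset_id\tgroup\trole\tevent_id\tevent_type\t"
    "gene_id\tchrom\tstart\tend\tstrand"
)


def cassette_design_rows() -> list[str]:
    """1 gene, 1 cassette event, 4 event probesets + 2 constitutive, 2 probes each."""
    rows = []
    specs = [
        ("psE", "exclusion", "junction", "ev1", "cassette", 1101, 1300),
        ("psB", "inclusion", "exon_body", "ev1", "cassette", 1101, 1300),
        ("psJ5", "inclusion", "junction", "ev1", "cassette", 1101, 1300),
        ("psJ3", "inclusion", "junction", "ev1", "cassette", 1101, 1300),
        ("psC1", "constitutive", "exon_body", ".", ".", 101, 2000),
        ("psC2", "constitutive", "exon_body", ".", ".", 101, 2000),
    ]
    for ps, group, role, ev, evt, start, end in specs:
        for k in (1, 2):
            rows.append(
                f"{ps}_p{k}\t{ps}\t{group}\t{role}\t{ev}\t{evt}\t"
                f"gA\tchr1\t{start}\t{end}\t+"
            )
    return rows


@pytest.fixture
def design_file(tmp_path):
    path = tmp_path / "design.tsv"
    path.write_text(DESIGN_HEADER + "\n" + "\n".join(cassette_design_rows()) + "\n")
    return path


@pytest.fixture
def tiny_design() -> ArrayDesign:
    """In-memory equivalent of the design_file fixture."""
    probesets = [
        ProbesetAnnot("psE", "ev1", "exclusion", "junction"),
        ProbesetAnnot("psB", "ev1", "inclusion", "exon_body"),
        ProbesetAnnot("psJ5", "ev1", "inclusion", "junction"),
        ProbesetAnnot("psJ3", "ev1", "inclusion", "junction"),
        ProbesetAnnot("psC1", None, "constitutive", "exon_body"),
        ProbesetAnnot("psC2", None, "constitutive", "exon_body"),
    ]
    probes = [
        ProbeAnnot(f"{ps.probeset_id}_p{k}", ps.probeset_id)
        for ps in probesets
        for k in (1, 2)
    ]
    return ArrayDesign(
        genes=[GeneAnnot("gA", "chr1", "+", 101, 2000)],
        events=[EventAnnot("ev1", "gA", "cassette", 1101, 1300)],
        probesets=probesets,
        probes=probes,
        constitutive_gene={"psC1": "gA", "psC2": "gA"},
    )


def matrix_for(design: ArrayDesign, values: np.ndarray, n_per_cond: int = 3) -> IntensityMatrix:
    """Wrap a value array as an IntensityMatrix with control/treated labels."""
    samples = [f"control_{i+1}" for i in range(n_per_cond)] + [
        f"treated_{i+1}" for i in range(n_per_cond)
    ]
    cond = {s: ("control" if s.startswith("control") else "treated") for s in samples}
    return IntensityMatrix(
        values=pd.DataFrame(values, index=design.probe_ids, columns=samples),
        condition_map=cond,
        state="raw",
    )
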