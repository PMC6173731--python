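"""Lineage calling from gated flow-cytometry count tables.

Single-cell-derived colonies are harvested and phenotyped by
high-throughput flow; the input here is the per-well table of gated cell
counts (already gated — no FCS parsing).  Calls apply fixed cell-count
thresholds:

* a well holds a colony if CD45-total + GlyA+ events >= 30;
* a lineage is present if its gate holds >= 30 cells
  (Ery: CD45-GlyA+, Meg: CD41+, My: CD45+CD14+ plus CD45+CD15+,
  NK: CD45+CD56+; in the B/NK assay B: CD45+CD19++, My: CD45+CD11b+);
* xenograft marrow is engrafted if (%CD45++ + %GlyA+) >= 0.01% with >= 30
  recorded human cells, and graft lineages use >= 20-cell gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColonyReadout",
    "ColonyCall",
    "EngraftmentRecord",
    "EngraftmentCall",
    "call_colony",
    "subclassify_my",
    "call_bias",
    "call_engraftment",
    "summarize_colonies",
    "COLONY_CELL_THRESHOLD",
    "GRAFT_LINEAGE_THRESHOLD",
    "ENGRAFTMENT_PCT_THRESHOLD",
]

COLONY_CELL_THRESHOLD = 30
GRAFT_LINEAGE_THRESHOLD = 20
ENGRAFTMENT_PCT_THRESHOLD = 0.01
#: canonical lineage order used to build the type label
LINEAGE_ORDER = ("My", "NK", "Ery", "Meg", "B")

COUNT_FIELDS = (
    "GlyA_pos",
    "CD41_pos",
    "CD45_CD14",
    "CD45_CD15",
    "CD45_CD56",
    "CD45_CD19",
    "CD45_CD11b",
    "CD45_total",
)


@dataclass
class ColonyReadout:
    """Gated cell counts for one well of a differentiation assay."""

    well_id: str
    assay: str = "MS5_multilineage"  # or "MS5_B_NK"
    GlyA_pos: int = 0       # CD45- GlyA+
    CD41_pos: int = 0
    CD45_CD14: int = 0
    CD45_CD15: int = 0
    CD45_CD56: int = 0
    CD45_CD19: int = 0
    CD45_CD11b: int = 0
    CD45_total: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("MS5_multilineage", "MS5_B_NK"):
            raise ValueError(f"unknown assay kind: {self.assay!r}")
        for name in COUNT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative count in {name}")


@dataclass
class ColonyCall:
    """Derived lineage call for one well."""

    well_id: str
    present: bool
    lineages: frozenset = field(default_factory=frozenset)
    type_label: str = ""
    my_subclass: str = "none"
    size: int = 0
    bias: str = "NA"


def _type_label(lineages) -> str:
    return "/".join(l for l in LINEAGE_ORDER if l in lineages)


def call_colony(
    readout: ColonyReadout, threshold: int = COLONY_CELL_THRESHOLD
) -> ColonyCall:
    """Classify one well's colony presence and lineage content.

    Presence: CD45_total + GlyA_pos >= threshold.  Lineage flags use the
    same per-gate threshold.  Colony size counts CD45+, GlyA+ and CD41+
    (Meg) events.
    """
    r = readout
    present = (r.CD45_total + r.GlyA_pos) >= threshold
    lineages: set[str] = set()
    if present:
        if r.assay == "MS5_multilineage":
            if r.GlyA_pos >= threshold:
                lineages.add("Ery")
            if r.CD41_pos >= threshold:
                lineages.add("Meg")
            if (r.CD45_CD14 + r.CD45_CD15) >= threshold:
                lineages.add("My")
            if r.CD45_CD56 >= threshold:
                lineages.add("NK")
        else:  # MS5_B_NK
            if r.CD45_CD19 >= threshold:
                lineages.add("B")
            if r.CD45_CD11b >= threshold:
                lineages.add("My")
            if r.CD45_CD56 >= threshold:
                lineages.add("NK")
    size = r.CD45_total + r.GlyA_pos + r.CD41_pos if present else 0
    call = ColonyCall(
        well_id=r.well_id,
        present=present,
        lineages=frozenset(lineages),
        type_label=_type_label(lineages),
        size=size,
    )
    # Mono/Gran sub-typing relies on the CD14/CD15 panel, absent in B/NK wells
    if "My" in lineages and r.assay == "MS5_multilineage":
        call.my_subclass = subclassify_my(r, threshold=threshold)
    call.bias = call_bias(call, r)
    return call


def subclassify_my(
    readout: ColonyReadout, threshold: int = COLONY_CELL_THRESHOLD
) -> str:
    """Sub-classify a myeloid colony by its monocyte/granulocyte content.

    MonoGran takes precedence (CD15 >= t and CD14 >= t), then Gran
    (CD15 >= t, CD14 <= t), then Mono (CD14 >= t, CD15 <= t).  The printed
    rules overlap at exactly the threshold; precedence resolves the tie.
    """
    r = readout
    if (r.CD45_CD14 + r.CD45_CD15) < threshold:
        raise ValueError("subclassify_my called on a well without a My colony")
    gran = r.CD45_CD15 >= threshold
    mono = r.CD45_CD14 >= threshold
    if gran and mono:
        return "MonoGran"
    if gran and r.CD45_CD14 <= threshold:
        return "Gran"
    if mono and r.CD45_CD15 <= threshold:
        return "Mono"
    return "none"


def call_bias(call: ColonyCall, readout: ColonyReadout) -> str:
    """Lineage bias within a bipotent colony.

    Only My+NK and My+Ery colonies have a defined bias: Ly-bias if NK cells
    outnumber My cells, Ery-bias if Ery cells outnumber My cells, My-bias
    if My strictly outnumbers the partner, unbiased on an exact tie; NA for
    every other composition.
    """
    r = readout
    my_count = r.CD45_CD14 + r.CD45_CD15
    if call.lineages == frozenset({"My", "NK"}):
        other, label = r.CD45_CD56, "Ly-bias"
    elif call.lineages == frozenset({"My", "Ery"}):
        other, label = r.GlyA_pos, "Ery-bias"
    else:
        return "NA"
    if other > my_count:
        return label
    if my_count > other:
        return "My-bias"
    return "unbiased"


@dataclass
class EngraftmentRecord:
    """Per-mouse xenograft marrow gate percentages and cell counts."""

    mouse_id: str
    pct_CD45dd: float = 0.0      # % positive for both CD45 antibodies
    pct_GlyA: float = 0.0
    n_human_cells: int = 0       # cells recorded in those gates
    n_CD33: int = 0              # CD45++ CD33+
    n_CD19dd: int = 0            # CD45++ CD19++
    n_GlyA_CD45neg: int = 0      # CD45- GlyA+
    n_CD71GlyA_CD45neg: int = 0  # CD45- CD71+ GlyA+

    def __post_init__(self) -> None:
        for name in (
            "pct_CD45dd", "pct_GlyA", "n_human_cells", "n_CD33",
            "n_CD19dd", "n_GlyA_CD45neg", "n_CD71GlyA_CD45neg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative value in {name}")


@dataclass
class EngraftmentCall:
    mouse_id: str
    engrafted: bool
    lineages: frozenset = field(default_factory=frozenset)
    multilineage: bool = False


def call_engraftment(
    rec: EngraftmentRecord,
    pct_threshold: float = ENGRAFTMENT_PCT_THRESHOLD,
    min_cells: int = COLONY_CELL_THRESHOLD,
    lineage_threshold: int = GRAFT_LINEAGE_THRESHOLD,
) -> EngraftmentCall:
    """Engraftment and graft lineage composition for one mouse.

    Engrafted iff (%CD45++ + %GlyA+) >= 0.01% and >= 30 human cells were
    recorded.  Lineages by >= 20-cell gates; the Ery flag accepts either
    GlyA gate variant.  Multilineage = My and Ly and Ery simultaneously.
    """
    engrafted = (rec.pct_CD45dd + rec.pct_GlyA) >= pct_threshold and (
        rec.n_human_cells >= min_cells
    )
    lineages: set[str] = set()
    if engrafted:
        if rec.n_CD33 >= lineage_threshold:
            lineages.add("My")
        if rec.n_CD19dd >= lineage_threshold:
            lineages.add("Ly")
        if (
            rec.n_GlyA_CD45neg >= lineage_threshold
            or rec.n_CD71GlyA_CD45neg >= lineage_threshold
        ):
            lineages.add("Ery")
    return EngraftmentCall(
        mouse_id=rec.mouse_id,
        engrafted=engrafted,
        lineages=frozenset(lineages),
        multilineage=lineages == {"My", "Ly", "Ery"},
    )


def summarize_colonies(
    calls: list[ColonyCall], replicates: list[str] | None = None
) -> pd.DataFrame:
    """Per-type colony percentages, mean +/- SEM across replicates.

    Percentages are over colony-forming wells (present = True) within each
    replicate and sum to 100 per replicate.  With a single replicate the
    SEM is 0.
    """
    if not calls:
        raise ValueError("no colony calls")
    if replicates is None:
        replicates = ["rep1"] * len(calls)
    df = pd.DataFrame(
        {
            "type_label": [c.type_label for c in calls],
            "present": [c.present for c in calls],
            "replicate": replicates,
        }
    )
    df = df[df["present"]]
    if len(df) == 0:
        raise ValueError("no colonies present")
    types = sorted(df["type_label"].unique())
    rows = []
    per_rep = {
        rep: sub["type_label"].value_counts(normalize=True) * 100.0
        for rep, sub in df.groupby("replicate")
    }
    for t in types:
        vals = np.array([per_rep[rep].get(t, 0.0) for rep in per_rep])
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({"type_label": t, "mean_pct": vals.mean(), "sem_pct": sem,
                     "n_replicates": len(vals)})
    return pd.DataFrame(rows)
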