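"""Summaries over collections of solved strategies.

These operations aggregate many per-target designs into the tables used to
study where valves concentrate in the network: valve occurrence counts by
metabolic subsystem, reaction connectivity (a degree-based centrality), and
the valve co-occurrence adjacency matrix that downstream clustering tools
can consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import MetabolicModel
from .milp import InterventionStrategy


@dataclass
class StrategyEntry:
    target: str
    spec_digest: str
    strategy: InterventionStrategy
    #: whether allowing more valves improved the objective for this target
    #: (the filter applied before co-occurrence clustering); None = unknown
    improved_objective: bool | None = None


@dataclass
class StrategyCollection:
    entries: list[StrategyEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [(e.target, e.spec_digest) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (target, spec) entry in collection")

    def add(self, entry: StrategyEntry) -> None:
        if any(
            (e.target, e.spec_digest) == (entry.target, entry.spec_digest)
            for e in self.entries
        ):
            raise ValueError("duplicate (target, spec) entry in collection")
        self.entries.append(entry)


def valve_frequency(
    collection: StrategyCollection, model: MetabolicModel
) -> pd.DataFrame:
    """Occurrence count of each valve across entries, grouped by subsystem.

    Returns a DataFrame with columns ``valve``, ``subsystem``, ``count``
    sorted by descending count (then valve id for determinism).
    """
    counts: dict[str, int] = {}
    for entry in collection.entries:
        for rid in entry.strategy.valves:
            counts[rid] = counts.get(rid, 0) + 1
    rows = [
        {
            "valve": rid,
            "subsystem": model.reaction(rid).subsystem,
            "count": cnt,
        }
        for rid, cnt in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["valve", "subsystem", "count"])
    return df.sort_values(
        ["count", "valve"], ascending=[False, True], ignore_index=True
    )


def reaction_connectivity(model: MetabolicModel) -> pd.Series:
    """Sum of metabolite degrees over each reaction's participants.

    A metabolite's degree is the number of reactions it partakes in; a
    reaction's connectivity is the sum over its metabolites.
    """
    degree: dict[str, int] = {m.id: 0 for m in model.metabolites}
    for rxn in model.reactions:
        for mid in rxn.stoichiometry:
            degree[mid] += 1
    conn = {
        rxn.id: sum(degree[mid] for mid in rxn.stoichiometry)
        for rxn in model.reactions
    }
    return pd.Series(conn, name="connectivity")


def cooccurrence_adjacency(
    collection: StrategyCollection, only_improved: bool = False
) -> pd.DataFrame:
    """Symmetric valve co-occurrence matrix as a similarity for clustering.

    Entry (i, j) counts strategies containing both valves; the diagonal
    carries plain occurrence counts.  ``only_improved`` restricts to
    entries flagged as having improved the objective with extra valves.
    """
    entries = collection.entries
    if only_improved:
        entries = [e for e in entries if e.improved_objective]
    valves = sorted({rid for e in entries for rid in e.strategy.valves})
    mat = pd.DataFrame(0, index=valves, columns=valves, dtype=int)
    for e in entries:
        vs = sorted(e.strategy.valves)
        for i, a in enumerate(vs):
            mat.loc[a, a] += 1
            for b in vs[i + 1:]:
                mat.loc[a, b] += 1
                mat.loc[b, a] += 1
    return mat


def adjacency_to_triplets(adj: pd.DataFrame) -> str:
    """Matrix-market-style triplet TSV (row, col, count), nonzeros only."""
    lines = ["valve_i\tvalve_j\tcount"]
    for a in adj.index:
        for b in adj.columns:
            v = int(adj.loc[a, b])
            if v:
                lines.append(f"{a}\t{b}\t{v}")
    return "\n".join(lines) + "\n"
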