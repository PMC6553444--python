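"""Parsimony mapping of binary characters onto a tree.

Each character's minimum change count is computed by unit-cost small
parsimony (Sankoff dynamic programming, which is exact on polytomies and
handles '?' as the full {0,1} state set).  Characters are then classed as:

* synapomorphy — a single 0→1 change on an internal edge: the derived state
  defines a clade (a "taxonomic marker");
* autapomorphy — a single 0→1 change on a terminal edge;
* homoplasy — at least two changes (parallel gains and/or reversals);
* invariant — no change (including all-'?' characters).

Classification roots the tree on the outgroup edge so that 0 (the
outgroup/ancestral state) is basal; the change count itself is
root-independent.  Supporting edges are taken from one minimal
reconstruction resolved with the ACCTRAN convention (on ties, state changes
are placed as close to the root as possible), which makes edge placement —
not the count — deterministic.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import pandas as pd

from .coding import BinaryCharacter, BinaryMatrix
from .errors import DataError
from .io import TreeTopology

logger = logging.getLogger(__name__)

SYNAPOMORPHY = "synapomorphy"
AUTAPOMORPHY = "autapomorphy"
HOMOPLASY = "homoplasy"
INVARIANT = "invariant"

_INF = float("inf")


@dataclass(frozen=True)
class MarkerAssignment:
    event_id: str
    min_changes: int
    marker_class: str
    supporting_edges: tuple[frozenset[str], ...]  # child-clade leaf sets of 0->1 edges


def _leaf_costs(state: str) -> tuple[float, float]:
    if state == "0":
        return (0.0, _INF)
    if state == "1":
        return (_INF, 0.0)
    if state == "?":
        return (0.0, 0.0)
    raise DataError(f"invalid character state {state!r}")


def _node_costs(tree: TreeTopology, char: BinaryCharacter) -> dict:
    """Unit-cost Sankoff up-pass; returns node -> (cost0, cost1)."""
    costs: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in char.states:
                raise DataError(
                    f"leaf {label!r} missing from character {char.event_id}"
                )
            costs[node] = _leaf_costs(char.states[label])
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = costs[child]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            costs[node] = (c0, c1)
    return costs


def fitch_count(tree: TreeTopology, char: BinaryCharacter) -> int:
    """Minimum number of state changes explaining the leaf states.

    '?' leaves may take either state for free.  The value does not depend
    on where the tree is rooted.
    """
    costs = _node_costs(tree, char)
    root = tree.seed_node
    return int(min(costs[root]))


def _reroot_at_outgroup(tree: TreeTopology, outgroups: Sequence[str]) -> TreeTopology:
    """Clone the tree and root it on the edge subtending the outgroup(s)."""
    clone = tree.clone(depth=1)
    clone.is_rooted = True
    taxa = [t for t in clone.taxon_namespace if t.label in set(outgroups)]
    if not taxa:
        raise DataError(f"outgroup taxa {list(outgroups)} not found in tree")
    mrca = clone.mrca(taxa=taxa)
    if mrca is clone.seed_node:
        # outgroups span the current root; keep rooting as-is
        return clone
    clone.reroot_at_edge(mrca.edge, update_bipartitions=False)
    return clone


def classify_marker(
    tree: TreeTopology,
    char: BinaryCharacter,
    outgroups: Sequence[str] | None = None,
) -> MarkerAssignment:
    """Class a character and report the edges carrying its 0→1 changes."""
    work = _reroot_at_outgroup(tree, outgroups) if outgroups else tree
    costs = _node_costs(work, char)
    root = work.seed_node
    c0, c1 = costs[root]
    min_changes = int(min(c0, c1))

    states = set(char.states.values())
    if states <= {"?"}:
        logger.warning("character %s has no scored taxa; invariant", char.event_id)
        return MarkerAssignment(char.event_id, 0, INVARIANT, ())

    # down-pass: assign states, ACCTRAN tie-break (prefer changing early)
    assignment: dict = {}
    assignment[root] = 0 if c0 <= c1 else 1
    gains: list = []
    for node in work.preorder_node_iter():
        if node is root:
            continue
        parent_state = assignment[node.parent_node]
        k0, k1 = costs[node]
        cost_keep = (k0 if parent_state == 0 else k1)
        cost_flip = (k1 if parent_state == 0 else k0) + 1
        if cost_flip <= cost_keep:  # ACCTRAN: on ties, change as early as possible
            state = 1 - parent_state
        else:
            state = parent_state
        assignment[node] = state
        if parent_state == 0 and state == 1:
            gains.append(node)

    edges = tuple(
        frozenset(l.taxon.label for l in n.leaf_iter()) for n in gains
    )
    if min_changes == 0:
        cls = INVARIANT
    elif min_changes == 1:
        if len(edges) == 1 and len(edges[0]) >= 2:
            cls = SYNAPOMORPHY
        else:
            cls = AUTAPOMORPHY
    else:
        cls = HOMOPLASY
    return MarkerAssignment(char.event_id, min_changes, cls, edges)


@dataclass(frozen=True)
class MarkerReport:
    """Per-clade synapomorphy listing with letter-number marker codes, plus
    autapomorphy and homoplasy lists."""

    assignments: tuple[MarkerAssignment, ...]
    codes: dict  # event_id -> code (synapomorphies only)
    clades: tuple[tuple[frozenset[str], tuple[str, ...]], ...]  # (clade, event ids)

    @property
    def counts(self) -> dict:
        out = {SYNAPOMORPHY: 0, AUTAPOMORPHY: 0, HOMOPLASY: 0, INVARIANT: 0}
        for a in self.assignments:
            out[a.marker_class] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            rows.append(
                {
                    "event_id": a.event_id,
                    "marker_class": a.marker_class,
                    "min_changes": a.min_changes,
                    "code": self.codes.get(a.event_id, ""),
                    "supporting_clades": ";".join(
                        ",".join(sorted(e)) for e in a.supporting_edges
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["event_id", "marker_class", "min_changes", "code",
                     "supporting_clades"],
        )


def _series_letters():
    letters = list(string.ascii_uppercase)
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            letters.append(a + b)
    return letters


def marker_report(
    tree: TreeTopology,
    matrix: BinaryMatrix,
    outgroups: Sequence[str] | None = None,
) -> MarkerReport:
    """Classify every character of the matrix and assign marker codes.

    Synapomorphies for the same clade share a group number; the letter
    enumerates the series of markers within that clade (A1, B1, ... for
    clade 1; A2, ... for clade 2).
    """
    assignments = []
    clade_order: list[frozenset[str]] = []
    by_clade: dict[frozenset[str], list[str]] = {}
    for c in matrix.characters:
        a = classify_marker(tree, c, outgroups)
        assignments.append(a)
        if a.marker_class == SYNAPOMORPHY:
            clade = a.supporting_edges[0]
            if clade not in by_clade:
                clade_order.append(clade)
                by_clade[clade] = []
            by_clade[clade].append(a.event_id)
    letters = _series_letters()
    codes = {}
    for gi, clade in enumerate(clade_order, start=1):
        for si, event_id in enumerate(by_clade[clade]):
            codes[event_id] = f"{letters[si]}{gi}"
    return MarkerReport(
        assignments=tuple(assignments),
        codes=codes,
        clades=tuple((cl, tuple(by_clade[cl])) for cl in clade_order),
    )
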