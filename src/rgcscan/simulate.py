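"""Synthetic plastome-evolution generator with a known truth table.

The generator evolves a root sequence along a user tree under JC69 point
substitutions and *plants* structural events (it does not draw them from an
indel process), emitting the leaf sequences, the TRUE alignment implied by
the edit history, and a truth table — so detection and classification can
be tested without involving any external aligner.

Event kinds and how they are planted:

* ``ISD`` — a direct repeat of ``repeat_len`` bp is written at both ends of
  the chosen span in the ancestral sequence; the affected lineage then
  deletes from the first copy's start through the second copy's start,
  leaving exactly one copy.  This reproduces the evidence pattern of an
  intrastrand deletion: references show two flanking direct repeats, the
  deleted lineage one.
* ``SSM`` — a primitive tandem unit (``unit_len`` bp) is seeded as an array
  in the ancestral sequence; the lineage contracts (``copy_delta`` < 0) or
  expands (> 0) the array by ``|copy_delta|`` copies, always retaining a
  single adjacent copy as the slippage template.
* ``recombination_del`` / ``recombination_ins`` — a plain span deletion or
  insertion.  The junction windows are constructed from disjoint base sets
  ({A,C} inside the span edges, {G,T} in the retained flanks) so that no
  chance flanking direct repeat or tandem adjacency exists: planted
  recombination events are repeat-free by construction.
* ``micro_indel`` — a small (<50 bp) deletion, below the RGC size window.

All planting happens in the root sequence (structural context predating the
event is thereby shared by every reference lineage); lineage-specific edits
happen on the specified branch.  Events are placed at non-overlapping,
margin-separated positions, so the truth is unambiguous.  Fixed seed means
byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .io import Alignment, TreeTopology, parse_newick
from .mechanism import _primitive_period
from .plastome import revcomp

logger = logging.getLogger(__name__)

KINDS = ("ISD", "SSM", "recombination_del", "recombination_ins", "micro_indel")
_DETECTABLE_REPEAT = 8  # default minimum detectable flanking repeat
_MARGIN = 30
_SCRUB = 6  # width of the repeat-free junction windows


@dataclass(frozen=True)
class SimEventSpec:
    """One planted event on a tree branch (identified by its child clade)."""

    branch: frozenset
    kind: str
    length: int = 60
    repeat_len: int = 10
    unit_len: int = 5
    copy_delta: int = -10
    name: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "branch", frozenset(self.branch))
        if self.kind not in KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if self.kind == "micro_indel":
            if not (1 <= self.length < 50):
                raise ConfigError("micro_indel length must be in [1, 50)")
        elif self.length < 50:
            raise ConfigError(f"{self.kind} length must be >= 50 bp (RGC size)")
        if self.kind == "ISD" and self.repeat_len < _DETECTABLE_REPEAT:
            raise ConfigError(
                f"ISD repeat_len must be >= {_DETECTABLE_REPEAT} to be detectable"
            )
        if self.kind == "SSM":
            if self.unit_len < 2:
                raise ConfigError("SSM unit_len must be >= 2")
            if self.copy_delta == 0:
                raise ConfigError("SSM copy_delta must be nonzero")
            if self.length != self.unit_len * abs(self.copy_delta):
                raise ConfigError(
                    "SSM length must equal unit_len * |copy_delta| "
                    f"({self.unit_len} * {abs(self.copy_delta)} != {self.length})"
                )


@dataclass(frozen=True)
class TruthRow:
    event_id: str
    branch: frozenset
    kind: str
    affected_taxa: frozenset
    cols: tuple[int, int]  # true-alignment columns of the event
    length: int
    repeat: Optional[str]  # ISD repeat or SSM unit


@dataclass(frozen=True)
class TruthTable:
    rows: tuple[TruthRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event_id": r.event_id,
                    "branch": ",".join(sorted(r.branch)),
                    "kind": r.kind,
                    "affected_taxa": ",".join(sorted(r.affected_taxa)),
                    "start_col": r.cols[0],
                    "end_col": r.cols[1],
                    "length": r.length,
                    "repeat": r.repeat or "",
                }
                for r in self.rows
            ],
            columns=["event_id", "branch", "kind", "affected_taxa",
                     "start_col", "end_col", "length", "repeat"],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SimResult:
    sequences: dict  # leaf label -> ungapped sequence
    alignment: Alignment
    truth: TruthTable
    tree: TreeTopology


def random_sequence(n: int, rng, at_target: Optional[float] = None) -> str:
    """Random DNA, uniform or AT-biased toward ``at_target`` percent."""
    if at_target is None:
        probs = [0.25] * 4
    else:
        at = at_target / 100.0
        probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def jc69_expected_difference(distance: float) -> float:
    """Expected per-site difference between two sequences separated by a
    total substitution distance (rate x time summed over the path)."""
    return 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))


def _choice_str(rng, letters: str, n: int) -> str:
    return "".join(rng.choice(list(letters), size=n))


def _primitive_unit(rng, u: int) -> str:
    """A primitive tandem unit over {A,C} (so junction guards in {G,T} can
    never extend a match into or out of the array)."""
    while True:
        unit = _choice_str(rng, "AC", u)
        if "A" in unit and "C" in unit and _primitive_period(unit) == u:
            return unit


class _Layout:
    """Root-coordinate placement of one event (filled during planting)."""

    def __init__(self, spec, index):
        self.spec = spec
        self.id = spec.name or f"sim{index + 1:02d}_{spec.kind}"
        self.del_ids: tuple[int, int] | None = None  # root-id range deleted
        self.insert_after: int | None = None  # root id preceding an insertion
        self.insert_seq: str | None = None
        self.new_ids: list[int] = []
        self.repeat: Optional[str] = None


def simulate(
    tree: TreeTopology,
    root_len: int,
    sub_rate: float,
    events: Sequence[SimEventSpec],
    seed: int,
    at_target: Optional[float] = None,
) -> SimResult:
    """Evolve a root sequence along ``tree`` and plant the given events.

    ``sub_rate`` is the substitution rate per site per unit branch length
    (JC69).  Events reference branches by the leaf set below them; events
    overlapping on any root-to-leaf path are rejected (placement is globally
    non-overlapping, which is stricter and keeps the truth unambiguous).
    """
    rng = np.random.default_rng(seed)
    if root_len < 2 * _MARGIN:
        raise ConfigError("root_len too short")

    leafset = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[node] = frozenset([node.taxon.label])
        else:
            leafset[node] = frozenset().union(*(leafset[c] for c in node.child_nodes()))
    by_clade = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            by_clade.setdefault(leafset[node], node)

    root_chars = np.array(list(random_sequence(root_len, rng, at_target)), dtype="U1")

    # --- placement and root-side planting -------------------------------
    reserved: list[tuple[int, int]] = []

    def _reserve(width: int) -> int:
        for _ in range(10000):
            p = int(rng.integers(_MARGIN, root_len - _MARGIN - width))
            if all(p + width + _MARGIN <= s or p >= e + _MARGIN for s, e in reserved):
                reserved.append((p, p + width))
                return p
        raise DataError("could not place events without overlap; root_len too small")

    def _write(p: int, s: str) -> None:
        root_chars[p : p + len(s)] = list(s)

    layouts: list[_Layout] = []
    events_by_node: dict = {}
    next_id = root_len
    for idx, spec in enumerate(events):
        if spec.branch not in by_clade:
            raise ConfigError(
                f"event {idx}: no branch with child clade {sorted(spec.branch)}"
            )
        lay = _Layout(spec, idx)
        D = spec.length
        if spec.kind == "ISD":
            r = spec.repeat_len
            p = _reserve(D + r)
            lay.repeat = _choice_str(rng, "ACGT", r)
            _write(p, lay.repeat)
            _write(p + D, lay.repeat)
            lay.del_ids = (p, p + D)
        elif spec.kind == "SSM":
            u, delta = spec.unit_len, spec.copy_delta
            unit = _primitive_unit(rng, u)
            lay.repeat = unit
            if delta < 0:
                k = abs(delta) + 1  # lineage retains exactly one copy
                p = _reserve(k * u)
                _write(p, unit * k)
                lay.del_ids = (p, p + abs(delta) * u)
            else:
                p = _reserve(u)
                _write(p, unit)
                lay.insert_after = p - 1  # new copies precede the seeded one
                lay.insert_seq = unit * delta
            _write(p - _SCRUB, _choice_str(rng, "GT", _SCRUB))
            _write(p + (abs(delta) + 1 if delta < 0 else 1) * u,
                   _choice_str(rng, "GT", _SCRUB))
        elif spec.kind in ("recombination_del", "micro_indel"):
            p = _reserve(D)
            if spec.kind == "recombination_del":
                # repeat-free junctions: span edges {A,C}, retained flanks {G,T}
                _write(p, _choice_str(rng, "AC", _SCRUB))
                _write(p + D - _SCRUB, _choice_str(rng, "AC", _SCRUB))
                _write(p - _SCRUB, _choice_str(rng, "GT", _SCRUB))
                _write(p + D, _choice_str(rng, "GT", _SCRUB))
            lay.del_ids = (p, p + D)
        elif spec.kind == "recombination_ins":
            p = _reserve(2 * _SCRUB) + _SCRUB
            _write(p - _SCRUB, _choice_str(rng, "GT", _SCRUB))
            _write(p, _choice_str(rng, "GT", _SCRUB))
            core = _choice_str(rng, "ACGT", max(D - 2 * _SCRUB, 0))
            ins = (_choice_str(rng, "AC", _SCRUB) + core +
                   _choice_str(rng, "AC", _SCRUB))[:D]
            lay.insert_after = p - 1
            lay.insert_seq = ins
        layouts.append(lay)
        events_by_node.setdefault(by_clade[spec.branch], []).append(lay)

    # --- walk the tree ---------------------------------------------------
    splices: list[tuple[int, list[int]]] = []  # (anchor root id, new ids)
    seqs: dict = {}  # node -> (ids array, chars array)
    root = tree.seed_node
    seqs[root] = (np.arange(root_len, dtype=np.int64), root_chars.copy())
    bases = np.array(list("ACGT"), dtype="U1")

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        ids, chars = seqs[node.parent_node]
        ids, chars = ids.copy(), chars.copy()
        blen = node.edge.length or 0.0
        nsub = int(rng.poisson(sub_rate * blen * len(ids))) if sub_rate * blen > 0 else 0
        for _ in range(nsub):
            pos = int(rng.integers(len(ids)))
            cur = chars[pos]
            alt = bases[bases != cur]
            chars[pos] = alt[int(rng.integers(3))]
        for lay in events_by_node.get(node, ()):
            if lay.del_ids is not None:
                p, q = lay.del_ids
                (idx0,) = np.nonzero(ids == p)
                idx0 = int(idx0[0])
                w = q - p
                keep = np.ones(len(ids), dtype=bool)
                keep[idx0 : idx0 + w] = False
                ids, chars = ids[keep], chars[keep]
            if lay.insert_seq is not None:
                (anchor_idx,) = np.nonzero(ids == lay.insert_after)
                anchor_idx = int(anchor_idx[0])
                new = list(range(next_id, next_id + len(lay.insert_seq)))
                next_id += len(lay.insert_seq)
                lay.new_ids = new
                splices.append((lay.insert_after, new))
                ids = np.insert(ids, anchor_idx + 1, new)
                chars = np.insert(chars, anchor_idx + 1, list(lay.insert_seq))
        seqs[node] = (ids, chars)

    # --- true alignment ---------------------------------------------------
    master = list(range(root_len))
    for anchor, new in splices:
        pos = master.index(anchor)
        master[pos + 1 : pos + 1] = new
    master_index = {cid: i for i, cid in enumerate(master)}

    leaf_rows = []
    sequences = {}
    for leaf in tree.leaf_node_iter():
        ids, chars = seqs[leaf]
        label = leaf.taxon.label
        present = dict(zip(ids.tolist(), chars.tolist()))
        leaf_rows.append((label, "".join(present.get(c, "-") for c in master)))
        sequences[label] = "".join(chars.tolist())
    alignment = Alignment.from_pairs(leaf_rows)

    truth_rows = []
    for lay in layouts:
        if lay.del_ids is not None:
            p, q = lay.del_ids
            cols = (master_index[p], master_index[q - 1] + 1)
        else:
            cols = (master_index[lay.new_ids[0]], master_index[lay.new_ids[-1]] + 1)
        truth_rows.append(
            TruthRow(
                event_id=lay.id,
                branch=lay.spec.branch,
                kind=lay.spec.kind,
                affected_taxa=lay.spec.branch,
                cols=cols,
                length=lay.spec.length,
                repeat=lay.repeat,
            )
        )
    return SimResult(
        sequences=sequences,
        alignment=alignment,
        truth=TruthTable(tuple(truth_rows)),
        tree=tree,
    )


def make_quadripartite_root(
    lsc: int, ir: int, ssc: int, at_target: Optional[float] = None, seed: int = 0
) -> str:
    """LSC + IRb + SSC + revcomp(IRb): a quadripartite genome by construction.

    The first and last base of each single-copy region are fixed to 'A' so
    that maximal exact extension cannot cross a junction by chance and the
    planted partition is recovered exactly.
    """
    if min(lsc, ir, ssc) <= 0:
        raise ConfigError("all region lengths must be > 0")
    rng = np.random.default_rng(seed)

    def _guarded(n: int) -> str:
        s = random_sequence(n, rng, at_target)
        return "A" + s[1:-1] + "A" if n >= 2 else "A" * n

    lsc_seq = _guarded(lsc)
    ir_seq = random_sequence(ir, rng, at_target)
    ssc_seq = _guarded(ssc)
    return lsc_seq + ir_seq + ssc_seq + revcomp(ir_seq)


def load_sim_config(path) -> dict:
    """Parse a YAML simulation config into :func:`simulate` keyword args."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"simulation config {path} is not a mapping")
    try:
        tree_spec = raw["tree"]
        tree = (
            parse_newick(tree_spec)
            if tree_spec.strip().startswith("(")
            else parse_newick(Path(tree_spec).read_text())
        )
        events = [
            SimEventSpec(
                branch=frozenset(e["branch"]),
                kind=e["kind"],
                **{
                    k: e[k]
                    for k in ("length", "repeat_len", "unit_len", "copy_delta", "name")
                    if k in e
                },
            )
            for e in raw.get("events", [])
        ]
        return {
            "tree": tree,
            "root_len": int(raw["root_length"]),
            "sub_rate": float(raw.get("substitution_rate", 0.0)),
            "events": events,
            "at_target": raw.get("at_percent"),
        }
    except KeyError as exc:
        raise ConfigError(f"simulation config missing key: {exc}") from None
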