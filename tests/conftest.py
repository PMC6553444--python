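import numpy as np
import pytest

from rgcscan.coding import BinaryCharacter
from rgcscan.datasets import (
    load_festuca_psaj_rpl33_alignment,
    load_poeae_psbe_petl_alignment,
    POEAE_OUTGROUP,
)
from rgcscan.detect import RgcConfig, cluster_events, extract_gap_runs, filter_rgc, flag_ambiguous
from rgcscan.io import Alignment, parse_newick


@pytest.fixture(scope="session")
def poeae_aln() -> Alignment:
    """17-taxon psbE-petL excerpt with the 63 bp Polypogon fugax ISD."""
    return load_poeae_psbe_petl_alignment()


@pytest.fixture(scope="session")
def festuca_aln() -> Alignment:
    """5-taxon psaJ-rpl33 excerpt with the 78 bp Festuca ovina ISD."""
    return load_festuca_psaj_rpl33_alignment()


@pytest.fixture(scope="session")
def poeae_outgroup() -> str:
    return POEAE_OUTGROUP


def detect_rgc(aln, outgroups=(), cfg=None):
    """Run the detection stack (runs -> events -> culling -> size filter)."""
    cfg = cfg or RgcConfig()
    events = flag_ambiguous(cluster_events(extract_gap_runs(aln), cfg), aln, outgroups, cfg)
    return filter_rgc(events, cfg)


def binary_char(states: dict, event_id: str = "x") -> BinaryCharacter:
    return BinaryCharacter(
        event_id=event_id,
        states=states,
        ancestral_condition="span_present",
        polarity="deletion",
    )


def random_topology(labels, rng) -> str:
    """Random binary tree over the given labels, as a newick string."""
    nodes = [str(l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
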