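"""Shared fixtures: small hand-built trees/alignments and simulator output."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from editevol import CodonAlignment, Phylogeny
from editevol.synthetic_data import (GeneParams, SimulationParams,
                                     simulate_sequences, simulate_tree)


@pytest.fixture
def quartet_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_tip_tree():
    # ((X,(Y,Z)),(W1,W2)) - the shape where DELTRAN/ACCTRAN diverge for
    # a character that is 0 in X,Y and 1 elsewhere
    return Phylogeny.from_newick("((X:1,(Y:1,Z:1):1):1,(W1:1,W2:1):1);")


@pytest.fixture
def small_alignment():
    mat = np.array([list("ATGCCCTTC"), list("ATGCTCTTC"), list("ATGCCCTTT")])
    return CodonAlignment("g", ["A", "B", "C"], mat)


@pytest.fixture(scope="session")
def sim_small():
    """One simulated gene on a 12-taxon tree with moderate editing loss."""
    rng = np.random.default_rng(7)
    params = SimulationParams(
        n_taxa=12, genes=[GeneParams("sim", 120, 20)], lambda_es=5.0, seed=7)
    tree = simulate_tree(params, rng)
    dna, cdna, truth = simulate_sequences(tree, params, rng)
    return dict(params=params, tree=tree, dna=dna["sim"], cdna=cdna["sim"],
                truth=truth)


def brute_force_fitch(tree: Phylogeny, tip_states: dict[str, int | None],
                      n_states: int = 2):
    """Exhaustive minimum-change count over all ancestral assignments (and
    all completions of missing tips). Returns (min length, set of optimal
    full assignments as tuples over nodes)."""
    nodes = list(range(tree.n_nodes))
    choices = []
    for v in nodes:
        if tree.is_tip(v):
            s = tip_states.get(tree.labels[v])
            if s is None or (isinstance(s, float) and np.isnan(s)):
                choices.append(tuple(range(n_states)))
            else:
                choices.append((int(s),))
        else:
            choices.append(tuple(range(n_states)))
    best = None
    optimal = set()
    for assign in product(*choices):
        cost = sum(1 for v in range(tree.n_nodes - 1)
                   if assign[v] != assign[tree.parent[v]])
        if best is None or cost < best:
            best = cost
            optimal = {assign}
        elif cost == best:
            optimal.add(assign)
    return best, optimal


def random_topology(rng, n_tips: int, labels=None) -> Phylogeny:
    """Random binary rooted topology with unit branch lengths."""
    labels = labels or [f"t{i}" for i in range(n_tips)]
    parts = [f"{l}:1" for l in labels]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):1")
    return Phylogeny.from_newick(f"({parts[0]},{parts[1]});")
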