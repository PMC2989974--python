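"""Parsimony mapping of binary editing characters on a fixed rooted tree.

Fitch minimum lengths come from a unit-cost Sankoff dynamic program (which
handles polytomies and missing tips natively and equals classic Fitch on the
cases Fitch covers). Ambiguous most-parsimonious reconstructions are resolved
by a preorder backtrace with exact cost-to-go, breaking ties by mode:
DELTRAN keeps the parent state (delaying changes toward the tips, so losses
become parallel), ACCTRAN switches away from it (accelerating changes toward
the root, so a basal loss may be undone by a later regain). Both resolutions
always spend exactly the Fitch minimum number of changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edit_calling import EDITED_C, GENOMIC_T, UNEDITED_C, EditTable
from .seqio import Phylogeny

INF = 10 ** 9


class CharacterError(ValueError):
    pass


@dataclass
class BinaryCharacterMatrix:
    """Edited-site presence/absence: 1 = edited C, 0 = T or unedited C,
    None = missing. ``characters`` are 0-based alignment columns."""

    gene: str
    characters: list[int]
    states: pd.DataFrame  # taxa x characters, values 0/1/NaN

    @classmethod
    def from_edit_table(cls, table: EditTable,
                        scoring: str = "dna") -> "BinaryCharacterMatrix":
        """Build the character matrix from included edited columns.

        ``scoring="dna"`` (default) scores any genomic C at an edited column
        as state 1 even without cDNA confirmation — so T->C reversions count
        as gains, accepting some overestimation. ``scoring="strict"`` scores
        an unverified C as missing; only cDNA-confirmed statuses give 0/1.
        (cDNA-confirmed unedited C's at edited columns only exist in
        heterogeneous columns, which the exclusion filter removes.)
        """
        if scoring not in ("dna", "strict"):
            raise CharacterError(f"unknown scoring {scoring!r}")
        cols = table.edited_columns()
        sub = table.status[cols].to_numpy(dtype=object)
        ev = table.evidence[cols].to_numpy(dtype=object)
        vals = np.full(sub.shape, np.nan)
        vals[sub == EDITED_C] = 1.0
        vals[sub == GENOMIC_T] = 0.0
        if scoring == "dna":
            vals[sub == UNEDITED_C] = 1.0
        else:
            vals[(sub == UNEDITED_C) & (ev == "cDNA")] = 0.0
        return cls(table.gene, cols,
                   pd.DataFrame(vals, index=table.taxa, columns=cols))


@dataclass
class FitchResult:
    length: int
    downpass: list[frozenset]       # classic Fitch downpass sets per node
    mpr_sets: list[frozenset]       # exact MPR state sets per node
    cost: np.ndarray                # (n_nodes x n_states) subtree cost


@dataclass
class CharacterHistory:
    character: int
    fitch: FitchResult | None       # None when produced by the fast engine
    mode: str
    node_states: np.ndarray
    events: list[tuple[int, str]]   # (child node, "gain"/"loss")

    @property
    def length(self) -> int:
        return self.fitch.length if self.fitch is not None else len(self.events)


@dataclass
class BranchEvents:
    gene: str
    gains: np.ndarray               # per node (branch above node)
    losses: np.ndarray
    per_character: dict[int, list[tuple[int, str]]] = field(default_factory=dict)
    mode: str = "DELTRAN"


def _tip_state_sets(tree: Phylogeny, states: dict[str, float | int | None],
                    n_states: int = 2) -> list[set[int] | None]:
    allowed: list[set[int] | None] = [None] * tree.n_nodes
    for v in tree.tips:
        s = states.get(tree.labels[v])
        if s is None or (isinstance(s, float) and np.isnan(s)):
            allowed[v] = set(range(n_states))
        else:
            allowed[v] = {int(s)}
    return allowed


def _sankoff(tree: Phylogeny, allowed: list[set[int] | None],
             n_states: int) -> np.ndarray:
    cost = np.zeros((tree.n_nodes, n_states), dtype=np.int64)
    for v in tree.postorder():
        if tree.is_tip(v):
            for s in range(n_states):
                cost[v, s] = 0 if s in allowed[v] else INF
        else:
            for c in tree.children[v]:
                best = cost[c].min()
                cost[v] += np.minimum(cost[c], best + 1)
    return cost


def _upcost(tree: Phylogeny, cost: np.ndarray, n_states: int) -> np.ndarray:
    """up[v,s] = min changes outside the subtree of v given v has state s."""
    up = np.zeros((tree.n_nodes, n_states), dtype=np.int64)
    for v in tree.preorder():
        if tree.parent[v] == -1:
            continue
        p = tree.parent[v]
        # parent's subtree cost without this child's contribution
        contrib = np.minimum(cost[v], cost[v].min() + 1)
        rest = cost[p] - contrib + up[p]
        for s in range(n_states):
            best = rest.min()
            up[v, s] = min(rest[s], best + 1)
    return up


def fitch_reconstruct(tree: Phylogeny, states: dict[str, float | int | None],
                      n_states: int = 2) -> FitchResult:
    """Exact minimum-change reconstruction of one discrete character.

    ``states`` maps tip labels to 0..n_states-1 or None/NaN for missing
    (treated as the full ambiguity set). Returns the minimum length, the
    classic Fitch downpass sets, and the exact MPR set per node.
    """
    allowed = _tip_state_sets(tree, states, n_states)
    non_missing = [v for v in tree.tips if len(allowed[v]) < n_states]
    if not non_missing:
        raise CharacterError("character has no non-missing tips")
    cost = _sankoff(tree, allowed, n_states)
    length = int(cost[tree.root].min())

    # classic downpass sets (iterative pairwise intersection for polytomies)
    down: list[frozenset] = [frozenset()] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_tip(v):
            down[v] = frozenset(allowed[v])
        else:
            acc = down[tree.children[v][0]]
            for c in tree.children[v][1:]:
                inter = acc & down[c]
                acc = inter if inter else (acc | down[c])
            down[v] = acc

    up = _upcost(tree, cost, n_states)
    total = cost + up
    mpr = [frozenset(int(s) for s in range(n_states) if total[v, s] == length)
           for v in range(tree.n_nodes)]
    return FitchResult(length, down, mpr, cost)


def resolve_optimization(tree: Phylogeny, fitch: FitchResult, mode: str,
                         root_tie: int | None = None) -> CharacterHistory:
    """Resolve ambiguity by preorder backtrace with exact cost-to-go.

    Ties between keeping and changing the parent state are broken by
    ``mode``; a tie among root states defaults to the highest state (1 for
    binary, i.e. the edited condition, which lets DELTRAN place parallel
    losses toward the tips). Event count always equals the Fitch length.
    """
    if mode not in ("ACCTRAN", "DELTRAN"):
        raise CharacterError(f"unknown optimization mode {mode!r}")
    cost = fitch.cost
    n_states = cost.shape[1]
    node_states = np.full(tree.n_nodes, -1, dtype=int)
    events: list[tuple[int, str]] = []

    root = tree.root
    best = cost[root].min()
    cands = [s for s in range(n_states) if cost[root, s] == best]
    if root_tie is not None and root_tie in cands:
        node_states[root] = root_tie
    else:
        node_states[root] = max(cands)
    for v in sorted(range(tree.n_nodes - 1), reverse=True):
        p = tree.parent[v]
        sp = node_states[p]
        opts = cost[v] + (np.arange(n_states) != sp)
        best = opts.min()
        cands = [s for s in range(n_states) if opts[s] == best]
        if sp in cands and len(cands) > 1:
            if mode == "DELTRAN":
                s = sp
            else:
                s = max(c for c in cands if c != sp)
        elif sp in cands:
            s = sp
        else:
            s = max(cands)
        node_states[v] = s
        if s != sp:
            if n_states == 2:
                events.append((v, "gain" if s == 1 else "loss"))
            else:
                events.append((v, f"{sp}->{s}"))
    return CharacterHistory(-1, fitch, mode, node_states, events)


def map_characters(tree: Phylogeny, matrix: BinaryCharacterMatrix,
                   mode: str = "DELTRAN") -> list[CharacterHistory]:
    """Fitch + mode resolution for every character (vectorized engine;
    identical output to fitch_reconstruct/resolve_optimization per column)."""
    if not matrix.characters:
        return []
    vals = matrix.states.to_numpy(dtype=float)
    tip_nodes = [tree.tip_index(t) for t in matrix.states.index]
    tip_states = np.where(np.isnan(vals), -1, vals).astype(np.int32)
    lengths, states, _ = fitch_matrix(tree, tip_states, tip_nodes, mode,
                                      n_states=2)
    out = []
    for j, ch in enumerate(matrix.characters):
        events = []
        for v in range(tree.n_nodes - 2, -1, -1):
            s, sp = states[v, j], states[tree.parent[v], j]
            if s != sp:
                events.append((v, "gain" if s == 1 else "loss"))
        out.append(CharacterHistory(ch, None, mode, states[:, j].astype(int),
                                    events))
    return out


def count_branch_changes(tree: Phylogeny, histories: list[CharacterHistory],
                         gene: str = "") -> BranchEvents:
    gains = np.zeros(tree.n_nodes, dtype=int)
    losses = np.zeros(tree.n_nodes, dtype=int)
    per_char: dict[int, list[tuple[int, str]]] = {}
    mode = histories[0].mode if histories else "DELTRAN"
    for h in histories:
        per_char[h.character] = list(h.events)
        for v, kind in h.events:
            if kind == "gain":
                gains[v] += 1
            elif kind == "loss":
                losses[v] += 1
    return BranchEvents(gene, gains, losses, per_char, mode)


def cumulative_changes(tree: Phylogeny, events: BranchEvents, ancestor: int,
                       tip: int, losses_only: bool = False) -> int:
    """Sum of events over the branches from ``ancestor`` down to ``tip``."""
    path = tree.path(ancestor, tip)
    tot = 0
    for v in path:
        tot += int(events.losses[v])
        if not losses_only:
            tot += int(events.gains[v])
    return tot


def branch_events_to_tsv(tree: Phylogeny, events: BranchEvents, path) -> None:
    rows = []
    for ch, evs in sorted(events.per_character.items()):
        for v, kind in evs:
            rows.append({
                "gene": events.gene, "character_position": ch + 1,
                "branch_id": tree.branch_name(v), "event": kind,
                "mode": events.mode,
            })
    pd.DataFrame(rows, columns=["gene", "character_position", "branch_id",
                                "event", "mode"]).to_csv(path, sep="\t",
                                                         index=False)


# ---------------------------------------------------------------------------
# Parsimony tree statistics
# ---------------------------------------------------------------------------

def parsimony_stats(tree: Phylogeny,
                    characters: list[dict[str, object]]) -> tuple[int, float, float]:
    """Tree length L, consistency index (autapomorphies excluded) and
    retention index for arbitrary discrete characters.

    Each character maps tip label -> state (hashable; None = missing).
    CI is computed over parsimony-informative characters only; RI over all.
    """
    L = 0
    ci_min = ci_len = 0
    g_sum = m_sum = len_sum = 0
    any_informative = False
    for char in characters:
        vals = [s for s in char.values() if s is not None]
        counts = {}
        for s in vals:
            counts[s] = counts.get(s, 0) + 1
        if not counts:
            continue
        states = sorted(counts, key=str)
        idx = {s: i for i, s in enumerate(states)}
        mapped = {t: (None if s is None else idx[s]) for t, s in char.items()}
        if len(states) == 1:
            length = 0
        else:
            length = fitch_reconstruct(tree, mapped, n_states=len(states)).length
        m = len(states) - 1
        g = sum(counts.values()) - max(counts.values())
        informative = sum(1 for v in counts.values() if v >= 2) >= 2
        L += length
        len_sum += length
        m_sum += m
        g_sum += g
        if informative:
            any_informative = True
            ci_min += m
            ci_len += length
    if not any_informative:
        raise CharacterError("no parsimony-informative characters; RI undefined")
    ci = ci_min / ci_len if ci_len else 1.0
    denom = g_sum - m_sum
    ri = (g_sum - L) / denom if denom else 1.0
    return L, ci, ri


# ---------------------------------------------------------------------------
# Vectorized multi-character engine (same semantics as the scalar functions)
# ---------------------------------------------------------------------------

def fitch_matrix(tree: Phylogeny, tip_states: np.ndarray,
                 tip_nodes: list[int], mode: str = "DELTRAN",
                 n_states: int = 2, want_mpr: bool = False):
    """Fitch lengths + mode-resolved node states for many characters at once.

    ``tip_states`` is (n_tips x n_chars) of state indices with -1 for
    missing; ``tip_nodes`` gives the node index of each row. Tie-break rules
    match :func:`resolve_optimization` (root ties -> highest state). Returns
    (lengths (n_chars,), node_states (n_nodes x n_chars),
    mpr boolean (n_nodes x n_chars x n_states) or None).
    """
    if mode not in ("ACCTRAN", "DELTRAN"):
        raise CharacterError(f"unknown optimization mode {mode!r}")
    n_chars = tip_states.shape[1]
    big = np.int32(10 ** 6)
    cost = np.zeros((tree.n_nodes, n_chars, n_states), dtype=np.int32)
    for row, v in enumerate(tip_nodes):
        st = tip_states[row]
        c = np.where(st[:, None] == np.arange(n_states)[None, :], 0, big)
        c[st < 0] = 0
        cost[v] = c
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        acc = np.zeros((n_chars, n_states), dtype=np.int32)
        for ch in tree.children[v]:
            m = cost[ch].min(axis=1, keepdims=True)
            acc += np.minimum(cost[ch], m + 1)
        cost[v] = acc
    lengths = cost[tree.root].min(axis=1)

    def last_true(mask):
        return n_states - 1 - np.argmax(mask[:, ::-1], axis=1)

    states = np.empty((tree.n_nodes, n_chars), dtype=np.int32)
    rootc = cost[tree.root]
    cand = rootc == rootc.min(axis=1, keepdims=True)
    states[tree.root] = last_true(cand)
    idx = np.arange(n_chars)
    for v in range(tree.n_nodes - 2, -1, -1):
        sp = states[tree.parent[v]]
        opts = cost[v] + 1
        opts[idx, sp] -= 1
        best = opts.min(axis=1)
        cand = opts == best[:, None]
        sp_ok = cand[idx, sp]
        if mode == "DELTRAN":
            states[v] = np.where(sp_ok, sp, last_true(cand))
        else:
            nosp = cand.copy()
            nosp[idx, sp] = False
            multi = nosp.any(axis=1)
            alt = last_true(nosp)
            states[v] = np.where(sp_ok & ~multi, sp,
                                 np.where(multi & sp_ok, alt,
                                          np.where(sp_ok, sp, last_true(cand))))
    mpr = None
    if want_mpr:
        up = np.zeros((tree.n_nodes, n_chars, n_states), dtype=np.int32)
        for v in tree.preorder():
            p = tree.parent[v]
            if p == -1:
                continue
            m = cost[v].min(axis=1, keepdims=True)
            contrib = np.minimum(cost[v], m + 1)
            rest = cost[p] - contrib + up[p]
            rb = rest.min(axis=1, keepdims=True)
            up[v] = np.minimum(rest, rb + 1)
        total = cost + up
        mpr = total == lengths[None, :, None]
    return lengths, states, mpr
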