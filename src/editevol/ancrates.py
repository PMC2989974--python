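"""Ancestral codon reconstruction and counting-based synonymous rates.

dS per branch uses Nei-Gojobori-style counting between the reconstructed
ancestor and descendant sequences: synonymous site fractions per codon,
pathway-averaged observed differences, and a Jukes-Cantor correction of the
synonymous proportion. This counting estimator stands in for a full codon
likelihood; the analyses downstream only use ranks and ratios of dS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.linalg import expm
from scipy.stats import binomtest

from .genetics import translate_codon
from .seqio import CodonAlignment, Phylogeny

NUC = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUC)}


class SaturationError(ValueError):
    pass


class LineageError(ValueError):
    pass


@dataclass
class AncestralSequences:
    """Per-node nucleotide sequences on the alignment's columns.

    ``sequences[v]`` is the resolved sequence for node v ('?' at masked
    columns). ``mpr`` maps (node, column) -> frozenset of equally
    parsimonious states wherever more than one exists. ``masked`` marks
    columns containing any gap/ambiguity, which are excluded from
    reconstruction and all event counting.
    """

    method: str
    sequences: dict[int, str]
    mpr: dict[tuple[int, int], frozenset]
    masked: np.ndarray


def reconstruct_ancestral_sequences(tree: Phylogeny, aln: CodonAlignment,
                                    method: str = "parsimony") -> AncestralSequences:
    """Reconstruct nucleotide sequences at every internal node.

    parsimony: per-column 4-state Fitch with DELTRAN resolution (ties at the
    root fall back to the descendant-consensus via the backtrace); the full
    MPR set is retained per ambiguous position. ML: marginal reconstruction
    under a single-rate HKY-like model with empirical base frequencies and
    the input branch lengths.
    """
    tip_rows = {tree.labels[v]: aln.row(tree.labels[v]) for v in tree.tips}
    n_cols = aln.n_columns
    masked = np.zeros(n_cols, dtype=bool)
    for c in range(n_cols):
        for row in tip_rows.values():
            if row[c] not in NUC:
                masked[c] = True
                break
    seqs = {v: ["?"] * n_cols for v in range(tree.n_nodes)}
    for v in tree.tips:
        seqs[v] = list(tip_rows[tree.labels[v]])
    mpr: dict[tuple[int, int], frozenset] = {}

    if method == "parsimony":
        from .charmap import fitch_matrix

        cols = np.flatnonzero(~masked)
        if cols.size:
            tip_nodes = tree.tips
            tip_states = np.empty((len(tip_nodes), cols.size), dtype=np.int32)
            for i, v in enumerate(tip_nodes):
                row = tip_rows[tree.labels[v]]
                tip_states[i] = [NUC_INDEX[row[c]] for c in cols]
            _, states, mpr_bool = fitch_matrix(tree, tip_states, tip_nodes,
                                               "DELTRAN", n_states=4,
                                               want_mpr=True)
            nuc_arr = np.array(list(NUC))
            for v in range(tree.n_nodes):
                if tree.is_tip(v):
                    continue
                arr = np.array(seqs[v])
                arr[cols] = nuc_arr[states[v]]
                seqs[v] = arr.tolist()
                n_amb = mpr_bool[v].sum(axis=1)
                for j in np.flatnonzero(n_amb > 1):
                    mpr[(v, int(cols[j]))] = frozenset(
                        int(s) for s in np.flatnonzero(mpr_bool[v, j]))
    elif method == "ML":
        _ml_reconstruct(tree, tip_rows, masked, seqs, mpr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AncestralSequences(method, {v: "".join(s) for v, s in seqs.items()},
                              mpr, masked)


def _hky_q(freqs: np.ndarray, kappa: float = 2.0) -> np.ndarray:
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(freqs, np.diag(q))
    return q / scale


def _branch_scale(tree, tip_rows, masked) -> float:
    """Median ratio of JC-corrected pairwise distance to tree path length:
    converts branch lengths in arbitrary units (e.g. Ma) to expected
    substitutions/site for the transition matrices."""
    tips = tree.tips
    depth = tree.node_depths()
    keep = ~masked
    ratios = []
    rng = np.random.default_rng(0)
    pairs = [(tips[i], tips[j]) for i in range(len(tips))
             for j in range(i + 1, len(tips))]
    if len(pairs) > 30:
        pairs = [pairs[k] for k in rng.choice(len(pairs), 30, replace=False)]
    for a, b in pairs:
        ra = np.asarray(tip_rows[tree.labels[a]])
        rb = np.asarray(tip_rows[tree.labels[b]])
        p = float(np.mean(ra[keep] != rb[keep])) if keep.any() else 0.0
        p = min(p, 0.70)
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        # path length through the MRCA
        anc_a = set()
        v = a
        while v != -1:
            anc_a.add(v)
            v = tree.parent[v]
        v = b
        while v not in anc_a:
            v = tree.parent[v]
        path = depth[a] + depth[b] - 2 * depth[v]
        if path > 0 and d > 0:
            ratios.append(d / path)
    return float(np.median(ratios)) if ratios else 1.0


def _ml_reconstruct(tree, tip_rows, masked, seqs, mpr, kappa: float = 2.0):
    counts = np.zeros(4)
    for row in tip_rows.values():
        for b in row:
            if b in NUC:
                counts[NUC_INDEX[b]] += 1
    freqs = counts / counts.sum()
    q = _hky_q(freqs, kappa)
    scale = _branch_scale(tree, tip_rows, masked)
    pmats = {}
    for v in range(tree.n_nodes - 1):
        t = max(float(tree.lengths[v]) * scale, 1e-9)
        if t not in pmats:
            pmats[t] = expm(q * t)
    n_cols = len(masked)
    for c in range(n_cols):
        if masked[c]:
            continue
        down = np.ones((tree.n_nodes, 4))
        for v in tree.postorder():
            if tree.is_tip(v):
                down[v] = 0.0
                down[v, NUC_INDEX[tip_rows[tree.labels[v]][c]]] = 1.0
            else:
                for ch in tree.children[v]:
                    p = pmats[max(float(tree.lengths[ch]) * scale, 1e-9)]
                    down[v] *= p @ down[ch]
        up = np.ones((tree.n_nodes, 4))
        for v in tree.preorder():
            if tree.parent[v] == -1:
                up[v] = freqs
                continue
            par = tree.parent[v]
            sib = up[par].copy()
            for ch in tree.children[par]:
                if ch != v:
                    p = pmats[max(float(tree.lengths[ch]) * scale, 1e-9)]
                    sib *= p @ down[ch]
            p = pmats[max(float(tree.lengths[v]) * scale, 1e-9)]
            up[v] = sib @ p
        for v in range(tree.n_nodes):
            if tree.is_tip(v):
                continue
            post = down[v] * up[v]
            seqs[v][c] = NUC[int(np.argmax(post))]


# ---------------------------------------------------------------------------
# Nei-Gojobori-style counting
# ---------------------------------------------------------------------------

@dataclass
class BranchSubstitutions:
    syn_count: float
    nonsyn_count: float
    S: float
    N: float
    dS: float
    ct3_events: list[int] = field(default_factory=list)  # 0-based columns


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractions of the 9 one-step neighbours that are synonymous /
    nonsynonymous, summed per position (mutations to stops count as
    nonsynonymous)."""
    s = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        syn = 0
        for b in NUC:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all orders of
    applying the nucleotide changes; pathways through stop codons are
    dropped when any stop-free pathway exists."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate_codon(nxt) == "*":
                through_stop = True
            if translate_codon(nxt) == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [p for p in paths if not p[2]]
    use = clean if clean else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def branch_ds(anc_seq: str, desc_seq: str,
              collect_ct3: bool = True) -> BranchSubstitutions:
    """Counting dS between an ancestor/descendant sequence pair.

    Codons containing any non-ACGT character in either sequence are skipped.
    dS = -3/4 ln(1 - 4/3 p_s); p_s >= 3/4 raises :class:`SaturationError`.
    The result is symmetric in its arguments apart from the C->T 3rd-position
    event list, which is oriented ancestor -> descendant.
    """
    if len(anc_seq) != len(desc_seq):
        raise ValueError("sequences differ in length")
    if len(anc_seq) % 3:
        raise ValueError("sequence length not a codon multiple")
    S = N = sd = nd = 0.0
    ct3 = []
    for i in range(0, len(anc_seq), 3):
        ca, cd = anc_seq[i : i + 3], desc_seq[i : i + 3]
        if any(ch not in NUC for ch in ca + cd):
            continue
        if translate_codon(ca) == "*" or translate_codon(cd) == "*":
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cd)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        dsd, dnd = _pathway_counts(ca, cd)
        sd += dsd
        nd += dnd
        if collect_ct3 and ca[2] == "C" and cd[2] == "T":
            ct3.append(i + 2)
    if S == 0:
        return BranchSubstitutions(sd, nd, S, N, 0.0, ct3)
    ps = sd / S
    if ps >= 0.75:
        raise SaturationError(f"synonymous proportion {ps:.3f} >= 3/4")
    ds = -0.75 * np.log(1 - 4.0 * ps / 3.0)
    return BranchSubstitutions(sd, nd, S, N, float(ds), ct3)


def tree_branch_ds(tree: Phylogeny, anc: AncestralSequences) -> dict[int, BranchSubstitutions]:
    """dS for every branch (keyed by child node) from reconstructed
    sequences."""
    out = {}
    for v in range(tree.n_nodes - 1):
        p = tree.parent[v]
        out[v] = branch_ds(anc.sequences[p], anc.sequences[v])
    return out


def ds_path(tree: Phylogeny, branch_subs: dict[int, BranchSubstitutions],
            ancestor: int, tip: int) -> float:
    return sum(branch_subs[v].dS for v in tree.path(ancestor, tip))


# ---------------------------------------------------------------------------
# Relative rate test
# ---------------------------------------------------------------------------

def relative_rate_test(seq_a: str, seq_b: str, seq_out: str) -> tuple[int, int, float]:
    """Tajima-style 1D relative rate test restricted to 3rd codon positions.

    m_a counts third positions where A differs while B agrees with the
    outgroup; m_b is symmetric. Returns (m_a, m_b, two-sided exact binomial
    p at probability 1/2); p = 1 when no informative sites exist.
    """
    if not (len(seq_a) == len(seq_b) == len(seq_out)):
        raise ValueError("sequences differ in length")
    m_a = m_b = 0
    for i in range(2, len(seq_a), 3):
        a, b, o = seq_a[i], seq_b[i], seq_out[i]
        if any(ch not in NUC for ch in (a, b, o)):
            continue
        if a != b and b == o:
            m_a += 1
        elif a != b and a == o:
            m_b += 1
    if m_a + m_b == 0:
        return 0, 0, 1.0
    p = binomtest(m_a, m_a + m_b, 0.5, alternative="two-sided").pvalue
    return m_a, m_b, float(p)


# ---------------------------------------------------------------------------
# 3rd-position C->T event extraction
# ---------------------------------------------------------------------------

def third_position_ct_events(tree: Phylogeny, anc: AncestralSequences,
                             exclude_columns: set[int] | None = None,
                             fractional: bool = True) -> dict[int, list[tuple[int, float]]]:
    """Per-branch C->T events at 3rd codon positions.

    Returns {child node: [(0-based column, weight), ...]}. With
    ``fractional`` (default), a position whose endpoint states are ambiguous
    among several MPR states contributes the product of uniform weights over
    those sets; strict mode counts only unambiguously resolved C->T branches.
    Edited-site columns should be passed via ``exclude_columns``.
    """
    exclude = exclude_columns or set()
    out: dict[int, list[tuple[int, float]]] = {v: [] for v in range(tree.n_nodes - 1)}
    n_cols = len(anc.masked)
    for v in range(tree.n_nodes - 1):
        p = tree.parent[v]
        sp, sv = anc.sequences[p], anc.sequences[v]
        for c in range(2, n_cols, 3):
            if anc.masked[c] or c in exclude:
                continue
            set_p = anc.mpr.get((p, c), frozenset({sp[c]} if sp[c] in NUC else set()))
            set_v = anc.mpr.get((v, c), frozenset({sv[c]} if sv[c] in NUC else set()))
            set_p = {b if isinstance(b, str) else NUC[b] for b in set_p}
            set_v = {b if isinstance(b, str) else NUC[b] for b in set_v}
            if not set_p or not set_v:
                continue
            if fractional:
                # weight of the (ancestor=C, descendant=T) joint assignment
                # under uniform marginals on the MPR sets
                if "C" in set_p and "T" in set_v:
                    out[v].append((c, 1.0 / (len(set_p) * len(set_v))))
            else:
                if sp[c] == "C" and sv[c] == "T":
                    out[v].append((c, 1.0))
    return out


def eligible_third_positions(anc: AncestralSequences, focal: int,
                             exclude_columns: set[int] | None = None) -> list[int]:
    """3rd-position columns carrying a C in the focal ancestor (masked and
    excluded columns dropped)."""
    exclude = exclude_columns or set()
    seq = anc.sequences[focal]
    return [c for c in range(2, len(anc.masked), 3)
            if not anc.masked[c] and c not in exclude and seq[c] == "C"]
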