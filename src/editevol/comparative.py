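"""Comparative statistics: edited-site vs 3rd-position C->T rates, sister
clade contrasts with regression through the origin, phylogenetically
independent contrasts, zero-edit pruning, and the retroprocessing window
scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .charmap import BranchEvents, CharacterHistory
from .seqio import Phylogeny


class ContrastError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ES vs 3rd-position rate summary
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] (sum of tables at most
    as probable as the observed one). Degenerate margins give p = 1."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class RateSummary:
    """Per taxon: cumulative C->T change rates at edited sites (ES) and at
    3rd-position C's, from the focal ancestor to each tip, with the 2x2
    counts and Fisher p."""

    gene: str
    table: pd.DataFrame  # index taxon; es_changed, es_total, third_changed, third_total, es_rate, third_rate, fisher_p


def rate_summary(tree: Phylogeny, histories: list[CharacterHistory],
                 events: BranchEvents,
                 third_events: dict[int, list[tuple[int, float]]],
                 eligible_third: list[int], focal: int,
                 gene: str = "") -> RateSummary:
    """Build the ES vs 3rd-position comparison table.

    ES denominators count characters reconstructed as edited (state 1) at
    the focal node; the numerator sums losses of those characters along the
    focal-to-tip path. 3rd-position denominators count C-bearing 3rd
    positions in the focal ancestor; the numerator sums C->T event weights
    at those columns along the same path. Taxa with a zero denominator get
    NaN rates and p.
    """
    eligible_chars = [h for h in histories if h.node_states[focal] == 1]
    es_total = len(eligible_chars)
    third_set = set(eligible_third)
    third_total = len(third_set)
    rows = {}
    for tip in tree.subtree_tips(focal):
        taxon = tree.labels[tip]
        path = tree.path(focal, tip)
        es_changed = 0
        for h in eligible_chars:
            for v, kind in h.events:
                if kind == "loss" and v in path:
                    es_changed += 1
        third_changed = 0.0
        for v in path:
            for col, w in third_events.get(v, []):
                if col in third_set:
                    third_changed += w
        es_rate = es_changed / es_total if es_total else np.nan
        third_rate = third_changed / third_total if third_total else np.nan
        if es_total and third_total:
            p = fisher_exact_2x2(es_changed, es_total - es_changed,
                                 int(round(third_changed)),
                                 third_total - int(round(third_changed)))
        else:
            p = np.nan
        rows[taxon] = dict(es_changed=es_changed, es_total=es_total,
                           third_changed=third_changed, third_total=third_total,
                           es_rate=es_rate, third_rate=third_rate, fisher_p=p)
    return RateSummary(gene, pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# Sister-clade contrasts / regression through the origin
# ---------------------------------------------------------------------------

def node_to_tip_value(tree: Phylogeny, branch_values: dict[int, float],
                      node: int) -> float:
    """Averaged node-to-tip distance: a tip returns its own branch value; an
    internal node returns its branch value plus the mean of its children's
    node-to-tip values."""
    own = branch_values.get(node, 0.0)
    if tree.is_tip(node):
        return own
    return own + float(np.mean([node_to_tip_value(tree, branch_values, c)
                                for c in tree.children[node]]))


@dataclass
class ContrastSet:
    contrasts: pd.DataFrame  # node, dx, dy
    kind: str                # "sister" or "pic"
    n: int
    slope: float
    r: float
    p: float
    pruning_variant: str = "none"


def regression_through_origin(dx, dy) -> tuple[float, float, float]:
    """Slope, correlation and p for a regression forced through the origin.

    slope = Sxy/Sxx, r = Sxy/sqrt(Sxx*Syy); p from t = r*sqrt((n-1)/(1-r^2))
    on n-1 degrees of freedom.
    """
    x = np.asarray(dx, float)
    y = np.asarray(dy, float)
    if x.size < 3:
        raise ContrastError("need at least 3 contrasts")
    sxx = float(x @ x)
    if sxx == 0:
        raise ContrastError("all x contrasts are zero")
    sxy = float(x @ y)
    syy = float(y @ y)
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    n = x.size
    if abs(r) >= 1.0:
        return slope, float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 1) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return slope, float(r), float(p)


def sister_contrasts(tree: Phylogeny, x_branch: dict[int, float],
                     y_branch: dict[int, float]) -> ContrastSet:
    """One contrast per binary internal node: differences of the daughters'
    node-to-tip values, oriented so dx >= 0. Polytomies contribute no
    contrast."""
    rows = []
    for v in range(tree.n_nodes):
        if tree.is_tip(v) or len(tree.children[v]) != 2:
            continue
        a, b = tree.children[v]
        dx = node_to_tip_value(tree, x_branch, a) - node_to_tip_value(tree, x_branch, b)
        dy = node_to_tip_value(tree, y_branch, a) - node_to_tip_value(tree, y_branch, b)
        if dx < 0:
            dx, dy = -dx, -dy
        rows.append(dict(node=v, dx=dx, dy=dy))
    df = pd.DataFrame(rows, columns=["node", "dx", "dy"])
    try:
        slope, r, p = regression_through_origin(df["dx"], df["dy"])
    except ContrastError:
        slope = r = p = float("nan")
    return ContrastSet(df, "sister", len(df), slope, r, p)


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts (Felsenstein)
# ---------------------------------------------------------------------------

def pic(tree: Phylogeny, tip_values: dict[str, float],
        use_ages: bool = True) -> pd.DataFrame:
    """Standardized independent contrasts on a dated (ultrametric) tree.

    Branch variances are branch durations in Ma (age standardization) when
    ``use_ages``; otherwise the stored branch lengths. Polytomies are
    resolved by pairing children sequentially with zero-length connectors.
    Returns a DataFrame (node, contrast, variance).
    """
    if use_ages and tree.ages is None:
        raise ContrastError("tree has no ages; date it first or use_ages=False")

    def bdur(v):
        if use_ages:
            return float(tree.ages[tree.parent[v]] - tree.ages[v])
        return float(tree.lengths[v])

    xhat: dict[int, float] = {}
    vhat: dict[int, float] = {}
    rows = []
    for v in tree.postorder():
        if tree.is_tip(v):
            lab = tree.labels[v]
            if lab not in tip_values:
                raise ContrastError(f"no value for tip {lab!r}")
            xhat[v] = float(tip_values[lab])
            vhat[v] = bdur(v) if tree.parent[v] != -1 else 0.0
            continue
        kids = list(tree.children[v])
        # sequential pairing handles polytomies (zero-length connectors)
        x1, v1 = xhat[kids[0]], vhat[kids[0]]
        for c in kids[1:]:
            x2, v2 = xhat[c], vhat[c]
            tot = v1 + v2
            if tot <= 0:
                raise ContrastError(f"zero total variance at node {v}")
            rows.append(dict(node=v, contrast=(x1 - x2) / np.sqrt(tot),
                             variance=tot))
            x1 = (x1 * v2 + x2 * v1) / tot
            v1 = v1 * v2 / tot
        own = bdur(v) if tree.parent[v] != -1 else 0.0
        xhat[v] = x1
        vhat[v] = own + v1
    return pd.DataFrame(rows, columns=["node", "contrast", "variance"])


def pic_correlation(tree: Phylogeny, x_values: dict[str, float],
                    y_values: dict[str, float],
                    use_ages: bool = True) -> ContrastSet:
    """Pearson correlation (through the origin) of two traits' standardized
    contrasts."""
    cx = pic(tree, x_values, use_ages)
    cy = pic(tree, y_values, use_ages)
    df = pd.DataFrame({"node": cx["node"], "dx": cx["contrast"],
                       "dy": cy["contrast"]})
    # orient by x sign: contrasts have arbitrary direction per node
    flip = df["dx"] < 0
    df.loc[flip, ["dx", "dy"]] *= -1
    slope, r, p = regression_through_origin(df["dx"], df["dy"])
    return ContrastSet(df, "pic", len(df), slope, r, p)


# ---------------------------------------------------------------------------
# Pruning variants
# ---------------------------------------------------------------------------

def prune_zero_edit(tree: Phylogeny, edited_counts: dict[str, int],
                    keep: str = "longest") -> Phylogeny:
    """Collapse each maximal all-zero-edit clade to a single representative.

    ``keep`` selects the tip with the longest or shortest terminal branch
    (ties broken by label). Tips with nonzero counts are never removed.
    """
    if keep not in ("longest", "shortest"):
        raise ValueError("keep must be 'longest' or 'shortest'")
    zero = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            zero[v] = edited_counts.get(tree.labels[v], 0) == 0
        else:
            zero[v] = all(zero[c] for c in tree.children[v])
    drop: set[str] = set()
    for v in range(tree.n_nodes):
        if not zero[v]:
            continue
        p = tree.parent[v]
        if p != -1 and zero[p]:
            continue  # not maximal
        tips = tree.subtree_tips(v)
        if len(tips) <= 1:
            continue
        sign = 1 if keep == "longest" else -1
        chosen = max(tips, key=lambda t: (sign * tree.lengths[t],
                                          tree.labels[t]))
        drop.update(tree.labels[t] for t in tips if t != chosen)
    if not drop:
        return tree
    return tree.retain_tips([l for l in tree.tip_labels if l not in drop])


# ---------------------------------------------------------------------------
# Retroprocessing window scan
# ---------------------------------------------------------------------------

@dataclass
class RetroCandidate:
    branch: int
    k: int
    start: int          # 1-based nt, inclusive
    end: int
    p: float
    whole_gene: bool = False


def _min_window(positions: np.ndarray, k: int) -> tuple[int, int, int]:
    """Tightest window (span, start, end) containing k of the sorted
    positions."""
    spans = positions[k - 1 :] - positions[: positions.size - k + 1]
    i = int(np.argmin(spans))
    return int(spans[i]) + 1, int(positions[i]), int(positions[i + k - 1])


def retro_scan(losses_by_branch: dict[int, list[int]],
               at_risk_by_branch: dict[int, list[int]],
               gene_length: int, n_permutations: int = 10000,
               alpha: float = 0.05, seed: int | None = 0,
               min_k: int = 3) -> list[RetroCandidate]:
    """Scan branches for spatial clustering of edited-site losses.

    For each branch with >= ``min_k`` losses, the statistic is the minimum
    over k in [min_k, n_losses] of the permutation p-value of the tightest
    k-loss window; losses are redrawn uniformly (without replacement) from
    the branch's at-risk edited-site positions. The min-over-k statistic is
    itself calibrated by the same permutations (min-p adjustment), keeping
    the branch-level false-positive rate near ``alpha``. A branch losing
    every at-risk site is reported as a whole-gene conversion candidate with
    p = 0. Returns candidates with p < alpha (plus whole-gene flags).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    out: list[RetroCandidate] = []
    for branch, losses in sorted(losses_by_branch.items()):
        losses = sorted(losses)
        at_risk = np.array(sorted(at_risk_by_branch[branch]))
        m = len(losses)
        if m < 2:
            continue
        if m == at_risk.size:
            out.append(RetroCandidate(branch, m, 1, gene_length, 0.0,
                                      whole_gene=True))
            continue
        if m < min_k:
            continue
        pos = np.asarray(losses)
        ks = range(min_k, m + 1)
        obs = {k: _min_window(pos, k) for k in ks}
        # permutation null: same number of losses, uniform over at-risk sites
        perm_spans = np.empty((n_permutations, len(list(ks))))
        for j in range(n_permutations):
            draw = np.sort(rng.choice(at_risk, size=m, replace=False))
            for ki, k in enumerate(ks):
                perm_spans[j, ki] = _min_window(draw, k)[0]
        obs_p = {}
        for ki, k in enumerate(ks):
            obs_p[k] = (1 + np.sum(perm_spans[:, ki] <= obs[k][0])) / (
                n_permutations + 1)
        best_k = min(obs_p, key=lambda k: (obs_p[k], k))
        t_obs = obs_p[best_k]
        # min-p calibration: rank each permutation's spans against all others
        ranks = np.empty_like(perm_spans)
        for ki in range(perm_spans.shape[1]):
            order = np.sort(perm_spans[:, ki])
            ranks[:, ki] = (np.searchsorted(order, perm_spans[:, ki],
                                            side="right")) / n_permutations
        t_perm = ranks.min(axis=1)
        p_final = float((1 + np.sum(t_perm <= t_obs)) / (n_permutations + 1))
        if p_final < alpha:
            _, start, end = obs[best_k]
            out.append(RetroCandidate(branch, best_k, start, end, p_final))
    return out
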