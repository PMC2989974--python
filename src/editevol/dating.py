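"""Non-parametric rate smoothing (NPRS) and absolute synonymous rates.

NPRS converts a branch-length tree into a chronogram by choosing node ages
that minimise the sum of squared differences between the per-branch rates of
adjacent branches (rate = branch length / branch duration), with the root
age fixed by calibration and tips at age 0. The objective follows
Sanderson's formulation: for every internal node, the parent-branch rate is
compared against each child-branch rate; at the root, child rates are
compared against their mean. Ages are parameterised as fractions of the
parent age, optimised by L-BFGS-B from a path-length-proportional start with
randomly perturbed restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .seqio import Phylogeny


class DatingError(RuntimeError):
    pass


class LineageError(ValueError):
    pass


@dataclass
class DatedTree:
    tree: Phylogeny            # carries .ages (Ma per node)
    root_age: float
    objective: float
    n_restarts: int

    def age(self, v: int) -> float:
        return float(self.tree.ages[v])


def _free_nodes(tree: Phylogeny) -> list[int]:
    """Internal non-root nodes in preorder (parents before children)."""
    return [v for v in tree.preorder()
            if not tree.is_tip(v) and tree.parent[v] != -1]


def _ages_from_fractions(tree: Phylogeny, free: list[int], f: np.ndarray,
                         root_age: float) -> np.ndarray:
    ages = np.zeros(tree.n_nodes)
    ages[tree.root] = root_age
    for k, v in enumerate(free):
        ages[v] = f[k] * ages[tree.parent[v]]
    return ages


def nprs_objective(tree: Phylogeny, ages: np.ndarray,
                   eps: float | None = None) -> float:
    root_age = ages[tree.root]
    if eps is None:
        eps = 1e-6 * root_age
    dur = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes - 1):
        dur[v] = max(ages[tree.parent[v]] - ages[v], eps)
    rate = np.zeros(tree.n_nodes)
    rate[: tree.n_nodes - 1] = tree.lengths[: tree.n_nodes - 1] / dur[: tree.n_nodes - 1]
    obj = 0.0
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            continue
        kids = tree.children[v]
        if tree.parent[v] == -1:
            mean = float(np.mean([rate[c] for c in kids]))
            obj += sum((rate[c] - mean) ** 2 for c in kids)
        else:
            obj += sum((rate[v] - rate[c]) ** 2 for c in kids)
    return obj


def _initial_ages(tree: Phylogeny, root_age: float) -> np.ndarray:
    """Start ages proportional to remaining path length: for each node, the
    mean over its descendant tips of d(node, tip)/d(root, tip). Exact for
    clock-like input."""
    depth = tree.node_depths()
    ages = np.zeros(tree.n_nodes)
    ages[tree.root] = root_age
    for v in range(tree.n_nodes - 1):
        if tree.is_tip(v):
            continue
        fracs = []
        for t in tree.subtree_tips(v):
            if depth[t] > 0:
                fracs.append((depth[t] - depth[v]) / depth[t])
        ages[v] = root_age * (float(np.mean(fracs)) if fracs else 0.5)
    # enforce strict parent > child ordering
    for v in tree.preorder():
        p = tree.parent[v]
        if p != -1 and not tree.is_tip(v):
            ages[v] = min(ages[v], ages[p] * 0.9999)
            ages[v] = max(ages[v], 1e-6 * root_age)
    return ages


def nprs_date(tree: Phylogeny, root_age: float, n_restarts: int = 5,
              seed: int | None = 0) -> DatedTree:
    """Date a branch-length tree by non-parametric rate smoothing.

    The first optimisation starts from path-length-proportional ages; the
    remaining ``n_restarts - 1`` perturb that start point. The best
    objective across restarts is kept. Raises :class:`DatingError` if no
    restart converges.
    """
    if root_age <= 0:
        raise DatingError("root age must be positive")
    if np.any(tree.lengths[: tree.n_nodes - 1] < 0):
        raise DatingError("negative branch length")
    free = _free_nodes(tree)
    rng = np.random.default_rng(seed)

    if not free:  # two-tip tree or star: root age is the only parameter
        ages = np.zeros(tree.n_nodes)
        ages[tree.root] = root_age
        t = tree.copy()
        t.ages = ages
        return DatedTree(t, root_age, nprs_objective(tree, ages), n_restarts)

    ages0 = _initial_ages(tree, root_age)
    f0 = np.array([ages0[v] / ages0[tree.parent[v]] for v in free])
    lo, hi = 1e-4, 1.0 - 1e-4
    f0 = np.clip(f0, lo, hi)

    def fun(f):
        ages = _ages_from_fractions(tree, free, f, root_age)
        return nprs_objective(tree, ages)

    best = None
    failures = []
    for r in range(n_restarts):
        if r == 0:
            start = f0
        else:
            start = np.clip(f0 + rng.normal(0, 0.05, size=f0.size), lo, hi)
        res = minimize(fun, start, method="L-BFGS-B",
                       bounds=[(lo, hi)] * len(free),
                       options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
        if not res.success and not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise DatingError(f"NPRS failed in all restarts: {failures}")
    ages = _ages_from_fractions(tree, free, best.x, root_age)
    t = tree.copy()
    t.ages = ages
    return DatedTree(t, root_age, float(best.fun), n_restarts)


def absolute_rate(dated: DatedTree, branch_ds_values: dict[int, float],
                  focal: int, taxon: str,
                  focal_age_ma: float | None = None) -> float:
    """R_S for one taxon: summed dS from the focal node to the tip, divided
    by the focal node's age in years.

    ``branch_ds_values`` maps child-node index -> dS of the branch above it.
    ``focal_age_ma`` overrides the smoothed age (e.g. a published
    calibration) without re-dating.
    """
    tree = dated.tree
    tip = tree.tip_index(taxon)
    if not tree.is_descendant(tip, focal):
        raise LineageError(f"{taxon!r} is not in the focal clade")
    age = focal_age_ma if focal_age_ma is not None else float(tree.ages[focal])
    if age <= 0:
        raise DatingError("focal age must be positive")
    path = tree.path(focal, tip)
    total = sum(branch_ds_values[v] for v in path)
    return total / (age * 1e6)
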