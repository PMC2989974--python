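"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the shape of a multi-gene organellar data set from a
clade of aquatic monocots: a Yule tree scaled to a calibrated root age,
codon sequences evolving under a per-site HKY-like process, designated
edited-C sites at 1st/2nd codon positions whose C->T loss rate is a
multiple (lambda_ES) of the baseline 3rd-position C->T rate (lambda_3rd),
clade-specific rate multipliers, and retroprocessing events that convert
the remaining edited C's of a branch (whole gene or a window) to T in one
stroke. cDNA is derived from DNA by rendering every still-edited C as T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import CodonAlignment, Phylogeny

NUC = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUC)}

# codons providing an editable C at position 1 or 2 whose edit changes the
# protein (the biological signature of C->U editing)
_ES_CODONS = {1: ["CCA", "CGG", "CAT", "CGT"], 2: ["TCA", "CCA", "TCG", "ACG"]}
# codons with a synonymous C at the 3rd position
_THIRD_C_CODONS = ["TTC", "ATC", "GTC", "ACC", "GCC", "AAC", "GAC", "GGC"]
_FILLER = ["ATG", "GAA", "AAA", "GGA", "TGG", "ATT", "GAT", "AGA"]


@dataclass
class RetroEvent:
    """Instantaneous conversion of edited C's to T on one branch.

    ``clade`` gives the tip labels whose MRCA's parent branch carries the
    event; ``window`` is a 0-based half-open nt interval or None for the
    whole gene; ``completeness`` is the per-site conversion probability.
    """

    gene: str
    clade: list[str]
    window: tuple[int, int] | None = None
    completeness: float = 1.0


@dataclass
class GeneParams:
    name: str
    n_codons: int
    n_edited: int
    # fraction of edited sites at codon positions 1/2/3 (3rd not simulated:
    # editing there is synonymous and vanishingly rare)
    pos_mix: tuple[float, float] = (0.5, 0.5)


@dataclass
class SimulationParams:
    """Study-shaped defaults: 46 taxa, 5 genes, ~4357 aligned positions,
    edited-site counts per gene following the observed per-gene totals
    (atp1 5, ccmB 44, cob 25, mtt2 30, nad5 25)."""

    n_taxa: int = 46
    birth_rate: float = 0.03      # per Myr; only sets Yule shape pre-scaling
    root_age: float = 130.0       # Ma
    genes: list[GeneParams] = field(default_factory=lambda: [
        GeneParams("atp1", 380, 5),
        GeneParams("ccmB", 202, 44),
        GeneParams("cob", 390, 25),
        GeneParams("mtt2", 230, 30),
        GeneParams("nad5", 250, 25),
    ])
    base_rate: float = 5e-4       # subs/site/Myr at 3rd positions
    first_second_scale: float = 0.3
    kappa: float = 2.0
    lambda_es: float = 1.0        # C->T multiplier at edited sites
    lambda_3rd: float = 1.0       # C->T multiplier at 3rd-position C's
    clade_multipliers: dict[tuple[str, ...], float] = field(default_factory=dict)
    retro_events: list[RetroEvent] = field(default_factory=list)
    cdna_taxa: list[str] | None = None   # None = all taxa get cDNA
    user_tree: Phylogeny | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    tree: Phylogeny                       # with .ages (Ma)
    node_sequences: dict[str, dict[int, str]]        # gene -> node -> seq
    mutation_log: list[tuple]             # (gene, child node, column, frm, to)
    edited_sites: dict[str, list[int]]    # gene -> 0-based ES columns
    edited_status: dict[str, np.ndarray]  # gene -> (n_nodes x n_es) bool
    conversion_log: list[tuple]           # (gene, child node, column)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(params: SimulationParams,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Yule tree with ``n_taxa`` tips scaled so the root sits at
    ``root_age``; tips are labelled t01..tNN. A ``user_tree`` passes
    through untouched."""
    if params.user_tree is not None:
        return params.user_tree
    if params.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    b = params.birth_rate
    # birth process: start at the root split with 2 lineages
    split_times = [0.0]
    n = 2
    t = 0.0
    while n < params.n_taxa:
        t += rng.exponential(1.0 / (b * n))
        split_times.append(t)
        n += 1
    t_end = t + rng.exponential(1.0 / (b * n))
    # assemble newick by splitting random active lineages
    width = len(str(params.n_taxa))
    labels = [f"t{i + 1:0{width}d}" for i in range(params.n_taxa)]
    nodes = [{"children": None, "time": 0.0},
             {"children": None, "time": 0.0}]
    active = [0, 1]
    parent_time = {0: 0.0, 1: 0.0}
    for st in split_times[1:]:
        i = int(rng.integers(len(active)))
        v = active.pop(i)
        nodes[v]["children"] = (len(nodes), len(nodes) + 1)
        nodes[v]["split"] = st
        for _ in range(2):
            nodes.append({"children": None, "time": st})
            parent_time[len(nodes) - 1] = st
            active.append(len(nodes) - 1)
    lab_iter = iter(rng.permutation(labels))

    def nwk(v, birth):
        node = nodes[v]
        if node["children"] is None:
            return f"{next(lab_iter)}:{(t_end - birth) * params.root_age / t_end:.10g}"
        a, c = node["children"]
        st = node["split"]
        inner = f"({nwk(a, st)},{nwk(c, st)})"
        return f"{inner}:{(st - birth) * params.root_age / t_end:.10g}"

    a, c = nodes[0], nodes[1]
    text = f"({nwk(0, 0.0)},{nwk(1, 0.0)});"
    tree = Phylogeny.from_newick(text)
    # attach true ages (branch lengths are in Ma by construction)
    depth = tree.node_depths()
    tree.ages = params.root_age - depth
    tree.ages[np.array([tree.is_tip(v) for v in range(tree.n_nodes)])] = 0.0
    return tree


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _site_rate_matrix(kappa: float) -> np.ndarray:
    q = np.ones((4, 4))
    for i in range(4):
        for j in range(4):
            pair = {NUC[i], NUC[j]}
            if pair in ({"A", "G"}, {"C", "T"}):
                q[i, j] = kappa
    np.fill_diagonal(q, 0.0)
    q /= q.sum(axis=1).mean()  # normalise to ~1 expected sub per unit rate*time
    return q


def _root_sequence(gp: GeneParams, rng) -> tuple[list[str], list[int]]:
    """Root codons with ``n_edited`` designated edited-C sites; remaining
    codons drawn from 3rd-C and filler codons so 3rd-position C content is
    realistic. Returns (codons, 0-based ES columns)."""
    n1 = int(round(gp.n_edited * gp.pos_mix[0]))
    n2 = gp.n_edited - n1
    es_codon_idx = rng.choice(gp.n_codons, size=gp.n_edited, replace=False)
    es_codon_idx = np.sort(es_codon_idx)
    codons = []
    es_cols = []
    which = ([1] * n1) + ([2] * n2)
    rng.shuffle(which)
    es_map = dict(zip(es_codon_idx.tolist(), which))
    for i in range(gp.n_codons):
        if i in es_map:
            pos = es_map[i]
            codons.append(str(rng.choice(_ES_CODONS[pos])))
            es_cols.append(3 * i + pos - 1)
        elif rng.random() < 0.5:
            codons.append(str(rng.choice(_THIRD_C_CODONS)))
        else:
            codons.append(str(rng.choice(_FILLER)))
    return codons, es_cols


def _branch_multiplier(tree: Phylogeny, params: SimulationParams) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    for clade, m in params.clade_multipliers.items():
        mrca = tree.mrca(list(clade))
        for v in range(tree.n_nodes):
            if tree.is_descendant(v, mrca):
                mult[v] *= m
    return mult


def simulate_sequences(tree: Phylogeny, params: SimulationParams,
                       rng: np.random.Generator | None = None
                       ) -> tuple[dict[str, CodonAlignment],
                                  dict[str, CodonAlignment], GroundTruth]:
    """Evolve all genes along the tree; returns (dna, cdna, truth).

    Site-specific rates: codon positions 1/2 evolve at
    ``base_rate * first_second_scale``; 3rd positions at ``base_rate``.
    The C->T entry is additionally multiplied by ``lambda_es`` at edited
    sites and ``lambda_3rd`` at 3rd positions. Retro events fire at the end
    of their branch, before its descendants evolve. cDNA renders every
    still-edited C (a C at an edited-site column) as T.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if tree.ages is None:
        raise ValueError("tree must carry ages (Ma)")
    durations = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 1):
        durations[v] = tree.ages[tree.parent[v]] - tree.ages[v]
    mult = _branch_multiplier(tree, params)
    qbase = _site_rate_matrix(params.kappa)
    ct = (NUC_INDEX["C"], NUC_INDEX["T"])

    retro_by_branch: dict[tuple[str, int], list[RetroEvent]] = {}
    for ev in params.retro_events:
        node = tree.mrca(ev.clade)
        retro_by_branch.setdefault((ev.gene, node), []).append(ev)

    dna = {}
    cdna = {}
    node_seqs: dict[str, dict[int, str]] = {}
    mutation_log: list[tuple] = []
    conversion_log: list[tuple] = []
    edited_sites: dict[str, list[int]] = {}
    edited_status: dict[str, np.ndarray] = {}

    for gp in params.genes:
        codons, es_cols = _root_sequence(gp, rng)
        root_seq = np.array(list("".join(codons)))
        n_sites = root_seq.size
        es_set = set(es_cols)
        # per-site rate scale and Q modifications
        site_rate = np.full(n_sites, params.base_rate)
        for c in range(n_sites):
            if c % 3 != 2:
                site_rate[c] *= params.first_second_scale
        qs = np.broadcast_to(qbase, (n_sites, 4, 4)).copy()
        for c in range(n_sites):
            if c in es_set:
                # lambda_es is defined relative to the 3rd-position C->T
                # baseline, so undo the slower 1st/2nd site rate here
                qs[c, ct[0], ct[1]] *= params.lambda_es / params.first_second_scale
            elif c % 3 == 2:
                qs[c, ct[0], ct[1]] *= params.lambda_3rd

        out_rates = qs.sum(axis=2)          # (n_sites, 4) leaving rates
        qcum = np.cumsum(qs, axis=2)        # for fast target sampling
        root_idx = np.array([NUC_INDEX[b] for b in root_seq])

        seqs: dict[int, np.ndarray] = {tree.root: root_idx}
        for v in tree.preorder():
            if tree.parent[v] == -1:
                continue
            p = tree.parent[v]
            seq = seqs[p].copy()
            t_branch = durations[v] * mult[v]
            tl_all = t_branch * site_rate
            r_all = out_rates[np.arange(n_sites), seq]
            p_event = -np.expm1(-r_all * tl_all)
            hits = np.flatnonzero(rng.random(n_sites) < p_event)
            for c in hits:
                s = int(seq[c])
                tl = tl_all[c]
                r = out_rates[c, s]
                # first jump time conditioned on falling inside the branch
                u = rng.random()
                dt = -np.log1p(u * np.expm1(-r * tl)) / r
                while dt < tl:
                    tl -= dt
                    u = rng.random() * out_rates[c, s]
                    s_new = int(np.searchsorted(qcum[c, s], u, side="right"))
                    s_new = min(s_new, 3)
                    mutation_log.append((gp.name, v, int(c), NUC[s], NUC[s_new]))
                    s = s_new
                    r = out_rates[c, s]
                    dt = rng.exponential(1.0 / r)
                seq[c] = s
            for ev in retro_by_branch.get((gp.name, v), []):
                lo, hi = ev.window if ev.window else (0, n_sites)
                for c in es_cols:
                    if lo <= c < hi and seq[c] == NUC_INDEX["C"]:
                        if rng.random() < ev.completeness:
                            seq[c] = NUC_INDEX["T"]
                            conversion_log.append((gp.name, v, int(c)))
            seqs[v] = seq

        nuc_arr = np.array(list(NUC))
        taxa = sorted(tree.tip_labels)
        mat = np.array([nuc_arr[seqs[tree.tip_index(t)]] for t in taxa])
        dna[gp.name] = CodonAlignment(gp.name, taxa, mat)
        ctaxa = params.cdna_taxa if params.cdna_taxa is not None else taxa
        cmat = mat[[taxa.index(t) for t in ctaxa]].copy()
        for c in es_cols:
            col = cmat[:, c]
            col[col == "C"] = "T"
        cdna[gp.name] = CodonAlignment(gp.name, list(ctaxa), cmat)

        node_seqs[gp.name] = {v: "".join(nuc_arr[s]) for v, s in seqs.items()}
        edited_sites[gp.name] = es_cols
        status = np.zeros((tree.n_nodes, len(es_cols)), dtype=bool)
        for v, s in seqs.items():
            for j, c in enumerate(es_cols):
                status[v, j] = s[c] == NUC_INDEX["C"]
        edited_status[gp.name] = status

    truth = GroundTruth(tree, node_seqs, mutation_log, edited_sites,
                        edited_status, conversion_log)
    return dna, cdna, truth


def replay_mutations(truth: GroundTruth, gene: str) -> dict[int, str]:
    """Re-derive every node's sequence for ``gene`` from the root sequence,
    the mutation log and the conversion log (oracle for the simulator)."""
    tree = truth.tree
    seqs = {tree.root: list(truth.node_sequences[gene][tree.root])}
    by_branch: dict[int, list[tuple]] = {}
    for g, v, c, frm, to in truth.mutation_log:
        if g == gene:
            by_branch.setdefault(v, []).append((c, frm, to))
    conv: dict[int, list[int]] = {}
    for g, v, c in truth.conversion_log:
        if g == gene:
            conv.setdefault(v, []).append(c)
    for v in tree.preorder():
        if tree.parent[v] == -1:
            continue
        seq = list(seqs[tree.parent[v]])
        for c, frm, to in by_branch.get(v, []):
            assert seq[c] == frm, "mutation log out of order"
            seq[c] = to
        for c in conv.get(v, []):
            seq[c] = "T"
        seqs[v] = seq
    return {v: "".join(s) for v, s in seqs.items()}


# ---------------------------------------------------------------------------
# Recovery harness: run the pipeline on simulated data with known truth
# ---------------------------------------------------------------------------

def estimate_ct_ratio(tree: Phylogeny, dna: CodonAlignment,
                      cdna: CodonAlignment, focal: int | None = None):
    """Run the analysis chain on one simulated gene and estimate the
    edited-site vs 3rd-position C->T hazard ratio.

    Returns (rate_summary_df, ratio_hat, fisher_p_focal_taxon). The ratio
    estimator is an exposure-weighted event-rate MLE on the reconstructed
    histories: events / (at-risk site x branch-duration), where a site is at
    risk on a branch when its reconstructed parent state still carries the
    editable/3rd-position C. This corrects for sites already lost along deep
    paths.
    """
    from . import ancrates, charmap, comparative, edit_calling

    focal = tree.root if focal is None else focal
    table = edit_calling.filter_heterogeneous(
        edit_calling.call_edited_sites(dna, cdna))
    matrix = charmap.BinaryCharacterMatrix.from_edit_table(table)
    histories = charmap.map_characters(tree, matrix, "DELTRAN")
    events = charmap.count_branch_changes(tree, histories, dna.gene)
    anc = ancrates.reconstruct_ancestral_sequences(tree, dna, "parsimony")
    es_cols = set(matrix.characters)
    third_ev = ancrates.third_position_ct_events(tree, anc, es_cols)
    eligible = ancrates.eligible_third_positions(anc, focal, es_cols)
    rs = comparative.rate_summary(tree, histories, events, third_ev,
                                  eligible, focal, dna.gene)
    df = rs.table

    dur = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 1):
        dur[v] = tree.ages[tree.parent[v]] - tree.ages[v]
    es_events = es_expo = 0.0
    for h in histories:
        for v in range(tree.n_nodes - 1):
            if h.node_states[tree.parent[v]] == 1:
                es_expo += dur[v]
        es_events += sum(1 for _, kind in h.events if kind == "loss")
    th_events = th_expo = 0.0
    eligible_any = [c for c in range(2, len(anc.masked), 3)
                    if not anc.masked[c] and c not in es_cols]
    for c in eligible_any:
        for v in range(tree.n_nodes - 1):
            if anc.sequences[tree.parent[v]][c] == "C":
                th_expo += dur[v]
    for v, evs in third_ev.items():
        th_events += sum(w for _, w in evs)
    if es_expo > 0 and th_expo > 0 and th_events > 0:
        ratio = float((es_events / es_expo) / (th_events / th_expo))
    else:
        ratio = np.nan
    focal_taxon = sorted(df.index)[0]
    return df, ratio, float(df.loc[focal_taxon, "fisher_p"])


def ratio_recovery(true_ratio: float, n_replicates: int, seed: int,
                   n_taxa: int = 30, n_es: int = 40, n_third: int = 200,
                   root_age: float = 130.0, base_rate: float = 5e-4):
    """Simulate ``n_replicates`` single-gene data sets at a given
    lambda_ES/lambda_3rd ratio and re-estimate it through the full chain.

    Returns a DataFrame with one row per replicate (ratio_hat, fisher_p,
    n_es_eligible, n_third_eligible).
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        gp = GeneParams("sim", n_es + 2 * n_third, n_es)
        params = SimulationParams(
            n_taxa=n_taxa, root_age=root_age, genes=[gp],
            base_rate=base_rate, lambda_es=true_ratio, lambda_3rd=1.0,
            seed=0,
        )
        tree = simulate_tree(params, rng)
        dna, cdna, _ = simulate_sequences(tree, params, rng)
        df, ratio, fp = estimate_ct_ratio(tree, dna["sim"], cdna["sim"])
        rows.append(dict(true_ratio=true_ratio, ratio_hat=ratio, fisher_p=fp,
                         n_es_eligible=int(df["es_total"].iloc[0]),
                         n_third_eligible=int(df["third_total"].iloc[0])))
    return pd.DataFrame(rows)


def dating_recovery(n_replicates: int, seed: int, n_taxa: int = 20,
                    root_age: float = 100.0, rate_sigma: float = 0.2):
    """Simulate trees whose branch rates drift smoothly (log-normal steps on
    the lineage rate), date them by NPRS, and report the median relative
    node-age error per replicate."""
    import pandas as pd

    from .dating import nprs_date

    rows = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        params = SimulationParams(n_taxa=n_taxa, root_age=root_age)
        tree = simulate_tree(params, rng)
        true_ages = tree.ages.copy()
        # autocorrelated rates: child rate = parent rate * exp(sigma * N(0,1))
        rates = np.ones(tree.n_nodes)
        for v in tree.preorder():
            p = tree.parent[v]
            base = rates[p] if p != -1 else 1.0
            rates[v] = base * np.exp(rng.normal(0.0, rate_sigma))
        blen = tree.copy()
        for v in range(tree.n_nodes - 1):
            dur = true_ages[tree.parent[v]] - true_ages[v]
            blen.lengths[v] = dur * rates[v] * 1e-3
        blen.ages = None
        dated = nprs_date(blen, root_age, seed=int(rng.integers(2**31)))
        errs = []
        for v in range(tree.n_nodes):
            if tree.is_tip(v) or v == tree.root:
                continue
            errs.append(abs(dated.tree.ages[v] - true_ages[v]) / true_ages[v])
        rows.append(dict(median_rel_err=float(np.median(errs))))
    return pd.DataFrame(rows)


def pic_recovery(rho: float, n_replicates: int, seed: int,
                 n_taxa: int = 30, root_age: float = 100.0):
    """Co-simulate two Brownian traits with correlation ``rho`` on Yule
    chronograms and recover the correlation from standardized contrasts."""
    import pandas as pd

    from .comparative import pic_correlation

    rows = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        params = SimulationParams(n_taxa=n_taxa, root_age=root_age)
        tree = simulate_tree(params, rng)
        x = np.zeros(tree.n_nodes)
        y = np.zeros(tree.n_nodes)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        chol = np.linalg.cholesky(cov)
        for v in tree.preorder():
            p = tree.parent[v]
            if p == -1:
                continue
            dur = tree.ages[p] - tree.ages[v]
            step = chol @ rng.normal(size=2) * np.sqrt(max(dur, 0.0))
            x[v] = x[p] + step[0]
            y[v] = y[p] + step[1]
        xv = {tree.labels[v]: x[v] for v in tree.tips}
        yv = {tree.labels[v]: y[v] for v in tree.tips}
        cs = pic_correlation(tree, xv, yv)
        rows.append(dict(true_rho=rho, r_hat=cs.r, n=cs.n))
    return pd.DataFrame(rows)


def retro_recovery(n_replicates: int, seed: int, whole_gene: bool,
                   n_at_risk: int = 30, n_losses: int = 12,
                   gene_length: int = 900, n_permutations: int = 500,
                   alpha: float = 0.05):
    """Sensitivity (whole-gene conversions) or false-positive rate (uniform
    null losses) of the retroprocessing scan, one scanned branch per
    replicate."""
    import pandas as pd

    from .comparative import retro_scan

    rows = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        at_risk = np.sort(rng.choice(gene_length, size=n_at_risk,
                                     replace=False)) + 1
        if whole_gene:
            losses = list(at_risk)
        else:
            losses = sorted(rng.choice(at_risk, size=n_losses, replace=False))
        cands = retro_scan({0: list(losses)}, {0: list(at_risk)}, gene_length,
                           n_permutations=n_permutations, alpha=alpha,
                           seed=int(rng.integers(2**31)))
        hit = any(c.whole_gene for c in cands) if whole_gene else bool(cands)
        rows.append(dict(flagged=hit))
    return pd.DataFrame(rows)


def recovery_harness(ratios=(1.0, 3.0, 5.0, 10.0), n_replicates: int = 50,
                     seed: int = 0):
    """Run the ratio-recovery grid and summarise bias per true ratio."""
    import pandas as pd

    parts = []
    for i, r in enumerate(ratios):
        df = ratio_recovery(r, n_replicates, seed + 1000 * i)
        parts.append(df)
    all_df = pd.concat(parts, ignore_index=True)
    summary = all_df.groupby("true_ratio")["ratio_hat"].median().reset_index()
    summary["rel_bias"] = summary["ratio_hat"] / summary["true_ratio"] - 1
    return all_df, summary
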