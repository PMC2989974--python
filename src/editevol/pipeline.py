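"""End-to-end pipeline: call -> map -> rates -> date -> contrasts -> retro scan.

Each stage failure is re-raised with the stage name so a run aborts with a
clear pointer. All numeric TSV output uses a fixed float format, so two runs
with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import json
import os
import sys

import numpy as np
import pandas as pd

from . import __version__
from . import ancrates, charmap, comparative, dating, edit_calling
from .seqio import Phylogeny, RunConfig, read_alignment, read_tree, write_tree

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured gene and write the result bundle.

    Outputs (per out_dir): edit_table.tsv, branch_events.tsv,
    branch_substitutions.tsv, chronogram.nwk, absolute_rates.tsv,
    rate_summary.tsv, contrasts.tsv, retro_scan.tsv, run_summary.json.
    Returns the in-memory bundle.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    tree = _load_tree(config)
    alignments, cdnas = _load_alignments(config, tree)

    tables = {}
    matrices = {}
    histories = {}
    events = {}
    ancs = {}
    branch_subs = {}
    for g in config.genes:
        tables[g] = _call_stage(alignments[g], cdnas.get(g), config)
        matrices[g] = charmap.BinaryCharacterMatrix.from_edit_table(
            tables[g], scoring=config.gain_scoring)
        histories[g], events[g] = _map_stage(tree, matrices[g], config)
        ancs[g], branch_subs[g] = _rates_stage(tree, alignments[g])

    dated, focal = _date_stage(tree, config)
    rates_df = _absolute_rates(dated, branch_subs, focal, config)
    summaries, contrast_rows = _comparative_stage(
        tree, dated, config, histories, events, ancs, matrices, branch_subs,
        focal)
    retro_df = _retro_stage(tree, config, histories, matrices, alignments,
                            focal)

    _write_outputs(config, tree, dated, tables, events, branch_subs,
                   rates_df, summaries, contrast_rows, retro_df, alignments)
    return dict(tree=tree, dated=dated, tables=tables, histories=histories,
                events=events, branch_subs=branch_subs, rates=rates_df,
                summaries=summaries, contrasts=contrast_rows, retro=retro_df)


@_stage("load-tree")
def _load_tree(config: RunConfig) -> Phylogeny:
    return read_tree(config.tree_path)


@_stage("load-alignments")
def _load_alignments(config, tree):
    alignments = {}
    cdnas = {}
    for g in config.genes:
        alignments[g] = read_alignment(config.dna_paths[g], gene=g)
        if g in config.cdna_paths:
            cdnas[g] = read_alignment(config.cdna_paths[g], gene=g)
    for g, aln in alignments.items():
        missing = set(tree.tip_labels) - set(aln.taxa)
        if missing:
            raise ValueError(
                f"tree tips absent from {g} alignment: {sorted(missing)}")
    return alignments, cdnas


@_stage("call-edits")
def _call_stage(dna, cdna, config):
    if cdna is not None:
        table = edit_calling.call_edited_sites(dna, cdna)
    else:
        raise ValueError(f"gene {dna.gene!r} has neither cDNA nor a "
                         "reference profile for prediction")
    return edit_calling.filter_heterogeneous(table)


@_stage("map-changes")
def _map_stage(tree, matrix, config):
    hists = charmap.map_characters(tree, matrix, config.optimization_mode)
    ev = charmap.count_branch_changes(tree, hists, matrix.gene)
    return hists, ev


@_stage("rates")
def _rates_stage(tree, aln):
    anc = ancrates.reconstruct_ancestral_sequences(tree, aln, "parsimony")
    subs = ancrates.tree_branch_ds(tree, anc)
    return anc, subs


@_stage("date")
def _date_stage(tree, config):
    dated = dating.nprs_date(tree, config.root_age, seed=config.seed)
    focal = (tree.mrca(config.focal_clade) if config.focal_clade
             else tree.root)
    return dated, focal


@_stage("rates")
def _absolute_rates(dated, branch_subs, focal, config):
    rows = []
    tree = dated.tree
    for g, subs in branch_subs.items():
        ds_map = {v: b.dS for v, b in subs.items()}
        for tip in tree.subtree_tips(focal):
            taxon = tree.labels[tip]
            ds = ancrates.ds_path(tree, subs, focal, tip)
            rs = dating.absolute_rate(dated, ds_map, focal, taxon,
                                      focal_age_ma=config.focal_age)
            rows.append(dict(taxon=taxon, gene=g, ds_path=ds, R_S=rs))
    return pd.DataFrame(rows)


@_stage("contrasts")
def _comparative_stage(tree, dated, config, histories, events, ancs,
                       matrices, branch_subs, focal):
    summaries = {}
    contrast_rows = []
    for g in config.genes:
        es_cols = set(matrices[g].characters)
        third_ev = ancrates.third_position_ct_events(tree, ancs[g], es_cols)
        eligible = ancrates.eligible_third_positions(ancs[g], focal, es_cols)
        summaries[g] = comparative.rate_summary(
            tree, histories[g], events[g], third_ev, eligible, focal, g)
        # sister contrasts: dS per branch vs changes per branch
        losses_only = config.changes == "losses"
        x = {v: branch_subs[g][v].dS for v in range(tree.n_nodes - 1)}
        y = {}
        for v in range(tree.n_nodes - 1):
            y[v] = int(events[g].losses[v])
            if not losses_only:
                y[v] += int(events[g].gains[v])
        try:
            cs = comparative.sister_contrasts(tree, x, y)
            contrast_rows.append(dict(gene=g, kind="sister",
                                      variables="dS_vs_changes",
                                      variant="none", n=cs.n,
                                      slope=cs.slope, r=cs.r, p=cs.p))
        except comparative.ContrastError:
            pass
        contrast_rows.extend(
            _pic_rows(tree, dated, config, g, histories[g], events[g],
                      branch_subs[g], focal))
    cols = ["gene", "kind", "variables", "variant", "n", "slope", "r", "p"]
    return summaries, pd.DataFrame(contrast_rows, columns=cols)


def _dated_subtree(dated, keep_labels):
    """Prune a dated tree to ``keep_labels``, rebuilding ages from the
    (ultrametric) duration branch lengths."""
    t = dated.tree.copy()
    for v in range(t.n_nodes - 1):
        t.lengths[v] = t.ages[t.parent[v]] - t.ages[v]
    pruned = t.retain_tips(keep_labels)
    depth = pruned.node_depths()
    span = max(depth[v] for v in pruned.tips)
    pruned.ages = span - depth
    for v in pruned.tips:
        pruned.ages[v] = 0.0
    return pruned


def _pic_rows(tree, dated, config, gene, hists, events, subs, focal):
    """Age-standardized contrasts of per-taxon R_S against (a) cumulative
    edited-site changes from the focal node and (b) edited-site counts,
    under the configured pruning variant (plus the unpruned analysis)."""
    losses_only = config.changes == "losses"
    ds_map = {v: subs[v].dS for v in range(tree.n_nodes - 1)}
    rs_vals, chg_vals, cnt_vals = {}, {}, {}
    for tip in tree.subtree_tips(focal):
        taxon = tree.labels[tip]
        rs_vals[taxon] = dating.absolute_rate(dated, ds_map, focal, taxon,
                                              focal_age_ma=config.focal_age)
        chg_vals[taxon] = float(charmap.cumulative_changes(
            tree, events, focal, tip, losses_only=losses_only))
        cnt_vals[taxon] = float(sum(
            1 for h in hists if h.node_states[tip] == 1))
    variants = ["none"]
    if config.pruning_variant != "none":
        variants.append(config.pruning_variant)
    rows = []
    for variant in variants:
        if variant == "none":
            taxa = list(rs_vals)
            sub = (dated.tree if set(taxa) == set(dated.tree.tip_labels)
                   else _dated_subtree(dated, taxa))
        else:
            keep = comparative.prune_zero_edit(
                dated.tree, {t: int(c) for t, c in cnt_vals.items()},
                keep=variant.split("-")[1]).tip_labels
            taxa = [t for t in keep if t in rs_vals]
            if len(taxa) < 4:
                continue
            sub = _dated_subtree(dated, taxa)
        for name, y in (("RS_vs_changes", chg_vals),
                        ("RS_vs_n_edited", cnt_vals)):
            try:
                cs = comparative.pic_correlation(
                    sub, {t: rs_vals[t] for t in taxa},
                    {t: y[t] for t in taxa})
                rows.append(dict(gene=gene, kind="pic", variables=name,
                                 variant=variant, n=cs.n, slope=cs.slope,
                                 r=cs.r, p=cs.p))
            except comparative.ContrastError:
                pass
    return rows


@_stage("retro-scan")
def _retro_stage(tree, config, histories, matrices, alignments, focal):
    rows = []
    for g in config.genes:
        losses = {}
        at_risk = {}
        eligible = [h for h in histories[g] if h.node_states[focal] == 1]
        for v in range(tree.n_nodes - 1):
            if not tree.is_descendant(v, focal):
                continue
            pos = [h.character + 1 for h in eligible
                   for b, kind in h.events if b == v and kind == "loss"]
            if len(pos) >= 2:
                losses[v] = sorted(pos)
                at_risk[v] = sorted(
                    h.character + 1 for h in histories[g]
                    if h.node_states[tree.parent[v]] == 1)
        if not losses:
            continue
        cands = comparative.retro_scan(
            losses, at_risk, alignments[g].n_columns,
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=config.seed)
        for c in cands:
            rows.append(dict(gene=g, branch_id=tree.branch_name(c.branch),
                             k=c.k, start=c.start, end=c.end, p=c.p,
                             whole_gene=c.whole_gene))
    return pd.DataFrame(rows, columns=["gene", "branch_id", "k", "start",
                                       "end", "p", "whole_gene"])


@_stage("write-outputs")
def _write_outputs(config, tree, dated, tables, events, branch_subs,
                   rates_df, summaries, contrast_rows, retro_df, alignments):
    out = config.out_dir

    def path(name):
        return os.path.join(out, name)

    with open(path("edit_table.tsv"), "w") as fh:
        first = True
        for g, t in tables.items():
            import io as _io
            buf = _io.StringIO()
            t.to_tsv(buf, frame=alignments[g].frame)
            text = buf.getvalue()
            fh.write(text if first else text.split("\n", 1)[1])
            first = False
    with open(path("branch_events.tsv"), "w") as fh:
        first = True
        for g, ev in events.items():
            import io as _io
            buf = _io.StringIO()
            charmap.branch_events_to_tsv(tree, ev, buf)
            text = buf.getvalue()
            fh.write(text if first else text.split("\n", 1)[1])
            first = False
    rows = []
    for g, subs in branch_subs.items():
        for v, b in sorted(subs.items()):
            rows.append(dict(
                gene=g, branch_id=tree.branch_name(v),
                syn_count=b.syn_count, nonsyn_count=b.nonsyn_count,
                S=b.S, N=b.N, dS=b.dS,
                ct3_events=";".join(str(c + 1) for c in b.ct3_events)))
    pd.DataFrame(rows).to_csv(path("branch_substitutions.tsv"), sep="\t",
                              index=False, float_format=FLOAT_FMT)
    age_labels = {v: f"{dated.tree.ages[v]:.6g}"
                  for v in range(tree.n_nodes) if not tree.is_tip(v)}
    write_tree(dated.tree, path("chronogram.nwk"), node_labels=age_labels)
    rates_df.to_csv(path("absolute_rates.tsv"), sep="\t", index=False,
                    float_format=FLOAT_FMT)
    parts = []
    for g, s in summaries.items():
        df = s.table.copy()
        df.insert(0, "gene", g)
        df.insert(1, "taxon", df.index)
        parts.append(df)
    pd.concat(parts, ignore_index=True).to_csv(
        path("rate_summary.tsv"), sep="\t", index=False,
        float_format=FLOAT_FMT)
    contrast_rows.to_csv(path("contrasts.tsv"), sep="\t", index=False,
                         float_format=FLOAT_FMT)
    retro_df.to_csv(path("retro_scan.tsv"), sep="\t", index=False,
                    float_format=FLOAT_FMT)
    summary = dict(
        version=__version__,
        python=sys.version.split()[0],
        seed=config.seed,
        optimization_mode=config.optimization_mode,
        pruning_variant=config.pruning_variant,
        gain_scoring=config.gain_scoring,
        prep_threshold=config.prep_threshold,
        root_age=config.root_age,
        focal_age=config.focal_age,
        genes=list(config.genes),
        nprs_objective=dated.objective,
    )
    with open(path("run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
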