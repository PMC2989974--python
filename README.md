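# editevol

Evolutionary dynamics of C-to-U RNA-editing sites in plant mitochondrial
protein-coding genes, for molecular evolutionists working with DNA/cDNA
alignment pairs on a fixed phylogeny.

RNA editing converts genomic C's to U in the mature transcript; a genomic
C→T substitution at such a site makes editing superfluous (a *loss*), and
gene conversion with a reverse-transcribed edited cDNA (*retroprocessing*)
can erase many edited sites at once. `editevol` provides the full analysis
chain for studying these dynamics:

- **Edit calling** from DNA/cDNA pairs, with the heterogeneity exclusion
  rule (sites verifiably edited in some taxa but unedited-C in others are
  dropped) and a profile-based predictor (threshold 0.6) for taxa without
  transcripts.
- **Parsimony mapping** of edited-site gains and losses on a rooted tree:
  exact Fitch/Sankoff lengths, full MPR sets, ACCTRAN/DELTRAN resolution
  (DELTRAN default, favouring parallel loss), per-branch event tables,
  cumulative node-to-tip change counts and tree statistics (L, CI excluding
  autapomorphies, RI).
- **Synonymous rates**: ancestral codon reconstruction (parsimony, optional
  ML), Nei–Gojobori-style per-branch dS with Jukes–Cantor correction,
  Tajima-style relative rate tests, and extraction of C→T events at neutral
  3rd codon positions.
- **Dating**: non-parametric rate smoothing (NPRS) with a fixed root age
  (default 130 Ma) and absolute synonymous rates
  R_S = dS(focal node→tip) / focal age (default 79.1 Ma).
- **Comparative tests**: per-taxon edited-site vs 3rd-position C→T rate
  tables with Fisher exact tests; sister-clade contrasts with regression
  through the origin; Felsenstein's independent contrasts standardized by
  split ages; pruning of zero-editing clades to one representative.
- **Retro-scan**: a min-p calibrated permutation test for spatial
  clustering of a branch's edited-site losses (windowed or whole-gene
  conversion candidates).
- A fully seeded **simulator** with ground truth (trees with ages, node
  sequences, mutation logs, conversion events) for every stage.

## Worked example

`examples/` holds one short script per capability. For instance, mapping an
ambiguous editing character under both optimization modes
(`python examples/02_map_gains_and_losses.py`):

```
DELTRAN: [('Y', 'loss'), ('X', 'loss')]
ACCTRAN: [('node7', 'loss'), ('Z', 'gain')]
```

DELTRAN explains the character by two parallel losses on the tip branches X
and Y; ACCTRAN by one early loss on their stem plus a regain in Z — both
spend the same minimum number of changes. Running the full pipeline on
simulated data (`python examples/06_full_pipeline.py`) prints, per gene,
the edited-site vs 3rd-position comparison:

```
gene2: ES vs 3rd-position C->T rates (first 4 taxa)
     es_rate  third_rate  fisher_p
t12      0.1       0.000     0.204
t03      0.1       0.000     0.204
t05      0.4       0.000     0.001
t07      0.1       0.017     0.370
```

`es_rate` is the fraction of the focal ancestor's edited sites lost on the
path to that taxon, `third_rate` the same for C-bearing 3rd codon
positions, and `fisher_p` tests whether edited sites are being lost faster
than the neutral background — here taxon t05 lost 40% of its ancestral
edited sites while the 3rd-position background stayed untouched.

The library API mirrors the chain: `call_edited_sites` /
`filter_heterogeneous` / `predict_edited_sites` → `map_characters` /
`count_branch_changes` → `reconstruct_ancestral_sequences` /
`tree_branch_ds` / `third_position_ct_events` → `nprs_date` /
`absolute_rate` → `rate_summary` / `sister_contrasts` / `pic_correlation` /
`prune_zero_edit` / `retro_scan`, with `run_pipeline(RunConfig(...))`
chaining everything and writing TSV/JSON outputs. See `docs/methods.md`
for the underlying models and conventions.

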