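"""Scan a branch's edited-site losses for retroprocessing signatures.

Retroprocessing (gene conversion with a reverse-transcribed, edited cDNA)
removes many edited sites of a gene at once, so its footprint is a branch
whose losses cluster in a contiguous window -- or cover the whole gene.
"""

import numpy as np

from editevol import retro_scan

gene_length = 600
at_risk = list(range(8, 600, 15))          # 40 edited sites, evenly spread

# branch 1: eight losses packed into ~120 nt plus four scattered ones
window = [p for p in at_risk if 203 <= p <= 323]
rng = np.random.default_rng(0)
scatter = sorted(rng.choice([p for p in at_risk if p not in window], 4,
                            replace=False))
losses_clustered = sorted(window + scatter)

# branch 2: every ancestral edited site lost at once
losses_whole = list(at_risk)

cands = retro_scan({1: losses_clustered, 2: losses_whole},
                   {1: at_risk, 2: at_risk}, gene_length,
                   n_permutations=2000, seed=42)
for c in cands:
    kind = "whole-gene conversion" if c.whole_gene else "windowed conversion"
    print(f"branch {c.branch}: {kind}, k={c.k} losses in "
          f"[{c.start}, {c.end}] nt, permutation p={c.p:.4g}")
# The permutation p asks: if the same number of losses were scattered
# uniformly over the branch's at-risk edited sites, how often would any
# k-subset sit in an equally tight window?
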