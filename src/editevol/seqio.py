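"""Readers/writers and core containers: codon alignments, rooted trees, run config.

Alignment columns are 0-based internally and 1-based in every report/TSV.
Codon index = column // 3 after the frame offset has been trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import dendropy
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlignmentError(ValueError):
    pass


class FrameError(ValueError):
    pass


class TreeError(ValueError):
    pass


class ConfigError(ValueError):
    pass


_VALID = set("ACGT-?")


@dataclass
class CodonAlignment:
    """A codon-aware nucleotide alignment for one gene.

    ``matrix`` is a (taxa x columns) array of single characters from
    {A,C,G,T,-,?}; rows are in the order of ``taxa``. ``frame`` records how
    many leading nucleotides were trimmed from the source file, so reported
    coordinates can refer to the original sequence.
    """

    gene: str
    taxa: list[str]
    matrix: np.ndarray
    frame: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.matrix.shape[0]} matrix rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if self.matrix.shape[1] % 3 != 0:
            raise FrameError(
                f"alignment length {self.matrix.shape[1]} not divisible by 3"
            )
        bad = set(self.matrix.ravel()) - _VALID
        if bad:
            raise AlignmentError(f"invalid characters: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_codons(self) -> int:
        return self.matrix.shape[1] // 3

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def codon(self, taxon: str, codon_index: int) -> str:
        i = self.taxa.index(taxon)
        return "".join(self.matrix[i, 3 * codon_index : 3 * codon_index + 3])

    def subset_taxa(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(self.gene, list(taxa), self.matrix[idx].copy(), self.frame)


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T").replace("N", "?").replace(".", "-")


def read_alignment(path, frame: int = 0, gene: str | None = None) -> CodonAlignment:
    """Read a FASTA alignment, trim ``frame`` leading columns, validate codon frame.

    Characters are uppercased, U mapped to T, N to '?'. Raises
    :class:`AlignmentError` for ragged input and :class:`FrameError` when the
    trimmed length is not a codon multiple.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    names = [r.id for r in records]
    seqs = [_clean(str(r.seq)) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths {sorted(lengths)} in {path}")
    if frame not in (0, 1, 2):
        raise FrameError(f"frame must be 0, 1 or 2, got {frame}")
    seqs = [s[frame:] for s in seqs]
    if len(seqs[0]) % 3 != 0:
        raise FrameError(
            f"length {len(seqs[0])} after frame trim not divisible by 3 in {path}"
        )
    mat = np.array([list(s) for s in seqs], dtype="<U1")
    if gene is None:
        gene = str(path).rsplit("/", 1)[-1].split(".")[0]
    return CodonAlignment(gene, names, mat, frame)


def write_alignment(aln: CodonAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """A rooted tree in postorder-indexed array form.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder (every child precedes
    its parent; the root is last). ``lengths[v]`` is the branch above node
    ``v`` (0 for the root). ``labels[v]`` is the taxon label for tips and an
    optional label for internal nodes. ``ages`` (Ma) is filled by dating.
    """

    labels: list[str | None]
    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    ages: np.ndarray | None = None

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        # deterministic child order: sort by smallest tip label in subtree
        def min_label(nd):
            if nd.is_leaf():
                return nd.taxon.label if nd.taxon else (nd.label or "")
            return min(min_label(c) for c in nd.child_nodes())

        order: list = []

        def post(nd):
            for c in sorted(nd.child_nodes(), key=min_label):
                post(c)
            order.append(nd)

        post(dtree.seed_node)
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        labels: list[str | None] = []
        parent = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        lengths = np.zeros(n)
        for i, nd in enumerate(order):
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else nd.label)
            else:
                labels.append(nd.label)
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(labels, parent, children, lengths)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        if "[&U]" in newick:
            raise TreeError("tree is explicitly unrooted")
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        t = cls.from_dendropy(dtree)
        if t.n_tips < 2:
            raise TreeError("tree must have at least 2 tips")
        return t

    # -- basic queries -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tips]

    def tip_index(self, label: str) -> int:
        for v in self.tips:
            if self.labels[v] == label:
                return v
        raise TreeError(f"no tip labelled {label!r}")

    def postorder(self):
        return range(self.n_nodes)

    def preorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def subtree_tips(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out

    def mrca(self, labels) -> int:
        want = set(labels)
        have = {self.tip_index(l) for l in want}
        for v in self.postorder():
            if have <= set(self.subtree_tips(v)):
                return v
        return self.root

    def path(self, ancestor: int, descendant: int) -> list[int]:
        """Nodes on the path from (below) ``ancestor`` down to ``descendant``,
        descendant-first; i.e. the branches summed over are those above each
        returned node."""
        out = []
        v = descendant
        while v != ancestor:
            if v == -1:
                raise TreeError(
                    f"node {descendant} is not a descendant of {ancestor}"
                )
            out.append(v)
            v = self.parent[v]
        return out

    def is_descendant(self, v: int, ancestor: int) -> bool:
        while v != -1:
            if v == ancestor:
                return True
            v = self.parent[v]
        return False

    def node_depths(self) -> np.ndarray:
        """Path length (sum of branch lengths) from the root to each node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if self.parent[v] != -1:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    # -- output --------------------------------------------------------------
    def branch_name(self, v: int) -> str:
        """Deterministic branch id: the child-node label, or node{postorder}."""
        lab = self.labels[v]
        return lab if lab else f"node{v}"

    def to_newick(self, node_labels: dict[int, str] | None = None,
                  lengths: np.ndarray | None = None) -> str:
        br = self.lengths if lengths is None else lengths

        def fmt(v):
            if self.is_tip(v):
                core = self.labels[v]
            else:
                inner = ",".join(fmt(c) for c in self.children[v])
                lab = (node_labels or {}).get(v, self.labels[v] or "")
                core = f"({inner}){lab}"
            if self.parent[v] == -1:
                return core
            return f"{core}:{br[v]:.10g}"

        return fmt(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            list(self.labels), self.parent.copy(),
            [list(c) for c in self.children], self.lengths.copy(),
            None if self.ages is None else self.ages.copy(),
        )

    def retain_tips(self, keep_labels) -> "Phylogeny":
        """Induced subtree on ``keep_labels``; unifurcations are collapsed and
        their branch lengths summed."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                  preserve_underscores=True)
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        return Phylogeny.from_newick(dtree.as_string(schema="newick").strip())


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree; polytomies are preserved."""
    with open(path) as fh:
        text = fh.read()
    if text.count(";") > 1:
        raise TreeError(f"multiple trees in {path}; expected one")
    return Phylogeny.from_newick(text)


def write_tree(tree: Phylogeny, path, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(**kw) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration; all thresholds and calibrations live
    here, none are hard-coded downstream."""

    genes: list[str]
    dna_paths: dict[str, str]
    tree_path: str
    cdna_paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "."
    optimization_mode: str = "DELTRAN"
    prep_threshold: float = 0.6
    root_age: float = 130.0
    focal_age: float = 79.1
    focal_clade: list[str] | None = None
    seed: int = 0
    pruning_variant: str = "none"
    gain_scoring: str = "dna"  # or "strict" (require cDNA confirmation)
    changes: str = "both"  # or "losses"
    n_permutations: int = 10000
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.prep_threshold <= 1:
            raise ConfigError("prep_threshold must be in (0, 1]")
        if self.root_age <= 0 or self.focal_age <= 0:
            raise ConfigError("calibration ages must be positive")
        if self.optimization_mode not in ("ACCTRAN", "DELTRAN"):
            raise ConfigError(f"unknown optimization mode {self.optimization_mode}")
        if self.pruning_variant not in ("none", "keep-longest", "keep-shortest"):
            raise ConfigError(f"unknown pruning variant {self.pruning_variant}")
        if self.gain_scoring not in ("dna", "strict"):
            raise ConfigError(f"unknown gain scoring {self.gain_scoring}")
        for g in self.genes:
            if g not in self.dna_paths:
                raise ConfigError(f"gene {g!r} has no DNA alignment path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_yaml(self) -> str:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        return yaml.safe_dump(out, sort_keys=True)
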