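"""Calling C-to-U editing sites from DNA/cDNA pairs and predicting them from
conserved protein profiles.

A site is *edited* when at least one taxon carries a genomic C whose cDNA
reads T at that alignment column. Columns where cDNA-verified taxa disagree
about the editing status of their C (edited in some, unedited C in others)
are heterogeneous and excluded from all downstream counts; a genomic T in
another taxon is a *loss*, not heterogeneity, and does not trigger exclusion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import hydropathy, translate_codon
from .seqio import CodonAlignment

EDITED_C = "EDITED_C"
UNEDITED_C = "UNEDITED_C"
GENOMIC_T = "GENOMIC_T"
OTHER = "OTHER"
MISSING = "MISSING"


class CoordinateError(ValueError):
    pass


@dataclass
class EditTable:
    """Per-column, per-taxon editing status for one gene.

    ``status`` and ``evidence`` are (taxa x columns) DataFrames indexed by
    taxon label with 0-based alignment columns; ``excluded`` marks columns
    removed by the heterogeneity rule. ``score`` holds predictor scores for
    predicted columns (NaN otherwise).
    """

    gene: str
    status: pd.DataFrame
    evidence: pd.DataFrame
    excluded: pd.Series
    score: pd.DataFrame | None = None

    @property
    def columns(self) -> list[int]:
        return list(self.status.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.status.index)

    def edited_columns(self, include_excluded: bool = False) -> list[int]:
        """Columns where >=1 taxon has EDITED_C (excluded ones dropped by
        default)."""
        any_edited = (self.status.to_numpy(dtype=object) == EDITED_C).any(axis=0)
        cols = [c for c, e in zip(self.status.columns, any_edited) if e]
        if not include_excluded:
            cols = [c for c in cols if not self.excluded[c]]
        return cols

    def to_tsv(self, path, frame: int = 0) -> None:
        rows = []
        for c in self.status.columns:
            for t in self.status.index:
                st = self.status.at[t, c]
                if st in (OTHER, MISSING):
                    continue
                sc = np.nan if self.score is None else self.score.at[t, c]
                rows.append({
                    "gene": self.gene,
                    "position": c + frame + 1,
                    "codon_position": c % 3 + 1,
                    "taxon": t,
                    "status": st,
                    "evidence": self.evidence.at[t, c],
                    "excluded": bool(self.excluded[c]),
                    "score": sc,
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                                  float_format="%.6g")


def _status_of(dna: str, cdna: str | None) -> tuple[str, str]:
    if dna in ("-", "?"):
        return MISSING, "none"
    if dna == "C":
        if cdna is None:
            return UNEDITED_C, "none"
        if cdna == "T":
            return EDITED_C, "cDNA"
        if cdna == "C":
            return UNEDITED_C, "cDNA"
        return OTHER, "cDNA"
    if dna == "T":
        return GENOMIC_T, "cDNA" if cdna is not None else "none"
    return OTHER, "cDNA" if cdna is not None else "none"


def call_edited_sites(dna: CodonAlignment, cdna: CodonAlignment,
                      taxon_map: dict[str, str] | None = None) -> EditTable:
    """Determine per-site editing status by comparing DNA to cDNA.

    ``taxon_map`` maps cDNA record names to DNA taxon labels (identity by
    default). Taxa without cDNA get UNEDITED_C/GENOMIC_T statuses with
    evidence "none": a genomic C with no transcript data is *not* inferred to
    be edited; downstream operations decide how to treat such cells.
    """
    if dna.n_columns != cdna.n_columns:
        raise CoordinateError(
            f"DNA has {dna.n_columns} columns but cDNA has {cdna.n_columns}"
        )
    taxon_map = taxon_map or {t: t for t in cdna.taxa}
    unknown = set(taxon_map.values()) - set(dna.taxa)
    if unknown:
        raise CoordinateError(f"cDNA taxa absent from DNA alignment: {sorted(unknown)}")
    cdna_of = {}
    for ct, dt in taxon_map.items():
        cdna_of[dt] = cdna.row(ct)

    D = dna.matrix
    C = np.full(D.shape, "?", dtype="<U1")
    for ti, t in enumerate(dna.taxa):
        if t in cdna_of:
            C[ti] = cdna_of[t]
    cd_known = (C != "?") & (C != "-")

    st = np.full(D.shape, OTHER, dtype=object)
    st[(D == "-") | (D == "?")] = MISSING
    st[D == "T"] = GENOMIC_T
    is_c = D == "C"
    st[is_c] = UNEDITED_C
    st[is_c & cd_known & (C == "T")] = EDITED_C
    st[is_c & cd_known & (C != "T") & (C != "C")] = OTHER
    ev = np.where(cd_known & (st != MISSING), "cDNA", "none").astype(object)
    ev[is_c & ~cd_known] = "none"

    status = pd.DataFrame(st, index=dna.taxa, columns=range(dna.n_columns))
    evidence = pd.DataFrame(ev, index=dna.taxa, columns=range(dna.n_columns))
    excluded = pd.Series(False, index=status.columns)
    return EditTable(dna.gene, status, evidence, excluded)


def filter_heterogeneous(table: EditTable) -> EditTable:
    """Flag columns with cDNA-verified editing heterogeneity as excluded.

    A column is heterogeneous when, among taxa with cDNA evidence, some have
    EDITED_C and others UNEDITED_C. Idempotent.
    """
    excluded = table.excluded.copy()
    st = table.status.to_numpy(dtype=object)
    has_cdna = table.evidence.to_numpy(dtype=object) == "cDNA"
    edited = ((st == EDITED_C) & has_cdna).any(axis=0)
    unedited = ((st == UNEDITED_C) & has_cdna).any(axis=0)
    het = edited & unedited
    for c, h in zip(table.status.columns, het):
        if h:
            excluded[c] = True
    return EditTable(table.gene, table.status, table.evidence, excluded,
                     table.score)


def predict_edited_sites(dna: CodonAlignment, reference_profile: list[str],
                         threshold: float = 0.6) -> EditTable:
    """Profile-based editing prediction for every genomic C.

    For each taxon and each C, the candidate edit converts that C to T within
    its codon; the score is the fraction of reference protein sequences whose
    residue at that codon is matched by the edited amino acid but not by the
    unedited one (exact identity; ties and double misses contribute 0). A C
    scoring >= ``threshold`` is predicted edited. This is a deliberately
    simple majority-profile scorer in the spirit of comparative predictors.
    """
    if not reference_profile:
        raise CoordinateError("empty reference profile")
    for r in reference_profile:
        if len(r) != dna.n_codons:
            raise CoordinateError(
                f"reference length {len(r)} != {dna.n_codons} codons"
            )
    status = pd.DataFrame(index=dna.taxa, columns=range(dna.n_columns), dtype=object)
    evidence = pd.DataFrame("none", index=dna.taxa, columns=range(dna.n_columns))
    score = pd.DataFrame(np.nan, index=dna.taxa, columns=range(dna.n_columns))
    for ti, t in enumerate(dna.taxa):
        for c in range(dna.n_columns):
            st, _ = _status_of(dna.matrix[ti, c], None)
            status.iat[ti, c] = st
            if st != UNEDITED_C:
                continue
            ci = c // 3
            codon = "".join(dna.matrix[ti, 3 * ci : 3 * ci + 3])
            if any(ch not in "ACGT" for ch in codon):
                continue
            edited = codon[: c % 3] + "T" + codon[c % 3 + 1 :]
            aa_un = translate_codon(codon)
            aa_ed = translate_codon(edited)
            hits = sum(
                1 for r in reference_profile
                if r[ci] == aa_ed and r[ci] != aa_un
            )
            s = hits / len(reference_profile)
            score.iat[ti, c] = s
            if s >= threshold:
                status.iat[ti, c] = EDITED_C
                evidence.iat[ti, c] = "predicted"
    excluded = pd.Series(False, index=status.columns)
    return EditTable(dna.gene, status, evidence, excluded, score)


@dataclass
class EditEffect:
    column: int
    codon_position: int
    aa_unedited: str
    aa_edited: str
    hydropathy_delta: float | None


@dataclass
class EditSummary:
    effects: list[EditEffect]
    position_counts: dict[int, int]
    position_percent: dict[int, int]
    spectrum: dict[tuple[str, str], float]
    spectrum_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    mean_hydropathy_delta: float = float("nan")


def editing_effect_summary(table: EditTable, dna: CodonAlignment) -> EditSummary:
    """Protein-level consequences of the (filtered) edited columns.

    For each included edited column, the unedited codon is taken from the
    first (label-sorted) taxon with EDITED_C status and the edit applied in
    isolation. Percentages are rounded to the nearest integer and therefore
    sum to 100 +/- rounding.
    """
    effects: list[EditEffect] = []
    for c in table.edited_columns():
        carriers = sorted(t for t in table.taxa
                          if table.status.at[t, c] == EDITED_C)
        t = carriers[0]
        ci, off = c // 3, c % 3
        codon = dna.codon(t, ci)
        edited = codon[:off] + "T" + codon[off + 1 :]
        aa_un = translate_codon(codon)
        aa_ed = translate_codon(edited)
        h0, h1 = hydropathy(aa_un), hydropathy(aa_ed)
        delta = None if h0 is None or h1 is None else h1 - h0
        effects.append(EditEffect(c, off + 1, aa_un, aa_ed, delta))

    pos_counts = {p: sum(1 for e in effects if e.codon_position == p)
                  for p in (1, 2, 3)}
    n = len(effects)
    pos_pct = {p: (round(100 * k / n) if n else 0) for p, k in pos_counts.items()}
    spec_counts = Counter((e.aa_unedited, e.aa_edited) for e in effects
                          if e.aa_unedited != e.aa_edited)
    total = sum(spec_counts.values())
    spectrum = {k: v / total for k, v in spec_counts.items()} if total else {}
    deltas = [e.hydropathy_delta for e in effects if e.hydropathy_delta is not None]
    mean_delta = float(np.mean(deltas)) if deltas else float("nan")
    return EditSummary(effects, pos_counts, pos_pct, spectrum,
                       dict(spec_counts), mean_delta)
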