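"""Parsimony mapping: Fitch lengths vs brute force, ACCTRAN/DELTRAN
membership in the enumerated MPR set, branch-event bookkeeping and tree
statistics."""

import numpy as np
import pytest

from editevol import (BinaryCharacterMatrix, count_branch_changes,
                      cumulative_changes, fitch_reconstruct, map_characters,
                      parsimony_stats, resolve_optimization)
from editevol.charmap import CharacterError, fitch_matrix
from conftest import brute_force_fitch, random_topology


class TestFitchLength:
    def test_one_change(self, quartet_tree):
        fr = fitch_reconstruct(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert fr.length == 1

    def test_constant_character(self, quartet_tree):
        fr = fitch_reconstruct(quartet_tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert fr.length == 0

    def test_all_missing_rejected(self, quartet_tree):
        with pytest.raises(CharacterError):
            fitch_reconstruct(quartet_tree,
                              {"A": None, "B": None, "C": None, "D": None})

    def test_length_vs_brute_force_200_instances(self):
        """Exact agreement with exhaustive enumeration on random <=7-tip
        trees, including missing tips."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            tree = random_topology(rng, n)
            states = {}
            for l in tree.tip_labels:
                r = rng.random()
                states[l] = None if r < 0.15 else int(rng.integers(2))
            if all(v is None for v in states.values()):
                states[tree.tip_labels[0]] = 1
            oracle_len, _ = brute_force_fitch(tree, states)
            fr = fitch_reconstruct(tree, states)
            assert fr.length == oracle_len

    def test_binary_length_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            tree = random_topology(rng, n)
            states = {l: int(rng.integers(2)) for l in tree.tip_labels}
            assert fitch_reconstruct(tree, states).length <= n - 1


class TestOptimizationModes:
    def test_resolutions_are_mprs(self):
        """Both modes must return assignments belonging to the enumerated
        MPR set, spending exactly the Fitch length in changes."""
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(3, 8))
            tree = random_topology(rng, n)
            states = {l: int(rng.integers(2)) for l in tree.tip_labels}
            oracle_len, optimal = brute_force_fitch(tree, states)
            fr = fitch_reconstruct(tree, states)
            for mode in ("ACCTRAN", "DELTRAN"):
                h = resolve_optimization(tree, fr, mode)
                assert tuple(h.node_states) in optimal
                assert len(h.events) == oracle_len

    def test_mpr_sets_match_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            tree = random_topology(rng, n)
            states = {l: int(rng.integers(2)) for l in tree.tip_labels}
            _, optimal = brute_force_fitch(tree, states)
            fr = fitch_reconstruct(tree, states)
            for v in range(tree.n_nodes):
                seen = {a[v] for a in optimal}
                assert fr.mpr_sets[v] == frozenset(seen)

    def test_deltran_parallel_loss_vs_acctran_reversal(self, five_tip_tree):
        """The signature disagreement: DELTRAN places two independent losses
        inside the clade; ACCTRAN a basal loss plus a regain."""
        tree = five_tip_tree
        states = {"X": 0, "Y": 0, "Z": 1, "W1": 1, "W2": 1}
        fr = fitch_reconstruct(tree, states)
        assert fr.length == 2
        delt = resolve_optimization(tree, fr, "DELTRAN")
        acct = resolve_optimization(tree, fr, "ACCTRAN")
        d_kinds = sorted(k for _, k in delt.events)
        a_kinds = sorted(k for _, k in acct.events)
        assert d_kinds == ["loss", "loss"]
        assert a_kinds == ["gain", "loss"]
        d_labels = sorted(tree.labels[v] or "internal" for v, _ in delt.events)
        assert d_labels == ["X", "Y"]
        assert len(delt.events) == len(acct.events) == fr.length

    def test_unambiguous_character_same_under_both_modes(self, quartet_tree):
        states = {"A": 1, "B": 1, "C": 0, "D": 0}
        fr = fitch_reconstruct(quartet_tree, states)
        d = resolve_optimization(quartet_tree, fr, "DELTRAN")
        a = resolve_optimization(quartet_tree, fr, "ACCTRAN")
        assert d.events == a.events

    def test_unknown_mode_rejected(self, quartet_tree):
        fr = fitch_reconstruct(quartet_tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        with pytest.raises(CharacterError):
            resolve_optimization(quartet_tree, fr, "MIDTRAN")

    def test_vectorized_engine_matches_scalar(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            tree = random_topology(rng, n)
            k = int(rng.integers(2, 5))
            tips = tree.tips
            st = rng.integers(-1, k, size=(len(tips), 4)).astype(np.int32)
            st[0] = np.abs(st[0])  # keep at least one informative row
            for mode in ("DELTRAN", "ACCTRAN"):
                L, S, M = fitch_matrix(tree, st, tips, mode, n_states=k,
                                       want_mpr=True)
                for j in range(st.shape[1]):
                    d = {tree.labels[v]: (None if st[i, j] < 0 else int(st[i, j]))
                         for i, v in enumerate(tips)}
                    fr = fitch_reconstruct(tree, d, n_states=k)
                    h = resolve_optimization(tree, fr, mode)
                    assert fr.length == L[j]
                    assert (h.node_states == S[:, j]).all()
                    for v in range(tree.n_nodes):
                        assert fr.mpr_sets[v] == frozenset(
                            int(s) for s in np.flatnonzero(M[v, j]))


class TestBranchEvents:
    def test_single_loss_bookkeeping(self, quartet_tree):
        import pandas as pd
        states = pd.DataFrame({0: [1, 1, 0, 0]}, index=list("ABCD"))
        m = BinaryCharacterMatrix("g", [0], states)
        hists = map_characters(quartet_tree, m, "DELTRAN")
        ev = count_branch_changes(quartet_tree, hists, "g")
        assert ev.gains.sum() == 0
        assert ev.losses.sum() == 1

    def test_empty_matrix_all_zero(self, quartet_tree):
        import pandas as pd
        m = BinaryCharacterMatrix("g", [], pd.DataFrame(index=list("ABCD")))
        hists = map_characters(quartet_tree, m)
        ev = count_branch_changes(quartet_tree, hists, "g")
        assert ev.gains.sum() == ev.losses.sum() == 0

    def test_event_conservation(self):
        """Sum of branch events equals the sum of Fitch lengths."""
        import pandas as pd
        rng = np.random.default_rng(23)
        for _ in range(30):
            tree = random_topology(rng, int(rng.integers(4, 9)))
            n_chars = 6
            data = {j: rng.integers(0, 2, size=tree.n_tips).astype(float)
                    for j in range(n_chars)}
            m = BinaryCharacterMatrix("g", list(range(n_chars)),
                                      pd.DataFrame(data, index=tree.tip_labels))
            total_len = sum(
                fitch_reconstruct(tree, m.states[j].to_dict()).length
                for j in range(n_chars))
            for mode in ("DELTRAN", "ACCTRAN"):
                hists = map_characters(tree, m, mode)
                ev = count_branch_changes(tree, hists, "g")
                assert ev.gains.sum() + ev.losses.sum() == total_len

    def test_simulated_events_recovered_when_mpr_unique(self, sim_small):
        """Where the planted history is the unique MPR, mapped per-branch
        loss totals equal the simulator's event log."""
        from editevol import call_edited_sites, filter_heterogeneous
        tree = sim_small["tree"]
        truth = sim_small["truth"]
        table = filter_heterogeneous(
            call_edited_sites(sim_small["dna"], sim_small["cdna"]))
        m = BinaryCharacterMatrix.from_edit_table(table)
        hists = map_characters(tree, m, "DELTRAN")
        es = truth.edited_sites["sim"]
        status = truth.edited_status["sim"]
        checked = 0
        for h in hists:
            if h.character not in es:
                continue
            j = es.index(h.character)
            true_states = status[:, j].astype(int)
            fr = fitch_reconstruct(
                tree, {tree.labels[v]: int(true_states[v]) for v in tree.tips})
            _, optimal = brute_force_fitch(
                tree, {tree.labels[v]: int(true_states[v]) for v in tree.tips}) \
                if tree.n_tips <= 7 else (None, None)
            # uniqueness via MPR sets: every node unambiguous
            if any(len(s) > 1 for s in fr.mpr_sets):
                continue
            true_events = {
                v for v in range(tree.n_nodes - 1)
                if true_states[v] != true_states[tree.parent[v]]}
            mapped = {v for v, _ in h.events}
            if fr.length == len(true_events):
                assert mapped == true_events
                checked += 1
        assert checked >= 1


class TestCumulativeChanges:
    def test_path_sum(self):
        tree = random_topology(np.random.default_rng(1), 6)
        import pandas as pd
        rng = np.random.default_rng(3)
        data = {j: rng.integers(0, 2, size=6).astype(float) for j in range(8)}
        m = BinaryCharacterMatrix("g", list(range(8)),
                                  pd.DataFrame(data, index=tree.tip_labels))
        ev = count_branch_changes(tree, map_characters(tree, m), "g")
        for tip in tree.tips:
            total = cumulative_changes(tree, ev, tree.root, tip)
            manual = sum(int(ev.gains[v] + ev.losses[v])
                         for v in tree.path(tree.root, tip))
            assert total == manual

    def test_additive_over_path_concatenation(self):
        rng = np.random.default_rng(31)
        import pandas as pd
        for _ in range(20):
            tree = random_topology(rng, 7)
            data = {j: rng.integers(0, 2, size=7).astype(float)
                    for j in range(5)}
            m = BinaryCharacterMatrix("g", list(range(5)),
                                      pd.DataFrame(data, index=tree.tip_labels))
            ev = count_branch_changes(tree, map_characters(tree, m), "g")
            tip = tree.tips[0]
            path = tree.path(tree.root, tip)
            if len(path) < 2:
                continue
            mid = path[len(path) // 2]
            assert (cumulative_changes(tree, ev, tree.root, tip)
                    == cumulative_changes(tree, ev, tree.root, mid)
                    + cumulative_changes(tree, ev, mid, tip))

    def test_losses_only_flag(self, quartet_tree):
        import pandas as pd
        states = pd.DataFrame({0: [0.0, 1, 1, 1]}, index=list("ABCD"))
        m = BinaryCharacterMatrix("g", [0], states)
        ev = count_branch_changes(quartet_tree, map_characters(quartet_tree, m), "g")
        a = quartet_tree.tip_index("A")
        both = cumulative_changes(quartet_tree, ev, quartet_tree.root, a)
        losses = cumulative_changes(quartet_tree, ev, quartet_tree.root, a,
                                    losses_only=True)
        assert both >= losses


class TestParsimonyStats:
    def test_perfect_character(self, quartet_tree):
        chars = [{"A": 1, "B": 1, "C": 0, "D": 0}]
        L, ci, ri = parsimony_stats(quartet_tree, chars)
        assert (L, ci, ri) == (1, 1.0, 1.0)

    def test_invariant_column_contributes_zero(self, quartet_tree):
        chars = [{"A": 1, "B": 1, "C": 0, "D": 0},
                 {"A": "G", "B": "G", "C": "G", "D": "G"}]
        L, _, _ = parsimony_stats(quartet_tree, chars)
        assert L == 1

    def test_no_informative_characters_rejected(self, quartet_tree):
        with pytest.raises(CharacterError):
            parsimony_stats(quartet_tree, [{"A": 1, "B": 0, "C": 0, "D": 0}])

    def test_against_oracle_random_matrices(self):
        """L, CI, RI recomputed by hand from brute-force lengths."""
        rng = np.random.default_rng(37)
        for _ in range(60):
            n = int(rng.integers(4, 7))
            tree = random_topology(rng, n)
            chars = []
            for _ in range(6):
                k = int(rng.integers(2, 4))
                chars.append({l: int(rng.integers(k)) for l in tree.tip_labels})
            # oracle
            L_o = 0
            ci_min = ci_len = 0
            g_sum = m_sum = 0
            informative_seen = False
            for ch in chars:
                counts = {}
                for s in ch.values():
                    counts[s] = counts.get(s, 0) + 1
                k = len(counts)
                length, _ = brute_force_fitch(
                    tree, {t: list(sorted(counts)).index(s)
                           for t, s in ch.items()}, n_states=k)
                m = k - 1
                g = sum(counts.values()) - max(counts.values())
                informative = sum(1 for v in counts.values() if v >= 2) >= 2
                L_o += length
                m_sum += m
                g_sum += g
                if informative:
                    informative_seen = True
                    ci_min += m
                    ci_len += length
            if not informative_seen:
                continue
            L, ci, ri = parsimony_stats(tree, chars)
            assert L == L_o
            assert ci == pytest.approx(ci_min / ci_len if ci_len else 1.0)
            denom = g_sum - m_sum
            assert ri == pytest.approx((g_sum - L_o) / denom if denom else 1.0)


class TestCharacterScoring:
    """DNA-level vs strict scoring of unverified genomic C's at edited
    columns."""

    def _table(self):
        import numpy as np
        from editevol import CodonAlignment, call_edited_sites, \
            filter_heterogeneous
        dna = CodonAlignment("g", ["A", "B", "C"], np.array([
            list("TCA"), list("TCA"), list("TTA")]))
        cdna = CodonAlignment("g", ["A"], np.array([list("TTA")]))
        return filter_heterogeneous(call_edited_sites(dna, cdna))

    def test_dna_scoring_counts_unverified_c_as_edited(self):
        m = BinaryCharacterMatrix.from_edit_table(self._table(), "dna")
        assert m.states.at["A", 1] == 1.0   # cDNA-confirmed edit
        assert m.states.at["B", 1] == 1.0   # unverified C -> editable C
        assert m.states.at["C", 1] == 0.0   # genomic T = loss

    def test_strict_scoring_marks_unverified_c_missing(self):
        import numpy as np
        m = BinaryCharacterMatrix.from_edit_table(self._table(), "strict")
        assert m.states.at["A", 1] == 1.0
        assert np.isnan(m.states.at["B", 1])
        assert m.states.at["C", 1] == 0.0
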