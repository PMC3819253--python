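import itertools
import math

import dendropy
import numpy as np
import pytest

from kirfam.records import Alignment, Transcript
from kirfam.selection import (
    codon_site_counts,
    codon_z_test,
    dn_ds,
    pathway_counts,
    site_selection_counting,
    sliding_omega,
)
from kirfam.simulate import simulate_coding_tree


def _codon_alignment(codon_rows: dict[str, list[str]]) -> Alignment:
    return Alignment(
        [Transcript(id=k, sequence="".join(v)) for k, v in codon_rows.items()]
    )


class TestSiteCounts:
    def test_classic_counts_at_no_bias(self):
        # TTT (Phe): only position 3 T->C is synonymous; equal weighting
        s, n = codon_site_counts("TTT", 0.5)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_fourfold_degenerate_third_position(self):
        s, n = codon_site_counts("GGG", 0.5)  # Gly: 4-fold at position 3
        assert s == pytest.approx(1.0)

    def test_transition_bias_raises_synonymous_sites(self):
        # at higher R the (usually synonymous) transition gets more weight
        s_lo, _ = codon_site_counts("TTT", 0.5)
        s_hi, _ = codon_site_counts("TTT", 5.0)
        assert s_hi > s_lo

    def test_stop_mutations_excluded(self):
        # TGG (Trp): every non-stop single change is nonsynonymous, and
        # positions are renormalized over non-stop targets
        s, n = codon_site_counts("TGG", 0.5)
        assert s == 0.0 and n == pytest.approx(3.0)


class TestPathways:
    def test_single_difference(self):
        assert pathway_counts("AAA", "AAG") == (1.0, 0.0)   # Lys->Lys
        assert pathway_counts("AAA", "AAC") == (0.0, 1.0)   # Lys->Asn

    def test_double_difference_averages_orders(self):
        # TTT(F) -> TTA(L) -> CTA(L) vs TTT -> CTT(L) -> CTA(L)
        s, n = pathway_counts("TTT", "CTA")
        assert s + n == pytest.approx(2.0)
        # both pathways have exactly one nonsynonymous step (F->L), then L->L
        assert n == pytest.approx(1.0) and s == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        # brute-force all 3!-order pathways for a triple difference
        ca, cb = "TTT", "GCA"
        from kirfam.selection import _CODON_TABLE

        diffs = [p for p in range(3) if ca[p] != cb[p]]
        paths = []
        for order in itertools.permutations(diffs):
            cur, s, n, stop = ca, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if _CODON_TABLE[nxt] == "*" and nxt != cb:
                    stop = True
                if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if not stop:
                paths.append((s, n))
        exp_s = sum(p[0] for p in paths) / len(paths)
        exp_n = sum(p[1] for p in paths) / len(paths)
        assert pathway_counts(ca, cb) == (
            pytest.approx(exp_s), pytest.approx(exp_n)
        )


class TestDnDs:
    def test_synonymous_only_differences(self):
        # one synonymous difference per repeat keeps pS comfortably below
        # the Jukes-Cantor saturation bound
        aln = _codon_alignment({
            "a": ["AAA", "GGA", "CTA"] * 30,
            "b": ["AAG", "GGA", "CTA"] * 30,
        })
        res = dn_ds(aln, R=0.5, bootstrap_reps=50, seed=0)
        assert res.dN == pytest.approx(0.0, abs=1e-12)
        assert res.dS > 0

    def test_single_nonsynonymous_change_oracle(self):
        codons = ["GCA"] * 100
        other = codons.copy()
        other[0] = "CCA"   # Ala -> Pro, nonsynonymous transversion
        aln = _codon_alignment({"a": codons, "b": other})
        res = dn_ds(aln, R=0.5, bootstrap_reps=10, seed=0)
        # oracle: Nd=1, Sd=0; sites from per-codon counts
        s_site, n_site = codon_site_counts("GCA", 0.5)
        s2, n2 = codon_site_counts("CCA", 0.5)
        S = 99 * s_site + (s_site + s2) / 2
        N = 99 * n_site + (n_site + n2) / 2
        pN = 1.0 / N
        expected_dn = -0.75 * math.log(1 - 4 * pN / 3)
        assert res.dS == pytest.approx(0.0, abs=1e-10)
        assert res.dN == pytest.approx(expected_dn, abs=1e-10)

    def test_symmetric_in_sequence_order(self):
        aln, _ = simulate_coding_tree(4, 60, 0.1, 0.5, seed=1)
        rev = Alignment(list(reversed(aln.members)))
        r1 = dn_ds(aln, R=1.0, bootstrap_reps=0, seed=0)
        r2 = dn_ds(rev, R=1.0, bootstrap_reps=0, seed=0)
        assert r1.dN == pytest.approx(r2.dN)
        assert r1.dS == pytest.approx(r2.dS)


class TestZTest:
    def test_equal_rates_give_z_zero(self):
        Z, p = codon_z_test(0.1, 0.1, 0.02, 0.02, "purifying")
        assert Z == 0.0 and p == pytest.approx(0.5)

    def test_purifying_direction(self):
        Z, p = codon_z_test(0.02, 0.12, 0.01, 0.02, "purifying")
        assert Z > 0 and p < 0.01

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            codon_z_test(0.1, 0.1, 0.0, 0.01)

    def test_purifying_simulation_power(self):
        """Purifying selection (true omega 0.2) is detected in most runs."""
        hits = 0
        n = 12
        for seed in range(n):
            aln, _ = simulate_coding_tree(8, 300, 0.05, 0.2, seed=seed)
            res = dn_ds(aln, bootstrap_reps=100, seed=seed)
            _, p = codon_z_test(res.dN, res.dS, res.dN_se, res.dS_se,
                                "purifying")
            hits += p < 0.05
        assert hits / n >= 0.8


class TestSlidingOmega:
    def test_full_length_window_equals_global_ratio(self):
        aln, _ = simulate_coding_tree(4, 80, 0.1, 0.5, seed=2)
        res = dn_ds(aln, R=1.0, bootstrap_reps=0, seed=0)
        prof = sliding_omega(aln, window=80, step=10, R=1.0)
        assert len(prof) == 1
        assert prof.omega.iloc[0] == pytest.approx(res.dN / res.dS)

    def test_undefined_windows_are_missing_not_zero(self):
        aln = _codon_alignment({
            "a": ["GCA"] * 20, "b": ["GCA"] * 10 + ["CCA"] * 10,
        })
        prof = sliding_omega(aln, window=5, step=5, R=0.5)
        # dS = 0 everywhere: all windows must be NaN, never 0
        assert prof.omega.isna().all()

    def test_window_exceeding_length_rejected(self):
        aln = _codon_alignment({"a": ["GCA"] * 5, "b": ["GCA"] * 5})
        with pytest.raises(ValueError):
            sliding_omega(aln, window=10, step=1)


class TestSiteSelection:
    def test_invariant_columns_not_called(self):
        aln = _codon_alignment({
            "a": ["GCA"] * 10, "b": ["GCA"] * 10, "c": ["GCA"] * 10,
        })
        tree = dendropy.Tree.get(data="(a:0.1,b:0.1,c:0.1);", schema="newick")
        calls = site_selection_counting(aln, tree)
        assert all(c.call == "neutral" for c in calls)

    def test_synonymous_only_column_is_negative_direction(self):
        # 4 taxa, one codon column cycling synonymous codons of Leu/Ser/Gly
        rows = {
            "a": ["GGA"], "b": ["GGC"], "c": ["GGG"], "d": ["GGT"],
        }
        for k in rows:
            rows[k] = rows[k] + ["ATG"] * 5   # anchor invariant context
        aln = _codon_alignment(rows)
        tree = dendropy.Tree.get(
            data="((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);", schema="newick"
        )
        calls = site_selection_counting(aln, tree, p_max=0.2)
        first = calls[0]
        assert first.s_changes >= 3 and first.n_changes == 0
        assert first.call == "negative"

    def test_power_and_false_positive_rate(self):
        """Positive sites at omega=5 are recovered with controlled FPR."""
        tp = fp = 0
        seeds = 10
        for seed in range(seeds):
            omega = np.full(300, 0.1)
            omega[100:110] = 5.0
            aln, tree = simulate_coding_tree(48, 300, 0.08, omega, seed=seed)
            calls = site_selection_counting(aln, tree, p_max=0.1)
            pos = {c.position for c in calls if c.call == "positive"}
            true_pos = set(range(101, 111))
            tp += len(pos & true_pos)
            fp += len(pos - true_pos)
        assert tp / (seeds * 10) >= 0.5
        assert fp / (seeds * 290) <= 0.15
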