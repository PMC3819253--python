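import itertools

import numpy as np
import pytest

from kirfam.genemodel import SpliceEvent, apply_splice_event
from kirfam.phylo import k2p_distance
from kirfam.diversity import nucleotide_diversity
from kirfam.records import Alignment
from kirfam.simulate import (
    D2_SLOT,
    SimulationParams,
    build_template,
    evolve_coding,
    mutate_k2p,
    simulate_family,
)


class TestMutateK2P:
    def test_zero_branch_returns_identical_sequence(self):
        s = "ACGT" * 100
        assert mutate_k2p(s, 0.0, kappa=3, seed=1) == s

    def test_distance_reestimation_is_consistent(self):
        rng = np.random.default_rng(10)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
        m = mutate_k2p(s, 0.1, kappa=5, seed=2)
        r = k2p_distance(s, m)
        assert abs(r.d - 0.1) < 3 * np.sqrt(r.variance)

    def test_large_kappa_suppresses_transversions(self):
        rng = np.random.default_rng(3)
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        m = mutate_k2p(s, 0.1, kappa=1e9, seed=4)
        r = k2p_distance(s, m)
        assert r.Q == 0.0 and r.P > 0.0

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            mutate_k2p("ACGT", -0.1)


class TestEvolveCoding:
    def test_protected_positions_never_change(self):
        rng = np.random.default_rng(0)
        tpl = build_template(rng)
        seq = tpl.cdna
        protected = frozenset(range(0, 30))
        rng2 = np.random.default_rng(1)
        out = evolve_coding(seq, 0.3, 4.0, 1.0, rng2, protected=protected)
        assert out[:30] == seq[:30]
        assert out != seq

    def test_no_stop_codons_created(self):
        from kirfam.selection import STOP_CODONS

        rng = np.random.default_rng(0)
        tpl = build_template(rng)
        seq = tpl.cdna
        rng2 = np.random.default_rng(1)
        out = evolve_coding(seq, 0.5, 4.0, 1.0, rng2)
        internal = {
            out[i: i + 3] for i in range(0, len(out) - 3, 3)
        } & STOP_CODONS
        existing = {
            seq[i: i + 3] for i in range(0, len(seq) - 3, 3)
        } & STOP_CODONS
        assert internal <= existing

    def test_omega_zero_allows_only_synonymous_change(self):
        from kirfam.annotation import translate

        rng = np.random.default_rng(0)
        tpl = build_template(rng)
        seq = tpl.cdna
        rng2 = np.random.default_rng(1)
        out = evolve_coding(seq, 0.4, 4.0, 1e-12, rng2)
        assert translate(out) == translate(seq)
        assert out != seq


class TestSimulateFamily:
    def test_deterministic_given_seed(self):
        f1 = simulate_family(SimulationParams(seed=9, n_loci=4))
        f2 = simulate_family(SimulationParams(seed=9, n_loci=4))
        assert [t.sequence for t in f1.transcripts] == \
               [t.sequence for t in f2.transcripts]
        assert [t.id for t in f1.transcripts] == [t.id for t in f2.transcripts]

    def test_single_locus_single_allele(self):
        params = SimulationParams(
            n_loci=1, alleles_per_locus={1: 1.0}, p_variant=0.0, seed=0
        )
        fam = simulate_family(params)
        assert len(fam.transcripts) == 1
        assert fam.truth.sequences[0].locus == 1

    def test_every_sequence_has_exactly_one_truth_row(self, family):
        ids = [t.id for t in family.transcripts]
        truth_ids = [s.id for s in family.truth.sequences]
        assert sorted(ids) == sorted(truth_ids)
        assert len(set(truth_ids)) == len(truth_ids)

    def test_divergence_target_within_band(self):
        """Monte-Carlo calibration: realized inter-locus K2P distance stays
        within 20% of the 0.08 target."""
        means = []
        for seed in range(10):
            fam = simulate_family(SimulationParams(seed=seed, n_loci=6))
            truth = fam.truth.by_id()
            reps = {}
            for t in fam.transcripts:
                s = truth[t.id]
                if not s.events and s.locus not in reps:
                    reps[s.locus] = t
            ds = [
                k2p_distance(reps[a].sequence, reps[b].sequence).d
                for a, b in itertools.combinations(sorted(reps), 2)
                if len(reps[a]) == len(reps[b])
            ]
            means.append(np.mean(ds))
        assert 0.064 <= np.mean(means) <= 0.096

    def test_intra_locus_theta_recovered(self):
        """pi over 12 alleles of one locus recovers theta within 50%."""
        params = SimulationParams(
            n_loci=1, alleles_per_locus={12: 1.0}, intra_locus_theta=0.004,
            p_variant=0.0, seed=3,
        )
        fam = simulate_family(params)
        aln = Alignment(fam.transcripts)
        pi, _ = nucleotide_diversity(aln)
        assert 0.5 * 0.004 <= pi <= 1.5 * 0.004

    def test_unreachable_divergence_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(inter_locus_divergence=0.6)

    def test_recombination_implanted_in_truth(self):
        params = SimulationParams(
            n_loci=4, seed=2, recombination_events=((1, 2, 400, 700),),
            p_4d=0.0,
        )
        fam = simulate_family(params)
        assert fam.truth.recombination == [
            {"donor_locus": 1, "acceptor_locus": 2, "start": 400, "end": 700}
        ]
        # acceptor ancestor actually carries donor material: alleles of
        # locus 2 are closer to locus 1 inside the fragment than outside
        truth = fam.truth.by_id()
        by_locus = {}
        for t in fam.transcripts:
            s = truth[t.id]
            if not s.events:
                by_locus.setdefault(s.locus, t)
        # map template coordinates to emitted (D0b-free) coordinates
        a, b = by_locus[1].sequence, by_locus[2].sequence
        d0b = 288
        lo, hi = 400 - d0b, 700 - d0b
        inside = sum(x != y for x, y in zip(a[lo:hi], b[lo:hi])) / (hi - lo)
        out_seg = a[:lo], b[:lo]
        outside = sum(x != y for x, y in zip(*out_seg)) / max(len(out_seg[0]), 1)
        assert inside < outside


class TestSpliceEventApplication:
    def test_exon_skip_removes_exact_segment(self, family, family_models):
        model = family_models["locus01"]
        truth = family.truth.by_id()
        allele = next(
            t for t in family.transcripts if not truth[t.id].events
            and truth[t.id].locus == 1
        )
        d2_exon = next(e.index for e in model.exons
                       if e.template_slot == D2_SLOT)
        var, realized = apply_splice_event(
            allele, model, SpliceEvent("exon_skip", d2_exon)
        )
        assert len(var) == len(allele) - 294
        assert realized[0].nt_delta == -294 and realized[0].in_frame

    def test_alt_acceptor_in_frame_deletion(self, family, family_models):
        model = family_models["locus01"]
        truth = family.truth.by_id()
        allele = next(
            t for t in family.transcripts if not truth[t.id].events
            and truth[t.id].locus == 1
        )
        d1_exon = next(e.index for e in model.exons if e.domain == "D1")
        var, realized = apply_splice_event(
            allele, model, SpliceEvent("alt_acceptor", d1_exon, offset=36)
        )
        assert len(var) == len(allele) - 36
        assert realized[0].in_frame and realized[0].ptc is None

    def test_event_outside_model_bounds_rejected(self, family, family_models):
        model = family_models["locus01"]
        allele = next(iter(family.transcripts))
        with pytest.raises(ValueError):
            apply_splice_event(
                allele, model, SpliceEvent("exon_skip", 99)
            )

    def test_frameshifting_donor_flags_ptc(self, family, family_models):
        truth = family.truth.by_id()
        model = family_models["locus01"]
        allele = next(
            t for t in family.transcripts if not truth[t.id].events
            and truth[t.id].locus == 1
        )
        tm_exon = next(e.index for e in model.exons if e.domain == "TM")
        var, realized = apply_splice_event(
            allele, model, SpliceEvent("alt_donor", tm_exon, offset=4)
        )
        assert not realized[0].in_frame
        assert realized[0].ptc is not None
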