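import pytest

from kirfam.genemodel import SpliceEvent, apply_splice_event
from kirfam.records import Transcript
from kirfam.splicing import (
    MappingError,
    call_events,
    infer_splice_variants,
    map_to_exons,
)


def _allele(family, locus=1):
    truth = family.truth.by_id()
    return next(
        t for t in family.transcripts
        if truth[t.id].locus == locus and not truth[t.id].events
    )


def _model(family_models, locus=1):
    return family_models[f"locus{locus:02d}"]


class TestMapping:
    def test_identity_mapping_full_coverage(self, family, family_models):
        t = _allele(family)
        mapping = map_to_exons(t, _model(family_models))
        assert mapping.identity > 0.99
        for cov in mapping.coverages:
            assert cov.fraction == 1.0 and cov.internal_gap == 0
        assert mapping.insertions == []

    def test_wrong_model_rejected(self, family, family_models):
        import numpy as np

        rng = np.random.default_rng(0)
        junk = Transcript(
            id="junk",
            sequence="".join("ACGT"[i] for i in rng.integers(0, 4, 1251)),
        )
        with pytest.raises(MappingError, match="wrong model"):
            map_to_exons(junk, _model(family_models))

    def test_partial_exon_truncation_located(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        d1 = next(e.index for e in model.exons if e.domain == "D1")
        var, _ = apply_splice_event(
            t, model, SpliceEvent("alt_acceptor", d1, offset=36)
        )
        mapping = map_to_exons(var, model)
        cov = next(c for c in mapping.coverages if c.exon_index == d1)
        assert cov.missing5 == 36 and cov.missing3 == 0

    def test_retained_intron_reported_as_insertion(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        tm = next(e.index for e in model.exons if e.domain == "TM")
        var, _ = apply_splice_event(
            t, model, SpliceEvent("intron_retention", tm, offset=45)
        )
        mapping = map_to_exons(var, model)
        assert any(qe - qs >= 20 for qs, qe, _ in mapping.insertions)


class TestEventCalling:
    def test_identity_yields_no_events(self, family, family_models):
        t = _allele(family)
        mapping = map_to_exons(t, _model(family_models))
        assert call_events(mapping, t) == []

    @pytest.mark.parametrize("domain,exp_delta", [("D2", -294), ("D0a", -288)])
    def test_exon_skip_called(self, family, family_models, domain, exp_delta):
        model = _model(family_models)
        t = _allele(family)
        exon = next(e.index for e in model.exons if e.domain == domain)
        var, _ = apply_splice_event(t, model, SpliceEvent("exon_skip", exon))
        mapping = map_to_exons(var, model)
        events = call_events(mapping, var)
        assert [(e.type, e.exon, e.nt_delta) for e in events] == [
            ("exon_skip", exon, exp_delta)
        ]
        assert events[0].in_frame

    def test_alt_acceptor_called_with_exact_offset(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        d1 = next(e.index for e in model.exons if e.domain == "D1")
        var, _ = apply_splice_event(
            t, model, SpliceEvent("alt_acceptor", d1, offset=36)
        )
        events = call_events(map_to_exons(var, model), var)
        assert [(e.type, e.exon, e.offset) for e in events] == [
            ("alt_acceptor", d1, 36)
        ]

    def test_frameshifting_alt_donor_sets_ptc(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        tm = next(e.index for e in model.exons if e.domain == "TM")
        var, _ = apply_splice_event(
            t, model, SpliceEvent("alt_donor", tm, offset=4)
        )
        events = call_events(map_to_exons(var, model), var)
        assert events and events[0].type == "alt_donor"
        assert not events[0].in_frame

    def test_intron_retention_called(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        tm = next(e.index for e in model.exons if e.domain == "TM")
        var, _ = apply_splice_event(
            t, model, SpliceEvent("intron_retention", tm, offset=45)
        )
        events = call_events(map_to_exons(var, model), var)
        assert [(e.type, e.exon) for e in events] == [("intron_retention", tm)]

    def test_nt_delta_sums_to_length_difference(self, family, family_models):
        model = _model(family_models)
        t = _allele(family)
        stem = next(e.index for e in model.exons if e.domain == "STEM")
        tm = next(e.index for e in model.exons if e.domain == "TM")
        var, _ = apply_splice_event(
            t, model,
            [SpliceEvent("exon_skip", stem), SpliceEvent("exon_skip", tm)],
        )
        events = call_events(map_to_exons(var, model), var)
        assert sum(e.nt_delta for e in events) == len(var) - len(model.cdna)

    def test_uninterpretable_deletion_reported_complex(
        self, family, family_models
    ):
        model = _model(family_models)
        t = _allele(family)
        # carve 40 nt out of the middle of the D2 exon: not a splice pattern
        offs = model.exon_offsets()
        d2_pos = next(
            k for k, e in enumerate(model.exons) if e.domain == "D2"
        )
        s, e = offs[d2_pos]
        mid = (s + e) // 2
        seq = t.sequence[: mid - 20] + t.sequence[mid + 20:]
        weird = Transcript(id="weird", sequence=seq)
        events = call_events(map_to_exons(weird, model), weird)
        assert events and any(ev.type == "complex" for ev in events)

    def test_closed_loop_accuracy(self, family, family_models):
        """Called events equal truth (type and exon) for the whole family."""
        truth = family.truth.by_id()
        agree = total = 0
        for t in family.transcripts:
            s = truth[t.id]
            model = family_models[f"locus{s.locus:02d}"]
            events = call_events(map_to_exons(t, model), t)
            total += 1
            agree += (
                sorted(e.key() for e in events)
                == sorted(e.key() for e in s.events)
            )
        assert agree / total >= 0.95


class TestModelChoice:
    def test_best_model_is_the_true_locus(self, family, family_models):
        truth = family.truth.by_id()
        t = _allele(family, locus=2)
        mapping, events = infer_splice_variants(t, list(family.models))
        assert mapping.model.locus == "locus02"
        assert events == []
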