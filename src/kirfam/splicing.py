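"""Splice-variant inference against a genomic exon model.

A transcript is globally aligned to the model's concatenated exons
(BLAST-like affine-gap scores); per-exon coverage then drives event calling:
whole-exon absence is an exon skip, partial 5'/3' absence with a canonical
AG/GT at the new boundary is an alternative acceptor/donor, and unaligned
transcript segments matching a model intron are intron retention. Anything
uninterpretable is reported as "complex", never dropped. Frame consequences
and premature termination codons are computed on the spliced product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .genemodel import ExonModel, SpliceEvent, find_stop
from .records import Transcript

MIN_MODEL_IDENTITY = 0.80
MIN_INTRON_NT = 20
MIN_INTRON_IDENTITY = 0.95


class MappingError(ValueError):
    pass


@dataclass
class ExonCoverage:
    exon_index: int
    fraction: float
    missing5: int           # nt absent at the exon 5' end
    missing3: int
    internal_gap: int       # nt absent strictly inside the covered span
    var_start: int | None   # transcript nt coords of the covered segment
    var_end: int | None


@dataclass
class ModelMapping:
    model: ExonModel
    identity: float
    coverages: list[ExonCoverage]
    insertions: list[tuple[int, int, int]]  # (q_start, q_end, model_pos)
    score: float = 0.0
    boundary_warning: bool = False

    def layout(self) -> list[tuple[int, int, int, int, int]]:
        """(exon_index, var_start, var_end, trim5, trim3) of covered exons."""
        out = []
        for c in self.coverages:
            if c.var_start is None:
                continue
            out.append(
                (c.exon_index, c.var_start, c.var_end, c.missing5, c.missing3)
            )
        return out


def _gap_badness(gs: int, ge: int, offsets: list[tuple[int, int]],
                 target: str) -> int:
    """How awkwardly a model-side deletion sits against exon boundaries.

    0: exactly one or more whole exons (a clean skip); 1: inside one exon
    touching its 5' end with a canonical AG upstream of the new acceptor, or
    its 3' end with a canonical GT donor; 2: touching a boundary without the
    canonical dinucleotide; 3: interior of one exon; 4: straddling exons.
    """
    starts = [s for s, _ in offsets]
    ends = [e for _, e in offsets]
    if gs in starts and ge in ends + starts:
        return 0
    exon = next(((s, e) for s, e in offsets if s <= gs and ge <= e), None)
    if exon is None:
        return 4
    s, e = exon
    if gs == s:  # alternative acceptor: offset removed from the exon start
        return 1 if target[ge - 2: ge] == "AG" else 2
    if ge == e:  # alternative donor
        return 1 if target[gs: gs + 2] == "GT" else 2
    return 3


def _snap_gaps(blocks_t, blocks_q, model: ExonModel):
    """Slide score-equivalent deletion gaps to sit cleanly on exon
    boundaries (alignment gap placement is otherwise arbitrary within runs
    of repeated sequence)."""
    target = model.cdna
    offsets = model.exon_offsets()
    for k in range(1, len(blocks_t)):
        if blocks_q[k][0] != blocks_q[k - 1][1]:
            continue  # insertion in between: leave untouched
        gs, ge = blocks_t[k - 1][1], blocks_t[k][0]
        if ge <= gs:
            continue
        # score-equivalent shift range (gap slides while chars repeat)
        max_right = 0
        while (
            max_right < 90
            and ge + max_right < len(target)
            and target[gs + max_right] == target[ge + max_right]
        ):
            max_right += 1
        max_left = 0
        while (
            max_left < 90
            and gs - max_left > 0
            and target[gs - max_left - 1] == target[ge - max_left - 1]
        ):
            max_left += 1
        best_shift = 0
        best = (_gap_badness(gs, ge, offsets, target), 0)
        for shift in range(-max_left, max_right + 1):
            score = (_gap_badness(gs + shift, ge + shift, offsets, target),
                     abs(shift))
            if score < best:
                best = score
                best_shift = shift
        if best_shift:
            blocks_t[k - 1][1] += best_shift
            blocks_q[k - 1][1] += best_shift
            blocks_t[k][0] += best_shift
            blocks_q[k][0] += best_shift
    return blocks_t, blocks_q


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def map_to_exons(transcript: Transcript, model: ExonModel) -> ModelMapping:
    """Align a transcript to the model's concatenated exons.

    Reports per-exon coverage with 5'/3' truncation offsets, plus unaligned
    transcript segments (candidate retained introns). Identity below 80%
    means the wrong model was supplied and raises.
    """
    target = model.cdna
    query = transcript.sequence.replace("-", "")
    aln = _aligner().align(target, query)[0]
    blocks_t, blocks_q = _snap_gaps(
        [list(map(int, b)) for b in aln.aligned[0]],
        [list(map(int, b)) for b in aln.aligned[1]],
        model,
    )
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        aligned_cols += te - ts
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    identity = matches / max(aligned_cols, 1)
    if identity < MIN_MODEL_IDENTITY:
        raise MappingError(
            f"{transcript.id}: identity {identity:.2f} below "
            f"{MIN_MODEL_IDENTITY:.2f} -- wrong model"
        )
    # per-exon coverage
    coverages = []
    for exon, (es, ee) in zip(model.exons, model.exon_offsets()):
        cov_nt = 0
        c_start = c_end = None
        q_start = q_end = None
        for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
            lo, hi = max(ts, es), min(te, ee)
            if lo >= hi:
                continue
            cov_nt += hi - lo
            if c_start is None or lo < c_start:
                c_start = lo
                q_start = qs + (lo - ts)
            if c_end is None or hi > c_end:
                c_end = hi
                q_end = qs + (hi - ts)
        length = ee - es
        if cov_nt == 0:
            coverages.append(
                ExonCoverage(exon.index, 0.0, length, length, 0, None, None)
            )
            continue
        missing5 = c_start - es
        missing3 = ee - c_end
        internal = (c_end - c_start) - cov_nt
        coverages.append(
            ExonCoverage(
                exon.index, cov_nt / length, missing5, missing3, internal,
                q_start, q_end,
            )
        )
    # unaligned transcript segments (insertions relative to the model)
    insertions = []
    for k in range(1, len(blocks_q)):
        q_gap_start = blocks_q[k - 1][1]
        q_gap_end = blocks_q[k][0]
        if q_gap_end > q_gap_start:
            insertions.append(
                (int(q_gap_start), int(q_gap_end), int(blocks_t[k - 1][1]))
            )
    if blocks_q[0][0] > 0:
        insertions.insert(0, (0, int(blocks_q[0][0]), 0))
    if blocks_q[-1][1] < len(query):
        insertions.append(
            (int(blocks_q[-1][1]), len(query), len(target))
        )
    return ModelMapping(
        model=model, identity=identity, coverages=coverages,
        insertions=insertions, score=aln.score,
    )


def _segment_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def call_events(
    mapping: ModelMapping, transcript: Transcript
) -> list[SpliceEvent]:
    """Interpret per-exon coverage as splice events.

    Precedence when a deletion has several explanations: the single-event
    explanation with canonical splice dinucleotides wins; remaining
    ambiguity goes to the fewest events, then the 5'-most. Uninterpretable
    coverage becomes a "complex" event.
    """
    model = mapping.model
    events: list[SpliceEvent] = []
    exon_seq = {e.index: e.sequence for e in model.exons}
    for cov in mapping.coverages:
        seq = exon_seq[cov.exon_index]
        L = len(seq)
        if cov.fraction == 0.0:
            events.append(
                SpliceEvent("exon_skip", cov.exon_index, nt_delta=-L)
            )
            continue
        if cov.fraction == 1.0 and cov.internal_gap == 0:
            continue
        if cov.internal_gap > 0 or (cov.missing5 > 0 and cov.missing3 > 0):
            delta = -(cov.missing5 + cov.missing3 + cov.internal_gap)
            events.append(
                SpliceEvent("complex", cov.exon_index, nt_delta=delta)
            )
            continue
        if cov.missing5 > 0:
            canonical = seq[cov.missing5 - 2: cov.missing5] == "AG"
            etype = "alt_acceptor" if canonical else "complex"
            events.append(
                SpliceEvent(etype, cov.exon_index, nt_delta=-cov.missing5,
                            offset=cov.missing5)
            )
        elif cov.missing3 > 0:
            cut = L - cov.missing3
            canonical = seq[cut: cut + 2] == "GT"
            etype = "alt_donor" if canonical else "complex"
            events.append(
                SpliceEvent(etype, cov.exon_index, nt_delta=-cov.missing3,
                            offset=cov.missing3)
            )
    # insertions: retained introns or complex
    query = transcript.sequence.replace("-", "")
    boundary = {e.index: span[1] for e, span in
                zip(model.exons, model.exon_offsets())}
    for q_start, q_end, model_pos in mapping.insertions:
        seg = query[q_start:q_end]
        called = False
        if len(seg) >= MIN_INTRON_NT:
            for k, intron in enumerate(model.introns):
                exon_idx = model.exons[k].index
                if abs(boundary[exon_idx] - model_pos) > 6:
                    continue
                ident = _segment_identity(seg, intron.sequence)
                if ident >= MIN_INTRON_IDENTITY:
                    events.append(
                        SpliceEvent(
                            "intron_retention", exon_idx,
                            nt_delta=len(seg), offset=len(seg),
                        )
                    )
                    called = True
                    break
        if not called:
            nearest = min(
                boundary, key=lambda i: abs(boundary[i] - model_pos)
            )
            events.append(
                SpliceEvent("complex", nearest, nt_delta=len(seg))
            )
    events.sort(key=lambda e: e.exon)
    # frame and premature-stop consequences on the spliced product
    total_delta = sum(e.nt_delta for e in events)
    in_frame = total_delta % 3 == 0
    ptc = detect_ptc(transcript, mapping)
    annotated = [
        SpliceEvent(e.type, e.exon, e.nt_delta, e.offset,
                    in_frame=in_frame and ptc is None, ptc=ptc)
        for e in events
    ]
    return annotated


def detect_ptc(
    transcript: Transcript, mapping: ModelMapping
) -> int | None:
    """Premature termination codon: the first in-frame stop upstream of the
    final exon junction (a stop inside the last exon is the natural end)."""
    query = transcript.sequence.replace("-", "")
    stop = find_stop(query)
    if stop is None:
        return None
    last_cov = [c for c in mapping.coverages if c.var_start is not None]
    if not last_cov:
        return None
    final_junction = last_cov[-1].var_start
    if stop < final_junction:
        return stop // 3 + 1
    return None


def infer_splice_variants(
    transcript: Transcript, models: list[ExonModel]
) -> tuple[ModelMapping, list[SpliceEvent]]:
    """Map against every candidate model, keep the best, call events."""
    best: ModelMapping | None = None
    for model in models:
        try:
            mapping = map_to_exons(transcript, model)
        except MappingError:
            continue
        if best is None or mapping.score > best.score:
            best = mapping
    if best is None:
        raise MappingError(
            f"{transcript.id}: no exon model reached "
            f"{MIN_MODEL_IDENTITY:.0%} identity"
        )
    return best, call_events(best, transcript)
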