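"""Receptor annotation: ORFs, domains, ITIMs, transmembrane features, class.

Transcripts are translated (sense strand only; these are oriented cDNAs),
their Ig-like and C-terminal domains delimited from the exon model mapping,
ITIM hexamers matched against the immunoreceptor consensus
{I,L,V,S}xYxx{L,V}, and a Kyte-Doolittle hydropathy window locates the
transmembrane helix when no exon mapping is available. Receptor class
follows the standard KIR logic: long ITIM-bearing tails are inhibitory;
short tails with a charged residue at transmembrane position 4 are
activating; short tails whose TM conserves proline 11 / threonine 13 are
putative activating; receptors without a membrane anchor are soluble.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genemodel import ExonModel, SpliceEvent
from .records import Transcript
from .selection import translate_codon

LONG_TAIL_MIN_AA = 40

ITIM_PATTERN = re.compile(r"(?=([ILVS].Y..[LV]))")

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


class AnnotationError(ValueError):
    pass


@dataclass
class DomainSpan:
    label: str
    start: int    # 1-based aa, inclusive
    end: int
    partial: bool = False


@dataclass
class ReceptorAnnotation:
    transcript_id: str
    orf_start: int            # 1-based nt, inclusive
    orf_end: int
    protein: str
    no_start: bool
    domains: list[DomainSpan] = field(default_factory=list)
    itims: list[tuple[str, int]] = field(default_factory=list)
    tm: tuple[int, int, float] | None = None   # (start aa, end aa, max KD)
    charged_tm_residue: tuple[str, int] | None = None  # (residue, TM pos)
    tail_class: str = "absent"                 # long | short | absent
    receptor_class: str = "ambiguous"
    configuration: str = ""

    @property
    def n_ig_domains(self) -> int:
        return sum(1 for d in self.domains if d.label in
                   ("D0a", "D0b", "D1", "D2"))


def translate(seq: str) -> str:
    return "".join(
        translate_codon(seq[i: i + 3]) for i in range(0, len(seq) - 2, 3)
    )


def find_orf(
    transcript: Transcript, min_length_aa: int = 80
) -> tuple[int, int, str, bool]:
    """Locate the coding region.

    Returns (start, end) as a 0-based half-open nt span, the protein, and a
    flag marking the no-ATG fallback. The longest ATG-initiated ORF of at
    least ``min_length_aa`` residues wins; failing that, the longest
    stop-free stretch in any forward frame is returned flagged no-start
    (incompletely sequenced 5' ends occur in real cDNA sets).
    """
    seq = transcript.sequence
    if len(seq) < 3 * min_length_aa:
        raise AnnotationError(
            f"{transcript.id}: sequence shorter than 3*min_length_aa"
        )
    best: tuple[int, int, str] | None = None
    for frame in range(3):
        prot = translate(seq[frame:])
        # ATG-initiated ORFs within this frame
        pos = 0
        while True:
            m = prot.find("M", pos)
            if m < 0:
                break
            stop = prot.find("*", m)
            aa = prot[m: stop if stop >= 0 else len(prot)]
            nt_start = frame + 3 * m
            nt_end = frame + 3 * (m + len(aa)) + (3 if stop >= 0 else 0)
            if len(aa) >= min_length_aa and (
                best is None or len(aa) > len(best[2])
            ):
                best = (nt_start, min(nt_end, len(seq)), aa)
            pos = (stop + 1) if stop >= 0 else len(prot)
    if best is not None:
        return best[0], best[1], best[2], False
    # fallback: longest stop-free stretch, flagged
    fallback: tuple[int, int, str] | None = None
    for frame in range(3):
        prot = translate(seq[frame:])
        for run in re.finditer(r"[^*]+", prot):
            aa = run.group(0)
            if fallback is None or len(aa) > len(fallback[2]):
                nt_start = frame + 3 * run.start()
                nt_end = frame + 3 * run.end()
                fallback = (nt_start, min(nt_end, len(seq)), aa)
    if fallback is None or len(fallback[2]) < min_length_aa:
        raise AnnotationError(
            f"{transcript.id}: no open reading frame of >= {min_length_aa} aa"
        )
    return fallback[0], fallback[1], fallback[2], True


def detect_itims(protein: str) -> list[tuple[str, int]]:
    """All (overlapping) ITIM consensus matches with 1-based positions."""
    out = []
    for m in ITIM_PATTERN.finditer(protein):
        out.append((m.group(1), m.start() + 1))
    return out


def detect_tm(
    protein: str, window: int = 19, trigger: float = 1.6, extend: float = 1.0
) -> tuple[int, int, float] | None:
    """Kyte-Doolittle transmembrane scan.

    The maximal ``window``-wide mean above ``trigger`` seeds the span, which
    grows while the shifted window mean stays above ``extend``. Returns
    (start, end) 1-based inclusive and the peak window mean, or None.
    """
    if len(protein) < window:
        return None
    values = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    means = [
        sum(values[i: i + window]) / window
        for i in range(len(values) - window + 1)
    ]
    peak = max(range(len(means)), key=lambda i: means[i])
    if means[peak] <= trigger:
        return None
    lo = hi = peak
    while lo > 0 and means[lo - 1] > extend:
        lo -= 1
    while hi < len(means) - 1 and means[hi + 1] > extend:
        hi += 1
    return lo + 1, hi + window, means[peak]


def annotate_domains(
    protein: str,
    model: ExonModel,
    layout: list[tuple[int, int, int, int, int]],
    orf_start_nt: int,
) -> list[DomainSpan]:
    """Label protein segments with their exon's domain.

    ``layout`` rows are (exon_index, var_start, var_end, trim5, trim3) in
    transcript nt coordinates (the identity layout for unspliced
    transcripts). Partially retained exons keep their domain label with a
    partial flag. Frame-inconsistent segments raise.
    """
    spans: list[DomainSpan] = []
    exon_len = {e.index: len(e.sequence) for e in model.exons}
    prot_len = len(protein)
    for exon_idx, vs, ve, t5, t3 in layout:
        if ve <= orf_start_nt:
            continue
        if exon_idx not in exon_len:
            raise AnnotationError(f"layout references unknown exon {exon_idx}")
        start_nt = max(vs, orf_start_nt)
        aa_start = (start_nt - orf_start_nt) // 3 + 1
        aa_end = (ve - orf_start_nt + 2) // 3
        aa_end = min(aa_end, prot_len)
        if aa_end < aa_start:
            continue
        domain = model.exon_by_index(exon_idx).domain
        partial = (t5 > 0 or t3 > 0
                   or (ve - vs) < exon_len[exon_idx]
                   or aa_end - aa_start + 1 < (ve - vs) // 3)
        spans.append(DomainSpan(domain, aa_start, aa_end, partial))
    merged: list[DomainSpan] = []
    for s in spans:
        if merged and merged[-1].label == s.label and s.start <= merged[-1].end + 1:
            merged[-1].end = max(merged[-1].end, s.end)
            merged[-1].partial = merged[-1].partial or s.partial
        else:
            merged.append(s)
    return merged


def identity_layout(model: ExonModel) -> list[tuple[int, int, int, int, int]]:
    return [
        (e.index, s, t, 0, 0)
        for e, (s, t) in zip(model.exons, model.exon_offsets())
    ]


def classify_receptor(ann: ReceptorAnnotation) -> str:
    """Receptor class from tail, ITIMs and transmembrane features."""
    tm_span = _tm_span(ann)
    if tm_span is None:
        return "soluble"
    tm_start, tm_end = tm_span
    tail_itims = [p for _, p in ann.itims if p > tm_end]
    if ann.tail_class == "long" and tail_itims:
        return "inhibitory"
    if ann.tail_class == "short":
        if ann.charged_tm_residue is not None:
            return "activating"
        prot = ann.protein
        p11 = tm_start + 10
        t13 = tm_start + 12
        if (
            t13 <= len(prot)
            and prot[p11 - 1] == "P"
            and prot[t13 - 1] == "T"
        ):
            return "putative_activating"
    return "ambiguous"


def _tm_span(ann: ReceptorAnnotation) -> tuple[int, int] | None:
    # with an exon-model mapping the TM segment is authoritative: a variant
    # whose stem/TM exons are spliced out is soluble even if some
    # extracellular stretch happens to look hydrophobic
    if ann.domains:
        for d in ann.domains:
            if d.label == "TM":
                return d.start, d.end
        return None
    if ann.tm is not None:
        return ann.tm[0], ann.tm[1]
    return None


def annotate_transcript(
    transcript: Transcript,
    model: ExonModel | None = None,
    layout: list[tuple[int, int, int, int, int]] | None = None,
    events: list[SpliceEvent] | None = None,
    min_length_aa: int = 80,
) -> ReceptorAnnotation:
    """Full annotation of one transcript.

    With an exon model, domain spans come from the (splice-aware) exon
    layout; otherwise only sequence-level features are reported. The
    transmembrane span prefers the exon-model TM segment and falls back to
    the hydropathy scan.
    """
    s0, e0, protein, no_start = find_orf(transcript, min_length_aa)
    ann = ReceptorAnnotation(
        transcript_id=transcript.id,
        orf_start=s0 + 1,
        orf_end=e0,
        protein=protein,
        no_start=no_start,
    )
    ann.itims = detect_itims(protein)
    ann.tm = detect_tm(protein)
    if model is not None:
        if layout is None:
            layout = identity_layout(model)
        ann.domains = annotate_domains(protein, model, layout, s0)
    tm_span = _tm_span(ann)
    if tm_span is None:
        ann.tail_class = "absent"
    else:
        tail_len = len(protein) - tm_span[1]
        ann.tail_class = "long" if tail_len >= LONG_TAIL_MIN_AA else "short"
        pos4 = tm_span[0] + 3
        if pos4 <= len(protein) and protein[pos4 - 1] in "RK":
            ann.charged_tm_residue = (protein[pos4 - 1], 4)
    ann.receptor_class = classify_receptor(ann)
    ig = [d.label for d in ann.domains if d.label in ("D0a", "D0b", "D1", "D2")]
    n_ig = len(set(ig)) if ig else _ig_from_length(len(protein))
    letter = "L" if ann.tail_class == "long" else "S"
    ann.configuration = f"{n_ig}D{letter}"
    return ann


def _ig_from_length(n_aa: int) -> int:
    # crude fallback when no exon model is available
    if n_aa >= 470:
        return 4
    if n_aa >= 370:
        return 3
    return 2
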