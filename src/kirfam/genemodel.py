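"""Genomic exon models and splice events.

An :class:`ExonModel` is the reference gene structure a transcript is
interpreted against: ordered exons with sequences, domain labels and phases,
and the introns between them (canonical GT..AG boundaries unless flagged).
KIR genes are modelled with two signal-peptide exons, one exon per Ig-like
domain (with an optional duplicated D0 exon in 4-domain loci), a stem exon,
a transmembrane exon and two cytoplasmic exons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .records import Transcript

DOMAIN_LABELS = ("SP", "D0a", "D0b", "D1", "D2", "STEM", "TM", "CYT")
IG_DOMAINS = ("D0a", "D0b", "D1", "D2")

EVENT_TYPES = (
    "exon_skip",
    "alt_acceptor",
    "alt_donor",
    "intron_retention",
    "exon_extension_junction",
)


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event relative to an exon model.

    ``offset`` is the number of exon nucleotides removed (alt acceptor/donor)
    or intron nucleotides retained; ``nt_delta`` the signed length change of
    the mature transcript; ``ptc`` a 1-based protein position when the event
    creates a premature termination codon.
    """

    type: str
    exon: int                 # 1-based exon index in the model
    nt_delta: int = 0
    offset: int = 0
    in_frame: bool = True
    ptc: int | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES and self.type != "complex":
            raise ValueError(f"unknown splice event type {self.type!r}")

    def key(self) -> tuple[str, int]:
        return (self.type, self.exon)


@dataclass
class Exon:
    index: int                # 1-based position in the model
    sequence: str
    domain: str
    phase: int = 0            # reading-frame phase at exon start
    template_slot: int | None = None  # position in the family-wide template

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {self.domain!r}")


@dataclass
class Intron:
    sequence: str
    donor: str = "GT"
    acceptor: str = "AG"
    non_canonical: bool = False

    def __post_init__(self) -> None:
        if self.sequence:
            self.donor = self.sequence[:2]
            self.acceptor = self.sequence[-2:]
            self.non_canonical = not (
                self.donor == "GT" and self.acceptor == "AG"
            )


@dataclass
class ExonModel:
    locus: str
    exons: list[Exon] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.introns and len(self.introns) != len(self.exons) - 1:
            raise ValueError("need exactly one intron between adjacent exons")
        phase = 0
        for exon in self.exons:
            if exon.phase != phase:
                raise ValueError(
                    f"exon {exon.index}: phase {exon.phase} inconsistent "
                    f"with running frame {phase}"
                )
            phase = (phase + len(exon.sequence)) % 3

    @property
    def cdna(self) -> str:
        return "".join(e.sequence for e in self.exons)

    def exon_by_index(self, index: int) -> Exon:
        for e in self.exons:
            if e.index == index:
                return e
        raise KeyError(f"no exon {index} in model {self.locus!r}")

    def exon_offsets(self) -> list[tuple[int, int]]:
        """0-based half-open (start, end) of each exon in the cDNA."""
        out = []
        pos = 0
        for e in self.exons:
            out.append((pos, pos + len(e.sequence)))
            pos += len(e.sequence)
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "locus": self.locus,
            "exons": [asdict(e) for e in self.exons],
            "introns": [asdict(i) for i in self.introns],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExonModel":
        data = json.loads(Path(path).read_text())
        return cls(
            locus=data["locus"],
            exons=[Exon(**e) for e in data["exons"]],
            introns=[Intron(**i) for i in data["introns"]],
        )


def models_to_json(models: list[ExonModel], path: str | Path) -> None:
    data = [
        {
            "locus": m.locus,
            "exons": [asdict(e) for e in m.exons],
            "introns": [asdict(i) for i in m.introns],
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def models_from_json(path: str | Path) -> list[ExonModel]:
    data = json.loads(Path(path).read_text())
    return [
        ExonModel(
            locus=m["locus"],
            exons=[Exon(**e) for e in m["exons"]],
            introns=[Intron(**i) for i in m["introns"]],
        )
        for m in data
    ]


def find_stop(seq: str, frame_start: int = 0) -> int | None:
    """0-based nt index of the first in-frame stop codon, or None."""
    from .selection import STOP_CODONS

    for i in range(frame_start, len(seq) - 2, 3):
        if seq[i: i + 3] in STOP_CODONS:
            return i
    return None


def apply_splice_event(
    transcript: Transcript,
    model: ExonModel,
    events: SpliceEvent | list[SpliceEvent],
    new_id: str | None = None,
) -> tuple[Transcript, list[SpliceEvent]]:
    """Apply splice events to a transcript segmented like the model.

    The transcript must have the model's cDNA length (the exon boundaries of
    the transcript are taken from the model). Returns the spliced transcript
    and the events annotated with realized nt_delta, frame consequence and
    any premature termination codon.
    """
    if isinstance(events, SpliceEvent):
        events = [events]
    if len(transcript) != len(model.cdna):
        raise ValueError(
            f"transcript length {len(transcript)} does not match model "
            f"cDNA length {len(model.cdna)}"
        )
    offsets = model.exon_offsets()
    segments: dict[int, str] = {
        e.index: transcript.sequence[s:t]
        for e, (s, t) in zip(model.exons, offsets)
    }
    inserts: dict[int, str] = {}   # after exon index -> retained intron
    for ev in events:
        if ev.exon not in segments:
            raise ValueError(f"event exon {ev.exon} outside model bounds")
        if ev.type == "exon_skip":
            segments[ev.exon] = ""
        elif ev.type == "alt_acceptor":
            seg = segments[ev.exon]
            if not 0 < ev.offset < len(seg):
                raise ValueError("alt_acceptor offset outside exon")
            segments[ev.exon] = seg[ev.offset:]
        elif ev.type == "alt_donor":
            seg = segments[ev.exon]
            if not 0 < ev.offset < len(seg):
                raise ValueError("alt_donor offset outside exon")
            segments[ev.exon] = seg[: len(seg) - ev.offset]
        elif ev.type == "intron_retention":
            if ev.exon >= len(model.exons):
                raise ValueError("no intron downstream of the last exon")
            intron = model.introns[ev.exon - 1].sequence
            length = ev.offset or len(intron)
            inserts[ev.exon] = intron[:length]
        else:
            raise ValueError(f"cannot apply event type {ev.type!r}")
    parts = []
    for e in model.exons:
        parts.append(segments[e.index])
        if e.index in inserts:
            parts.append(inserts[e.index])
    spliced = "".join(parts)
    # annotate realized consequences
    delta = len(spliced) - len(transcript)
    stop = find_stop(spliced)
    # a premature stop is one that is NOT the image of the transcript's own
    # stop codon (some receptors terminate early by construction)
    base_stop = find_stop(transcript.sequence)
    expected_stop = None
    if base_stop is not None:
        shift = 0
        removed = False
        for ev in events:
            pos = _pos(model, ev.exon)
            es, ee = offsets[pos]
            if ev.type == "exon_skip":
                region, ev_delta = (es, ee), es - ee
            elif ev.type == "alt_acceptor":
                region, ev_delta = (es, es + ev.offset), -ev.offset
            elif ev.type == "alt_donor":
                region, ev_delta = (ee - ev.offset, ee), -ev.offset
            else:  # intron_retention: insertion at the exon 3' boundary
                region, ev_delta = (ee, ee), len(inserts[ev.exon])
            if region[1] <= base_stop:
                shift += ev_delta
            elif region[0] <= base_stop < region[1]:
                removed = True
        if not removed:
            expected_stop = base_stop + shift
    ptc = None
    if stop is not None and stop != expected_stop:
        ptc = stop // 3 + 1
    realized = []
    for ev in events:
        if ev.type == "exon_skip":
            ev_delta = -len(
                transcript.sequence[slice(*offsets[_pos(model, ev.exon)])]
            )
        elif ev.type in ("alt_acceptor", "alt_donor"):
            ev_delta = -ev.offset
        else:
            ev_delta = len(inserts[ev.exon])
        realized.append(
            SpliceEvent(
                type=ev.type, exon=ev.exon, nt_delta=ev_delta,
                offset=ev.offset, in_frame=(delta % 3 == 0 and ptc is None),
                ptc=ptc,
            )
        )
    out = Transcript(
        id=new_id or transcript.id + "_v",
        sequence=spliced,
        individual=transcript.individual,
    )
    return out, realized


def _pos(model: ExonModel, index: int) -> int:
    for k, e in enumerate(model.exons):
        if e.index == index:
            return k
    raise KeyError(index)
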