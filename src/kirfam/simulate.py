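"""Synthetic KIR-like multigene families with full ground truth.

The generator emulates a family of paralogous loci produced by ancient
duplications (birth-and-death evolution): deep splits on a locus tree give
high inter-paralog divergence, while alleles within each locus diverge only
by a small within-locus theta. Sequences evolve by a K2P substitution
process with discrete-gamma rate variation; codon-level selection classes
are imposed by acceptance sampling on nonsynonymous proposals, and
stop-creating proposals are rejected. Each locus carries receptor-defining
features (ITIM hexamers, transmembrane charge or proline/threonine anchors,
tail truncation) and a menu of alternative-splicing events produces variant
transcripts. Every emitted sequence has a truth row; recombinant fragments
can be implanted between locus ancestors before allele divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genemodel import (
    Exon,
    ExonModel,
    Intron,
    SpliceEvent,
    apply_splice_event,
    find_stop,
)
from .records import Alignment, Transcript
from .selection import STOP_CODONS, SENSE_CODONS, translate_codon

# ---------------------------------------------------------------------------
# template gene structure
# ---------------------------------------------------------------------------

#: (template slot, domain label, length in nt); all lengths are multiples of
#: 3 so every whole-exon skip is in-frame and frameshifts come only from
#: alternative acceptor/donor use.
TEMPLATE_PLAN = (
    (1, "SP", 27),
    (2, "SP", 21),
    (3, "D0a", 288),
    (4, "D0b", 288),
    (5, "D1", 306),
    (6, "D2", 294),
    (7, "STEM", 51),
    (8, "TM", 63),
    (9, "CYT", 51),     # CYT1: carries the first ITIM
    (10, "CYT", 150),   # CYT2: second ITIM, natural stop at the end
)

IG_SLOTS = (3, 4, 5, 6)
TM_SLOT, CYT1_SLOT, CYT2_SLOT = 8, 9, 10
D1_SLOT, D2_SLOT, D0A_SLOT, D0B_SLOT, STEM_SLOT = 5, 6, 3, 4, 7

ITIM1_CODONS = ("GTG", "ACC", "TAC", "GCC", "CAG", "CTG")   # VTYAQL
ITIM2_CODONS = ("TCC", "GTG", "TAC", "ATG", "GAA", "CTG")   # SVYMEL
ITIM1_AT = (CYT1_SLOT, 2)    # codons 3-8 of CYT1
ITIM2_AT = (CYT2_SLOT, 4)    # codons 5-10 of CYT2
HYDROPHOBIC_CODONS = ("CTG", "ATC", "GTG", "TTC", "GCC", "CTC", "GCT", "ATT")

RECEPTOR_CLASSES = ("inhibitory", "activating", "putative_activating")


#: roughly natural globular-protein composition, with strongly hydrophobic
#: residues downweighted so extracellular domains do not mimic membrane
#: helices under a hydropathy scan
_AA_WEIGHTS = {
    "A": 5.5, "R": 5.1, "N": 4.3, "D": 5.3, "C": 1.3, "Q": 4.2, "E": 6.3,
    "G": 7.2, "H": 2.3, "I": 3.7, "L": 6.4, "K": 5.9, "M": 1.6, "F": 2.7,
    "P": 5.2, "S": 6.8, "T": 5.9, "W": 1.0, "Y": 3.2, "V": 4.6,
}
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(translate_codon(_c), []).append(_c)
_AA_LIST = sorted(_AA_WEIGHTS)
_AA_P = np.array([_AA_WEIGHTS[a] for a in _AA_LIST])
_AA_P = _AA_P / _AA_P.sum()


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    """Random sense codons drawn via a globular amino-acid composition."""
    out = []
    for i in rng.choice(len(_AA_LIST), size=n, p=_AA_P):
        codons = _CODONS_BY_AA[_AA_LIST[i]]
        out.append(codons[rng.integers(0, len(codons))])
    return out


def _random_intron(rng: np.random.Generator, length: int) -> str:
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, length - 4))
    return "GT" + body + "AG"


def build_template(rng: np.random.Generator) -> ExonModel:
    """Family-wide ancestral gene structure (4-Ig-domain layout).

    Feature codons are implanted at fixed template positions: the start
    codon, both ITIM hexamers, hydrophobic TM residues with neutral defaults
    at TM positions 4/11/13, an AG anchor inside the D1 exon enabling a
    canonical 36-nt alternative acceptor, a GT anchor near the TM exon end
    enabling a frameshifting 4-nt alternative donor, and the natural stop.
    """
    exons = []
    for slot, domain, length in TEMPLATE_PLAN:
        codons = _random_codons(rng, length // 3)
        if slot == 1:
            codons[0] = "ATG"
        if slot == D1_SLOT:
            codons[11] = "AAG"  # positions 34-35 = AG: alt-acceptor anchor
        if slot == TM_SLOT:
            codons = [
                HYDROPHOBIC_CODONS[i]
                for i in rng.integers(0, len(HYDROPHOBIC_CODONS), length // 3)
            ]
            codons[3] = "GCT"    # TM position 4: neutral by default
            codons[10] = "CTG"
            codons[12] = "CTG"
            codons[19] = "CTG"   # ends G...
            codons[20] = "TTC"   # ...starts T: GT alt-donor anchor
        if slot == CYT1_SLOT:
            for k, c in enumerate(ITIM1_CODONS):
                codons[ITIM1_AT[1] + k] = c
        if slot == CYT2_SLOT:
            for k, c in enumerate(ITIM2_CODONS):
                codons[ITIM2_AT[1] + k] = c
            codons[-1] = "TAA"
        exons.append(
            Exon(index=slot, sequence="".join(codons), domain=domain,
                 phase=0, template_slot=slot)
        )
    # re-derive phases (all exon lengths are multiples of 3 -> all zero)
    introns = []
    for k in range(len(exons) - 1):
        if exons[k].template_slot == TM_SLOT:
            # in-frame, stop-free intron: retention keeps the reading frame
            codons = [
                c for c in _random_codons(rng, 15) if c not in STOP_CODONS
            ]
            seq = "GT" + "".join(codons)[: 45 - 4] + "AG"
            # pad to a multiple of 3 of length 45
            while len(seq) < 45:
                seq = seq[:2] + "C" + seq[2:]
            introns.append(Intron(sequence=seq))
        else:
            introns.append(
                Intron(sequence=_random_intron(rng, int(rng.integers(80, 200))))
            )
    return ExonModel(locus="template", exons=exons, introns=introns)


def template_feature_positions(model: ExonModel) -> dict[str, list[int]]:
    """Protected nt positions (cDNA coordinates) of receptor features."""
    start = {e.template_slot: s for e, (s, _) in
             zip(model.exons, model.exon_offsets())}

    def codon_nt(slot: int, codon_idx: int) -> list[int]:
        base = start[slot] + 3 * codon_idx
        return [base, base + 1, base + 2]

    feats: dict[str, list[int]] = {}
    feats["start"] = codon_nt(1, 0)
    feats["itim1"] = sum(
        (codon_nt(CYT1_SLOT, ITIM1_AT[1] + k) for k in range(6)), []
    )
    feats["itim2"] = sum(
        (codon_nt(CYT2_SLOT, ITIM2_AT[1] + k) for k in range(6)), []
    )
    feats["tm4"] = codon_nt(TM_SLOT, 3)
    feats["tm11"] = codon_nt(TM_SLOT, 10)
    feats["tm13"] = codon_nt(TM_SLOT, 12)
    feats["donor_anchor"] = codon_nt(TM_SLOT, 19) + codon_nt(TM_SLOT, 20)
    feats["acceptor_anchor"] = codon_nt(D1_SLOT, 11)
    feats["stop"] = codon_nt(CYT2_SLOT, 49)
    feats["early_stop"] = codon_nt(CYT2_SLOT, 2)
    return feats


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
_TRANSVERSIONS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}
_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}


def _gamma_site_rates(
    rng: np.random.Generator, n: int, gamma_alpha: float | None, ncat: int = 4
) -> np.ndarray:
    if gamma_alpha is None:
        return np.ones(n)
    from .phylo import discrete_gamma_rates

    cats = discrete_gamma_rates(gamma_alpha, ncat)
    return cats[rng.integers(0, ncat, n)]


def mutate_k2p(
    sequence: str,
    branch_length: float,
    kappa: float = 4.0,
    gamma_alpha: float | None = None,
    seed: int | np.random.Generator = 0,
    site_rates: np.ndarray | None = None,
) -> str:
    """Evolve a sequence along one branch under neutral K2P.

    Exact per-site sampling from the K2P transition probabilities at the
    per-site distance branch_length * rate, with site rates from a 4-category
    discrete gamma when ``gamma_alpha`` is given. Re-estimating the distance
    between input and output recovers ``branch_length`` in expectation.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    enc = np.array([_ENC.get(c, -1) for c in sequence])
    n = len(enc)
    # site rates are a property of the site: pass the same array for every
    # branch of a tree to model rate variation consistently
    rates = (
        site_rates if site_rates is not None
        else _gamma_site_rates(rng, n, gamma_alpha)
    )
    d = branch_length * rates
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_tv_each = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    u = rng.random(n)
    out = enc.copy()
    valid = enc >= 0
    ts_hit = valid & (u < p_ts)
    tv1_hit = valid & (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2_hit = valid & (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    for i in np.flatnonzero(ts_hit):
        out[i] = _TRANSITION[enc[i]]
    for i in np.flatnonzero(tv1_hit):
        out[i] = _TRANSVERSIONS[enc[i]][0]
    for i in np.flatnonzero(tv2_hit):
        out[i] = _TRANSVERSIONS[enc[i]][1]
    chars = list(sequence)
    for i in np.flatnonzero(out != enc):
        chars[i] = _BASES[out[i]]
    return "".join(chars)


def evolve_coding(
    sequence: str,
    branch_length: float,
    kappa: float,
    omega: float | np.ndarray,
    rng: np.random.Generator,
    gamma_alpha: float | None = None,
    protected: frozenset[int] | set[int] = frozenset(),
    site_rates: np.ndarray | None = None,
) -> str:
    """Evolve a coding sequence with codon-level selection classes.

    Proposals follow K2P (transition weight kappa); a nonsynonymous proposal
    at a codon with ratio w is accepted with probability min(1, w) and a
    synonymous one with min(1, 1/w), preserving the nonsynonymous-to-
    synonymous rate ratio w. Stop-creating proposals and proposals at
    protected positions are rejected, so the realized substitution rate is
    below the proposal rate (callers calibrate branch lengths against this).
    """
    L = len(sequence)
    if L % 3 != 0:
        raise ValueError("coding sequence length must be a multiple of 3")
    omega_arr = np.broadcast_to(np.asarray(omega, dtype=float), (L // 3,))
    rates = (
        site_rates if site_rates is not None
        else _gamma_site_rates(rng, L, gamma_alpha)
    )
    p_site = rates / rates.sum()
    n_prop = rng.poisson(branch_length * L)
    if n_prop == 0:
        return sequence
    sites = rng.choice(L, size=n_prop, p=p_site)
    u_kind = rng.random(n_prop)
    u_tv = rng.integers(0, 2, n_prop)
    u_acc = rng.random(n_prop)
    p_ts = kappa / (kappa + 2.0)
    seq = list(sequence)
    for k in range(n_prop):
        i = int(sites[k])
        if i in protected:
            continue
        b = _ENC.get(seq[i], -1)
        if b < 0:
            continue
        if u_kind[k] < p_ts:
            nb = _TRANSITION[b]
        else:
            nb = _TRANSVERSIONS[b][u_tv[k]]
        c0 = 3 * (i // 3)
        old_codon = "".join(seq[c0: c0 + 3])
        new_codon = (
            old_codon[: i - c0] + _BASES[nb] + old_codon[i - c0 + 1:]
        )
        if new_codon in STOP_CODONS:
            continue
        if old_codon in STOP_CODONS:
            continue  # existing stops are structural; leave them alone
        w = float(omega_arr[i // 3])
        syn = translate_codon(old_codon) == translate_codon(new_codon)
        p_accept = min(1.0, 1.0 / w) if syn else min(1.0, w)
        if u_acc[k] <= p_accept:
            seq[i] = _BASES[nb]
    return "".join(seq)


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

def default_splice_menu() -> tuple[tuple[tuple[SpliceEvent, ...], float], ...]:
    """Event menu: (events, weight) with exons given as template slots."""
    return (
        ((SpliceEvent("exon_skip", D2_SLOT),), 0.20),
        ((SpliceEvent("exon_skip", D0A_SLOT),), 0.15),
        ((SpliceEvent("alt_acceptor", D1_SLOT, offset=36),), 0.20),
        ((SpliceEvent("exon_skip", STEM_SLOT),), 0.10),
        ((SpliceEvent("exon_skip", STEM_SLOT),
          SpliceEvent("exon_skip", TM_SLOT)), 0.15),
        ((SpliceEvent("alt_donor", TM_SLOT, offset=4),), 0.10),
        ((SpliceEvent("intron_retention", TM_SLOT, offset=45),), 0.10),
    )


@dataclass
class SimulationParams:
    n_loci: int = 10
    alleles_per_locus: dict = field(
        default_factory=lambda: {1: 0.2, 2: 0.5, 3: 0.2, 4: 0.1}
    )
    inter_locus_divergence: float = 0.08
    intra_locus_theta: float = 0.004
    kappa: float = 4.0
    gamma_alpha: float | None = 1.0
    omega_default: float = 0.2
    omega_patches: tuple = ()        # (start_codon0, end_codon0, omega)
    p_variant: float = 0.35
    p_4d: float = 0.2
    class_probs: dict = field(
        default_factory=lambda: {
            "inhibitory": 0.6, "activating": 0.2, "putative_activating": 0.2
        }
    )
    splice_event_menu: tuple = field(default_factory=default_splice_menu)
    recombination_events: tuple = ()  # (donor locus, acceptor locus, s, e)
    n_individuals: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 < self.inter_locus_divergence < 0.5:
            raise ValueError("inter_locus_divergence must be in (0, 0.5)")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        total = sum(self.alleles_per_locus.values())
        if not np.isclose(total, 1.0):
            raise ValueError("alleles_per_locus probabilities must sum to 1")


@dataclass
class SequenceTruth:
    id: str
    locus: int
    allele: int
    events: list[SpliceEvent]
    receptor_class: str
    configuration: str
    individual: str


@dataclass
class TruthTable:
    sequences: list[SequenceTruth]
    locus_classes: dict[int, str]
    locus_4d: dict[int, bool]
    omega_by_codon: list[float]
    recombination: list[dict]

    def by_id(self) -> dict[str, SequenceTruth]:
        return {s.id: s for s in self.sequences}

    def to_json(self, path: str | Path) -> None:
        data = {
            "sequences": [
                {
                    "id": s.id, "locus": s.locus, "allele": s.allele,
                    "events": [
                        {"type": e.type, "exon": e.exon, "offset": e.offset,
                         "nt_delta": e.nt_delta, "in_frame": e.in_frame,
                         "ptc": e.ptc}
                        for e in s.events
                    ],
                    "receptor_class": s.receptor_class,
                    "configuration": s.configuration,
                    "individual": s.individual,
                }
                for s in self.sequences
            ],
            "locus_classes": self.locus_classes,
            "locus_4d": self.locus_4d,
            "omega_by_codon": self.omega_by_codon,
            "recombination": self.recombination,
        }
        Path(path).write_text(json.dumps(data, indent=1))


@dataclass
class FamilySimulation:
    transcripts: list[Transcript]
    models: list[ExonModel]
    truth: TruthTable
    template: ExonModel


# ---------------------------------------------------------------------------
# locus tree
# ---------------------------------------------------------------------------

def _locus_tree(
    n: int, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    """Random duplication history with ancient splits.

    Returns merge operations [(i, j, depth)] over node indices (leaves are
    0..n-1); leaves sit at depth 0, so a leaf-pair path length is twice the
    depth of the pair's most recent common ancestor. Split depths are drawn
    deep (uniform on [0.4, 1]) so individual loci stay well separated, as
    under birth-and-death evolution with old duplications.
    """
    depths = np.sort(rng.uniform(0.4, 1.0, n - 1))
    active = list(range(n))
    merges = []
    nxt = n
    for d in depths:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        merges.append((a, b, float(d)))
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [nxt]
        nxt += 1
    return merges


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def _omega_array(params: SimulationParams, n_codons: int) -> np.ndarray:
    omega = np.full(n_codons, params.omega_default)
    for start, end, w in params.omega_patches:
        omega[start:end] = w
    return omega


def _evolve_tree(
    root_seq: str,
    merges: list[tuple[int, int, float]],
    n: int,
    scale: float,
    params: SimulationParams,
    omega: np.ndarray,
    protected: frozenset[int],
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> list[str]:
    """Sequences at the leaves of the merge tree (template coordinates)."""
    if n == 1:
        return [root_seq]
    # rebuild child lists and depths from merges
    children: dict[int, tuple[int, int]] = {}
    depth = {i: 0.0 for i in range(n)}
    for k, (a, b, d) in enumerate(merges):
        node = n + k
        children[node] = (a, b)
        depth[node] = d
    root = n + len(merges) - 1
    seqs: dict[int, str] = {root: root_seq}
    for node in range(root, n - 1, -1):
        a, b = children[node]
        for child in (a, b):
            t = (depth[node] - depth[child]) * scale
            seqs[child] = evolve_coding(
                seqs[node], t, params.kappa, omega, rng,
                params.gamma_alpha, protected, site_rates,
            )
    return [seqs[i] for i in range(n)]


def _calibration_factor(
    template_cdna: str,
    params: SimulationParams,
    omega: np.ndarray,
    protected: frozenset[int],
    rng: np.random.Generator,
) -> float:
    """Proposal-to-substitution inflation factor.

    Selection and protected positions make realized divergence fall short of
    the proposal branch length; two probe lineages measure the shortfall so
    all branch lengths can be pre-scaled.
    """
    from .phylo import k2p_distance

    t_probe = 0.05
    realized = []
    for _ in range(4):
        rates = _gamma_site_rates(rng, len(template_cdna), params.gamma_alpha)
        a = evolve_coding(template_cdna, t_probe, params.kappa, omega, rng,
                          params.gamma_alpha, protected, rates)
        b = evolve_coding(template_cdna, t_probe, params.kappa, omega, rng,
                          params.gamma_alpha, protected, rates)
        realized.append(k2p_distance(a, b).d)
    mean_realized = float(np.mean(realized))
    if mean_realized <= 0:
        raise ValueError("calibration probe produced no divergence")
    return 2.0 * t_probe / mean_realized


_CHARGED = {"R", "K"}


def _locus_feature_edits(
    seq: str, cls: str, feats: dict[str, list[int]]
) -> str:
    """Impose the receptor-class-defining codons on a locus ancestor."""
    s = list(seq)

    def put(positions: list[int], codons: tuple[str, ...]) -> None:
        for k, codon in enumerate(codons):
            base = positions[3 * k]
            s[base: base + 3] = list(codon)

    put(feats["start"], ("ATG",))
    put(feats["stop"], ("TAA",))
    put(feats["itim1"], ITIM1_CODONS)
    put(feats["itim2"], ITIM2_CODONS)
    put(feats["acceptor_anchor"], ("AAG",))
    put(feats["donor_anchor"], ("CTG", "TTC"))
    put(feats["tm4"], ("GCT",))
    put(feats["tm11"], ("CTG",))
    put(feats["tm13"], ("CTG",))
    if cls == "activating":
        put(feats["tm4"], ("CGT",))            # charged R at TM position 4
        put(feats["itim1"][6:9], ("TTC",))     # first ITIM tyrosine -> F
        put(feats["early_stop"], ("TAA",))     # short cytoplasmic tail
    elif cls == "putative_activating":
        put(feats["tm11"], ("CCT",))           # proline 11
        put(feats["tm13"], ("ACT",))           # threonine 13
        put(feats["itim1"][6:9], ("TTC",))
        put(feats["early_stop"], ("TAA",))
    return "".join(s)


def _drop_d0b(seq: str, template: ExonModel) -> str:
    offs = {
        e.template_slot: span
        for e, span in zip(template.exons, template.exon_offsets())
    }
    s, t = offs[D0B_SLOT]
    return seq[:s] + seq[t:]


def _locus_model(
    locus_label: str, ancestor: str, template: ExonModel, is_4d: bool
) -> ExonModel:
    exons = []
    introns = []
    pos = 0
    idx = 0
    for k, e in enumerate(template.exons):
        if e.template_slot == D0B_SLOT and not is_4d:
            continue
        idx += 1
        exons.append(
            Exon(index=idx, sequence=ancestor[pos: pos + len(e.sequence)],
                 domain=e.domain, phase=0, template_slot=e.template_slot)
        )
        pos += len(e.sequence)
    kept_slots = [e.template_slot for e in exons]
    for a, b in zip(kept_slots[:-1], kept_slots[1:]):
        # the intron following template slot a on the kept path; when D0b is
        # absent, use the intron that precedes D1 in the template
        donor_slot = a if (a != D0A_SLOT or b != D1_SLOT) else D0B_SLOT
        introns.append(template.introns[donor_slot - 1])
    return ExonModel(locus=locus_label, exons=exons, introns=introns)


@dataclass
class _Layout:
    """Retained-exon layout of a (possibly spliced) transcript."""
    segments: list[tuple[int, int, int, int, int]]
    # (template_slot, var_start, var_end, trim5, trim3)
    length: int


def _variant_layout(
    model: ExonModel, events: list[SpliceEvent]
) -> _Layout:
    skip = {e.exon for e in events if e.type == "exon_skip"}
    trim5 = {e.exon: e.offset for e in events if e.type == "alt_acceptor"}
    trim3 = {e.exon: e.offset for e in events if e.type == "alt_donor"}
    retain = {e.exon: e.offset for e in events if e.type == "intron_retention"}
    segs = []
    pos = 0
    for e in model.exons:
        if e.index in skip:
            continue
        t5 = trim5.get(e.index, 0)
        t3 = trim3.get(e.index, 0)
        kept = len(e.sequence) - t5 - t3
        segs.append((e.template_slot, pos, pos + kept, t5, t3))
        pos += kept
        if e.index in retain:
            length = retain[e.index] or len(model.introns[e.index - 1].sequence)
            pos += length
    return _Layout(segments=segs, length=pos)


def _classify_truth(
    variant_seq: str, model: ExonModel, events: list[SpliceEvent], cls: str,
    is_4d: bool,
) -> tuple[str, str]:
    """(receptor class, configuration) from the known structure."""
    layout = _variant_layout(model, events)
    stop = find_stop(variant_seq)
    stop_nt = stop if stop is not None else len(variant_seq)
    seg_by_slot = {s[0]: s for s in layout.segments}
    exon_len = {e.template_slot: len(e.sequence) for e in model.exons}

    def in_frame_at(slot: int, nt_in_exon: int, length: int) -> bool:
        seg = seg_by_slot.get(slot)
        if seg is None:
            return False
        _, vs, ve, t5, _ = seg
        if nt_in_exon < t5 or nt_in_exon + length > t5 + (ve - vs):
            return False
        pos = vs + nt_in_exon - t5
        return pos % 3 == 0 and pos + length <= stop_nt

    # transmembrane region
    tm_seg = seg_by_slot.get(TM_SLOT)
    tm_present = False
    tm_end_aa = 0
    if tm_seg is not None:
        _, vs, ve, t5, _ = tm_seg
        usable = min(ve, stop_nt) - vs
        tm_present = vs % 3 == 0 and usable >= 2 * exon_len[TM_SLOT] // 3
        tm_end_aa = min(ve, stop_nt) // 3
    prot_len = stop_nt // 3
    tail = prot_len - tm_end_aa if tm_present else 0
    # intact ITIMs (the tyrosine is disrupted in activating-type loci)
    itims_ok = cls == "inhibitory" and (
        in_frame_at(CYT1_SLOT, 3 * ITIM1_AT[1], 18)
        or in_frame_at(CYT2_SLOT, 3 * ITIM2_AT[1], 18)
    )
    charged = cls == "activating" and in_frame_at(TM_SLOT, 9, 3)
    pt_anchor = cls == "putative_activating" and (
        in_frame_at(TM_SLOT, 30, 3) and in_frame_at(TM_SLOT, 36, 3)
    )
    if not tm_present:
        rec = "soluble"
    elif tail >= 40 and itims_ok:
        rec = "inhibitory"
    elif tail < 40 and charged:
        rec = "activating"
    elif tail < 40 and pt_anchor:
        rec = "putative_activating"
    else:
        rec = "ambiguous"
    # configuration: Ig domains with at least half their exon in frame
    n_ig = 0
    for slot in IG_SLOTS:
        if slot == D0B_SLOT and not is_4d:
            continue
        seg = seg_by_slot.get(slot)
        if seg is None:
            continue
        _, vs, ve, _, _ = seg
        if vs % 3 == 0 and min(ve, stop_nt) - vs >= exon_len[slot] // 2:
            n_ig += 1
    letter = "L" if (tm_present and tail >= 40) else "S"
    return rec, f"{n_ig}D{letter}"


def simulate_family(params: SimulationParams) -> FamilySimulation:
    """Generate a KIR-like family with transcripts, exon models and truth.

    Deterministic for a given params.seed. Raises if the divergence target
    is unreachable.
    """
    root = np.random.default_rng(params.seed)
    rng_template = np.random.default_rng(root.integers(2**31))
    rng_probe = np.random.default_rng(root.integers(2**31))
    rng_tree = np.random.default_rng(root.integers(2**31))
    rng_evolve = np.random.default_rng(root.integers(2**31))
    rng_alleles = np.random.default_rng(root.integers(2**31))
    rng_assign = np.random.default_rng(root.integers(2**31))

    template = build_template(rng_template)
    cdna = template.cdna
    feats = template_feature_positions(template)
    protected = frozenset(p for ps in feats.values() for p in ps)
    omega = _omega_array(params, len(cdna) // 3)

    factor = _calibration_factor(cdna, params, omega, protected, rng_probe)
    # per-site rates fixed for the whole family history
    site_rates = _gamma_site_rates(rng_evolve, len(cdna), params.gamma_alpha)

    n = params.n_loci
    if n > 1:
        merges = _locus_tree(n, rng_tree)
        # normalize so the mean leaf-pair path length is 1, then scale to the
        # divergence target (pre-inflated for selective rejection)
        norm = _mean_pair_depth(merges, n)
        merges = [(a, b, d / norm) for (a, b, d) in merges]
        ancestors = _evolve_tree(
            cdna, merges, n, params.inter_locus_divergence * factor,
            params, omega, protected, rng_evolve, site_rates,
        )
    else:
        ancestors = [cdna]

    # implant recombinant fragments between locus ancestors
    recomb_truth = []
    for donor, acceptor, s, e in params.recombination_events:
        if not (1 <= donor <= n and 1 <= acceptor <= n):
            raise ValueError("recombination event locus out of range")
        da, aa = ancestors[donor - 1], ancestors[acceptor - 1]
        ancestors[acceptor - 1] = aa[:s] + da[s:e] + aa[e:]
        recomb_truth.append(
            {"donor_locus": donor, "acceptor_locus": acceptor,
             "start": s, "end": e}
        )

    classes = list(params.class_probs)
    class_p = np.array([params.class_probs[c] for c in classes])
    locus_classes: dict[int, str] = {}
    locus_4d: dict[int, bool] = {}
    models: list[ExonModel] = []
    transcripts: list[Transcript] = []
    truths: list[SequenceTruth] = []

    counts = sorted(params.alleles_per_locus)
    count_p = np.array([params.alleles_per_locus[c] for c in counts])
    menu = params.splice_event_menu
    menu_p = np.array([w for _, w in menu], dtype=float)
    menu_p = menu_p / menu_p.sum()

    offs = {
        e.template_slot: sp
        for e, sp in zip(template.exons, template.exon_offsets())
    }
    s_d0b, t_d0b = offs[D0B_SLOT]
    width = t_d0b - s_d0b
    prot_3d = frozenset(
        p - width if p >= t_d0b else p
        for p in protected
        if not (s_d0b <= p < t_d0b)
    )
    omega_3d = np.concatenate([omega[: s_d0b // 3], omega[t_d0b // 3:]])

    for locus in range(1, n + 1):
        cls = classes[rng_assign.choice(len(classes), p=class_p)]
        is_4d = bool(rng_assign.random() < params.p_4d)
        locus_classes[locus] = cls
        locus_4d[locus] = is_4d
        anc = _locus_feature_edits(ancestors[locus - 1], cls, feats)
        anc_em = anc if is_4d else _drop_d0b(anc, template)
        model = _locus_model(f"locus{locus:02d}", anc_em, template, is_4d)
        models.append(model)
        n_alleles = counts[rng_assign.choice(len(counts), p=count_p)]
        prot_em = protected if is_4d else prot_3d
        omega_em = omega if is_4d else omega_3d
        rates_em = site_rates if is_4d else np.concatenate(
            [site_rates[:s_d0b], site_rates[t_d0b:]]
        )
        for allele in range(1, n_alleles + 1):
            t_allele = params.intra_locus_theta / 2.0 * factor
            seq = evolve_coding(
                anc_em, t_allele, params.kappa, omega_em, rng_alleles,
                params.gamma_alpha, prot_em, rates_em,
            )
            indiv = f"AV{int(rng_assign.integers(1, params.n_individuals + 1)):02d}"
            tid = f"KIRL{locus:02d}A{allele:02d}"
            tr = Transcript(id=tid, sequence=seq, individual=indiv)
            rec, conf = _classify_truth(seq, model, [], cls, is_4d)
            transcripts.append(tr)
            truths.append(
                SequenceTruth(tid, locus, allele, [], rec, conf, indiv)
            )
            if rng_assign.random() < params.p_variant:
                choice = int(rng_assign.choice(len(menu), p=menu_p))
                slot_events = menu[choice][0]
                events = []
                ok = True
                for ev in slot_events:
                    exon = next(
                        (e.index for e in model.exons
                         if e.template_slot == ev.exon), None
                    )
                    if exon is None:
                        ok = False
                        break
                    events.append(
                        SpliceEvent(ev.type, exon, offset=ev.offset)
                    )
                if not ok:
                    continue
                vid = f"{tid}V1"
                var, realized = apply_splice_event(tr, model, events, vid)
                rec_v, conf_v = _classify_truth(
                    var.sequence, model, events, cls, is_4d
                )
                transcripts.append(var)
                truths.append(
                    SequenceTruth(vid, locus, allele, realized, rec_v,
                                  conf_v, indiv)
                )

    truth = TruthTable(
        sequences=truths,
        locus_classes=locus_classes,
        locus_4d=locus_4d,
        omega_by_codon=list(map(float, omega)),
        recombination=recomb_truth,
    )
    return FamilySimulation(transcripts, models, truth, template)


def _mean_pair_depth(merges: list[tuple[int, int, float]], n: int) -> float:
    """Mean over leaf pairs of 2 * depth(MRCA) for the merge sequence."""
    leaves_below: dict[int, list[int]] = {i: [i] for i in range(n)}
    total = 0.0
    count = 0
    for k, (a, b, d) in enumerate(merges):
        node = n + k
        for la in leaves_below[a]:
            for lb in leaves_below[b]:
                total += 2 * d
                count += 1
        leaves_below[node] = leaves_below[a] + leaves_below[b]
    return total / count if count else 1.0


# ---------------------------------------------------------------------------
# small helpers used by selection/recombination calibration studies
# ---------------------------------------------------------------------------

def simulate_coding_tree(
    n_taxa: int,
    n_codons: int,
    branch_length: float,
    omega: float | np.ndarray,
    kappa: float = 4.0,
    seed: int = 0,
) -> tuple[Alignment, dendropy.Tree]:
    """Coding alignment evolved on a balanced tree, plus that tree.

    Useful for calibration studies: every codon's selection class is known.
    """
    rng = np.random.default_rng(seed)
    root_codons = _random_codons(rng, n_codons)
    root_seq = "".join(root_codons)
    # balanced bifurcating topology over n_taxa
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    newick = _balanced_newick(labels, branch_length)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    seqs: dict[str, str] = {}

    def descend(node, seq):
        t = node.edge.length or 0.0
        out = evolve_coding(seq, t, kappa, omega, rng) if t > 0 else seq
        if node.is_leaf():
            seqs[node.taxon.label] = out
        else:
            for child in node.child_nodes():
                descend(child, out)

    descend(tree.seed_node, root_seq)
    members = [Transcript(id=lab, sequence=seqs[lab]) for lab in labels]
    return Alignment(members), tree


def _balanced_newick(labels: list[str], b: float) -> str:
    nodes = [f"{lab}:{b}" for lab in labels]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(f"({nodes[i]},{nodes[i + 1]}):{b}")
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0] + ";"
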