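"""End-to-end workflow: characterization -> phylogeny -> diversity/selection
-> recombination.

Stages mirror the study design: transcripts are collapsed for clone
evidence, mapped to exon models and annotated; a family alignment is built
by projecting every transcript onto the shared exon-template coordinate
system; a bootstrap NJ tree drives locus calling and naming; per-domain and
per-locus diversity tables, per-domain dN/dS with codon Z-tests, per-site
selection calls and a MaxChi recombination scan complete the report bundle.
Deterministic for a given configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as kio
from .annotation import ReceptorAnnotation, annotate_transcript, identity_layout
from .config import PipelineConfig
from .diversity import diversity_stats
from .genemodel import ExonModel, SpliceEvent, models_from_json
from .nomenclature import (
    KirName,
    LocusAssignment,
    NomenclatureRegistry,
    assign_loci,
)
from .phylo import bootstrap_supports, distance_matrix, nj_tree
from .records import Alignment, Transcript
from .recombination import consolidate_fragments, maxchi_scan
from .selection import codon_z_test, dn_ds, site_selection_counting
from .splicing import MappingError, infer_splice_variants, map_to_exons

logger = logging.getLogger(__name__)

#: master-alignment domain groups: domain -> template slots
DOMAIN_SLOTS = {
    "D0a": (3,), "D0b": (4,), "D1": (5,), "D2": (6,), "STC": (7, 8, 9, 10),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class TranscriptRecord:
    transcript: Transcript
    annotation: ReceptorAnnotation
    events: list[SpliceEvent]
    model_locus: str | None
    evidence: int = 1


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[TranscriptRecord]
    annotation_table: pd.DataFrame
    assignments: list[LocusAssignment]
    names: dict[str, KirName]
    master_alignment: Alignment | None
    tree: dendropy.Tree | None
    domain_trees: dict[str, dendropy.Tree] = field(default_factory=dict)
    diversity_domains: pd.DataFrame | None = None
    diversity_loci: pd.DataFrame | None = None
    selection_table: pd.DataFrame | None = None
    site_calls: pd.DataFrame | None = None
    recombination: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.annotation_table.to_csv(
            out / "annotations.tsv", sep="\t", index=False
        )
        if self.tree is not None:
            kio.write_newick(self.tree, out / "tree.nwk")
        for name, t in self.domain_trees.items():
            kio.write_newick(t, out / f"tree_{name}.nwk")
        for attr, fname in (
            ("diversity_domains", "diversity_domains.tsv"),
            ("diversity_loci", "diversity_loci.tsv"),
            ("selection_table", "selection.tsv"),
            ("site_calls", "site_selection.tsv"),
            ("recombination", "recombination.tsv"),
        ):
            df = getattr(self, attr)
            if df is not None:
                df.to_csv(out / fname, sep="\t", index=False)
        self.config.to_yaml(out / "config_echo.yaml")


def collapse_clones(
    transcripts: list[Transcript], min_evidence: int
) -> list[tuple[Transcript, int]]:
    """Collapse identical clone sequences and apply the evidence filter.

    A sequence is kept when seen at least ``min_evidence`` times or in two
    or more individuals. Inputs with no duplicate sequences are treated as
    already collapsed and pass through unfiltered.
    """
    groups: dict[str, list[Transcript]] = {}
    order: list[str] = []
    for t in transcripts:
        if t.sequence not in groups:
            order.append(t.sequence)
        groups.setdefault(t.sequence, []).append(t)
    # clone-level inputs (many reads per unique sequence) engage the
    # evidence filter; unique-transcript inputs pass through, since a
    # coincidental duplicate does not make the set clone data
    if len(transcripts) < 1.5 * len(groups):
        return [(t, 1) for t in transcripts]
    out = []
    for seq in order:
        g = groups[seq]
        individuals = {t.individual for t in g if t.individual}
        evidence = len(g)
        if evidence >= min_evidence or len(individuals) >= 2:
            out.append((g[0], evidence))
        else:
            logger.info("dropped %s: evidence %d < %d",
                        g[0].id, evidence, min_evidence)
    return out


def _map_transcript(
    transcript: Transcript, models: list[ExonModel]
):
    """Best model mapping with a fast path for unspliced transcripts."""
    for model in models:
        cdna = model.cdna
        if len(cdna) == len(transcript):
            same = sum(
                1 for a, b in zip(cdna, transcript.sequence) if a == b
            )
            if same / len(cdna) >= 0.97:
                mapping = map_to_exons(transcript, model)
                return mapping, []
    return infer_splice_variants(transcript, models)


def _master_layout(models: list[ExonModel]) -> dict[int, tuple[int, int]]:
    """slot -> (offset, length) in family-wide master coordinates."""
    slot_len: dict[int, int] = {}
    for m in models:
        for e in m.exons:
            slot = e.template_slot if e.template_slot is not None else e.index
            slot_len.setdefault(slot, len(e.sequence))
    offsets = {}
    pos = 0
    for slot in sorted(slot_len):
        offsets[slot] = (pos, slot_len[slot])
        pos += slot_len[slot]
    return offsets


def _project(
    rec: TranscriptRecord, mapping, master: dict[int, tuple[int, int]]
) -> str:
    total = sum(length for _, length in master.values())
    row = ["-"] * total
    model = mapping.model
    slot_of = {
        e.index: (e.template_slot if e.template_slot is not None else e.index)
        for e in model.exons
    }
    seq = rec.transcript.sequence
    for exon_idx, vs, ve, t5, _t3 in mapping.layout():
        slot = slot_of[exon_idx]
        off, length = master[slot]
        start = off + t5
        seg = seq[vs:ve]
        seg = seg[: max(0, length - t5)]
        row[start: start + len(seg)] = list(seg)
    return "".join(row)


def run_pipeline(
    config: PipelineConfig,
    transcripts: list[Transcript] | str | Path,
    models: list[ExonModel] | str | Path,
    out_dir: str | Path | None = None,
    prefix: str = "SYN",
) -> PipelineResult:
    """Run every stage; any stage failure aborts naming the stage."""
    stage = "load"
    try:
        if not isinstance(transcripts, list):
            transcripts = kio.read_fasta(transcripts)
        if not isinstance(models, list):
            models = models_from_json(models)
        if not transcripts:
            raise ValueError("no input transcripts")
        if not models:
            raise ValueError("no exon models")

        stage = "collapse"
        kept = collapse_clones(transcripts, config.min_evidence_count)
        logger.info("stage=collapse in=%d out=%d", len(transcripts), len(kept))

        stage = "annotate"
        records: list[TranscriptRecord] = []
        mappings = {}
        for t, evidence in kept:
            try:
                mapping, events = _map_transcript(t, models)
            except MappingError as exc:
                logger.warning("unmapped transcript %s: %s", t.id, exc)
                ann = annotate_transcript(t, min_length_aa=config.min_orf_aa)
                records.append(TranscriptRecord(t, ann, [], None, evidence))
                continue
            ann = annotate_transcript(
                t, mapping.model, mapping.layout(), events,
                min_length_aa=config.min_orf_aa,
            )
            records.append(
                TranscriptRecord(t, ann, events, mapping.model.locus, evidence)
            )
            mappings[t.id] = mapping
        logger.info("stage=annotate in=%d out=%d", len(kept), len(records))

        stage = "align"
        master = _master_layout(models)
        rows = []
        aligned_records = []
        for rec in records:
            if rec.transcript.id in mappings:
                rows.append(
                    Transcript(
                        id=rec.transcript.id,
                        sequence=_project(rec, mappings[rec.transcript.id],
                                          master),
                        individual=rec.transcript.individual,
                    )
                )
                aligned_records.append(rec)
        master_aln = Alignment(rows) if rows else None

        stage = "tree"
        tree = None
        distances = None
        if master_aln is not None and len(master_aln) >= 3:
            distances = distance_matrix(
                master_aln, "k2p", gap_policy="pairwise_deletion"
            )
            tree = bootstrap_supports(
                master_aln, "k2p", reps=config.bootstrap_reps,
                seed=config.rng_seed, gap_policy="pairwise_deletion",
            )
        elif master_aln is not None:
            distances = distance_matrix(
                master_aln, "k2p", gap_policy="pairwise_deletion"
            )

        stage = "loci"
        if tree is not None:
            assignments = assign_loci(
                tree, distances, config.locus_distance_threshold,
                config.support_threshold,
            )
        elif master_aln is not None:
            assignments = _linkage_clusters(
                distances, config.locus_distance_threshold
            )
        else:
            assignments = []
        locus_of = {a.transcript_id: a.locus for a in assignments}
        logger.info("stage=loci clusters=%d",
                    len({a.locus for a in assignments}))

        stage = "naming"
        registry = NomenclatureRegistry(prefix=prefix)
        names: dict[str, KirName] = {}
        by_rec = {r.transcript.id: r for r in records}
        ordered = sorted(
            [r for r in records if r.transcript.id in locus_of],
            key=lambda r: (locus_of[r.transcript.id],
                           bool(r.events), r.transcript.id),
        )
        allele_of: dict[str, int] = {}
        for rec in ordered:
            tid = rec.transcript.id
            locus = locus_of[tid]
            if not rec.events:
                num = registry.register_allele(locus, tid, rec.annotation.protein)
                allele_of[tid] = num
                names[tid] = registry.name_allele(locus, num, rec.annotation)
            else:
                parent = _nearest_allele(tid, locus, locus_of, allele_of,
                                         distances)
                names[tid] = registry.register_variant(
                    locus, parent, tid, rec.events, rec.annotation
                )

        stage = "diversity"
        div_domains = div_loci = None
        if master_aln is not None:
            div_domains = _domain_diversity(master_aln, by_rec, master, config)
            div_loci = _locus_diversity(master_aln, by_rec, locus_of, config)

        stage = "selection"
        sel_table = site_df = None
        if master_aln is not None and len(master_aln) >= 3:
            sel_table, site_df = _selection_tables(
                master_aln, by_rec, master, tree, config
            )

        stage = "recombination"
        recomb_df = None
        if master_aln is not None and len(master_aln) >= 2:
            alleles_only = [
                t for t in master_aln.members if not by_rec[t.id].events
            ]
            if len(alleles_only) >= 2:
                sub = Alignment(alleles_only)
                candidates = maxchi_scan(
                    sub, permutations=config.recombination_permutations,
                    seed=config.rng_seed,
                    correction=config.recombination_correction,
                )
                frags = consolidate_fragments(
                    candidates, config.recombination_p_max
                )
                recomb_df = pd.DataFrame(
                    [
                        {"recombinant": f.recombinant,
                         "minor_parent": f.minor_parent,
                         "major_parent": f.major_parent,
                         "start": f.start + 1, "end": f.end + 1,
                         "p": f.p, "method": f.method}
                        for f in frags
                    ],
                    columns=["recombinant", "minor_parent", "major_parent",
                             "start", "end", "p", "method"],
                )

        stage = "report"
        ann_table = _annotation_table(records, locus_of, names)
        result = PipelineResult(
            config=config,
            records=records,
            annotation_table=ann_table,
            assignments=assignments,
            names=names,
            master_alignment=master_aln,
            tree=tree,
            diversity_domains=div_domains,
            diversity_loci=div_loci,
            selection_table=sel_table,
            site_calls=site_df,
            recombination=recomb_df,
        )
        if out_dir is not None:
            result.write(out_dir)
        return result
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc


def _linkage_clusters(
    distances: pd.DataFrame, threshold: float
) -> list[LocusAssignment]:
    """Single-linkage fallback when a tree cannot be built (< 3 taxa)."""
    ids = list(distances.index)
    cluster: dict[str, int] = {}
    next_label = 1
    for tid in ids:
        placed = None
        for other, lab in cluster.items():
            if distances.loc[tid, other] <= threshold:
                placed = lab
                break
        if placed is None:
            placed = next_label
            next_label += 1
        cluster[tid] = placed
    return [
        LocusAssignment(tid, lab, 0.0, None, None)
        for tid, lab in cluster.items()
    ]


def _nearest_allele(
    tid: str, locus: int, locus_of: dict[str, int],
    allele_of: dict[str, int], distances: pd.DataFrame | None,
) -> int:
    peers = [
        other for other, num in allele_of.items() if locus_of[other] == locus
    ]
    if not peers:
        return 1
    if distances is None or tid not in distances.index:
        return allele_of[peers[0]]
    best = min(peers, key=lambda o: float(distances.loc[tid, o]))
    return allele_of[best]


def _annotation_table(
    records: list[TranscriptRecord],
    locus_of: dict[str, int],
    names: dict[str, KirName],
) -> pd.DataFrame:
    rows = []
    for rec in records:
        ann = rec.annotation
        tid = rec.transcript.id
        rows.append(
            {
                "transcript": tid,
                "individual": rec.transcript.individual or "",
                "evidence": rec.evidence,
                "model": rec.model_locus or "",
                "locus": locus_of.get(tid, ""),
                "name": str(names[tid]) if tid in names else "",
                "orf_start": ann.orf_start,
                "orf_end": ann.orf_end,
                "protein_length": len(ann.protein),
                "no_start": ann.no_start,
                "configuration": ann.configuration,
                "tail_class": ann.tail_class,
                "receptor_class": ann.receptor_class,
                "n_itims": len(ann.itims),
                "itims": ";".join(f"{m}@{p}" for m, p in ann.itims),
                "tm": (f"{ann.tm[0]}-{ann.tm[1]}" if ann.tm else ""),
                "charged_tm_residue": (
                    f"{ann.charged_tm_residue[0]}@{ann.charged_tm_residue[1]}"
                    if ann.charged_tm_residue else ""
                ),
                "events": ";".join(
                    f"{e.type}:exon{e.exon}:{e.nt_delta:+d}" for e in rec.events
                ),
                "ptc": next((e.ptc for e in rec.events if e.ptc), ""),
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float | None, nd: int = 3) -> str:
    return "-" if x is None else f"{x:.{nd}f}"


def _group_stats_row(
    label: str, aln: Alignment | None, config: PipelineConfig
) -> dict:
    st = diversity_stats(aln, config.gap_policy)
    return {
        "n": st.n, "Domain": label, "Sites": st.L if st.defined() else "-",
        "Ss": st.S if st.defined() else "-",
        "theta_w (SD)": (
            f"{_fmt(st.theta_w)} ({_fmt(st.theta_sd)})" if st.defined() else "-"
        ),
        "pi (SD)": (
            f"{_fmt(st.pi)} ({_fmt(st.pi_sd)})" if st.defined() else "-"
        ),
    }


def _domain_members(
    master_aln: Alignment, by_rec: dict, master: dict, domain: str
) -> dict[str, Alignment | None]:
    """Sub-alignments per reported domain group (STC split by tail)."""
    slots = [s for s in DOMAIN_SLOTS[domain] if s in master]
    if not slots:
        return {domain: None}
    cols = np.concatenate(
        [np.arange(master[s][0], master[s][0] + master[s][1]) for s in slots]
    )
    out: dict[str, Alignment | None] = {}

    def covered(t: Transcript) -> bool:
        seg = [t.sequence[c] for c in cols]
        return sum(1 for c in seg if c != "-") / len(seg) >= 0.9

    if domain == "STC":
        for tail, label in (("short", "STC-A"), ("long", "STC-I")):
            members = [
                t for t in master_aln.members
                if covered(t) and by_rec[t.id].annotation.tail_class == tail
            ]
            out[label] = (
                Alignment(members).take_columns(cols) if members else None
            )
    else:
        members = [t for t in master_aln.members if covered(t)]
        out[domain] = (
            Alignment(members).take_columns(cols) if members else None
        )
    return out


def _domain_diversity(
    master_aln: Alignment, by_rec: dict, master: dict, config: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for domain in ("D0a", "D0b", "D1", "D2", "STC"):
        for label, aln in _domain_members(
            master_aln, by_rec, master, domain
        ).items():
            try:
                rows.append(_group_stats_row(label, aln, config))
            except ValueError:  # e.g. every column gapped in the group
                rows.append(_group_stats_row(label, None, config))
    return pd.DataFrame(rows)


def _locus_diversity(
    master_aln: Alignment, by_rec: dict, locus_of: dict, config: PipelineConfig
) -> pd.DataFrame:
    rows = []
    loci = sorted({locus_of[t.id] for t in master_aln.members
                   if t.id in locus_of})
    for locus in loci:
        members = [
            t for t in master_aln.members if locus_of.get(t.id) == locus
        ]
        # drop all-gap columns for this locus before statistics
        aln = Alignment(members)
        m = aln.to_matrix()
        keep = ~(m == b"-").all(axis=0)
        aln = aln.take_columns(np.flatnonzero(keep))
        alleles = {
            by_rec[t.id].annotation.protein
            for t in members if not by_rec[t.id].events
        }
        variants = {
            by_rec[t.id].annotation.protein
            for t in members if by_rec[t.id].events
        }
        np_str = (
            f"{len(alleles) + len(variants)}"
            f"({len(alleles)}a,{len(variants)}b)"
        )
        try:
            row = _group_stats_row(f"KIR{locus}", aln if len(aln) >= 2 else None,
                                   config)
        except ValueError:
            row = _group_stats_row(f"KIR{locus}", None, config)
        row["n"] = len(members)
        row["NP"] = np_str
        row = {
            "n": row["n"], "Gene": row["Domain"], "Sites": row["Sites"],
            "Ss": row["Ss"], "NP": np_str,
            "theta_w (SD)": row["theta_w (SD)"], "pi (SD)": row["pi (SD)"],
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _selection_tables(
    master_aln: Alignment, by_rec: dict, master: dict,
    tree: dendropy.Tree | None, config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    rows = []
    site_df = None
    # per-site calls on the full coding master alignment
    if tree is not None:
        calls = site_selection_counting(
            master_aln, tree, p_max=config.site_test_p_max
        )
        site_df = pd.DataFrame(
            [
                {"codon": c.position, "class": c.call, "p": c.p,
                 "N_changes": round(c.n_changes, 3),
                 "S_changes": round(c.s_changes, 3)}
                for c in calls if c.call != "neutral"
            ],
            columns=["codon", "class", "p", "N_changes", "S_changes"],
        )
    positive_by_codon = (
        set(site_df[site_df["class"] == "positive"]["codon"])
        if site_df is not None else set()
    )
    for domain in ("D0a", "D0b", "D1", "D2", "STC"):
        slots = [s for s in DOMAIN_SLOTS[domain] if s in master]
        if not slots:
            continue
        codon_lo = min(master[s][0] for s in slots) // 3 + 1
        codon_hi = max(master[s][0] + master[s][1] for s in slots) // 3
        for label, aln in _domain_members(
            master_aln, by_rec, master, domain
        ).items():
            if aln is None or len(aln) < 2:
                rows.append({"Domain": label, "n": 0 if aln is None else len(aln),
                             "dN (SE)": "-", "dS (SE)": "-", "Z": "-",
                             "p": "-", "positive_sites": ""})
                continue
            res = dn_ds(
                aln, bootstrap_reps=config.dnds_bootstrap_reps,
                seed=config.rng_seed, scope=label,
            )
            if res.dN is None or res.dN_se is None or res.dS_se is None \
                    or res.dN_se <= 0 or res.dS_se <= 0:
                z_str = p_str = "-"
            else:
                Z, p = codon_z_test(res.dN, res.dS, res.dN_se, res.dS_se,
                                    "purifying")
                z_str, p_str = f"{Z:.3f}", f"{p:.4f}"
            pos_sites = sorted(
                c for c in positive_by_codon if codon_lo <= c <= codon_hi
            )
            rows.append(
                {
                    "Domain": label, "n": len(aln),
                    "dN (SE)": (
                        f"{_fmt(res.dN)} ({_fmt(res.dN_se)})"
                        if res.dN is not None else "-"
                    ),
                    "dS (SE)": (
                        f"{_fmt(res.dS)} ({_fmt(res.dS_se)})"
                        if res.dS is not None else "-"
                    ),
                    "Z": z_str, "p": p_str,
                    "positive_sites": ", ".join(map(str, pos_sites)),
                }
            )
    return pd.DataFrame(rows), site_df
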