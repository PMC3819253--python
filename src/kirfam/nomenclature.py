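"""Putative-locus calling and IPD-KIR-style naming.

Loci are maximal clades of the (midpoint-rooted) tree whose intra-clade
maximum distance stays below a threshold chosen between observed intra-locus
polymorphism and inter-paralog divergence, with the separating branch
required to hold bootstrap support when supports are present. Names follow
the <prefix>KIR<nD><L|S><locus>*<allele>[v<k>] scheme: two-digit allele
numbers change only with the encoded protein (synonymous-only differences
become sub-entries), and splice variants count v1, v2, ... within their
allele, with the configuration digit and tail letter recomputed from the
variant's own annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .annotation import ReceptorAnnotation
from .genemodel import SpliceEvent

logger = logging.getLogger(__name__)


@dataclass
class LocusAssignment:
    transcript_id: str
    locus: int
    max_intra_distance: float
    min_inter_distance: float | None
    clade_support: float | None


@dataclass
class KirName:
    prefix: str
    configuration: int
    tail: str                 # L or S
    locus: int
    allele: int
    variant: int | None = None

    def __str__(self) -> str:
        s = (
            f"{self.prefix}KIR{self.configuration}D{self.tail}"
            f"{self.locus}*{self.allele:02d}"
        )
        if self.variant is not None:
            s += f"v{self.variant}"
        return s


def _node_support(node: dendropy.Node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def assign_loci(
    tree: dendropy.Tree,
    distances: pd.DataFrame,
    distance_threshold: float = 0.02,
    support_threshold: float = 70.0,
) -> list[LocusAssignment]:
    """Cluster sequences into putative loci from tree and distance structure.

    A preorder traversal accepts the first (maximal) clade whose leaves are
    all within ``distance_threshold`` of each other and whose subtending
    branch support, when present, is at least ``support_threshold``;
    singletons are allowed. Labels are dense from 1 in traversal order, so
    they are stable under input reordering.
    """
    work = tree.clone(depth=1)
    all_leaves = sorted(t.label for t in tree.taxon_namespace)
    ref, full = all_leaves[0], frozenset(all_leaves)

    def normalize(side: frozenset) -> frozenset:
        return full - side if ref in side else side

    # bipartition -> bootstrap support, read off the tree before rerooting
    # (supports are symmetric properties of bipartitions, not of nodes)
    support_of: dict[frozenset, float] = {}
    for node in work.preorder_node_iter():
        if node.is_leaf():
            continue
        sup = _node_support(node)
        if sup is None:
            continue
        side = normalize(
            frozenset(lf.taxon.label for lf in node.leaf_iter())
        )
        support_of[side] = sup
    try:
        work.reroot_at_midpoint(update_bipartitions=False)
    except Exception:  # zero-length or degenerate trees
        pass
    assignments: list[LocusAssignment] = []
    clusters: list[list[str]] = []

    def leaves_of(node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def max_intra(labels: list[str]) -> float:
        if len(labels) < 2:
            return 0.0
        sub = distances.loc[labels, labels]
        return float(sub.to_numpy().max())

    def acceptable(node) -> bool:
        labels = leaves_of(node)
        if max_intra(labels) > distance_threshold:
            return False
        if node.parent_node is None or node.is_leaf():
            return True
        sup = support_of.get(normalize(frozenset(labels)))
        if sup is not None and sup < support_threshold:
            return False
        return True

    def walk(node) -> None:
        if acceptable(node):
            clusters.append(leaves_of(node))
            return
        if node.is_leaf():
            clusters.append(leaves_of(node))
            return
        for child in node.child_nodes():
            walk(child)

    walk(work.seed_node)
    # evidence: min distance to any other cluster
    for locus, labels in enumerate(clusters, start=1):
        others = [
            lab for other in clusters for lab in other if other is not labels
        ]
        if others:
            min_inter = float(
                distances.loc[labels, others].to_numpy().min()
            )
        else:
            min_inter = None
        intra = max_intra(labels)
        for lab in labels:
            assignments.append(
                LocusAssignment(lab, locus, intra, min_inter, None)
            )
    if len(clusters) == 1 and len(distances) > 1:
        if float(distances.to_numpy().max()) > 2 * distance_threshold:
            logger.warning(
                "threshold too loose: one cluster but distances exceed "
                "2x threshold"
            )
    return assignments


@dataclass
class _AlleleEntry:
    number: int
    protein: str
    transcripts: list[str] = field(default_factory=list)
    synonymous_subentries: list[str] = field(default_factory=list)
    n_variants: int = 0


@dataclass
class NomenclatureRegistry:
    """Per-run naming authority; a pure function of its input order."""

    prefix: str = "SYN"
    loci: dict[int, list[_AlleleEntry]] = field(default_factory=dict)

    def register_allele(
        self, locus: int, transcript_id: str, protein: str,
        events: list[SpliceEvent] | None = None,
    ) -> int:
        """Admit a transcript as an allele; returns the allele number.

        Identical proteins share a number (a synonymous nucleotide change is
        recorded as a sub-entry); a transcript carrying splice events must go
        through :meth:`register_variant` instead.
        """
        if events:
            raise ValueError(
                f"{transcript_id}: has splice events; use register_variant"
            )
        entries = self.loci.setdefault(locus, [])
        for entry in entries:
            if entry.protein == protein:
                entry.synonymous_subentries.append(transcript_id)
                return entry.number
        number = len(entries) + 1
        entries.append(
            _AlleleEntry(number, protein, transcripts=[transcript_id])
        )
        return number

    def register_variant(
        self,
        locus: int,
        allele: int,
        transcript_id: str,
        events: list[SpliceEvent],
        annotation: ReceptorAnnotation,
    ) -> KirName:
        """Name a splice variant of an existing allele.

        The variant number is sequential within the allele; configuration
        digit and tail letter come from the variant's own annotation (a
        variant may change both).
        """
        if not events:
            raise ValueError(f"{transcript_id}: no splice events; not a variant")
        entries = self.loci.setdefault(locus, [])
        entry = next((e for e in entries if e.number == allele), None)
        if entry is None:
            entry = _AlleleEntry(allele, protein="")
            entries.append(entry)
        entry.n_variants += 1
        digit = int(annotation.configuration[0]) if annotation.configuration else 0
        tail = "L" if annotation.tail_class == "long" else "S"
        return KirName(
            prefix=self.prefix, configuration=digit, tail=tail,
            locus=locus, allele=allele, variant=entry.n_variants,
        )

    def name_allele(
        self, locus: int, allele: int, annotation: ReceptorAnnotation
    ) -> KirName:
        digit = int(annotation.configuration[0]) if annotation.configuration else 0
        tail = "L" if annotation.tail_class == "long" else "S"
        return KirName(
            prefix=self.prefix, configuration=digit, tail=tail,
            locus=locus, allele=allele,
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "prefix": self.prefix,
            "loci": {
                str(locus): [asdict(e) for e in entries]
                for locus, entries in self.loci.items()
            },
        }
        Path(path).write_text(json.dumps(data, indent=1))
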