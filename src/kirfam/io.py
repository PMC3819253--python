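"""FASTA and newick readers/writers.

FASTA goes through Bio.SeqIO; trees through dendropy. Round-trips preserve
record order, sequence case normalization (upper), tree topology, branch
lengths to 6 decimals and internal support labels.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import FormatError, Transcript, check_unique_ids


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from a FASTA file.

    One :class:`Transcript` per record, order preserved, sequences
    upper-cased. Duplicate ids and empty files are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise FormatError(f"{path}: not FASTA, first line is {first!r}")
    transcripts: list[Transcript] = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        try:
            transcripts.append(
                Transcript(id=rec.id, sequence=str(rec.seq), description=desc)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not transcripts:
        raise FormatError(f"{path}: no records parsed")
    check_unique_ids(transcripts)
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=t.description or "")
        for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a newick tree; supports stored as internal node labels."""
    text = Path(path).read_text()
    return parse_newick(text)


def parse_newick(text: str) -> dendropy.Tree:
    if text.count("(") != text.count(")"):
        pos = len(text)
        raise FormatError(
            f"unbalanced parentheses in newick string (length {pos})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"newick parse error: {exc}") from exc
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths to 6 decimals and support labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    ).strip()
    return s + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))
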