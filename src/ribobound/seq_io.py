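"""Reading and writing the pipeline's file formats.

FASTA for sequences, tab-separated values (with header) for taxonomy,
Newick for trees. Any path may be plain or gzip-compressed (``.gz``).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import (
    DuplicateIDError,
    ParseError,
    SchemaError,
    SequenceRecord,
    StrainDataset,
    TaxonomyRecord,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "join_dataset",
    "JoinReport",
    "read_newick",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_TAXONOMY_COLUMNS = ("strain_id", "domain", "phylum", "class", "order", "family", "genus", "species")

# upper-case plus U->T; rRNA genes are handled in the DNA alphabet throughout
_CANONICAL = str.maketrans(
    "abcdefghijklmnopqrstuvwxyzU", "ABCDEFGHIJKLMNOPQRSTTVWXYZT"
)


def canonicalize(sequence: str) -> str:
    """Upper-case a nucleotide string and map U to T."""
    return sequence.translate(_CANONICAL)


def _open_text(path: PathLike, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into canonicalized sequence records.

    The strain ID is the header token before the first whitespace; the rest
    of the header is kept as a free-text description. Sequences are
    upper-cased with U mapped to T.

    Raises
    ------
    ParseError
        For text before the first header or an entry with no sequence,
        naming the offending line.
    DuplicateIDError
        If two entries share an ID.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()

    # pre-scan for structural problems so errors can name line numbers,
    # then let Biopython do the actual parsing
    header_line = None
    has_seq = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not has_seq:
                raise ParseError(f"{path}: entry at line {header_line} has no sequence")
            header_line = lineno
            has_seq = False
        else:
            if header_line is None:
                raise ParseError(f"{path}: line {lineno}: text before first FASTA header")
            has_seq = True
    if header_line is not None and not has_seq:
        raise ParseError(f"{path}: entry at line {header_line} has no sequence")

    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    handle = io.StringIO("\n".join(lines) + "\n") if lines else io.StringIO()
    for entry in SeqIO.parse(handle, "fasta"):
        seen[entry.id] = seen.get(entry.id, 0) + 1
        records.append(
            SequenceRecord(
                strain_id=entry.id,
                sequence=canonicalize(str(entry.seq)),
                description=entry.description[len(entry.id):].strip(),
            )
        )
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise DuplicateIDError(dups, context=str(path))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.strain_id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_taxonomy_table(path: PathLike) -> list[TaxonomyRecord]:
    """Read a tab-separated taxonomy table with a header row.

    Required columns: strain_id, domain, phylum, class, order, family,
    genus, species. An optional ``subspecies`` column may be present;
    empty cells there become absent subspecies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    dup_mask = df["strain_id"].duplicated(keep=False)
    if dup_mask.any():
        raise DuplicateIDError(df.loc[dup_mask, "strain_id"].tolist(), context=str(path))

    records = []
    for row in df.to_dict("records"):  # "class" is not a valid attribute name
        subsp = row.get("subspecies", "")
        records.append(
            TaxonomyRecord(
                strain_id=row["strain_id"],
                domain=row["domain"],
                phylum=row["phylum"],
                class_=row["class"],
                order=row["order"],
                family=row["family"],
                genus=row["genus"],
                species=row["species"],
                subspecies=subsp if subsp else None,
            )
        )
    return records


def write_taxonomy_table(records: Iterable[TaxonomyRecord], path: PathLike) -> None:
    rows = [
        {
            "strain_id": r.strain_id,
            "domain": r.domain,
            "phylum": r.phylum,
            "class": r.class_,
            "order": r.order,
            "family": r.family,
            "genus": r.genus,
            "species": r.species,
            "subspecies": r.subspecies or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class JoinReport:
    """Bookkeeping for an inner join of sequences and taxonomy."""

    n_matched: int
    n_sequence_only: int
    n_taxonomy_only: int
    sequence_only_ids: tuple[str, ...]
    taxonomy_only_ids: tuple[str, ...]


def join_dataset(
    seqs: Iterable[SequenceRecord], taxa: Iterable[TaxonomyRecord]
) -> tuple[StrainDataset, JoinReport]:
    """Inner-join sequences and taxonomy on strain_id.

    Unmatched records on either side are dropped and counted, not raised:
    nomenclature registries routinely list strains without a deposited
    sequence, so an incomplete join is the normal case.
    """
    seq_map = {r.strain_id: r for r in seqs}
    tax_map = {r.strain_id: r for r in taxa}
    shared = set(seq_map) & set(tax_map)
    seq_only = tuple(sorted(set(seq_map) - shared))
    tax_only = tuple(sorted(set(tax_map) - shared))
    report = JoinReport(
        n_matched=len(shared),
        n_sequence_only=len(seq_only),
        n_taxonomy_only=len(tax_only),
        sequence_only_ids=seq_only,
        taxonomy_only_ids=tax_only,
    )
    log.info(
        "joined dataset: %d matched, %d sequence-only, %d taxonomy-only",
        report.n_matched, report.n_sequence_only, report.n_taxonomy_only,
    )
    ds = StrainDataset(
        sequences={k: seq_map[k] for k in shared},
        taxonomy={k: tax_map[k] for k in shared},
    )
    return ds, report


def read_newick(path: PathLike):
    """Read a rooted Newick tree with branch lengths into a :class:`RedTree`.

    Leaf labels are preserved verbatim; polytomies are allowed. Duplicate
    leaf labels or a missing branch length on a non-root edge raise
    :class:`~ribobound.records.ParseError`.
    """
    from .red import RedTree

    return RedTree.from_newick_file(path)
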