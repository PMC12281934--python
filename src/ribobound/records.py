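"""Core record types shared across the pipeline.

A dataset is a set of strains, each carrying exactly one near-full-length
16S rRNA gene sequence and a seven-rank taxonomic lineage (domain through
species, with an optional subspecies). Ranks are ordered by inclusiveness:
species is the most exclusive rank considered, phylum the most inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "RANK_ORDER",
    "RANK_ATTRS",
    "SequenceRecord",
    "TaxonomyRecord",
    "StrainDataset",
    "ParseError",
    "SchemaError",
    "DuplicateIDError",
]

#: Ranks used for boundary statistics, from most to least exclusive.
RANK_ORDER: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

#: Maps a rank name to the TaxonomyRecord attribute that stores it.
RANK_ATTRS: dict[str, str] = {
    "domain": "domain",
    "phylum": "phylum",
    "class": "class_",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "subspecies": "subspecies",
}


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class SchemaError(ValueError):
    """A tabular file is missing required columns."""


class DuplicateIDError(ValueError):
    """Duplicate strain identifiers were found where uniqueness is required."""

    def __init__(self, duplicates: Iterable[str], context: str = ""):
        self.duplicates = sorted(set(duplicates))
        msg = f"duplicate strain IDs: {', '.join(self.duplicates)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


@dataclass(frozen=True)
class SequenceRecord:
    """One strain's 16S rRNA gene sequence.

    The sequence is canonicalized on input: upper case, with U mapped to T
    (some sources deposit rRNA genes in the RNA alphabet).
    """

    strain_id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.strain_id}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def n_ambiguous(self) -> int:
        """Number of characters outside the unambiguous DNA alphabet A/C/G/T."""
        return sum(1 for c in self.sequence if c not in "ACGT")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Seven-rank lineage for one strain; subspecies is optional.

    Placeholder names (e.g. ``No-Family``) may be present before filtering.
    """

    strain_id: str
    domain: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    subspecies: Optional[str] = None

    def __post_init__(self):
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        for rank in ("domain", "phylum", "class_", "order", "family", "genus", "species"):
            if not getattr(self, rank):
                raise ValueError(f"{self.strain_id}: rank {rank!r} must be non-empty")

    def rank_value(self, rank: str) -> Optional[str]:
        """Name at ``rank`` ('domain'...'species', 'subspecies')."""
        try:
            return getattr(self, RANK_ATTRS[rank])
        except KeyError:
            raise KeyError(f"unknown rank {rank!r}") from None

    def lineage(self, down_to: str = "species") -> tuple[str, ...]:
        """Names from domain down to ``down_to``, inclusive."""
        order = ("domain", "phylum", "class", "order", "family", "genus", "species")
        if down_to not in order:
            raise KeyError(f"unknown rank {down_to!r}")
        stop = order.index(down_to)
        return tuple(self.rank_value(r) for r in order[: stop + 1])


@dataclass
class StrainDataset:
    """Joined sequences and taxonomy, keyed by strain_id.

    Invariant: identical key sets on both sides — every sequence has a
    taxonomy and vice versa.
    """

    sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    taxonomy: dict[str, TaxonomyRecord] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.sequences) != set(self.taxonomy):
            only_seq = sorted(set(self.sequences) - set(self.taxonomy))[:5]
            only_tax = sorted(set(self.taxonomy) - set(self.sequences))[:5]
            raise ValueError(
                "sequence and taxonomy IDs differ "
                f"(sequence-only: {only_seq}, taxonomy-only: {only_tax})"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids())

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self.sequences

    def ids(self) -> list[str]:
        """Strain IDs in sorted order (the canonical iteration order)."""
        return sorted(self.sequences)

    def subset(self, keep: Iterable[str]) -> "StrainDataset":
        keep = set(keep)
        missing = keep - set(self.sequences)
        if missing:
            raise KeyError(f"IDs not in dataset: {sorted(missing)[:10]}")
        return StrainDataset(
            sequences={k: self.sequences[k] for k in keep},
            taxonomy={k: self.taxonomy[k] for k in keep},
        )
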