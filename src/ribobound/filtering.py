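"""Length/quality filtering of sequences and removal of ambiguous taxonomy.

Near-full-length 16S rRNA gene surveys drop partial amplicons (too short),
suspect concatenations (too long), sequences with many ambiguous base
calls, and strains whose lineage carries placeholder rank names such as
``No-Family``. Both filters return an auditable report whose counts add up
to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import StrainDataset

__all__ = [
    "FilterReport",
    "filter_sequences",
    "filter_taxonomy",
    "DEFAULT_PLACEHOLDER_MARKERS",
]

DEFAULT_PLACEHOLDER_MARKERS: tuple[str, ...] = ("No-Family", "No-Order", "No-Class")

#: Fixed attribution order: the first failing rule names the removal reason.
REASONS = ("short", "long", "ambiguous_chars", "ambiguous_taxonomy")


@dataclass
class FilterReport:
    """Removal bookkeeping for one filtering pass.

    Every removed strain has exactly one primary reason — the first rule it
    fails in the order short → long → ambiguous characters → taxonomy —
    so ``n_input == n_retained + sum(removal counts)`` always holds.
    """

    n_input: int = 0
    n_removed_short: int = 0
    n_removed_long: int = 0
    n_removed_ambiguous_chars: int = 0
    n_removed_ambiguous_taxonomy: int = 0
    n_retained: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_short
            + self.n_removed_long
            + self.n_removed_ambiguous_chars
            + self.n_removed_ambiguous_taxonomy
        )

    def check_conservation(self) -> None:
        if self.n_input != self.n_retained + self.n_removed:
            raise AssertionError(
                f"filter report does not conserve counts: {self.n_input} != "
                f"{self.n_retained} + {self.n_removed}"
            )
        if len(self.removed_ids) != self.n_removed:
            raise AssertionError("removed_ids length disagrees with removal counts")

    def removed_percent(self, ndigits: int = 1) -> float:
        """Removed strains as a percentage of the input, rounded for reporting."""
        if self.n_input == 0:
            return 0.0
        return round(100.0 * self.n_removed / self.n_input, ndigits)

    def retained_percent(self, ndigits: int = 0) -> float:
        if self.n_input == 0:
            return 0.0
        return round(100.0 * self.n_retained / self.n_input, ndigits)


def filter_sequences(
    ds: StrainDataset,
    min_len: int = 1100,
    max_len: int = 1750,
    max_ambiguous: int = 9,
) -> tuple[StrainDataset, FilterReport]:
    """Remove sequences outside [min_len, max_len] or with too many ambiguous characters.

    A strain is retained iff ``min_len <= len(seq) <= max_len`` and the
    count of characters outside {A, C, G, T} is at most ``max_ambiguous``
    (defaults drop sequences with ten or more ambiguous characters).
    Ambiguity is counted after canonicalization, so case and U/T spelling
    never count as ambiguous.
    """
    report = FilterReport(n_input=len(ds))
    keep: list[str] = []
    for sid in ds.ids():
        seq = ds.sequences[sid]
        if len(seq) < min_len:
            report.n_removed_short += 1
            report.removed_ids.append((sid, "short"))
        elif len(seq) > max_len:
            report.n_removed_long += 1
            report.removed_ids.append((sid, "long"))
        elif seq.n_ambiguous() > max_ambiguous:
            report.n_removed_ambiguous_chars += 1
            report.removed_ids.append((sid, "ambiguous_chars"))
        else:
            keep.append(sid)
    report.n_retained = len(keep)
    report.check_conservation()
    return ds.subset(keep), report


def filter_taxonomy(
    ds: StrainDataset,
    placeholder_markers: tuple[str, ...] = DEFAULT_PLACEHOLDER_MARKERS,
    exact: bool = False,
) -> tuple[StrainDataset, FilterReport]:
    """Remove strains whose lineage contains a placeholder rank name.

    A strain is removed iff any of its rank values contains (substring
    match; ``exact=True`` for whole-string match) any of the placeholder
    markers, by default ``No-Family``/``No-Order``/``No-Class``.
    """
    report = FilterReport(n_input=len(ds))
    keep: list[str] = []
    for sid in ds.ids():
        tax = ds.taxonomy[sid]
        values = [
            tax.domain, tax.phylum, tax.class_, tax.order,
            tax.family, tax.genus, tax.species,
        ]
        if tax.subspecies is not None:
            values.append(tax.subspecies)
        if exact:
            hit = any(v == m for v in values for m in placeholder_markers)
        else:
            hit = any(m in v for v in values for m in placeholder_markers)
        if hit:
            report.n_removed_ambiguous_taxonomy += 1
            report.removed_ids.append((sid, "ambiguous_taxonomy"))
        else:
            keep.append(sid)
    report.n_retained = len(keep)
    report.check_conservation()
    return ds.subset(keep), report
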