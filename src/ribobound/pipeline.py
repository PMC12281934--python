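"""End-to-end driver: filter -> align -> boundaries (-> RED), with a manifest.

The manifest records package and library versions, all parameters, SHA-256
digests of the inputs, and the record counts at every stage, so a run can
be audited and reproduced; it deliberately contains no timestamps, making
reruns with identical inputs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .align import ScoringScheme, all_vs_all_identity
from .boundaries import (
    BoundaryTable,
    min_within_taxon,
    percentile_boundaries,
    within_taxon_identities,
)
from .filtering import (
    DEFAULT_PLACEHOLDER_MARKERS,
    filter_sequences,
    filter_taxonomy,
)
from .records import RANK_ORDER, StrainDataset
from .red import compute_reds, identity_red_pairs, min_red_within_taxon
from .seq_io import read_fasta, read_newick, read_taxonomy_table, join_dataset, write_fasta

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

GROUPS = ("prokaryotes", "bacteria", "archaea")


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    fasta: PathLike
    taxonomy: PathLike
    out_dir: PathLike
    tree: Optional[PathLike] = None
    min_len: int = 1100
    max_len: int = 1750
    max_ambiguous: int = 9
    placeholder_markers: tuple[str, ...] = DEFAULT_PLACEHOLDER_MARKERS
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    group: str = "prokaryotes"
    p_lower: float = 0.05
    p_upper: float = 0.95
    n_chunks: int = 1000
    n_workers: int = 1

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    @classmethod
    def from_file(cls, path: PathLike, **overrides) -> "PipelineConfig":
        """Read a plain-text ``key = value`` config file; kwargs override."""
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val
        ints = {"min_len", "max_len", "max_ambiguous", "n_chunks", "n_workers"}
        floats = {"p_lower", "p_upper"}
        kwargs: dict = {}
        for key, val in kv.items():
            if key in ints:
                kwargs[key] = int(val)
            elif key in floats:
                kwargs[key] = float(val)
            elif key == "placeholder_markers":
                kwargs[key] = tuple(s.strip() for s in val.split(",") if s.strip())
            elif key in {"match", "mismatch", "gap_open", "gap_extend"}:
                kwargs.setdefault("_scoring", {})[key] = float(val)
            else:
                kwargs[key] = val
        scoring_kv = kwargs.pop("_scoring", None)
        if scoring_kv:
            kwargs["scoring"] = ScoringScheme(**scoring_kv)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    boundary_table: BoundaryTable
    manifest: dict
    out_dir: Path
    dataset: StrainDataset


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _select_group(ds: StrainDataset, group: str) -> StrainDataset:
    if group == "prokaryotes":
        return ds
    wanted = group.capitalize()  # "Bacteria" / "Archaea"
    keep = [sid for sid in ds.ids() if ds.taxonomy[sid].domain == wanted]
    return ds.subset(keep)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write all outputs under ``config.out_dir``.

    Stages: read and join inputs, sequence filter, taxonomy filter, group
    selection, all-vs-all identity, per-rank minima and percentile
    boundaries, and — when a tree is supplied — RED minima per rank and
    identity-vs-RED pairs. Failures carry the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": {"ribobound": __version__},
        "parameters": {
            "min_len": config.min_len,
            "max_len": config.max_len,
            "max_ambiguous": config.max_ambiguous,
            "placeholder_markers": list(config.placeholder_markers),
            "scoring": {
                "match": config.scoring.match,
                "mismatch": config.scoring.mismatch,
                "gap_open": config.scoring.gap_open,
                "gap_extend": config.scoring.gap_extend,
            },
            "group": config.group,
            "p_lower": config.p_lower,
            "p_upper": config.p_upper,
            "n_chunks": config.n_chunks,
            "n_workers": config.n_workers,
        },
        "inputs": {},
        "counts": {},
    }
    import numpy, pandas, dendropy, numba  # versions for the audit trail

    manifest["versions"].update(
        numpy=numpy.__version__, pandas=pandas.__version__,
        dendropy=dendropy.__version__, numba=numba.__version__,
    )

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    try:
        t0 = stage("read inputs")
        manifest["inputs"]["fasta"] = _sha256(config.fasta)
        manifest["inputs"]["taxonomy"] = _sha256(config.taxonomy)
        seqs = read_fasta(config.fasta)
        taxa = read_taxonomy_table(config.taxonomy)
        ds, join_report = join_dataset(seqs, taxa)
        manifest["counts"]["n_sequences"] = len(seqs)
        manifest["counts"]["n_taxonomy"] = len(taxa)
        manifest["counts"]["n_joined"] = join_report.n_matched
        manifest["counts"]["n_sequence_only"] = join_report.n_sequence_only
        manifest["counts"]["n_taxonomy_only"] = join_report.n_taxonomy_only
        log.info("read inputs in %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage 'read inputs' failed: {exc}") from exc

    try:
        t0 = stage("filter")
        ds, seq_report = filter_sequences(
            ds, config.min_len, config.max_len, config.max_ambiguous
        )
        ds, tax_report = filter_taxonomy(ds, config.placeholder_markers)
        manifest["counts"]["filter_input"] = seq_report.n_input
        manifest["counts"]["removed_short"] = seq_report.n_removed_short
        manifest["counts"]["removed_long"] = seq_report.n_removed_long
        manifest["counts"]["removed_ambiguous_chars"] = seq_report.n_removed_ambiguous_chars
        manifest["counts"]["removed_ambiguous_taxonomy"] = tax_report.n_removed_ambiguous_taxonomy
        manifest["counts"]["retained"] = tax_report.n_retained
        rows = ["strain_id\treason"]
        rows += [f"{sid}\t{reason}" for sid, reason in seq_report.removed_ids]
        rows += [f"{sid}\t{reason}" for sid, reason in tax_report.removed_ids]
        (out_dir / "filter_report.tsv").write_text("\n".join(rows) + "\n")
        ds = _select_group(ds, config.group)
        manifest["counts"]["in_group"] = len(ds)
        write_fasta((ds.sequences[s] for s in ds.ids()), out_dir / "filtered.fasta")
        log.info("filtered in %.1fs; %d strains retained", time.perf_counter() - t0, len(ds))
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    try:
        t0 = stage("align")
        matrix = all_vs_all_identity(
            ds, config.scoring, n_chunks=config.n_chunks, n_workers=config.n_workers
        )
        matrix.write_pairs_tsv(out_dir / "identities.tsv")
        manifest["counts"]["n_pairs"] = len(matrix.ids) * (len(matrix.ids) - 1) // 2
        log.info("aligned in %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage 'align' failed: {exc}") from exc

    try:
        t0 = stage("boundaries")
        taxa_list = [ds.taxonomy[sid] for sid in ds.ids()]
        all_minima = []
        minima_rows = ["rank\ttaxon\tn_members\tmin_identity\tid_a\tid_b"]
        for rank in RANK_ORDER:
            values = within_taxon_identities(matrix, taxa_list, rank, with_pairs=True)
            minima = min_within_taxon(values, rank)
            all_minima.extend(minima)
            for tm in minima:
                ida, idb = tm.argmin_pair
                minima_rows.append(
                    f"{rank}\t{tm.taxon_name}\t{tm.n_members}"
                    f"\t{tm.min_identity:.4f}\t{ida}\t{idb}"
                )
        (out_dir / "taxon_minima.tsv").write_text("\n".join(minima_rows) + "\n")
        table = percentile_boundaries(all_minima, config.p_lower, config.p_upper)
        table.write_tsv(out_dir / "boundaries.tsv")
        manifest["counts"]["n_taxa_with_minima"] = len(all_minima)
        log.info("boundaries in %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage 'boundaries' failed: {exc}") from exc

    if config.tree is not None:
        try:
            t0 = stage("red")
            manifest["inputs"]["tree"] = _sha256(config.tree)
            tree = read_newick(config.tree)
            compute_reds(tree)
            in_tree = [sid for sid in ds.ids() if sid in tree._leaf]
            taxa_in_tree = [ds.taxonomy[sid] for sid in in_tree]
            red_rows = ["rank\ttaxon\tn_members\tmin_red\tid_a\tid_b"]
            for rank in RANK_ORDER:
                for tm in min_red_within_taxon(tree, taxa_in_tree, rank):
                    ida, idb = tm.argmin_pair
                    red_rows.append(
                        f"{rank}\t{tm.taxon_name}\t{tm.n_members}"
                        f"\t{tm.min_red:.6f}\t{ida}\t{idb}"
                    )
            (out_dir / "red_minima.tsv").write_text("\n".join(red_rows) + "\n")
            pairs = identity_red_pairs(matrix, tree, in_tree)
            pairs.to_csv(
                out_dir / "identity_red_pairs.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
            manifest["counts"]["n_in_tree"] = len(in_tree)
            log.info("red in %.1fs", time.perf_counter() - t0)
        except Exception as exc:
            raise RuntimeError(f"stage 'red' failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return PipelineResult(
        boundary_table=table, manifest=manifest, out_dir=out_dir, dataset=ds
    )
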