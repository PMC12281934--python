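"""Synthetic benchmark data with known taxonomic structure.

The generator emulates the statistical shape of a type-strain 16S dataset
without any downloads: a rooted clocklike (ultrametric) pure-birth tree
scaled to unit root-to-leaf height, rank labels induced by cutting the
tree at fixed depths (so taxa are clades and ranks nest perfectly), and
sequences evolved along the tree under the Jukes-Cantor model. Under JC
the expected identity of two leaves separated by total path length D has
the closed form

    E[identity] = 100 * (1/4 + 3/4 * exp(-4 * rate * D / 3))

which is what makes every downstream stage checkable against planted
structure. All randomness flows from a single integer seed; equal configs
give byte-identical outputs.

Defaults: 1,400 bp sequences (mid-range for a near-full-length 16S gene),
substitution rate 0.2 per site per unit height, and rank cut heights
(0.02, 0.15, 0.35, 0.55, 0.75, 0.9) above the leaves for species through
phylum — chosen so simulated within-rank identities span roughly the
70-100% range observed across real prokaryotic ranks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np

from .records import SequenceRecord, StrainDataset, TaxonomyRecord
from .red import RedTree
from .seq_io import write_fasta, write_taxonomy_table

__all__ = [
    "SimulationConfig",
    "Benchmark",
    "simulate_tree",
    "assign_ranks_from_depths",
    "evolve_sequences",
    "expected_identity",
    "make_benchmark",
]

#: Label prefix per rank for synthetic taxon names (p01, c03, g17, ...).
_RANK_PREFIX = {
    "species": "s", "genus": "g", "family": "f",
    "order": "o", "class": "c", "phylum": "p",
}
_RANKS_BY_CUT = ("species", "genus", "family", "order", "class", "phylum")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic benchmark.

    ``rank_depth_thresholds`` are six strictly increasing fractions in
    (0, 1), the heights *above the leaves* (as a fraction of total tree
    height) at which the tree is cut to define species, genus, family,
    order, class and phylum taxa; a small cut height means many small
    taxa. ``subst_rate`` is in expected substitutions per site per unit
    of branch length. ``ambiguous_injection = (fraction, count)`` plants
    ``count`` N characters into a fraction of sequences, and
    ``length_outliers = (n_short, n_long)`` plants length-filter
    violations, to exercise the filters with known removal counts.
    """

    n_leaves: int
    seq_length: int = 1400
    subst_rate: float = 0.2
    rank_depth_thresholds: tuple[float, ...] = (0.02, 0.15, 0.35, 0.55, 0.75, 0.9)
    seed: int = 0
    ambiguous_injection: Optional[tuple[float, int]] = None
    length_outliers: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be non-negative")
        t = self.rank_depth_thresholds
        if len(t) != 6 or any(not 0 < x < 1 for x in t) or any(
            t[i] >= t[i + 1] for i in range(5)
        ):
            raise ValueError(
                "rank_depth_thresholds must be six strictly increasing "
                "fractions in (0, 1), species through phylum"
            )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_tree(cfg: SimulationConfig) -> RedTree:
    """Rooted binary clocklike tree from a pure-birth (Yule) process.

    The root splits at time zero; each of k active lineages splits next
    after an Exp(k) waiting time, and all surviving lineages run to the
    present. Node times are rescaled so every root-to-leaf distance is
    exactly 1. Deterministic given the config seed.
    """
    rng = _rng(cfg, 0)
    tree = dendropy.Tree()
    root = tree.seed_node
    root.time = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.time = None
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < cfg.n_leaves:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.time = t
        for _ in range(2):
            child = dendropy.Node()
            child.time = None
            node.add_child(child)
            active.append(child)
    present = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.time = present

    width = max(4, len(str(cfg.n_leaves)))
    leaf_no = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            node.edge.length = (node.time - parent.time) / present
        if node.is_leaf():
            leaf_no += 1
            node.taxon = tree.taxon_namespace.new_taxon(label=f"t{leaf_no:0{width}d}")
    return RedTree(tree)


def assign_ranks_from_depths(
    t: RedTree, thresholds: tuple[float, ...]
) -> list[TaxonomyRecord]:
    """Rank labels from cutting a clocklike tree at fixed depths.

    For each rank, taxa are the clades hanging below the first edge that
    crosses the rank's cut depth; since the species cut is closest to the
    leaves and the phylum cut closest to the root, labels nest perfectly
    (every species lies inside exactly one genus, and so on). Singleton
    taxa are permitted. Labels are synthetic tokens (s0007, g03, p01...).
    """
    if len(thresholds) != 6 or any(
        thresholds[i] >= thresholds[i + 1] for i in range(5)
    ):
        raise ValueError("thresholds must be six strictly increasing values")

    depth: dict[int, float] = {}
    height = 0.0
    for node in t.tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (
            0.0 if parent is None else depth[id(parent)] + node.edge.length
        )
        if node.is_leaf():
            height = max(height, depth[id(node)])
    if height <= 0:
        raise ValueError("tree has zero height")

    leaf_labels = t.leaf_labels()
    assignment: dict[str, dict[str, str]] = {lab: {} for lab in leaf_labels}
    for rank, thr in zip(_RANKS_BY_CUT, thresholds):
        cut = height * (1.0 - thr)  # depth from root
        prefix = _RANK_PREFIX[rank]
        counter = 0
        for node in t.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            if depth[id(parent)] < cut <= depth[id(node)]:
                counter += 1
                label = f"{prefix}{counter:02d}"
                for lf in node.leaf_iter():
                    assignment[lf.taxon.label][rank] = label
        # guard: a leaf shallower than the cut becomes its own taxon
        for lab in leaf_labels:
            if rank not in assignment[lab]:
                counter += 1
                assignment[lab][rank] = f"{prefix}{counter:02d}"

    return [
        TaxonomyRecord(
            strain_id=lab,
            domain="d01",
            phylum=assignment[lab]["phylum"],
            class_=assignment[lab]["class"],
            order=assignment[lab]["order"],
            family=assignment[lab]["family"],
            genus=assignment[lab]["genus"],
            species=assignment[lab]["species"],
        )
        for lab in leaf_labels
    ]


def evolve_sequences(t: RedTree, cfg: SimulationConfig) -> list[SequenceRecord]:
    """Evolve sequences along the tree under Jukes-Cantor.

    The root sequence is uniform over {A, C, G, T}; along a branch of
    length b each site substitutes independently with probability
    3/4 * (1 - exp(-4 * rate * b / 3)), choosing uniformly among the
    three other bases (the exact JC transition kernel, so the process
    composes correctly across consecutive branches). No indels.
    """
    rng = _rng(cfg, 1)
    L = cfg.seq_length
    seqs: dict[int, np.ndarray] = {}
    leaf_seqs: dict[str, str] = {}
    for node in t.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        else:
            b = node.edge.length
            p = 0.75 * (1.0 - np.exp(-4.0 * cfg.subst_rate * b / 3.0))
            seq = seqs[id(parent)].copy()
            mask = rng.random(L) < p
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
        seqs[id(node)] = seq
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = _BASES[seq].tobytes().decode("ascii")
    return [
        SequenceRecord(strain_id=lab, sequence=leaf_seqs[lab])
        for lab in sorted(leaf_seqs)
    ]


def expected_identity(subst_rate: float, path_length: float) -> float:
    """Jukes-Cantor expected percent identity at total path length D."""
    return 100.0 * (0.25 + 0.75 * np.exp(-4.0 * subst_rate * path_length / 3.0))


@dataclass
class Benchmark:
    """Paths and bookkeeping of one generated benchmark."""

    fasta: Path
    taxonomy: Path
    newick: Path
    report_path: Path
    report: dict = field(default_factory=dict)
    dataset: Optional[StrainDataset] = None
    tree: Optional[RedTree] = None


def make_benchmark(cfg: SimulationConfig, out_dir: Union[str, Path]) -> Benchmark:
    """Generate and write a complete benchmark: FASTA, taxonomy, Newick, report.

    The report records the expected within-rank identity range from the
    JC closed form and, when filter-violating sequences are planted
    (ambiguous characters, length outliers), exactly which strain IDs
    carry them — so filter tests can compare removal counts against
    planted counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(cfg)
    taxa = assign_ranks_from_depths(tree, cfg.rank_depth_thresholds)
    seqs = evolve_sequences(tree, cfg)

    rng = _rng(cfg, 2)
    all_ids = [s.strain_id for s in seqs]
    planted = {"ambiguous_ids": [], "short_ids": [], "long_ids": []}
    pool = list(all_ids)

    def draw(k: int) -> list[str]:
        picked = sorted(rng.choice(len(pool), size=k, replace=False).tolist())
        chosen = [pool[i] for i in picked]
        for c in chosen:
            pool.remove(c)
        return chosen

    seq_map = {s.strain_id: s for s in seqs}
    if cfg.ambiguous_injection is not None:
        frac, count = cfg.ambiguous_injection
        n_amb = int(np.floor(frac * len(all_ids)))
        for sid in draw(n_amb):
            s = seq_map[sid].sequence
            pos = rng.choice(len(s), size=count, replace=False)
            chars = list(s)
            for p in pos:
                chars[p] = "N"
            seq_map[sid] = SequenceRecord(strain_id=sid, sequence="".join(chars))
            planted["ambiguous_ids"].append(sid)
    if cfg.length_outliers is not None:
        n_short, n_long = cfg.length_outliers
        for sid in draw(n_short):
            s = seq_map[sid].sequence
            seq_map[sid] = SequenceRecord(strain_id=sid, sequence=s[: len(s) // 2])
            planted["short_ids"].append(sid)
        for sid in draw(n_long):
            s = seq_map[sid].sequence
            seq_map[sid] = SequenceRecord(strain_id=sid, sequence=s + s)
            planted["long_ids"].append(sid)
    seqs = [seq_map[sid] for sid in all_ids]

    expected = {}
    for rank, thr in zip(_RANKS_BY_CUT, cfg.rank_depth_thresholds):
        expected[rank] = {
            "cut_height_above_leaves": thr,
            "max_within_taxon_path": 2.0 * thr,
            "expected_min_identity": expected_identity(cfg.subst_rate, 2.0 * thr),
        }

    report = {
        "config": {
            "n_leaves": cfg.n_leaves,
            "seq_length": cfg.seq_length,
            "subst_rate": cfg.subst_rate,
            "rank_depth_thresholds": list(cfg.rank_depth_thresholds),
            "seed": cfg.seed,
            "ambiguous_injection": list(cfg.ambiguous_injection)
            if cfg.ambiguous_injection
            else None,
            "length_outliers": list(cfg.length_outliers)
            if cfg.length_outliers
            else None,
        },
        "planted": planted,
        "expected_within_rank_identity": expected,
    }

    fasta = out_dir / "sequences.fasta"
    taxonomy = out_dir / "taxonomy.tsv"
    newick = out_dir / "tree.nwk"
    report_path = out_dir / "report.json"
    write_fasta(seqs, fasta)
    write_taxonomy_table(taxa, taxonomy)
    newick.write_text(tree.as_newick() + "\n", encoding="utf-8")
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    ds = StrainDataset(
        sequences={s.strain_id: s for s in seqs},
        taxonomy={t_.strain_id: t_ for t_ in taxa},
    )
    return Benchmark(
        fasta=fasta,
        taxonomy=taxonomy,
        newick=newick,
        report_path=report_path,
        report=report,
        dataset=ds,
        tree=tree,
    )
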