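"""Relative evolutionary divergence (RED) and its agreement with identity.

Computes RED on a toy tree by hand-checkable recursion, then, on a
synthetic benchmark, compares per-rank minimum MRCA-RED with per-rank
minimum identity and reports their rank correlation across strain pairs.
Takes about half a minute (60-leaf all-vs-all alignment).
"""

import tempfile

import pandas as pd

from ribobound import PipelineConfig, RedTree, compute_reds, find_mrca, run_all
from ribobound.simulate import SimulationConfig, make_benchmark

toy = compute_reds(RedTree.from_newick_string("((A:1,B:1):1,C:2);"))
print("toy tree ((A:1,B:1):1,C:2);")
print(f"  red(root)       = {toy.red_of(toy.root):.2f}")
print(f"  red(mrca(A, B)) = {toy.red_of(find_mrca(toy, 'A', 'B')):.2f}")
print(f"  red(leaf A)     = {toy.red_of('A'):.2f}")
print()

with tempfile.TemporaryDirectory() as tmp:
    bench = make_benchmark(SimulationConfig(n_leaves=60, seed=7), f"{tmp}/b")
    result = run_all(
        PipelineConfig(
            fasta=bench.fasta, taxonomy=bench.taxonomy, tree=bench.newick,
            out_dir=f"{tmp}/out",
        )
    )
    pairs = pd.read_csv(f"{tmp}/out/identity_red_pairs.tsv", sep="\t")
    rx = pairs["identity_pct"].rank()
    ry = pairs["mrca_red"].rank()
    rho = rx.corr(ry)
    print(f"{len(pairs)} strain pairs; Spearman rho(identity, RED) = {rho:.3f}")
    rm = pd.read_csv(f"{tmp}/out/red_minima.tsv", sep="\t")
    med = rm.groupby("rank")["min_red"].median()
    print("median per-taxon minimum RED by rank:")
    for rank in ("species", "genus", "family", "order", "class", "phylum"):
        if rank in med.index:
            print(f"  {rank:<8} {med[rank]:.3f}")
print()
print(
    "RED is 0 at the root and 1 at every leaf, so shallow taxa (species)",
    "have MRCA-RED near 1 and deep taxa (phyla) near 0 - the same",
    "ordering the identity boundaries show, which is why the two metrics",
    "correlate strongly across pairs.",
)
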