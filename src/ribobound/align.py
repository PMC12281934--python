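"""Affine-gap global alignment and gap-excluded percent identity.

The aligner is a three-state (Gotoh) dynamic program over the full length
of both sequences: terminal gaps are penalized, and a maximal gap run of
length k costs ``gap_open + (k - 1) * gap_extend`` (the first gap character
is priced at the opening score). Percent identity is computed from the
optimal alignment as

    identity = matching characters / gapless alignment columns * 100

i.e. columns containing a gap are excluded from both numerator and
denominator. This is the identity definition used by 16S rRNA comparison
services, and it is the published quantity; the raw alignment score is
internal.

Traceback is deterministic: ties prefer a match/mismatch column over a gap
in the second sequence over a gap in the first, and gap opening over gap
extension. Co-optimal alignments can differ in identity by fractions of a
percentage point; only the deterministic choice is surfaced.

Ambiguity codes (N, R, Y, ...) match only on exact character equality and
score as mismatches otherwise; upstream filtering bounds their number.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from math import nan
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numba
import numpy as np
import pandas as pd

from .records import StrainDataset

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "IdentityMatrix",
    "global_align",
    "percent_identity",
    "all_vs_all_identity",
    "score_from_aligned",
    "pair_count",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: match / mismatch per column, affine gap run cost.

    Defaults are the scheme used for 16S rRNA gene comparisons: a strongly
    penalized gap opening with a cheap extension, so substitution-level
    divergence is absorbed as mismatches rather than spurious gaps.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")

    def gap_run_cost(self, k: int) -> float:
        """Score contribution of a maximal gap run of length ``k >= 1``."""
        return self.gap_open + (k - 1) * self.gap_extend


DEFAULT_SCHEME = ScoringScheme()

_NEG = -1e30

# pointer bits per cell: 0-1 = predecessor state of the match state
# (0=M, 1=X, 2=Y); bit 3 = X reached by extension; bit 4 = Y by extension
_FROM_MASK = np.uint8(3)
_X_EXT = np.uint8(8)
_Y_EXT = np.uint8(16)


@numba.njit(cache=True, nogil=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    """Three-state affine DP with rolling rows and a full pointer matrix.

    States: M = match/mismatch column, X = gap in b (consumes a),
    Y = gap in a (consumes b). Returns (score, ops, n_match, n_mismatch,
    n_gap_columns) where ops[k] is 0 (column from both), 1 (gap in b),
    or 2 (gap in a) for alignment column k.
    """
    la, lb = len(a), len(b)
    M = np.empty(lb + 1, np.float64)
    X = np.empty(lb + 1, np.float64)
    Y = np.empty(lb + 1, np.float64)
    ptr = np.empty((la + 1, lb + 1), np.uint8)

    M[0] = 0.0
    X[0] = _NEG
    Y[0] = _NEG
    ptr[0, 0] = 0
    for j in range(1, lb + 1):
        M[j] = _NEG
        X[j] = _NEG
        Y[j] = gap_open + (j - 1) * gap_extend
        ptr[0, j] = 0 if j == 1 else _Y_EXT
    for i in range(1, la + 1):
        ai = a[i - 1]
        rowp = ptr[i]
        diagM, diagX, diagY = M[0], X[0], Y[0]
        M[0] = _NEG
        X[0] = gap_open + (i - 1) * gap_extend
        Y[0] = _NEG
        rowp[0] = 0 if i == 1 else _X_EXT
        for j in range(1, lb + 1):
            upM, upX, upY = M[j], X[j], Y[j]
            s = match if ai == b[j - 1] else mismatch
            best = diagM
            pb = np.uint8(0)
            if diagX > best:
                best = diagX
                pb = np.uint8(1)
            if diagY > best:
                best = diagY
                pb = np.uint8(2)
            newM = best + s
            xo = upM + gap_open
            xe = upX + gap_extend
            if xo >= xe:
                newX = xo
            else:
                newX = xe
                pb |= _X_EXT
            yo = M[j - 1] + gap_open
            ye = Y[j - 1] + gap_extend
            if yo >= ye:
                newY = yo
            else:
                newY = ye
                pb |= _Y_EXT
            diagM, diagX, diagY = upM, upX, upY
            M[j] = newM
            X[j] = newX
            Y[j] = newY
            rowp[j] = pb

    # final state: prefer M over X (gap in b) over Y (gap in a) on ties
    score = M[lb]
    state = 0
    if X[lb] > score:
        score = X[lb]
        state = 1
    if Y[lb] > score:
        score = Y[lb]
        state = 2

    ops = np.empty(la + lb, np.uint8)
    k = la + lb
    i, j = la, lb
    nm = 0
    nmm = 0
    ng = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        k -= 1
        if state == 0:
            ops[k] = 0
            if a[i - 1] == b[j - 1]:
                nm += 1
            else:
                nmm += 1
            state = p & _FROM_MASK
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            ng += 1
            state = 1 if (p & _X_EXT) else 0
            i -= 1
        else:
            ops[k] = 2
            ng += 1
            state = 2 if (p & _Y_EXT) else 0
            j -= 1
    return score, ops[k:], nm, nmm, ng


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal global alignment and its column bookkeeping.

    ``n_match`` + ``n_mismatch`` + ``n_gap_columns`` equals the alignment
    length; ``identity_pct`` excludes gap columns from its denominator.
    """

    aligned_a: str
    aligned_b: str
    score: float
    n_match: int
    n_mismatch: int
    n_gap_columns: int
    identity_pct: float

    @classmethod
    def from_aligned(
        cls,
        aligned_a: str,
        aligned_b: str,
        scheme: ScoringScheme = DEFAULT_SCHEME,
        score: Optional[float] = None,
    ) -> "AlignmentResult":
        """Build a result from two gapped strings, recomputing the counts.

        The score, if not given, is recomputed column-by-column under
        ``scheme``. Useful for worked examples and round-trip checks.
        """
        if len(aligned_a) != len(aligned_b):
            raise ValueError("aligned strings must have equal length")
        nm = nmm = ng = 0
        for ca, cb in zip(aligned_a, aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("column with gaps in both rows")
            if ca == "-" or cb == "-":
                ng += 1
            elif ca == cb:
                nm += 1
            else:
                nmm += 1
        if score is None:
            score = score_from_aligned(aligned_a, aligned_b, scheme)
        ident = 100.0 * nm / (nm + nmm) if (nm + nmm) > 0 else nan
        return cls(aligned_a, aligned_b, float(score), nm, nmm, ng, ident)

    def validate(self) -> None:
        recomputed = AlignmentResult.from_aligned(self.aligned_a, self.aligned_b)
        if (recomputed.n_match, recomputed.n_mismatch, recomputed.n_gap_columns) != (
            self.n_match, self.n_mismatch, self.n_gap_columns,
        ):
            raise AssertionError("column counts disagree with aligned strings")


def score_from_aligned(
    aligned_a: str, aligned_b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Score of a given alignment, summed column-by-column with affine gap runs."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            score += scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += scheme.gap_extend if in_gap_b else scheme.gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += scheme.match if ca == cb else scheme.mismatch
            in_gap_a = in_gap_b = False
    return score


def global_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Optimal end-to-end global alignment of two canonicalized sequences.

    Raises ``ValueError`` for an empty input; alignment against the empty
    string is out of scope.
    """
    if not a or not b:
        raise ValueError("global alignment of an empty sequence is not supported")
    ea, eb = _encode(a), _encode(b)
    score, ops, nm, nmm, ng = _gotoh(
        ea, eb, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    ca: list[str] = []
    cb: list[str] = []
    i = j = 0
    for op in ops:
        if op == 0:
            ca.append(a[i]); cb.append(b[j])
            i += 1; j += 1
        elif op == 1:
            ca.append(a[i]); cb.append("-")
            i += 1
        else:
            ca.append("-"); cb.append(b[j])
            j += 1
    ident = 100.0 * nm / (nm + nmm) if (nm + nmm) > 0 else nan
    return AlignmentResult(
        aligned_a="".join(ca),
        aligned_b="".join(cb),
        score=float(score),
        n_match=int(nm),
        n_mismatch=int(nmm),
        n_gap_columns=int(ng),
        identity_pct=ident,
    )


def percent_identity(aln: AlignmentResult) -> float:
    """Gap-excluded percent identity of an alignment.

    Returns NaN (undefined) if every column contains a gap — impossible
    for an optimal alignment of non-empty sequences, but guarded.
    """
    denom = aln.n_match + aln.n_mismatch
    if denom == 0:
        log.warning("alignment has no gapless columns; identity undefined")
        return nan
    return 100.0 * aln.n_match / denom


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items, C(n, 2)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise percent identities.

    ``ids`` fixes the row/column order; the diagonal is 100 by definition
    (self-identity) and is never used by downstream statistics.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        self._index = {sid: k for k, sid in enumerate(self.ids)}

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise AssertionError("identity matrix is not symmetric")
        if self.values.min() < 0 or self.values.max() > 100:
            raise AssertionError("identities outside [0, 100]")
        if not np.allclose(np.diag(self.values), 100.0):
            raise AssertionError("diagonal must be 100")

    def iter_pairs(self):
        """Yield (id_a, id_b, identity) for unordered pairs in canonical order."""
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.ids[i], self.ids[j], float(self.values[i, j])

    def to_pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.iter_pairs()), columns=["id_a", "id_b", "identity_pct"]
        )

    def write_pairs_tsv(self, path: Union[str, Path]) -> None:
        df = self.to_pairs_frame()
        df["identity_pct"] = df["identity_pct"].map(lambda v: f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]], ids: Optional[Sequence[str]] = None
    ) -> "IdentityMatrix":
        pairs = list(pairs)
        if ids is None:
            ids = sorted({p[0] for p in pairs} | {p[1] for p in pairs})
        ids = tuple(ids)
        index = {sid: k for k, sid in enumerate(ids)}
        values = np.full((len(ids), len(ids)), np.nan)
        np.fill_diagonal(values, 100.0)
        for ida, idb, v in pairs:
            values[index[ida], index[idb]] = v
            values[index[idb], index[ida]] = v
        return cls(ids=ids, values=values)

    @classmethod
    def read_pairs_tsv(cls, path: Union[str, Path]) -> "IdentityMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        return cls.from_pairs(
            (r.id_a, r.id_b, float(r.identity_pct)) for r in df.itertuples(index=False)
        )


def _identity_of_pair(ea: np.ndarray, eb: np.ndarray, scheme: ScoringScheme) -> float:
    _, _, nm, nmm, _ = _gotoh(
        ea, eb, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    return 100.0 * nm / (nm + nmm) if (nm + nmm) > 0 else nan


def all_vs_all_identity(
    ds: StrainDataset,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    n_chunks: int = 1000,
    n_workers: int = 1,
) -> IdentityMatrix:
    """Identity matrix from one optimal alignment per unordered pair.

    Pairs are laid out in a fixed canonical order (sorted strain IDs) and
    split into ``n_chunks`` batches; batches may be processed by up to
    ``n_workers`` threads. The result is bit-for-bit independent of both
    parameters — they only control scheduling.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    ids = ds.ids()
    n = len(ids)
    if n < 2:
        raise ValueError("all-vs-all identity needs at least 2 sequences")
    encoded = [_encode(ds.sequences[sid].sequence) for sid in ids]
    n_pairs = pair_count(n)
    pair_idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.int64)
    chunks = [c for c in np.array_split(pair_idx, n_chunks) if len(c)]

    values = np.full((n, n), 100.0)

    def run_chunk(chunk: np.ndarray) -> np.ndarray:
        out = np.empty(len(chunk))
        for k, (i, j) in enumerate(chunk):
            out[k] = _identity_of_pair(encoded[i], encoded[j], scheme)
        return out

    log.info("aligning %d pairs in %d chunks (%d workers)", n_pairs, len(chunks), n_workers)
    if n_workers == 1:
        results = [run_chunk(c) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(run_chunk, chunks))
    for chunk, out in zip(chunks, results):
        values[chunk[:, 0], chunk[:, 1]] = out
        values[chunk[:, 1], chunk[:, 0]] = out
    return IdentityMatrix(ids=tuple(ids), values=values)
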