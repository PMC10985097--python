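"""Pairwise global alignment, percent identity and similarity-threshold
family annotation against a labelled reference toxin set.

Queries are aligned globally (Needleman-Wunsch, BLOSUM62, affine gaps
open -10 / extend -1) to every reference; the best reference's family label
is transferred when percent identity reaches the threshold (default 75%),
otherwise the query is classed "unknown".  Alignment is delegated to
Bio.Align.PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from . import scaffold as _scaffold
from .io_formats import ReferenceToxin, ValidationError

IDENTITY_THRESHOLD = 75.0
GAP_OPEN = -10.0
GAP_EXTEND = -1.0

_ALLOWED = set("ACDEFGHIKLMNPQRSTVWYXBZ")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    matches: int
    identity_pct: float

    def __len__(self):
        return len(self.aligned_query)


@dataclass(frozen=True)
class FamilyCall:
    query_id: str
    family: str                  # family label or "unknown"
    best_ref: str | None
    best_identity: float
    best_score: float
    scaffold_consistent: bool


@lru_cache(maxsize=None)
def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _check(seq: str, label: str) -> None:
    if not seq:
        raise ValidationError(f"{label}: empty sequence")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValidationError(f"{label}: illegal characters {sorted(bad)}")


def global_align(a: str, b: str, *, query_id: str = "query",
                 ref_id: str = "ref", gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND,
                 mode: str = "core") -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    The first optimal alignment under the aligner's deterministic traceback
    order is used, so results are reproducible.  ``mode`` selects the
    identity denominator (see :func:`percent_identity`).
    """
    _check(a, query_id)
    _check(b, ref_id)
    aln = _aligner(gap_open, gap_extend).align(a, b)[0]
    qa, ra = str(aln[0]), str(aln[1])
    matches = count_matches(qa, ra)
    return AlignmentResult(
        query_id=query_id, ref_id=ref_id,
        aligned_query=qa, aligned_ref=ra,
        score=float(aln.score), matches=matches,
        identity_pct=percent_identity_strings(qa, ra, mode=mode),
    )


def count_matches(qa: str, ra: str) -> int:
    """Identical aligned residue pairs; gaps never match and 'X' never
    counts as a match even against itself."""
    return sum(1 for x, y in zip(qa, ra)
               if x == y and x != "-" and x != "X")


def _core_span(qa: str, ra: str) -> tuple[int, int]:
    """Column span excluding terminal gap overhangs of either sequence."""
    n = len(qa)
    start = 0
    for s in (qa, ra):
        i = 0
        while i < n and s[i] == "-":
            i += 1
        start = max(start, i)
    end = n
    for s in (qa, ra):
        j = n
        while j > 0 and s[j - 1] == "-":
            j -= 1
        end = min(end, j)
    return start, max(start, end)


def percent_identity_strings(qa: str, ra: str, mode: str = "core") -> float:
    """Percent identity of an alignment, to 2 decimals.

    mode='core' (default): matches / columns, excluding terminal gap
    overhangs from the denominator.  mode='all': matches / all columns.
    """
    if len(qa) != len(ra):
        raise ValidationError("aligned strings differ in length")
    if mode == "all":
        lo, hi = 0, len(qa)
    elif mode == "core":
        lo, hi = _core_span(qa, ra)
    else:
        raise ValidationError(f"unknown identity mode {mode!r}")
    ncols = hi - lo
    if ncols == 0:
        raise ValidationError("zero effective alignment columns")
    m = count_matches(qa[lo:hi], ra[lo:hi])
    return round(100.0 * m / ncols, 2)


def percent_identity(alignment: AlignmentResult, mode: str = "core") -> float:
    return percent_identity_strings(alignment.aligned_query,
                                    alignment.aligned_ref, mode=mode)


def assign_family(query_id: str, query_seq: str,
                  reference_set: Sequence[ReferenceToxin],
                  threshold: float = IDENTITY_THRESHOLD,
                  templates: Iterable[_scaffold.FamilyTemplate]
                  = _scaffold.DEFAULT_TEMPLATES,
                  mode: str = "core") -> FamilyCall:
    """Annotate a query by its best global-alignment identity.

    Best reference = highest identity, ties broken by higher alignment
    score then lexicographic reference id.  Identity below the threshold
    (strict) gives family "unknown".
    """
    if not reference_set:
        raise ValidationError("reference set is empty")
    best: tuple[float, float, str, ReferenceToxin] | None = None
    for ref in reference_set:
        aln = global_align(query_seq, ref.seq, query_id=query_id,
                           ref_id=ref.id, mode=mode)
        key = (aln.identity_pct, aln.score, ref.id)
        if (best is None or key[0] > best[0]
                or (key[0] == best[0] and key[1] > best[1])
                or (key[0] == best[0] and key[1] == best[1]
                    and key[2] < best[2])):
            best = (key[0], key[1], ref.id, ref)
    identity, score, ref_id, ref = best
    family = ref.family if identity >= threshold else "unknown"
    qs = _scaffold.build_scaffold(query_seq)
    consistent = False
    if family != "unknown":
        consistent = any(t.family == family
                         for t, _ in _scaffold.match_template(qs, templates))
    return FamilyCall(query_id=query_id, family=family, best_ref=ref_id,
                      best_identity=identity, best_score=score,
                      scaffold_consistent=consistent)


def annotate_records(records, reference_set, **kw) -> list[FamilyCall]:
    return [assign_family(r.id, r.seq, reference_set, **kw) for r in records]
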