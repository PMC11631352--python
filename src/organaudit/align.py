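"""Semi-global pairwise DNA alignment with identity and coverage.

Alignments are computed with Biopython's ``PairwiseAligner`` (match +1,
mismatch −1, linear gap −2, terminal gaps free on both ends) over a custom
substitution matrix in which two IUPAC codes score as a match when their
base sets intersect. Identity is matches over alignment columns excluding
terminal-gap columns (internal gap columns count); coverage is the fraction
of the query inside the non-terminal-gap region.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .refdb import IUPAC_SETS

_ALPHABET = "ACGTRYSWKMBDHVN"


def _build_matrix():
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            m[x, y] = 1.0 if IUPAC_SETS[x] & IUPAC_SETS[y] else -1.0
    return m

_MATRIX = _build_matrix()


def _make_aligner(query_global: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # deletions are reference-base/query-gap columns: free reference flanks
    aligner.end_deletion_score = 0
    # insertions are query-base/reference-gap columns: dropping query ends
    # is free in overlap mode, penalized in query-global mode
    aligner.end_insertion_score = -2 if query_global else 0
    return aligner

_ALIGNER_OVERLAP = _make_aligner(query_global=False)
_ALIGNER_QUERY_GLOBAL = _make_aligner(query_global=True)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    ref_id: str
    identity: float
    coverage: float
    score: int

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


def semiglobal_align(a: str, b: str, query_id: str = "query",
                     ref_id: str = "ref", query_global: bool = False) -> AlignmentHit:
    """Optimal semi-global alignment of query ``a`` against reference ``b``.

    By default terminal gaps are free on both ends of both sequences
    (overlap alignment). With ``query_global=True`` only the reference's
    flanks are free — the query must align end to end, the semantics of a
    vsearch-style global database search. Identity and coverage are computed
    from the resulting alignment the same way in both modes.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _ALIGNER_QUERY_GLOBAL if query_global else _ALIGNER_OVERLAP
    alignments = aligner.align(b, a)  # target=reference, query=a
    best = alignments[0]
    t_blocks, q_blocks = best.aligned
    if len(q_blocks) == 0:  # no aligned columns at all
        return AlignmentHit(query_id, ref_id, 0.0, 0.0, int(best.score))
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for tb, qb in zip(b[ts:te], a[qs:qe]):
            if IUPAC_SETS[tb] & IUPAC_SETS[qb]:
                matches += 1
        columns += te - ts
    # internal gap columns between consecutive aligned blocks
    for i in range(len(q_blocks) - 1):
        columns += (t_blocks[i + 1][0] - t_blocks[i][1])
        columns += (q_blocks[i + 1][0] - q_blocks[i][1])
    q_start = q_blocks[0][0]
    q_end = q_blocks[-1][1]
    identity = matches / columns if columns else 0.0
    coverage = (q_end - q_start) / len(a)
    return AlignmentHit(query_id, ref_id, identity, coverage, int(best.score))
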