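"""Local-alignment kernel: exact k-mer seeding + Smith–Waterman scoring.

The healing designer needs BLAST-like searches of 2.5-kb flanks against
donor genomes at desk scale. The kernel seeds with exact k-mers to find
candidate windows, then resolves each window with an affine-gap
Smith–Waterman (Gotoh) alignment. Scoring follows familiar BLAST-ish
defaults: match +1, mismatch −1, first gap base −2, each further gap
base −1. Identity is defined as identical columns divided by total
alignment columns, gap columns counting against identity.

Small problems skip seeding and run the full dynamic program, so the
kernel is exact whenever the DP matrix is affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

from Bio import Align

from isforge.seqio import revcomp

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2  # score of the first base of a gap
GAP_EXTEND = -1  # score of each subsequent gap base

# full-DP ceiling: below this many matrix cells, skip seeding entirely
_FULL_DP_CELLS = 16_000_000
_MAX_TIE_ENUM = 64


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query within a reference.

    Coordinates are 0-based half-open on the forward reference strand;
    ``strand`` records which query orientation aligned.
    """

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    score: float
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _hit_from_alignment(aln, strand: str, ref_len: int, query_len: int) -> LocalHit:
    counts = aln.counts()
    ref_start = int(aln.coordinates[0][0])
    ref_end = int(aln.coordinates[0][-1])
    q_start = int(aln.coordinates[1][0])
    q_end = int(aln.coordinates[1][-1])
    if strand == "-":
        # alignment was computed against the reverse-complemented query
        q_start, q_end = query_len - q_end, query_len - q_start
    return LocalHit(
        ref_start=ref_start,
        ref_end=ref_end,
        query_start=q_start,
        query_end=q_end,
        strand=strand,
        score=float(aln.score),
        matches=int(counts.identities),
        columns=int(counts.identities + counts.mismatches + counts.gaps),
    )


def _best_in_window(query: str, ref: str, strand: str, query_len: int) -> LocalHit | None:
    """Optimal local alignment; ties broken by lowest reference coordinate."""
    aligner = _aligner("local")
    q = revcomp(query) if strand == "-" else query
    alignments = aligner.align(ref, q)
    try:
        first = alignments[0]
    except (IndexError, ValueError):
        return None
    if first.score <= 0:
        return None
    best = None
    for aln in islice(alignments, _MAX_TIE_ENUM):
        hit = _hit_from_alignment(aln, strand, len(ref), query_len)
        key = (hit.ref_start, hit.query_start)
        if best is None or key < (best.ref_start, best.query_start):
            best = hit
    return best


def _seed_windows(query: str, ref: str, k: int, band: int) -> list[tuple[int, int]]:
    """Candidate reference windows from exact k-mer seed diagonals."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    diagonals: list[int] = []
    step = max(1, k // 3)
    for j in range(0, len(ref) - k + 1, step):
        for qpos in index.get(ref[j : j + k], ()):
            diagonals.append(j - qpos)
    if not diagonals:
        return []
    diagonals.sort()
    clusters: list[list[int]] = [[diagonals[0]]]
    for d in diagonals[1:]:
        if d - clusters[-1][-1] <= 2 * band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    clusters.sort(key=len, reverse=True)
    windows = []
    for cl in clusters[:5]:
        lo = max(0, cl[0] - band)
        hi = min(len(ref), cl[-1] + len(query) + band)
        windows.append((lo, hi))
    return windows


def best_local_hit(
    query: str,
    ref: str,
    *,
    k: int = 15,
    band: int = 50,
    both_strands: bool = True,
) -> LocalHit | None:
    """Highest-scoring local alignment of ``query`` in ``ref``.

    Runs the full dynamic program outright when the matrix is small;
    otherwise exact k-mer seeds select candidate windows (on each strand)
    which are resolved by the same dynamic program. Returns ``None`` when
    nothing aligns with positive score (for seeded searches: when no seed
    hits at all), which callers interpret as "absent".

    Ties are broken deterministically by lowest reference coordinate,
    with the forward strand preferred over the reverse.
    """
    if not query or not ref:
        return None
    strands = ("+", "-") if both_strands else ("+",)
    best: LocalHit | None = None

    def consider(hit: LocalHit | None) -> None:
        nonlocal best
        if hit is None:
            return
        if (
            best is None
            or hit.score > best.score
            or (
                hit.score == best.score
                and (hit.ref_start, hit.strand) < (best.ref_start, best.strand)
            )
        ):
            best = hit

    if len(query) * len(ref) <= _FULL_DP_CELLS or len(query) < k:
        for strand in strands:
            consider(_best_in_window(query, ref, strand, len(query)))
        return best

    for strand in strands:
        q = revcomp(query) if strand == "-" else query
        for lo, hi in _seed_windows(q, ref, k, band):
            hit = _best_in_window(query, ref[lo:hi], strand, len(query))
            if hit is not None:
                consider(
                    LocalHit(
                        ref_start=hit.ref_start + lo,
                        ref_end=hit.ref_end + lo,
                        query_start=hit.query_start,
                        query_end=hit.query_end,
                        strand=strand,
                        score=hit.score,
                        matches=hit.matches,
                        columns=hit.columns,
                    )
                )
    return best


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global (Needleman–Wunsch) alignment.

    Identical columns over total columns; gap columns count as
    differences. Used for the fixed-window donor/target comparisons.
    """
    if not a or not b:
        raise ValueError("global_identity requires nonempty sequences")
    aligner = _aligner("global")
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns
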