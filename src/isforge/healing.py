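"""Comparative-genomics "genome healing" deletion design.

An IS element disrupting a locus can be removed scarlessly by importing
the syntenous, IS-free allele from a closely related donor genome: search
each donor for the two 2.5-kb flanks of the element, require them to be
co-linear and directly adjacent (the element absent), check that the
750-bp windows abutting the healed junction are >99% identical to the
target, and amplify a construct with 500–600-bp homology arms from the
best donor. Where no donor qualifies, a conventional deletion construct
(CDS + promoter, extents supplied by the user) is designed from the
target genome itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from isforge.align import LocalHit, best_local_hit, global_identity
from isforge.seqio import GenomeRecord, Interval, revcomp

DEFAULT_FLANK = 2500
DEFAULT_WINDOW = 750
DEFAULT_MIN_IDENTITY = 0.99
DEFAULT_ARM_RANGE = (500, 600)
# donor junction gap below this fraction of the IS length counts as "absent"
DEFAULT_MAX_GAP_FRAC = 0.10
# small alignment-overlap slack at the healed junction (bp)
JUNCTION_OVERLAP_SLACK = 50


@dataclass(frozen=True)
class ISAnnotation:
    """An annotated IS element on the target genome.

    ``ir_left``/``ir_right`` are the 24-bp imperfect terminal inverted
    repeats; ``locus`` spans the whole element including both repeats.
    """

    name: str
    locus: Interval
    family: str
    ir_left: str = ""
    ir_right: str = ""

    def __post_init__(self) -> None:
        if self.ir_left and len(self.locus) < 2 * len(self.ir_left):
            raise ValueError(f"{self.name}: locus shorter than its inverted repeats")

    def ir_mismatches(self) -> int | None:
        """Mismatches between ir_left and revcomp(ir_right); None if unset."""
        if not (self.ir_left and self.ir_right):
            return None
        rc = revcomp(self.ir_right)
        return sum(a != b for a, b in zip(self.ir_left, rc))


@dataclass(frozen=True)
class DonorCandidate:
    """One donor genome's syntenous, IS-free replacement region."""

    donor_id: str
    donor_interval: Interval  # forward-donor coordinates spanning both flank hits
    up_identity: float
    down_identity: float
    combined_identity: float
    is_absent: bool
    strand: str  # donor strand carrying the target-orientation region
    junction_gap: int  # bp between the flank hits at the healed junction
    # donor sequence in target orientation, ending at / starting from the junction
    upstream_seq: str = field(repr=False, default="")
    downstream_seq: str = field(repr=False, default="")


@dataclass(frozen=True)
class DeletionConstruct:
    """A deletion/healing construct: two homology arms and their source."""

    name: str
    left_arm: str
    right_arm: str
    insert_source: str  # "donor:<id>" or "conventional"
    healed_interval: Interval


def extract_query(target: GenomeRecord, is_ann: ISAnnotation, flank: int = DEFAULT_FLANK) -> str:
    """Element sequence with ``flank`` bp of context on each side.

    Wraps the origin on circular genomes; on a linear genome a flank
    overrunning either end is an error (raised by the fetch).
    """
    loc = is_ann.locus
    return target.fetch(loc.start - flank, loc.end + flank)


def align_flank(query_flank: str, donor: GenomeRecord, *, k: int = 15, band: int = 50) -> LocalHit | None:
    """Best local hit of one flank in a donor genome; None means absent."""
    return best_local_hit(query_flank, donor.seq, k=k, band=band)


def _candidate_for_donor(
    target: GenomeRecord,
    is_ann: ISAnnotation,
    donor: GenomeRecord,
    flank: int,
    window: int,
    max_gap_frac: float,
) -> DonorCandidate | None:
    loc = is_ann.locus
    is_len = len(loc)
    up_flank = target.fetch(loc.start - flank, loc.start)
    down_flank = target.fetch(loc.end, loc.end + flank)
    t_up = up_flank[-window:]
    t_down = down_flank[:window]

    for strand, donor_seq in (("+", donor.seq), ("-", revcomp(donor.seq))):
        hit_up = best_local_hit(up_flank, donor_seq, both_strands=False)
        hit_down = best_local_hit(down_flank, donor_seq, both_strands=False)
        if hit_up is None or hit_down is None:
            continue
        # require substantial flank hits, not chance micro-alignments
        if hit_up.columns < flank // 3 or hit_down.columns < flank // 3:
            continue
        gap = hit_down.ref_start - hit_up.ref_end
        if gap < -JUNCTION_OVERLAP_SLACK:
            continue  # not co-linear in this orientation
        is_absent = gap < max_gap_frac * is_len
        j_left = hit_up.ref_end
        j_right = max(hit_down.ref_start, j_left)
        up_start = max(0, j_left - flank)
        down_end = min(len(donor_seq), j_right + flank)
        upstream_seq = donor_seq[up_start:j_left]
        downstream_seq = donor_seq[j_right:down_end]
        if len(upstream_seq) < window or len(downstream_seq) < window:
            continue
        up_id = global_identity(t_up, upstream_seq[-window:])
        down_id = global_identity(t_down, downstream_seq[:window])
        # forward-donor coordinates of the whole replacement region
        n = len(donor_seq)
        if strand == "+":
            fwd = Interval(donor.id, hit_up.ref_start, hit_down.ref_end, "+")
        else:
            fwd = Interval(donor.id, n - hit_down.ref_end, n - hit_up.ref_start, "-")
        return DonorCandidate(
            donor_id=donor.id,
            donor_interval=fwd,
            up_identity=up_id,
            down_identity=down_id,
            combined_identity=(up_id + down_id) / 2.0,
            is_absent=is_absent,
            strand=strand,
            junction_gap=gap,
            upstream_seq=upstream_seq,
            downstream_seq=downstream_seq,
        )
    return None


def find_donor_candidates(
    target: GenomeRecord,
    is_ann: ISAnnotation,
    donors: list[GenomeRecord],
    *,
    flank: int = DEFAULT_FLANK,
    window: int = DEFAULT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
) -> list[DonorCandidate]:
    """Ranked healing candidates across donor genomes.

    A donor qualifies when both element flanks hit co-linearly on one
    donor strand, the junction gap is smaller than ``max_gap_frac`` of
    the element length (the element is absent), and both ``window``-bp
    identities immediately abutting the healed junction exceed
    ``min_identity``. Candidates are ranked by combined identity, ties
    broken by donor id then coordinate, so the ranking is a total order
    independent of donor input order.
    """
    candidates = []
    for donor in donors:
        cand = _candidate_for_donor(target, is_ann, donor, flank, window, max_gap_frac)
        if cand is None or not cand.is_absent:
            continue
        if cand.up_identity > min_identity and cand.down_identity > min_identity:
            candidates.append(cand)
    candidates.sort(
        key=lambda c: (-c.combined_identity, c.donor_id, c.donor_interval.start)
    )
    return candidates


def _arm_from_junction(seq_toward_junction: str, arm_range: tuple[int, int], side: str) -> str:
    """Pick the homology arm adjacent to the junction, avoiding N.

    ``seq_toward_junction`` is oriented so the junction is at its 3' end
    (left arm) — the right arm passes the reversed problem and flips back.
    Default arm length is the midpoint of the allowed range, shortened to
    exclude any N if that still leaves at least the minimum length.
    """
    lo, hi = arm_range
    if not lo <= hi:
        raise ValueError("invalid arm length range")
    default = (lo + hi) // 2
    if len(seq_toward_junction) < lo:
        raise ValueError(f"{side} arm: insufficient donor sequence ({len(seq_toward_junction)} bp)")
    window = seq_toward_junction[-min(default, len(seq_toward_junction)) :]
    n_pos = window.rfind("N")
    if n_pos == -1:
        length = len(window)
    else:
        length = len(window) - n_pos - 1
        if length < lo:
            raise ValueError(
                f"{side} arm: N within {default} bp of the junction leaves only "
                f"{length} clean bp (< {lo})"
            )
    return seq_toward_junction[-length:]


def design_healing_construct(
    candidate: DonorCandidate,
    target: GenomeRecord,
    is_ann: ISAnnotation,
    arm_len_range: tuple[int, int] = DEFAULT_ARM_RANGE,
) -> DeletionConstruct:
    """Emit the healing construct for a qualified donor candidate."""
    left = _arm_from_junction(candidate.upstream_seq, arm_len_range, "left")
    right = _arm_from_junction(candidate.downstream_seq[::-1], arm_len_range, "right")[::-1]
    return DeletionConstruct(
        name=f"{is_ann.name}_heal_{candidate.donor_id}",
        left_arm=left,
        right_arm=right,
        insert_source=f"donor:{candidate.donor_id}",
        healed_interval=is_ann.locus,
    )


def design_conventional_deletion(
    target: GenomeRecord,
    feature: Interval,
    name: str = "conventional_deletion",
    arm_len_range: tuple[int, int] = DEFAULT_ARM_RANGE,
) -> DeletionConstruct:
    """Deletion construct for a CDS + promoter interval on the target.

    Used for loci with no qualifying donor. The feature extent (including
    the promoter) is user input; arms are taken from the target genome
    immediately flanking it, wrapping the origin on circular genomes.
    """
    if len(feature) < 1:
        raise ValueError("feature interval must be nonempty")
    lo, hi = arm_len_range
    default = (lo + hi) // 2
    left_ctx = target.fetch(feature.start - default, feature.start)
    right_ctx = target.fetch(feature.end, feature.end + default)
    left = _arm_from_junction(left_ctx, arm_len_range, "left")
    right = _arm_from_junction(right_ctx[::-1], arm_len_range, "right")[::-1]
    return DeletionConstruct(
        name=name,
        left_arm=left,
        right_arm=right,
        insert_source="conventional",
        healed_interval=feature,
    )


def apply_construct(
    target: GenomeRecord, is_ann: ISAnnotation, construct: DeletionConstruct
) -> GenomeRecord:
    """In-silico double crossover: replace the element and the arm-length
    flanks of the target with the construct's joined arms."""
    loc = is_ann.locus
    left_len = len(construct.left_arm)
    right_len = len(construct.right_arm)
    n = len(target.seq)
    start = (loc.start - left_len) % n if target.topology == "circular" else loc.start - left_len
    end = loc.end + right_len
    if target.topology == "linear":
        if start < 0 or end > n:
            raise ValueError("arms overrun the linear target")
        healed = target.seq[:start] + construct.left_arm + construct.right_arm + target.seq[end:]
    else:
        replaced = left_len + len(loc) + right_len
        if replaced >= n:
            raise ValueError("construct replaces the whole circular target")
        # rotated so the construct sits at the origin of the healed record
        healed = (
            construct.left_arm
            + construct.right_arm
            + target.fetch(loc.end + right_len, loc.end + right_len + (n - replaced))
        )
    return GenomeRecord(target.id + "_healed", healed, target.topology)
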