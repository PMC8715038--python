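"""Insertion-site calling from marker-anchored long reads.

Enrichment reads run from inside the transposon's selection marker,
across the terminal inverted repeat (IR), into flanking genomic DNA.
Mapped against both the delivery plasmid and the genome, each informative
read therefore splits into a plasmid-local alignment ending at the IR's
outer edge and a genomic alignment starting right after it in read
space. Junction calling pairs those two blocks, classifies the event,
projects the junction back to the genome, and deduplicates events into
insertion sites with read counts.

Coordinate convention: ``junction_pos`` is the 0-based genomic position
of the first target base 3' of the IR *on the element's strand*. The
8-bp target window of a '+' site is ``[pos, pos+8)``; for a '-' site it
is the reverse complement of ``[pos-8, pos)``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from isforge.seqio import AlignmentRecord, Interval

logger = logging.getLogger(__name__)

DEFAULT_MAX_READ_GAP = 20
DEFAULT_IR_EDGE_TOL = 10
DEFAULT_BACKBONE_THRESHOLD = 50
DEFAULT_POSITION_TOL = 3
DEFAULT_MIN_READS_FOR_MOTIF = 2


@dataclass(frozen=True)
class JunctionEvent:
    """One read's marker–genome junction."""

    read_id: str
    marker_aln: AlignmentRecord
    genome_aln: AlignmentRecord | None
    junction_pos: int | None
    orientation: str | None  # strand of the inserted element in the genome
    gap_on_read: int | None  # signed bp between the two blocks on the read
    event_class: str  # {transposition, plasmid_integration, ambiguous}


@dataclass(frozen=True)
class InsertionSite:
    """A deduplicated genomic insertion site."""

    locus: Interval  # 1 bp
    orientation: str
    read_count: int
    octamer: str | None = None
    replichore_strand: str = "unassigned"  # {leading, lagging, unassigned}

    # BED6 adapter attributes
    @property
    def ref_id(self) -> str:
        return self.locus.ref_id

    @property
    def start(self) -> int:
        return self.locus.start

    @property
    def end(self) -> int:
        return self.locus.end

    @property
    def name(self) -> str:
        return f"site_{self.locus.start}_{self.orientation}"

    @property
    def score(self) -> int:
        return self.read_count

    @property
    def strand(self) -> str:
        return self.orientation


def call_junctions(
    alignments: list[AlignmentRecord],
    plasmid_marker: Interval,
    *,
    max_read_gap: int = DEFAULT_MAX_READ_GAP,
    ir_edge_tol: int = DEFAULT_IR_EDGE_TOL,
    backbone_threshold: int = DEFAULT_BACKBONE_THRESHOLD,
) -> list[JunctionEvent]:
    """Pair marker and genomic alignment blocks into junction events.

    ``plasmid_marker`` is the interval on the plasmid running through the
    marker up to (and ending exactly at) the IR's outer edge. A read
    yields an event when one of its plasmid alignments ends within
    ``ir_edge_tol`` of that edge; the event is

    * ``plasmid_integration`` when plasmid alignment continues more than
      ``backbone_threshold`` bp beyond the IR (whole-vector integration,
      e.g. via a cryptic attB site),
    * ``transposition`` when a genomic block starts within
      ``max_read_gap`` bp after the IR edge in read space,
    * ``ambiguous`` otherwise.

    For transpositions the junction is projected back to the exact IR
    edge: a read-space gap of g bp shifts the genomic coordinate by g so
    small alignment erosion at the junction does not move the site.
    Reads with genomic alignments only are skipped (no marker anchor)
    and tallied in the log.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)

    plasmid_id = plasmid_marker.ref_id
    ir_edge = plasmid_marker.end
    events: list[JunctionEvent] = []
    n_unanchored = 0

    for read_id, alns in by_read.items():
        plasmid_alns = [a for a in alns if a.ref_id == plasmid_id]
        genome_alns = [a for a in alns if a.ref_id != plasmid_id]
        # an anchor reaches (or crosses) the IR outer edge from inside the marker
        anchors = [
            a
            for a in plasmid_alns
            if a.ref_start < ir_edge and a.ref_end >= ir_edge - ir_edge_tol
        ]
        if not anchors:
            if genome_alns and not plasmid_alns:
                n_unanchored += 1
            # plasmid alignment far from the IR edge carries no junction
            continue
        # the anchor closest to the IR edge wins
        anchor = min(anchors, key=lambda a: (abs(a.ref_end - ir_edge), a.read_start))

        backbone_overrun = max(
            (a.ref_end - ir_edge for a in plasmid_alns), default=0
        )
        if backbone_overrun > backbone_threshold:
            events.append(
                JunctionEvent(read_id, anchor, None, None, None, None, "plasmid_integration")
            )
            continue

        # read-space position of the IR outer edge, projected along the
        # anchor's diagonal so over- or under-extension of the plasmid
        # block past the IR does not shift the junction
        overrun = anchor.ref_end - ir_edge
        if anchor.strand == "+":
            ir_read_pos = anchor.read_end - overrun
        else:
            ir_read_pos = anchor.read_start + overrun
        best = None
        for g in genome_alns:
            if anchor.strand == "+":
                gap = g.read_start - ir_read_pos
            else:
                gap = ir_read_pos - g.read_end
            # overlaps (negative gap) arise when one block's extension
            # drifts across the junction on chance matches; the diagonal
            # projection below recovers the exact junction, so the window
            # is symmetric
            if -max_read_gap <= gap <= max_read_gap:
                if best is None or abs(gap) < abs(best[1]):
                    best = (g, gap)
        if best is None:
            events.append(
                JunctionEvent(read_id, anchor, None, None, None, None, "ambiguous")
            )
            continue
        g, gap = best
        orientation = "+" if g.strand == anchor.strand else "-"
        if anchor.strand == "+":
            genome_fwd = g.strand == "+"
        else:
            genome_fwd = g.strand == "-"
        # project the junction back to the IR edge across the read-space gap
        if genome_fwd:
            junction_pos = g.ref_start - gap
        else:
            junction_pos = g.ref_end + gap
        if g.ref_len > 0:
            # wrap: junctions projected past the origin of a circular genome
            junction_pos %= g.ref_len
        events.append(
            JunctionEvent(
                read_id=read_id,
                marker_aln=anchor,
                genome_aln=g,
                junction_pos=junction_pos,
                orientation=orientation,
                gap_on_read=gap,
                event_class="transposition",
            )
        )
    if n_unanchored:
        logger.info("call_junctions: %d reads had genomic alignments only", n_unanchored)
    return events


def collapse_sites(
    events: list[JunctionEvent],
    *,
    position_tolerance: int = DEFAULT_POSITION_TOL,
    min_reads_for_motif: int = DEFAULT_MIN_READS_FOR_MOTIF,
) -> list[InsertionSite]:
    """Merge transposition events into deduplicated insertion sites.

    Events on the same strand within ``position_tolerance`` bp (single
    linkage over sorted positions) merge into one site whose coordinate
    is the modal junction position (ties to the smallest). Opposite
    strands never merge. The site list keeps single-read sites; the
    ``min_reads_for_motif`` threshold is applied downstream when target
    windows are extracted.
    """
    _ = min_reads_for_motif
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for ev in events:
        if ev.event_class != "transposition":
            continue
        groups[(ev.genome_aln.ref_id, ev.orientation)].append(ev.junction_pos)

    sites: list[InsertionSite] = []
    for (ref_id, orientation), positions in groups.items():
        positions.sort()
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > position_tolerance:
                sites.append(_emit_site(ref_id, orientation, cluster))
                cluster = []
            cluster.append(pos)
        if cluster:
            sites.append(_emit_site(ref_id, orientation, cluster))
    sites.sort(key=lambda s: (s.locus.ref_id, s.locus.start, 0 if s.orientation == "+" else 1))
    return sites


def _emit_site(ref_id: str, orientation: str, positions: list[int]) -> InsertionSite:
    counts = Counter(positions)
    top = max(counts.values())
    modal = min(p for p, c in counts.items() if c == top)
    return InsertionSite(
        locus=Interval(ref_id, modal, modal + 1, orientation),
        orientation=orientation,
        read_count=len(positions),
    )


def assign_replichore(
    sites: list[InsertionSite],
    oriC_pos: int,
    ter_pos: int,
    genome_len: int,
) -> list[InsertionSite]:
    """Classify each site's element orientation as leading or lagging.

    The circular chromosome splits at oriC and ter into two replichores.
    On replichore 1 (oriC -> ter, increasing coordinates modulo length)
    the replication fork travels with the '+' strand, so orientation '+'
    is leading and '-' lagging; on replichore 2 the assignment inverts.
    """
    if oriC_pos % genome_len == ter_pos % genome_len:
        raise ValueError("oriC and ter positions coincide")
    repl1_span = (ter_pos - oriC_pos) % genome_len
    out = []
    for s in sites:
        offset = (s.locus.start - oriC_pos) % genome_len
        on_repl1 = offset < repl1_span
        if on_repl1:
            strand = "leading" if s.orientation == "+" else "lagging"
        else:
            strand = "lagging" if s.orientation == "+" else "leading"
        out.append(
            InsertionSite(
                locus=s.locus,
                orientation=s.orientation,
                read_count=s.read_count,
                octamer=s.octamer,
                replichore_strand=strand,
            )
        )
    return out


def strand_partition(sites: list[InsertionSite]) -> dict[str, int]:
    """Counts of leading/lagging (and the plain +/- split, reported side
    by side since either convention may underlie a published figure)."""
    repl = Counter(s.replichore_strand for s in sites)
    plain = Counter(s.orientation for s in sites)
    return {
        "leading": repl.get("leading", 0),
        "lagging": repl.get("lagging", 0),
        "unassigned": repl.get("unassigned", 0),
        "plus": plain.get("+", 0),
        "minus": plain.get("-", 0),
    }


def positional_summary(
    sites: list[InsertionSite],
    genome_len: int,
    n_bins: int,
) -> pd.DataFrame:
    """Per-bin site counts for the two rings of a polar genome plot.

    Bins are half-open ``[i*w, (i+1)*w)`` with the last bin absorbing the
    remainder; counts over all bins and rings sum to the number of sites.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0, genome_len, n_bins + 1)
    rows = []
    pos = np.array([s.locus.start for s in sites], dtype=float)
    leading = np.array([s.replichore_strand == "leading" for s in sites], dtype=bool)
    idx = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        in_bin = idx == b
        rows.append(
            {
                "bin": b,
                "start": int(edges[b]),
                "end": int(edges[b + 1]),
                "leading": int(np.sum(in_bin & leading)),
                "lagging": int(np.sum(in_bin & ~leading)),
            }
        )
    return pd.DataFrame(rows)


def polar_plot(summary: pd.DataFrame, genome_len: int, path: str, title: str = "") -> None:
    """Render the positional summary as a polar plot: leading ring outer,
    lagging ring inner."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = (summary["start"] + summary["end"]) / 2.0
    theta = 2 * np.pi * centers / genome_len
    width = 2 * np.pi * (summary["end"] - summary["start"]) / genome_len
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    max_count = max(1, summary[["leading", "lagging"]].to_numpy().max())
    ax.bar(theta, summary["leading"] / max_count, width=width, bottom=1.1, color="tab:blue", label="leading")
    ax.bar(theta, -summary["lagging"] / max_count, width=width, bottom=1.0, color="tab:orange", label="lagging")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", bbox_to_anchor=(1.1, -0.1))
    fig.savefig(path, dpi=120)
    plt.close(fig)
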