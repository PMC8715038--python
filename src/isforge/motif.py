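"""Target-site preference statistics over the 8-bp window downstream of
the inverted repeat.

Each insertion site contributes one strand-specific octamer: for a '+'
site the genomic window [pos, pos+8), for a '-' site the reverse
complement of [pos-8, pos). The octamers feed a position frequency /
information-content matrix (logo heights, optionally with the standard
WebLogo small-sample correction) and a frequency table of the central
tetranucleotide (octamer positions 3–6, 1-based), where a transposase's
local AT preference shows up most clearly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from isforge.seqio import GenomeRecord, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
OCTAMER_LEN = 8
CENTRAL_SPAN = (2, 6)  # 0-based half-open slice for octamer positions 3-6
DEFAULT_CEILING = 0.20


@dataclass(frozen=True)
class PositionMatrix:
    """Per-position base counts and information content over the window."""

    counts: np.ndarray  # 4 x width, rows in BASES order
    n_sites: int
    info_bits: np.ndarray  # per-position 2 - H (bits), correction applied if set
    small_sample_correction: bool

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n_sites

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(BASES))
        df.columns = [str(i + 1) for i in range(self.counts.shape[1])]
        return df.reset_index(names="base")


@dataclass(frozen=True)
class TetramerTable:
    """Central 4-mer frequencies, sorted descending."""

    freqs: dict[str, float]
    n_sites: int
    ceiling: float
    ceiling_exceeded: bool

    @property
    def most_frequent(self) -> tuple[str, float]:
        return next(iter(self.freqs.items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tetramer": list(self.freqs), "frequency": list(self.freqs.values())}
        )


def extract_octamers(
    sites,
    genome: GenomeRecord,
    *,
    min_reads: int = 2,
    width: int = OCTAMER_LEN,
    read_weighted: bool = False,
) -> list[str]:
    """Strand-specific target windows for sites passing the read filter.

    Windows containing N are dropped and logged, as are windows running
    past the end of a linear contig. With ``read_weighted`` each site
    contributes its window once per supporting read instead of once per
    site.
    """
    octamers: list[str] = []
    n_dropped = 0
    n = len(genome.seq)
    for site in sites:
        if site.read_count < min_reads:
            continue
        pos = site.locus.start
        try:
            if site.orientation == "+":
                window = genome.fetch(pos, pos + width)
            else:
                window = revcomp(genome.fetch(pos - width, pos))
        except ValueError:
            n_dropped += 1
            continue
        if "N" in window:
            n_dropped += 1
            continue
        octamers.extend([window] * (site.read_count if read_weighted else 1))
    if n_dropped:
        logger.info("extract_octamers: dropped %d windows (N or contig edge)", n_dropped)
    _ = n
    return octamers


def position_matrix(octamers: list[str], small_sample_correction: bool = False) -> PositionMatrix:
    """Base counts and information content per window position.

    Information content is 2 − H_i bits with H_i the Shannon entropy of
    column i. With the correction on, the standard small-sample term
    e(n) = 3 / (2·ln2·n) is subtracted (floored at zero), matching how
    logo software compensates finite sample sizes.
    """
    if not octamers:
        raise ValueError("position_matrix requires at least one window")
    width = len(octamers[0])
    if any(len(o) != width for o in octamers):
        raise ValueError("all windows must have equal length")
    arr = np.frombuffer("".join(octamers).encode(), dtype=np.uint8).reshape(len(octamers), width)
    counts = np.zeros((4, width), dtype=int)
    for row, base in enumerate(BASES):
        counts[row] = np.sum(arr == ord(base), axis=0)
    if not np.all(counts.sum(axis=0) == len(octamers)):
        raise ValueError("windows contain characters outside ACGT")
    p = counts / len(octamers)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=0)
    info = 2.0 - entropy
    if small_sample_correction:
        info = np.maximum(0.0, info - 3.0 / (2.0 * math.log(2) * len(octamers)))
    return PositionMatrix(
        counts=counts,
        n_sites=len(octamers),
        info_bits=info,
        small_sample_correction=small_sample_correction,
    )


def tetramer_frequencies(
    octamers: list[str],
    central_span: tuple[int, int] = CENTRAL_SPAN,
    ceiling: float = DEFAULT_CEILING,
) -> TetramerTable:
    """Frequencies of the central 4-mer across all windows.

    Reported sorted descending, with a flag raised when any single
    tetramer exceeds the ``ceiling`` fraction of all insertions — the
    sanity line between "weak local preference" and "a genuine consensus
    target".
    """
    if not octamers:
        raise ValueError("tetramer_frequencies requires at least one window")
    lo, hi = central_span
    counts: dict[str, int] = {}
    for o in octamers:
        tet = o[lo:hi]
        counts[tet] = counts.get(tet, 0) + 1
    total = len(octamers)
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    freqs = {k: v / total for k, v in items}
    return TetramerTable(
        freqs=freqs,
        n_sites=total,
        ceiling=ceiling,
        ceiling_exceeded=any(f > ceiling for f in freqs.values()),
    )


_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def render_logo(matrix: PositionMatrix, path: str, title: str = "") -> None:
    """Draw a sequence logo: letters stacked by frequency × information.

    Letters are rendered as scaled text-path patches, tallest on top, on
    a 0–2 bit axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    font = FontProperties(family="DejaVu Sans", weight="bold")
    freqs = matrix.freqs
    width = freqs.shape[1]
    fig, ax = plt.subplots(figsize=(max(4, width * 0.7), 3))
    for col in range(width):
        heights = freqs[:, col] * matrix.info_bits[col]
        order = np.argsort(heights)  # small letters at the bottom
        y = 0.0
        for row in order:
            h = float(heights[row])
            if h <= 1e-9:
                continue
            letter = BASES[row]
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            sx = 0.9 / bbox.width
            sy = h / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(sx, sy)
                .translate(col + 0.05, y)
            )
            ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                                   color=_LOGO_COLORS[letter], lw=0))
            y += h
    ax.set_xlim(0, width)
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(width) + 0.5)
    ax.set_xticklabels([str(i + 1) for i in range(width)])
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
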