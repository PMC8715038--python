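"""Bxb1 serine-integrase site algebra.

Serine integrases recombine a bacterial attachment site (attB) with a
phage attachment site (attP), exchanging the half-sites around a central
dinucleotide to form the hybrids attL and attR. Without a recombination
directionality factor the reaction is one-way: attL/attR are not
substrates. Three consequences are modelled here:

* a genetic switch — attB and attP in inverted orientation flank a
  promoter; recombination inverts the intervening segment (flipping the
  promoter) and leaves attL/attR behind, so the switch throws once;
* plasmid integration — a circular plasmid carrying attP integrates at a
  genomic attB, ending up flanked by attL and attR;
* scanning for degenerate genomic attB sites with per-position weights,
  the phenomenon behind unintended vector integration at a partially
  conserved attB (central dinucleotide conservation is reported but not
  required, since a functional site was observed without it).

Crossover is placed between the two bases of the central dinucleotide,
so site sequences must have even length. The reference attB/attP
sequences and scan weights are user configuration: this module ships no
hard-coded attachment-site sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from isforge.seqio import GenomeRecord, Interval, revcomp


@dataclass(frozen=True)
class AttSite:
    """An attachment site placed on a sequence.

    ``seq`` is the site in its canonical orientation; when ``locus.strand``
    is '-', the hosting sequence carries its reverse complement.
    """

    kind: str  # {attB, attP, attL, attR}
    locus: Interval
    seq: str

    def __post_init__(self) -> None:
        if self.kind not in ("attB", "attP", "attL", "attR"):
            raise ValueError(f"invalid site kind {self.kind!r}")
        if len(self.seq) != len(self.locus):
            raise ValueError("site sequence and locus length differ")
        if len(self.seq) % 2 != 0:
            raise ValueError("attachment sites must have even length (central dinucleotide)")
        if self.locus.strand not in ("+", "-"):
            raise ValueError("attachment sites must be stranded")

    @property
    def central_dinucleotide(self) -> str:
        mid = len(self.seq) // 2
        return self.seq[mid - 1 : mid + 1]

    @property
    def crossover_offset(self) -> int:
        """Cut offset within the hosting sequence, strand-independent for
        even-length sites: between the two central bases."""
        return self.locus.start + len(self.seq) // 2


@dataclass(frozen=True)
class SwitchState:
    state: str  # {OFF, ON}
    promoter_strand: str  # {+, -, .}
    sites: tuple[AttSite, AttSite]


@dataclass(frozen=True)
class SwitchResult:
    product: GenomeRecord
    state: SwitchState


@dataclass(frozen=True)
class IntegrationResult:
    product: GenomeRecord
    attL: AttSite
    attR: AttSite


def _check_site_present(seq: str, site: AttSite, label: str) -> None:
    observed = seq[site.locus.start : site.locus.end]
    expected = site.seq if site.locus.strand == "+" else revcomp(site.seq)
    if observed != expected:
        raise ValueError(
            f"no {site.kind} substrate at {label}[{site.locus.start}:{site.locus.end}] "
            f"(site absent or already recombined)"
        )


def locate_site(record: GenomeRecord, site_seq: str, kind: str) -> list[AttSite]:
    """Exact occurrences of a canonical site on both strands."""
    hits = []
    for strand, needle in (("+", site_seq), ("-", revcomp(site_seq))):
        start = record.seq.find(needle)
        while start != -1:
            hits.append(
                AttSite(kind, Interval(record.id, start, start + len(needle), strand), site_seq)
            )
            start = record.seq.find(needle, start + 1)
    hits.sort(key=lambda s: (s.locus.start, s.locus.strand))
    return hits


def apply_switch(
    construct: GenomeRecord,
    attB: AttSite,
    attP: AttSite,
    promoter: Interval | None = None,
) -> SwitchResult:
    """Recombine attB×attP in inverted orientation, inverting the segment
    between the crossover points.

    The product carries attL and attR in place of the substrates; total
    length and double-stranded composition (A+T and G+C totals) are
    conserved, and a promoter interval
    lying between the crossovers comes out with its strand flipped. The
    product is no substrate: running the switch on it raises.
    """
    if attB.kind != "attB" or attP.kind != "attP":
        raise ValueError("apply_switch needs one attB and one attP site")
    _check_site_present(construct.seq, attB, construct.id)
    _check_site_present(construct.seq, attP, construct.id)
    if attB.locus.strand == attP.locus.strand:
        raise ValueError(
            "attB and attP are in direct orientation: that geometry is excision, "
            "which this switch model does not cover"
        )
    if attB.central_dinucleotide != revcomp(attP.central_dinucleotide) and (
        attB.central_dinucleotide != attP.central_dinucleotide
    ):
        raise ValueError("central dinucleotides of attB and attP are incompatible")

    left, right = sorted((attB, attP), key=lambda s: s.locus.start)
    cut1 = left.crossover_offset
    cut2 = right.crossover_offset
    if cut2 <= cut1:
        raise ValueError("attachment sites overlap")
    seq = construct.seq
    product_seq = seq[:cut1] + revcomp(seq[cut1:cut2]) + seq[cut2:]
    product = GenomeRecord(construct.id + "_switched", product_seq, construct.topology)

    right_half = len(right.seq) - len(right.seq) // 2
    attl_locus = Interval(product.id, left.locus.start, cut1 + right_half, left.locus.strand)
    attr_start = cut2 - (len(left.seq) - len(left.seq) // 2)
    attr_locus = Interval(product.id, attr_start, right.locus.end, right.locus.strand)

    def hybrid(locus: Interval, first_is_b: bool) -> AttSite:
        raw = product_seq[locus.start : locus.end]
        canon = raw if locus.strand == "+" else revcomp(raw)
        kind = "attL" if first_is_b else "attR"
        return AttSite(kind, locus, canon)

    first_is_b = left.kind == "attB"
    site_left = hybrid(attl_locus, first_is_b)
    site_right = hybrid(attr_locus, not first_is_b)

    promoter_strand = "."
    if promoter is not None:
        if not (cut1 <= promoter.start and promoter.end <= cut2):
            promoter_strand = promoter.strand
        else:
            promoter_strand = {"+": "-", "-": "+", ".": "."}[promoter.strand]
    state = SwitchState(state="ON", promoter_strand=promoter_strand, sites=(site_left, site_right))
    return SwitchResult(product=product, state=state)


def integrate_plasmid(
    genome: GenomeRecord,
    genomic_attB: AttSite,
    plasmid: GenomeRecord,
    plasmid_attP: AttSite,
) -> IntegrationResult:
    """Integrate a circular attP plasmid at a genomic attB site.

    The plasmid is linearized at the attP crossover and inserted at the
    attB crossover with the orientation fixed by site polarity; the
    product has length genome + plasmid and carries attL/attR at the
    insertion borders. attB is consumed, so integration cannot recur.
    """
    if plasmid.topology != "circular":
        raise ValueError("integration requires a circular plasmid")
    if genomic_attB.kind != "attB" or plasmid_attP.kind != "attP":
        raise ValueError("integrate_plasmid needs a genomic attB and a plasmid attP")
    _check_site_present(genome.seq, genomic_attB, genome.id)
    _check_site_present(plasmid.seq, plasmid_attP, plasmid.id)

    # orient the plasmid so attP reads canonically forward, then rotate to its cut
    if plasmid_attP.locus.strand == "+":
        oriented = plasmid.seq
        cut_p = plasmid_attP.crossover_offset
    else:
        oriented = revcomp(plasmid.seq)
        cut_p = len(plasmid.seq) - plasmid_attP.crossover_offset
    insert = oriented[cut_p:] + oriented[:cut_p]
    if genomic_attB.locus.strand == "-":
        insert = revcomp(insert)
    cut_b = genomic_attB.crossover_offset
    product_seq = genome.seq[:cut_b] + insert + genome.seq[cut_b:]
    product = GenomeRecord(genome.id + "_integrated", product_seq, genome.topology)

    half_b = len(genomic_attB.seq) // 2
    half_p = len(plasmid_attP.seq) // 2
    if genomic_attB.locus.strand == "+":
        attl_locus = Interval(product.id, cut_b - half_b, cut_b + half_p, "+")
        attr_locus = Interval(
            product.id, cut_b + len(insert) - half_p, cut_b + len(insert) + half_b, "+"
        )
        attl_seq = product_seq[attl_locus.start : attl_locus.end]
        attr_seq = product_seq[attr_locus.start : attr_locus.end]
    else:
        attr_locus = Interval(product.id, cut_b - half_b, cut_b + half_p, "-")
        attl_locus = Interval(
            product.id, cut_b + len(insert) - half_p, cut_b + len(insert) + half_b, "-"
        )
        attl_seq = revcomp(product_seq[attl_locus.start : attl_locus.end])
        attr_seq = revcomp(product_seq[attr_locus.start : attr_locus.end])
    attl = AttSite("attL", attl_locus, attl_seq)
    attr = AttSite("attR", attr_locus, attr_seq)
    return IntegrationResult(product=product, attL=attl, attR=attr)


@dataclass(frozen=True)
class AttScanHit:
    locus: Interval
    score: float
    central_match: bool
    seq: str


def scan_attB(
    genome: GenomeRecord,
    reference_site: str,
    weights,
    min_score: float,
) -> list[AttScanHit]:
    """Scan both strands for degenerate matches to a reference attB.

    The score of a window is the sum of ``weights`` at positions where
    the window base equals the reference base; weights encode which
    positions define site identity. A match at the central dinucleotide
    is reported separately but not required — a partially conserved site
    can be functional even there. Hits with score >= ``min_score`` are
    returned sorted by descending score, ties by coordinate with '+'
    first.
    """
    site = reference_site.upper()
    w = np.asarray(weights, dtype=float)
    if len(w) != len(site):
        raise ValueError(f"weights length {len(w)} != site length {len(site)}")
    L = len(site)
    n = len(genome.seq)
    if n < L:
        return []
    mid = L // 2
    central = site[mid - 1 : mid + 1]
    hits: list[AttScanHit] = []
    for strand in ("+", "-"):
        scan_seq = genome.seq if strand == "+" else revcomp(genome.seq)
        if genome.topology == "circular":
            scan_seq = scan_seq + scan_seq[: L - 1]
        arr = np.frombuffer(scan_seq.encode(), dtype=np.uint8)
        m = len(arr) - L + 1
        scores = np.zeros(m)
        for i in range(L):
            if w[i] != 0.0:
                scores += w[i] * (arr[i : i + m] == ord(site[i]))
        for pos in np.nonzero(scores >= min_score)[0]:
            pos = int(pos)
            window = scan_seq[pos : pos + L]
            if strand == "+":
                start = pos % n
            else:
                start = (n - pos - L) % n
            locus = Interval(genome.id, start, start + L, strand)
            hits.append(
                AttScanHit(
                    locus=locus,
                    score=float(scores[pos]),
                    central_match=window[mid - 1 : mid + 1] == central,
                    seq=window,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.locus.start, 0 if h.locus.strand == "+" else 1))
    return hits
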