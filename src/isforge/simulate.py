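"""Synthetic transposon-mutagenesis libraries for closed-loop testing.

The generator emulates the structure of a marker-anchored enrichment
experiment on a circular bacterial genome:

* a random genome at a configurable GC content (default 0.54, typical of
  *C. glutamicum*);
* insertions drawn without replacement across both strands with
  probability proportional to a 4×8 position weight matrix over the 8-bp
  target window, emulating a transposase with a weak AT-biased central
  preference; insertion duplicates the target window (target-site
  duplication), so reads leaving the element 3' of the inverted repeat
  run straight into the recorded octamer;
* enrichment reads shaped by half-nested amplification: 150 bp of marker
  tail, the 24-bp terminal inverted repeat, then genomic sequence from
  the junction outward, truncated by an ONT-like ~10-kb fragment-length
  draw; substitutions, insertions and deletions at 2:1:1 of the
  configured error rate;
* a naive seed-and-extend aligner producing PAF-contract records, for
  tests only — it is a bundled convenience, not a production mapper.

Every draw flows from a single integer seed, so outputs are
byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from isforge.seqio import AlignmentRecord, GenomeRecord, Interval, revcomp

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

MARKER_TAIL_LEN = 150  # nested primer sits 150 bp inside the marker
IR_LEN = 24  # terminal inverted repeat length
# lognormal fragment draw: mean 10 kb with 5-95% span of roughly 4-20 kb
_FRAG_SIGMA = math.log(5) / (2 * 1.645)


def default_pwm() -> np.ndarray:
    """4×8 target-window PWM: weak G/C edge tendency, T bias at positions
    3–4 and A bias at 5–6, with strong discrimination against G/C in the
    window centre. Rows A,C,G,T; columns sum to 1."""
    cols = [
        [0.20, 0.30, 0.30, 0.20],  # 1
        [0.20, 0.30, 0.30, 0.20],  # 2
        [0.20, 0.125, 0.125, 0.55],  # 3
        [0.30, 0.05, 0.05, 0.60],  # 4
        [0.60, 0.05, 0.05, 0.30],  # 5
        [0.55, 0.125, 0.125, 0.20],  # 6
        [0.20, 0.30, 0.30, 0.20],  # 7
        [0.20, 0.30, 0.30, 0.20],  # 8
    ]
    return np.array(cols, dtype=float).T


@dataclass
class SimConfig:
    """All knobs of one simulated library; ``seed`` fixes every draw."""

    genome_len: int = 100_000
    gc: float = 0.54
    n_insertions: int = 100
    pwm: np.ndarray = field(default_factory=default_pwm)
    tsd_len: int = 8
    fragment_len_mean: int = 10_000
    reads_per_site: int | tuple = 3  # int, or ("poisson", lam) truncated at >=1
    error_rate: float = 0.05
    seed: int = 0
    min_site_separation: int = 8

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (4, self.tsd_len):
            raise ValueError(f"pwm must be 4x{self.tsd_len}")
        if not np.allclose(self.pwm.sum(axis=0), 1.0):
            raise ValueError("pwm columns must sum to 1")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")


@dataclass(frozen=True)
class TrueInsertion:
    position: int
    orientation: str
    octamer: str


@dataclass(frozen=True)
class TrueInsertionSet:
    insertions: list[TrueInsertion]
    provenance: SimConfig

    def __len__(self) -> int:
        return len(self.insertions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [t.position for t in self.insertions],
                "orientation": [t.orientation for t in self.insertions],
                "octamer": [t.octamer for t in self.insertions],
            }
        )


def simulate_genome(length: int, gc: float, seed: int) -> GenomeRecord:
    """Circular i.i.d. random genome at the requested GC content."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng([seed, 1])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)
    return GenomeRecord("sim_genome", seq, "circular")


def simulate_plasmid(seed: int, backbone_len: int = 2_700, marker_len: int = 950) -> tuple[GenomeRecord, Interval]:
    """Delivery-plasmid stand-in: backbone, marker cassette, then the IR.

    Returns the plasmid and the marker interval whose end coincides with
    the IR's outer edge — the anchor geometry junction calling expects.
    """
    rng = np.random.default_rng([seed, 2])
    total = backbone_len + marker_len + IR_LEN
    codes = rng.choice(4, size=total)
    seq = "".join(BASES[c] for c in codes)
    plasmid = GenomeRecord("sim_plasmid", seq, "circular")
    ir_end = backbone_len + marker_len + IR_LEN
    marker = Interval("sim_plasmid", backbone_len, ir_end, "+")
    return plasmid, marker


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, c in _CODE.items():
        codes[arr == ord(b)] = c
    return codes


def site_weights(genome: GenomeRecord, pwm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position insertion weights on each strand.

    A '+' site at pos has window [pos, pos+w); a '-' site at pos has the
    reverse complement of [pos-w, pos). The weight is the product of PWM
    probabilities over the window, computed with circular wrap-around.
    """
    w = pwm.shape[1]
    codes = _encode(genome.seq)
    n = len(codes)
    ext = np.concatenate([codes, codes[: w - 1]])
    plus = np.ones(n)
    for i in range(w):
        plus *= pwm[ext[i : i + n], i]
    # '-' window base i is the complement of the base at pos-1-i
    minus = np.ones(n)
    for i in range(w):
        rolled = np.roll(codes, i + 1)  # rolled[pos] = codes[(pos - 1 - i) % n]
        minus *= pwm[3 - rolled, i]
    return plus, minus


def simulate_insertions(
    genome: GenomeRecord,
    n: int,
    pwm: np.ndarray,
    tsd_len: int = 8,
    seed: int = 0,
    min_separation: int = 8,
) -> TrueInsertionSet:
    """Draw ``n`` insertion sites without replacement, proportional to the
    PWM weight of each (position, strand) window.

    Sites closer than ``min_separation`` bp on the genome are rejected
    during the draw so that truth sites stay distinct after
    tolerance-based merging downstream.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape != (4, tsd_len):
        raise ValueError(f"pwm must be 4x{tsd_len}")
    plus, minus = site_weights(genome, pwm)
    weights = np.concatenate([plus, minus])
    positive = int(np.count_nonzero(weights))
    if n > positive:
        raise ValueError(f"requested {n} insertions but only {positive} positions have positive weight")
    # a stream keyed separately from the genome's: reusing one integer
    # seed across stages would correlate the selection noise with the
    # genome bases and bias the drawn sites
    rng = np.random.default_rng([seed, 3])
    # Gumbel top-k gives a without-replacement sample proportional to weights
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    order = np.argsort(-keys)
    g_len = len(genome.seq)
    chosen: list[tuple[int, str]] = []
    taken = np.zeros(g_len, dtype=bool)
    for idx in order:
        if weights[idx] <= 0 or len(chosen) >= n:
            break
        pos = int(idx % g_len)
        strand = "+" if idx < g_len else "-"
        window_idx = (pos + np.arange(-min_separation, min_separation + 1)) % g_len
        if taken[window_idx].any():
            continue
        taken[pos] = True
        chosen.append((pos, strand))
    if len(chosen) < n:
        raise ValueError("could not place the requested insertions with the given separation")
    insertions = []
    for pos, strand in sorted(chosen):
        if strand == "+":
            octamer = genome.fetch(pos, pos + tsd_len)
        else:
            octamer = revcomp(genome.fetch(pos - tsd_len, pos))
        insertions.append(TrueInsertion(pos, strand, octamer))
    cfg = SimConfig(genome_len=len(genome.seq), n_insertions=n, pwm=pwm, tsd_len=tsd_len, seed=seed)
    return TrueInsertionSet(insertions=insertions, provenance=cfg)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions : insertions : deletions at 2:1:1 of ``rate``."""
    if rate <= 0.0 or not seq:
        return seq
    codes = _encode(seq)
    n = len(codes)
    r = rng.random(n)
    p_sub, p_ins, p_del = rate / 2, rate / 4, rate / 4
    sub = r < p_sub
    ins = (r >= p_sub) & (r < p_sub + p_ins)
    dele = (r >= p_sub + p_ins) & (r < p_sub + p_ins + p_del)
    if sub.any():
        codes = codes.copy()
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    counts = np.where(dele, 0, 1) + ins
    out = np.repeat(codes, counts)
    if ins.any():
        # the second copy at each inserted position becomes a random base
        ends = np.cumsum(counts)
        idx = ends[ins] - 1
        out[idx] = rng.integers(0, 4, size=idx.size)
    return "".join(BASES[c] for c in out)


def simulate_enrichment_reads(
    genome: GenomeRecord,
    plasmid: GenomeRecord,
    plasmid_marker: Interval,
    truth: TrueInsertionSet,
    config: SimConfig,
) -> list[tuple[str, str]]:
    """Half-nested enrichment reads for every true insertion.

    Each read is marker tail (150 bp) + IR (24 bp) + genomic sequence
    from the junction outward on the element's strand, truncated by the
    fragment-length draw, with the configured error process applied.
    Returns (read_id, sequence) pairs; read ids encode the site index.
    """
    rng = np.random.default_rng([config.seed, 4])
    tail_len = MARKER_TAIL_LEN + IR_LEN
    tail = plasmid.seq[plasmid_marker.end - tail_len : plasmid_marker.end]
    mu = math.log(config.fragment_len_mean) - _FRAG_SIGMA**2 / 2
    g_len = len(genome.seq)
    reads: list[tuple[str, str]] = []
    for i, ins in enumerate(truth.insertions):
        if isinstance(config.reads_per_site, int):
            n_reads = config.reads_per_site
        else:
            kind, lam = config.reads_per_site
            if kind != "poisson":
                raise ValueError(f"unknown reads_per_site spec {config.reads_per_site!r}")
            n_reads = max(1, int(rng.poisson(lam)))
        for j in range(n_reads):
            frag = int(rng.lognormal(mu, _FRAG_SIGMA))
            genomic_len = max(100, frag - tail_len)
            genomic_len = min(genomic_len, g_len - 1)
            if ins.orientation == "+":
                genomic = genome.fetch(ins.position, ins.position + genomic_len)
            else:
                genomic = revcomp(genome.fetch(ins.position - genomic_len, ins.position))
            read = _apply_errors(tail + genomic, config.error_rate, rng)
            reads.append((f"read_{i}_{j}", read))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:].strip().split()[0], seq))
    return reads


# ---------------------------------------------------------------------------
# naive aligner (tests only)

_XDROP = 6
_RESEED_WIN = 14
_RESEED_MIN_MATCH = 12
_MAX_RESEEDS = 10


def _next_char(seq: str, edge: int, consumed: int, direction: int) -> int:
    """Index of the next base beyond ``consumed`` extension steps from an
    edge: exclusive end for direction +1, inclusive start for -1.
    Returns -1 when out of bounds."""
    idx = edge + consumed if direction > 0 else edge - consumed - 1
    return idx if 0 <= idx < len(seq) else -1


def _diag_extend(s: str, ref: str, q_edge: int, r_edge: int, qn: int, rn: int, direction: int) -> int:
    """Extend along one diagonal from an already-extended state; returns
    additional length at the best score under an X-drop rule
    (match +1, mismatch -2, no gaps)."""
    score = best = 0
    best_k = 0
    k = 0
    while True:
        si = _next_char(s, q_edge, qn + k, direction)
        ri = _next_char(ref, r_edge, rn + k, direction)
        if si < 0 or ri < 0:
            break
        score += 1 if s[si] == ref[ri] else -2
        k += 1
        if score > best:
            best, best_k = score, k
        elif best - score > _XDROP:
            break
    return best_k


def _window_matches(s: str, ref: str, q_edge: int, r_edge: int, qn: int, rn: int, direction: int) -> int:
    """Matches over the next _RESEED_WIN bases along a diagonal; -1 if
    the window runs off either sequence."""
    m = 0
    for k in range(_RESEED_WIN):
        si = _next_char(s, q_edge, qn + k, direction)
        ri = _next_char(ref, r_edge, rn + k, direction)
        if si < 0 or ri < 0:
            return -1
        m += s[si] == ref[ri]
    return m


def _extend(s: str, ref: str, q_edge: int, r_edge: int, direction: int) -> tuple[int, int]:
    """Extension with isolated-indel recovery.

    Diagonal X-drop extension; at each stall a 1–2-bp shifted diagonal
    (a short gap) is accepted only when the following 14 bases match at
    12 or better — strict enough that foreign sequence beyond a junction
    essentially never triggers it. Returns (query_ext, ref_ext).
    """
    qn = rn = 0
    for _ in range(_MAX_RESEEDS):
        k = _diag_extend(s, ref, q_edge, r_edge, qn, rn, direction)
        qn += k
        rn += k
        shift = 0
        for d in (1, -1, 2, -2):
            # skip one query base (substitution/insertion context) and d ref bases
            m = _window_matches(s, ref, q_edge, r_edge, qn + 1, rn + 1 + d, direction)
            if m >= _RESEED_MIN_MATCH:
                shift = d
                break
        if shift == 0:
            break
        qn += 1
        rn += 1 + shift
    return qn, rn


def _cluster_hits(hits: list[tuple[int, int]], max_diag_gap: int = 100) -> list[list[tuple[int, int]]]:
    """Group (query_pos, ref_pos) seed hits by alignment diagonal."""
    hits = sorted(hits, key=lambda h: (h[1] - h[0], h[0]))
    clusters: list[list[tuple[int, int]]] = []
    for h in hits:
        d = h[1] - h[0]
        if clusters and d - (clusters[-1][-1][1] - clusters[-1][-1][0]) <= max_diag_gap:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def naive_align(
    reads: list[tuple[str, str]],
    references: list[GenomeRecord],
    k: int = 15,
) -> list[AlignmentRecord]:
    """Exact-k-mer seeding with greedy mismatch-tolerant extension.

    Emits PAF-contract records on both strands of each reference, good
    enough for junction geometry at ONT-like error rates. Deliberately
    simple: no gapped extension beyond what the seed chain implies, no
    mapping quality model (a constant 60), no chimera splitting beyond
    per-cluster reporting.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for ref_idx, ref in enumerate(references):
        seq = ref.seq
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ref_idx, i))

    records: list[AlignmentRecord] = []
    for read_id, read in reads:
        read_len = len(read)
        for strand in ("+", "-"):
            s = read if strand == "+" else revcomp(read)
            per_ref: dict[int, list[tuple[int, int]]] = {}
            # stride-sampled seeds: extension recovers the exact block
            # edges, so only cluster detection needs seed density
            last = len(s) - k
            positions = list(range(0, last + 1, 4))
            if positions and positions[-1] != last:
                positions.append(last)
            for i in positions:
                for ref_idx, rpos in index.get(s[i : i + k], ()):
                    per_ref.setdefault(ref_idx, []).append((i, rpos))
            for ref_idx, hits in per_ref.items():
                ref = references[ref_idx]
                for cluster in _cluster_hits(hits):
                    cluster.sort()
                    smin, rmin = cluster[0]
                    smax, rmax = cluster[-1][0] + k, cluster[-1][1] + k
                    lq, lr = _extend(s, ref.seq, smin, rmin, -1)
                    rq, rr = _extend(s, ref.seq, smax, rmax, +1)
                    q_start, q_end = smin - lq, smax + rq
                    r_start, r_end = rmin - lr, rmax + rr
                    if q_end - q_start < k + 3 and len(cluster) < 2:
                        continue
                    aln = edlib.align(s[q_start:q_end], ref.seq[r_start:r_end], task="distance")
                    dist = aln["editDistance"]
                    block = max(q_end - q_start, r_end - r_start)
                    matches = max(0, min(q_end - q_start, r_end - r_start) - dist)
                    if strand == "+":
                        read_start, read_end = q_start, q_end
                    else:
                        read_start, read_end = read_len - q_end, read_len - q_start
                    records.append(
                        AlignmentRecord(
                            read_id=read_id,
                            ref_id=ref.id,
                            read_start=read_start,
                            read_end=read_end,
                            ref_start=r_start,
                            ref_end=r_end,
                            strand=strand,
                            matches=matches,
                            block_len=block,
                            mapq=60,
                            ref_len=len(ref.seq),
                        )
                    )
    return records
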