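# Methods

`isforge` models the computational side of an IS-element transposon
mutagenesis system in a mobile-element-free *Corynebacterium glutamicum*
chassis: designing the deletions that remove IS elements ("genome
healing"), modelling the Bxb1 integrase genetic switch that arms the
transposon delivery plasmid, calling insertion sites from marker-anchored
long reads, and quantifying the transposase's target-site preference.
This note records the models, the parameters that matter, and the design
decisions taken where the procedure was genuinely open.

## Coordinates

All internal coordinates are 0-based, half-open, on both reads and
references (the PAF convention); SAM input is converted on parsing, with
hard and soft clips both treated as unaligned read sequence so read
coordinates always refer to the original molecule. BED6 is emitted
natively. Circular genomes wrap: window extraction takes positions
modulo length, and junctions projected past the origin are normalized
back into `[0, n)`.

## Local alignment kernel (`align`)

Flank searches use exact k-mer seeding (default k = 15, sampled every
k/3 bases on the reference) to nominate candidate windows, each resolved
by an affine-gap Smith–Waterman (Gotoh) alignment. Scoring is match +1,
mismatch −1, first gap base −2, each further gap base −1 — BLAST-like
magnitudes at desk scale. Identity is identical columns over total
alignment columns, with gap columns counting against identity; this is
the conservative reading of a ">99% identity" rule whose denominator is
otherwise unspecified. When the full dynamic-programming matrix is small
(≤ 1.6·10⁷ cells) seeding is skipped and the kernel is exact. Ties are
broken deterministically: lowest reference coordinate, forward strand
first. The DP itself is Biopython's `PairwiseAligner`; the test suite
checks it against an independently written plain-Python Gotoh oracle on
random instances.

## Genome healing (`healing`)

For an annotated IS element the designer extracts the element with
2,500-bp flanks and searches each donor genome for both flanks, on both
donor strands. A donor qualifies when:

1. both flank hits are substantial, co-linear and on the same strand;
2. the gap between them at the would-be junction is smaller than 10% of
   the element length (the element is absent; no standard numeric
   synteny rule exists, so this minimal one is exposed as
   `max_gap_frac`), allowing up to 50 bp of alignment overlap slack;
3. the 750-bp windows immediately abutting the healed junction are
   >0.99 identical to the target's windows, by global alignment.

The windows start exactly at the healed junction (the alternative —
anchoring them at the outer search-flank edges — is config-overridable
by passing a different `window`). Candidates are ranked by mean of the
two window identities, ties broken by donor id then coordinate, making
selection a total order independent of donor input order. Homology arms
default to 550 bp (midpoint of the permitted 500–600 range) taken from
the donor immediately at the junction; an `N` inside the arm shortens it
to the clean stretch if that is still ≥ 500 bp, otherwise design fails
loudly. Conventional deletions (no qualifying donor) take the arms from
the target genome around a user-supplied CDS+promoter interval; promoter
extents are input, never inferred. The wildtype-as-donor case needs no
special handling: a wildtype genome is simply passed in the donor list.

## Bxb1 switch algebra (`recombinase`)

Serine-integrase recombination is modelled as cut-and-exchange at the
midpoint of each attachment site, between the two bases of the central
dinucleotide; site sequences must therefore have even length. attB×attP
in inverted orientation inverts the intervening segment (flipping a
promoter that lies inside it) and leaves attL/attR, which are rejected
as substrates — the reaction is unidirectional without a recombination
directionality factor, and RDF-mediated reversal is out of scope.
Intermolecular recombination integrates a circular attP plasmid at a
genomic attB, conserving total length and leaving attL/attR at the
borders. Only inversion and integration geometries are modelled; direct
repeats (excision) are rejected with an explicit message.

`scan_attB` finds degenerate attachment sites: a user-supplied reference
sequence and per-position weight vector, scored as the weighted count of
matching positions over both strands. A match at the central
dinucleotide is reported but **not required** — a partially conserved
genomic site can be functional even without it, which is precisely the
phenomenon (unintended whole-plasmid integration at a cryptic attB)
that motivates scanning. No attachment-site sequence ships with the
package: the canonical sequences are figure-level data in the source
material, so they are deliberately user configuration.

## Junction calling (`tnseq`)

Enrichment reads run marker tail → inverted repeat (IR) → genomic DNA.
Against the plasmid+genome references such a read splits into a plasmid
block ending at the IR's outer edge and a genomic block starting right
after it in read space. `call_junctions`:

* anchors on a plasmid alignment that reaches (or crosses) the IR outer
  edge, within a 10-bp tolerance;
* classifies the read `plasmid_integration` when plasmid alignment
  continues more than 50 bp past the IR (whole-vector integration);
* pairs the anchor with a genomic block whose read-space start lies
  within ±20 bp of the IR edge; the window is symmetric because block
  extensions can drift across the junction on chance matches in either
  direction;
* projects the junction to the exact IR edge: the anchor's overrun is
  corrected along its alignment diagonal, and the genomic coordinate is
  shifted by the read-space gap. Both projections are what make junction
  calls exact on clean reads — the raw block edges are not reliable to
  the base.

`junction_pos` is the 0-based genomic position of the first target base
3′ of the IR on the element's strand: the 8-bp target window of a `+`
site is `[pos, pos+8)` and of a `−` site the reverse complement of
`[pos−8, pos)`.

Events merge into sites by single-linkage within 3 bp on the same strand
(ONT junction jitter; configurable), site coordinate = modal junction
position (ties to the smallest), and opposite strands never merge. The
site list keeps single-read sites; the ≥2-read filter applies at window
extraction, and both totals are available since published site counts do
not always state whether singletons are included.

Replichore assignment splits the circular chromosome at user-supplied
oriC and terminus positions; on the oriC→ter arm orientation `+` is
leading and `−` lagging, inverted on the other arm. Because the
convention behind a published leading/lagging split may be either this
or the plain +/− strand, `strand_partition` reports both side by side.

## Target-site statistics (`motif`)

Per-site octamers (deduplicated per site by default; read-weighted by
flag) feed a 4×8 count matrix. Information content is `2 − H` bits per
column; the standard small-sample correction `3/(2·ln2·n)` is available
behind a flag and off by default, so the plain entropy arithmetic stays
inspectable. Background is uniform (no GC correction), matching common
logo-tool defaults. The central tetranucleotide is octamer positions 3–6
(1-based); its frequency table carries a ceiling flag at 20% — the line
between "weak local preference" and "a real consensus target". Logos are
drawn directly with matplotlib text paths (frequency × information
stacking).

## Synthetic libraries (`simulate`)

The generator emulates the structure, not the chemistry, of the
experiment:

| parameter | default | rationale |
|---|---|---|
| genome length | 100 kb | desk-scale stand-in for a 3.2-Mb chromosome |
| GC content | 0.54 | *C. glutamicum*-like |
| PWM | weak AT-biased centre | T bias at window positions 3–4, A at 5–6, strong discrimination against central G/C, mild G/C edge tendency |
| TSD length | 8 bp | equals the analyzed window; insertion duplicates the target, so reads leaving the IR run straight into the recorded octamer |
| fragment length | lognormal, mean 10 kb, σ = ln 5⁄3.29 | 5–95% span ≈ 4–20 kb around the nominal ~10-kb shearing |
| reads per site | 3 (or truncated Poisson) | enrichment depth |
| error rate | 0.05, substitutions:insertions:deletions 2:1:1 | ONT-like magnitude, declared rather than modelled |
| min site separation | 8 bp | keeps truth sites distinct under the 3-bp merge tolerance |

Insertion sites are drawn without replacement over every (position,
strand) with probability proportional to the PWM product over its
window, via Gumbel top-k with a greedy separation constraint. Every
stage derives its random stream as `default_rng([seed, stage])`:
distinct streams per stage matter, because reusing one integer seed
across stages correlates the selection noise with the genome bases and
visibly biases the drawn sites.

The bundled `naive_align` (exact k-mer seeds sampled every 4 bases,
diagonal X-drop extension, isolated 1–2-bp indel recovery gated on a
strict 12-of-14 downstream match, edlib for match counts) exists so the
whole pipeline closes the loop in tests without an external mapper. It
is not a production aligner: no chimera handling beyond per-cluster
reporting, constant mapping quality, and the strict indel gate
deliberately under-extends through dense error clusters.

What the simulation does **not** emulate: real ONT error structure
(homopolymer compression, quality correlation), PCR chimeras, capture
efficiency, biological insertion hotspots, and real genome repeat
content (random sequence has essentially no repeats, so mapping
ambiguity is untested). Passing recovery tests therefore demonstrate
the correctness of the junction geometry, filtering and statistics —
not robustness to repeat-rich real genomes.

## Problem sizes used in the checks

The packaged checks run at: 1,000 error-free reads (250 sites × 4) for
exact junction equivalence; 100 sites × 3 reads at 5% error for
recall/precision/orientation; 2,000 insertions × 2 clean reads on a
300-kb genome for target-preference recovery (recovered matrix compared
against the PWM reweighted by genome base composition — the analytic
sampling marginal — with hard-zeroed central G/C cells required back as
exact zeros); 1,000 uniform-PWM insertions for the leading/lagging
split; 200 random ≤80-bp instances for the alignment kernel. These sizes
are the package's chosen desk-scale conditions and are fixed in
`tests/test_acceptance.py` and `scripts/acceptance.py`.

## Known limitations

* The healing search treats donors as linear for flank search; a
  syntenous region spanning a donor's origin is found only in rotated
  input.
* `apply_switch` validates sites at their stated loci; it does not scan
  for additional cryptic sites in the construct (use `scan_attB`).
* Multi-insertion reads (two junctions on one molecule) emit one event
  per junction but are not specially flagged beyond the log.
* Identity is matches/columns; tools that exclude end gaps or use
  BLAST's positives will differ in the third decimal on gappy pairs.
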