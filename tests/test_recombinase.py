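from collections import Counter

import numpy as np
import pytest

from isforge.recombinase import (
    AttSite,
    apply_switch,
    integrate_plasmid,
    locate_site,
    scan_attB,
)
from isforge.seqio import GenomeRecord, Interval, revcomp

from oracles import weighted_site_score

BASES = "ACGT"


def _random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture(scope="module")
def switch_construct():
    """Toy switch: attB(+) ... promoter ... attP(-) with a shared central GT."""
    rng = np.random.default_rng(2024)
    attb = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
    attp = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
    prefix, middle, suffix = (_random_seq(rng, n) for n in (100, 60, 100))
    seq = prefix + attb + middle + revcomp(attp) + suffix
    construct = GenomeRecord("pToy", seq, "circular")
    site_b = AttSite("attB", Interval("pToy", 100, 140, "+"), attb)
    site_p = AttSite("attP", Interval("pToy", 200, 240, "-"), attp)
    promoter = Interval("pToy", 150, 180, "-")  # opposes the transposase: OFF
    return construct, site_b, site_p, promoter


class TestSwitch:
    def test_inversion_product_and_hybrid_sites(self, switch_construct):
        construct, site_b, site_p, promoter = switch_construct
        res = apply_switch(construct, site_b, site_p, promoter)
        assert len(res.product.seq) == len(construct.seq)
        # double-stranded composition is conserved: inversion swaps a base
        # for its complement, so A+T and G+C totals are invariant
        before, after = Counter(construct.seq), Counter(res.product.seq)
        assert before["A"] + before["T"] == after["A"] + after["T"]
        assert before["G"] + before["C"] == after["G"] + after["C"]
        attl, attr = res.state.sites
        assert (attl.kind, attr.kind) == ("attL", "attR")
        # hybrids exchange the half-sites around the central dinucleotide
        assert attl.seq == site_b.seq[:20] + site_p.seq[20:]
        assert attr.seq == site_p.seq[:20] + site_b.seq[20:]
        assert attl.central_dinucleotide == "GT"
        assert res.state.state == "ON"
        assert res.state.promoter_strand == "+"  # flipped to drive expression

    def test_unidirectional(self, switch_construct):
        construct, site_b, site_p, _ = switch_construct
        product = apply_switch(construct, site_b, site_p).product
        with pytest.raises(ValueError, match="no attB substrate"):
            apply_switch(product, site_b, site_p)

    def test_missing_site_is_error(self, switch_construct):
        construct, site_b, _, _ = switch_construct
        bogus_p = AttSite("attP", Interval("pToy", 10, 50, "-"), site_b.seq)
        with pytest.raises(ValueError, match="no attP substrate"):
            apply_switch(construct, site_b, bogus_p)

    def test_direct_orientation_rejected(self, switch_construct):
        rng = np.random.default_rng(9)
        attb = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
        attp = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
        seq = _random_seq(rng, 50) + attb + _random_seq(rng, 50) + attp + _random_seq(rng, 50)
        construct = GenomeRecord("direct", seq, "circular")
        b = AttSite("attB", Interval("direct", 50, 90, "+"), attb)
        p = AttSite("attP", Interval("direct", 140, 180, "+"), attp)
        with pytest.raises(ValueError, match="direct orientation"):
            apply_switch(construct, b, p)


@pytest.fixture(scope="module")
def parts():
    rng = np.random.default_rng(77)
    attb = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
    attp = _random_seq(rng, 19) + "GT" + _random_seq(rng, 19)
    gseq = _random_seq(rng, 5_000) + attb + _random_seq(rng, 4_960)
    pseq = _random_seq(rng, 1_000) + attp + _random_seq(rng, 2_960)
    genome = GenomeRecord("chr", gseq, "circular")
    plasmid = GenomeRecord("vec", pseq, "circular")
    site_b = AttSite("attB", Interval("chr", 5_000, 5_040, "+"), attb)
    site_p = AttSite("attP", Interval("vec", 1_000, 1_040, "+"), attp)
    return genome, site_b, plasmid, site_p


class TestIntegration:
    def test_length_conservation_and_flanking_hybrids(self, parts):
        genome, site_b, plasmid, site_p = parts
        res = integrate_plasmid(genome, site_b, plasmid, site_p)
        assert len(res.product.seq) == len(genome.seq) + len(plasmid.seq)
        assert res.attL.seq == site_b.seq[:20] + site_p.seq[20:]
        assert res.attR.seq == site_p.seq[:20] + site_b.seq[20:]
        # hybrids actually flank the insertion in the product
        s, e = res.attL.locus.start, res.attL.locus.end
        assert res.product.seq[s:e] == res.attL.seq

    def test_attB_consumed(self, parts):
        genome, site_b, plasmid, site_p = parts
        res = integrate_plasmid(genome, site_b, plasmid, site_p)
        with pytest.raises(ValueError, match="no attB substrate"):
            integrate_plasmid(res.product, site_b, plasmid, site_p)

    def test_linear_plasmid_rejected(self, parts):
        genome, site_b, plasmid, site_p = parts
        linear = GenomeRecord("vec", plasmid.seq, "linear")
        with pytest.raises(ValueError, match="circular"):
            integrate_plasmid(genome, site_b, linear, site_p)

    def test_genome_without_attB_rejected(self, parts):
        genome, site_b, plasmid, site_p = parts
        bare = GenomeRecord("chr", revcomp(genome.seq), "circular")
        with pytest.raises(ValueError, match="no attB substrate"):
            integrate_plasmid(bare, site_b, plasmid, site_p)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(55)
    site = _random_seq(rng, 20) + "GT" + _random_seq(rng, 20)
    w = rng.integers(0, 4, size=len(site)).astype(float)
    genome_seq = _random_seq(rng, 20_000)
    pos_fwd, pos_rev = 4_000, 12_000
    genome_seq = (
        genome_seq[:pos_fwd] + site + genome_seq[pos_fwd + len(site) : pos_rev]
        + revcomp(site) + genome_seq[pos_rev + len(site) :]
    )
    return GenomeRecord("chr", genome_seq, "circular"), site, w, pos_fwd, pos_rev


class TestScan:
    def test_verbatim_and_revcomp_hits_score_maximally(self, planted):
        genome, site, w, pos_fwd, pos_rev = planted
        max_score = float(w.sum())
        hits = scan_attB(genome, site, w, max_score)
        top = {(h.locus.start, h.locus.strand) for h in hits if h.score == max_score}
        assert (pos_fwd, "+") in top
        assert (pos_rev, "-") in top
        assert all(h.central_match for h in hits if h.score == max_score)

    def test_zero_weight_mismatches_keep_max_score(self, planted):
        genome, site, w, pos_fwd, _ = planted
        mutated = list(site)
        for i in np.flatnonzero(w == 0)[:5]:
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        mutated = "".join(mutated)
        seq = genome.seq[:pos_fwd] + mutated + genome.seq[pos_fwd + len(site) :]
        g2 = GenomeRecord("chr", seq, "circular")
        hits = scan_attB(g2, site, w, float(w.sum()))
        assert any(h.locus.start == pos_fwd and h.locus.strand == "+" for h in hits)
        # exhaustive per-position oracle agrees
        assert weighted_site_score(mutated, site, w) == float(w.sum())

    def test_scores_match_exhaustive_oracle(self, planted):
        genome, site, w, _, _ = planted
        hits = scan_attB(genome, site, w, 0.6 * float(w.sum()))
        for h in hits[:25]:
            window = h.seq if h.locus.strand == "+" else h.seq
            assert h.score == weighted_site_score(window, site, w)

    def test_mirror_symmetry_on_reverse_complemented_genome(self, planted):
        genome, site, w, _, _ = planted
        rc = GenomeRecord("chr", revcomp(genome.seq), "circular")
        fwd = scan_attB(genome, site, w, 0.7 * float(w.sum()))
        rev = scan_attB(rc, site, w, 0.7 * float(w.sum()))
        n = len(genome.seq)
        mirrored = {
            (n - h.locus.start - len(site) if h.locus.start + len(site) <= n
             else n - h.locus.start - len(site) + n,
             "-" if h.locus.strand == "+" else "+")
            for h in fwd
        }
        observed = {(h.locus.start, h.locus.strand) for h in rev}
        assert {(p % n, s) for p, s in mirrored} == observed

    def test_weight_length_mismatch_is_error(self, planted):
        genome, site, w, _, _ = planted
        with pytest.raises(ValueError, match="length"):
            scan_attB(genome, site, w[:-1], 1.0)


def test_locate_site_finds_both_strands():
    rng = np.random.default_rng(31)
    site = _random_seq(rng, 18) + "GT" + _random_seq(rng, 20)
    seq = _random_seq(rng, 500) + site + _random_seq(rng, 500) + revcomp(site) + _random_seq(rng, 100)
    rec = GenomeRecord("r", seq, "circular")
    hits = locate_site(rec, site, "attB")
    assert [(h.locus.start, h.locus.strand) for h in hits] == [(500, "+"), (1040, "-")]
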