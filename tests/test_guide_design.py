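"""Guide enumeration, filtering, scoring, de-clustering and controls.

Enumeration and off-target scoring are checked against independent
brute-force oracles written here with plain loops and an explicit IUPAC
table, not via the package's scanners.
"""

import random

import numpy as np
import pytest

from crispraid.genome_model import DesignRegion, GeneFeature, Genome
from crispraid.guide_design import (
    CAS_BY_MODALITY,
    LBCAS12A,
    SACAS9,
    SPCAS9,
    CandidateGuide,
    CasSpec,
    FilterRules,
    PamSiteIndex,
    cluster_dedup,
    enumerate_candidates,
    hard_filter,
    make_controls,
    off_target_score,
    position_score,
    rank_guides,
    score_guide,
    select_top,
)

# ---- independent oracle helpers ----

ORACLE_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
                "V": "ACG", "R": "AG"}
ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_rc(seq):
    return "".join(ORACLE_COMP[b] for b in reversed(seq))


def oracle_pam_match(window, pattern):
    return len(window) == len(pattern) and all(
        b in ORACLE_IUPAC[p] for b, p in zip(window, pattern))


def oracle_sites(seq, cas):
    """Brute-force double-strand scan; (start, end, strand, spacer) tuples
    with forward-strand coordinates."""
    plen, slen = len(cas.pam), cas.spacer_len
    hits = set()
    for strand in "+-":
        s = seq if strand == "+" else oracle_rc(seq)
        for p in range(len(s) - plen + 1):
            if not oracle_pam_match(s[p:p + plen], cas.pam):
                continue
            lo, hi = ((p - slen, p) if cas.pam_side == "3prime"
                      else (p + plen, p + plen + slen))
            if lo < 0 or hi > len(s):
                continue
            spacer = s[lo:hi]
            if strand == "-":
                lo, hi = len(s) - hi, len(s) - lo
            hits.add((lo, hi, strand, spacer))
    return hits


def random_dna(rng, n, gc=0.45):
    return "".join(rng.choices("ACGT", weights=[(1 - gc) / 2, gc / 2,
                                                gc / 2, (1 - gc) / 2], k=n))


# ---- enumeration ----

class TestEnumerate:
    def test_no_pam_in_homopolymer(self):
        genome = Genome({"c": "A" * 100})
        region = DesignRegion("g", "interference", "c", 0, 100, "+")
        assert enumerate_candidates(region, genome, SPCAS9) == []

    @pytest.mark.parametrize("cas", [LBCAS12A, SPCAS9, SACAS9],
                             ids=lambda c: c.name)
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_scan(self, cas, seed):
        rng = random.Random(seed)
        seq = random_dna(rng, 200)
        genome = Genome({"c": seq})
        region = DesignRegion("g", "interference", "c", 0, 200, "+")
        got = {(c.spacer_start, c.spacer_end, c.strand, c.protospacer)
               for c in enumerate_candidates(region, genome, cas)}
        assert got == oracle_sites(seq, cas)

    def test_region_interior_only(self):
        """Spacers must lie fully inside the region even when the full contig
        has sites outside it."""
        rng = random.Random(3)
        seq = random_dna(rng, 600)
        genome = Genome({"c": seq})
        region = DesignRegion("g", "interference", "c", 200, 400, "+")
        for cand in enumerate_candidates(region, genome, SPCAS9):
            assert 200 <= cand.spacer_start and cand.spacer_end <= 400

    def test_cas12a_spacer_length_20(self):
        rng = random.Random(4)
        genome = Genome({"c": random_dna(rng, 500)})
        region = DesignRegion("g", "activation", "c", 0, 500, "+")
        cands = enumerate_candidates(region, genome, LBCAS12A)
        assert cands and all(len(c.protospacer) == 20 for c in cands)

    def test_region_shorter_than_spacer(self):
        genome = Genome({"c": "ACGT" * 100})
        region = DesignRegion("g", "deletion", "c", 0, 10, "+")
        assert enumerate_candidates(region, genome, SACAS9) == []

    def test_protospacer_matches_genome(self, toy_genome):
        from crispraid._seq import revcomp
        region = DesignRegion("g", "interference", "chr1", 1000, 2000, "+")
        for c in enumerate_candidates(region, toy_genome, SPCAS9):
            site = toy_genome.fetch("chr1", c.spacer_start, c.spacer_end)
            assert c.protospacer == (site if c.strand == "+" else revcomp(site))


# ---- hard filters ----

@pytest.mark.parametrize("spacer,expected", [
    ("ACGGTCTCACGTACGTACGT", "BsaI"),
    ("ACGAGACCACGTACGTACGT", "BsaI"),
    ("ACGTTTTACGTACGTACGTA", "polyT"),
    ("ACGGGGGACGTACGTACGTA", "polyG"),
    ("ACGTACGTACGTACGTACGT", None),
])
def test_hard_filter(spacer, expected):
    guide = CandidateGuide("g", "interference", "c", spacer, "AGG", "+", 0, 20)
    passed, reason = hard_filter(guide, FilterRules())
    assert (passed, reason) == (expected is None, expected)


def test_polyt_fails_before_bsai():
    """First triggered reason wins: polyT is checked before BsaI."""
    guide = CandidateGuide("g", "interference", "c", "TTTTACGGTCTCACGTACGT", "AGG",
                           "+", 0, 20)
    assert hard_filter(guide)[1] == "polyT"


# ---- off-target scoring ----

def embed(spacer_plus_pam, rng, n=10_000):
    """Random genome with the given protospacer+PAM planted once (or more)."""
    backbone = random_dna(rng, n)
    pos = n // 3
    return backbone[:pos] + spacer_plus_pam + backbone[pos:]


class TestOffTarget:
    def test_unique_site_scores_one(self):
        rng = random.Random(10)
        spacer = "ACGTACGTGCACTGACGTAC"
        genome = Genome({"c": embed(spacer + "AGG", rng)})
        start = genome.contigs["c"].index(spacer)
        guide = CandidateGuide("g", "interference", "c", spacer, "AGG", "+",
                               start, start + 20)
        assert off_target_score(guide, genome, SPCAS9) == 1.0

    def test_perfect_duplicate_halves_score(self):
        rng = random.Random(11)
        spacer = "ACGTACGTGCACTGACGTAC"
        seq = embed(spacer + "AGG", rng, 5000)
        seq += random_dna(rng, 100) + spacer + "TGG" + random_dna(rng, 100)
        genome = Genome({"c": seq})
        start = seq.index(spacer)
        guide = CandidateGuide("g", "interference", "c", spacer, "AGG", "+",
                               start, start + 20)
        assert off_target_score(guide, genome, SPCAS9) == pytest.approx(0.5)

    def test_corrupted_index_detected(self):
        rng = random.Random(12)
        genome = Genome({"c": random_dna(rng, 1000)})
        guide = CandidateGuide("g", "interference", "c", "A" * 20, "AGG", "+", 0, 20)
        with pytest.raises(ValueError, match="index corruption"):
            off_target_score(guide, genome, SPCAS9)

    @pytest.mark.parametrize("seed", [20, 21])
    def test_matches_bruteforce_mismatch_count(self, seed):
        """Score equals the formula computed from an exhaustive sliding-window
        mismatch count over all PAM-adjacent sites."""
        rng = random.Random(seed)
        seq = random_dna(rng, 15_000)
        genome = Genome({"c": seq})
        region = DesignRegion("g", "interference", "c", 7000, 7300, "+")
        cands = enumerate_candidates(region, genome, SPCAS9)[:10]
        sites = oracle_sites(seq, SPCAS9)
        index = PamSiteIndex(genome, SPCAS9)
        for cand in cands:
            weighted = 0.0
            for lo, hi, strand, spacer in sites:
                if (lo, strand) == (cand.spacer_start, cand.strand):
                    continue
                mm = sum(a != b for a, b in zip(spacer, cand.protospacer))
                if mm <= 3:
                    weighted += (1.0, 0.5, 0.25, 0.125)[mm]
            expected = 1.0 / (1.0 + weighted)
            got = off_target_score(cand, genome, SPCAS9, index=index)
            assert got == pytest.approx(expected)


# ---- scoring ----

class TestScoring:
    GENE = GeneFeature("g", "c", "+", 1000, 2200, 1030, 2170)

    def make_genome(self, seed=30):
        rng = random.Random(seed)
        return Genome({"c": random_dna(rng, 4000)})

    def first_candidate(self, genome, lo=1000, hi=2200):
        region = DesignRegion("g", "interference", "c", lo, hi, "+")
        cands = enumerate_candidates(region, genome, SPCAS9, tss=self.GENE.tss)
        assert cands
        return cands[0]

    def test_deterministic(self):
        genome = self.make_genome()
        cand = self.first_candidate(genome)
        a = score_guide(cand, self.GENE, genome, SPCAS9)
        b = score_guide(cand, self.GENE, genome, SPCAS9)
        assert a == b

    def test_duplicate_site_lowers_composite(self):
        rng = random.Random(31)
        seq = random_dna(rng, 4000)
        genome1 = Genome({"c": seq})
        cand = self.first_candidate(genome1)
        # plant a perfect second copy of the protospacer+PAM far away
        from crispraid._seq import revcomp
        site = seq[cand.spacer_start:cand.spacer_end + 3]
        genome2 = Genome({"c": seq + random_dna(rng, 50) + site})
        s1 = score_guide(cand, self.GENE, genome1, SPCAS9)
        s2 = score_guide(cand, self.GENE, genome2, SPCAS9)
        assert s2.off_target < s1.off_target
        assert s2.composite < s1.composite

    def test_activation_position_prefers_window(self):
        """A guide 250 bp upstream of the TSS outranks one 700 bp upstream."""
        gene = GeneFeature("g", "c", "+", 1000, 2200, 1030, 2170)
        near = CandidateGuide("g", "activation", "c", "A" * 20, "TTTA", "+",
                              740, 760, tss_distance=-250)
        far = CandidateGuide("g", "activation", "c", "A" * 20, "TTTA", "+",
                             290, 310, tss_distance=-700)
        assert position_score(near, gene) > position_score(far, gene)
        assert position_score(near, gene) == 1.0

    def test_deletion_position_prefers_first_half(self):
        gene = GeneFeature("g", "c", "+", 1000, 2200, 1000, 2000)
        early = CandidateGuide("g", "deletion", "c", "A" * 22, "TTGAAT", "+",
                               1100, 1122)
        late = CandidateGuide("g", "deletion", "c", "A" * 22, "TTGAAT", "+",
                              1900, 1922)
        assert position_score(early, gene) == 1.0
        assert position_score(late, gene) < 1.0

    def test_components_and_composite_in_unit_interval(self):
        genome = self.make_genome(33)
        region = DesignRegion("g", "interference", "c", 1000, 2200, "+")
        index = PamSiteIndex(genome, SPCAS9)
        for cand in enumerate_candidates(region, genome, SPCAS9, tss=1000)[:25]:
            sg = score_guide(cand, self.GENE, genome, SPCAS9, index=index)
            for val in (sg.efficiency, sg.position_score, sg.gc_score,
                        sg.off_target, sg.composite):
                assert 0.0 <= val <= 1.0


# ---- de-clustering and selection ----

def scored_stub(gene_id, pos, comp, off=0.5):
    from crispraid.guide_design import ScoredGuide
    cand = CandidateGuide(gene_id, "interference", "c", "A" * 20, "AGG", "+",
                          pos - 10, pos + 10)
    return ScoredGuide(cand, 0.5, 0.5, 0.5, off, comp)


class TestClusterDedup:
    def test_overlapping_pair_keeps_best(self):
        guides = [scored_stub("g", 100, 0.9), scored_stub("g", 110, 0.8)]
        kept = cluster_dedup(guides, min_separation=30)
        assert [k.composite for k in kept] == [0.9]

    def test_separated_pair_both_kept(self):
        guides = [scored_stub("g", 100, 0.9), scored_stub("g", 200, 0.8)]
        assert len(cluster_dedup(guides, 30)) == 2

    def test_chain_matches_greedy_oracle(self):
        comps = [0.5, 0.9, 0.7, 0.8, 0.6]
        guides = [scored_stub("g", 100 + 10 * i, c) for i, c in enumerate(comps)]
        kept = cluster_dedup(guides, 30)
        # brute-force greedy oracle: sort desc, accept if far from accepted
        accepted = []
        for comp, pos in sorted(zip(comps, [100 + 10 * i for i in range(5)]),
                                reverse=True):
            if all(abs(pos - p) >= 30 for _, p in accepted):
                accepted.append((comp, pos))
        assert {(k.composite, k.candidate.position) for k in kept} == set(accepted)

    def test_different_genes_do_not_conflict(self):
        guides = [scored_stub("g1", 100, 0.9), scored_stub("g2", 105, 0.8)]
        assert len(cluster_dedup(guides, 30)) == 2

    def test_pairwise_separation_invariant(self):
        rng = random.Random(40)
        guides = [scored_stub("g", rng.randrange(0, 500), rng.random())
                  for _ in range(50)]
        kept = cluster_dedup(guides, 30)
        positions = sorted(k.candidate.position for k in kept)
        assert all(b - a >= 30 for a, b in zip(positions, positions[1:]))


class TestSelectTop:
    def test_counts_per_modality(self):
        guides = [scored_stub("g", 100 * i, 0.5 + 0.01 * i) for i in range(20)]
        top_a, short_a = select_top(guides, "activation")
        top_d, short_d = select_top(guides, "deletion")
        assert (len(top_a), short_a) == (6, False)
        assert (len(top_d), short_d) == (4, False)

    def test_shortfall_flag(self):
        guides = [scored_stub("g", 100 * i, 0.5) for i in range(3)]
        top, short = select_top(guides, "interference")
        assert (len(top), short) == (3, True)

    def test_best_first_with_dense_ranks(self):
        guides = [scored_stub("g", 100 * i, c)
                  for i, c in enumerate([0.5, 0.9, 0.9, 0.7])]
        ranked = rank_guides(guides)
        assert [r.composite for r in ranked] == [0.9, 0.9, 0.7, 0.5]
        assert [r.rank for r in ranked] == [1, 1, 2, 3]

    def test_ties_broken_by_off_target_then_position(self):
        a = scored_stub("g", 300, 0.8, off=0.9)
        b = scored_stub("g", 100, 0.8, off=0.5)
        c = scored_stub("g", 200, 0.8, off=0.5)
        ranked = rank_guides([a, b, c])
        assert [r.candidate.position for r in ranked] == [300, 100, 200]


# ---- controls ----

class TestControls:
    def test_exact_count_and_no_genomic_hits(self, toy_genome):
        controls = make_controls(100, toy_genome, SPCAS9, seed=5)
        assert len(controls) == 100
        # oracle: exhaustive scan of both strands for exact matches
        seqs = list(toy_genome.contigs.values())
        for spacer in controls:
            rc = oracle_rc(spacer)
            assert not any(spacer in s or rc in s for s in seqs)
            assert hard_filter(
                CandidateGuide("x", "interference", "", spacer, "", "+", 0, 20))[0]

    def test_deterministic_under_seed(self, toy_genome):
        a = make_controls(20, toy_genome, SACAS9, seed=9)
        b = make_controls(20, toy_genome, SACAS9, seed=9)
        assert a == b
        assert make_controls(20, toy_genome, SACAS9, seed=10) != a

    def test_impossible_request_errors(self):
        # a genome containing every 2-mer makes non-matching controls impossible
        cas = CasSpec("tiny", "NGG", "3prime", 2)
        genome = Genome({"c": "AACAGATCCGCTTGGTATTA" * 3})
        with pytest.raises(RuntimeError, match="controls"):
            make_controls(5, genome, cas, seed=1, max_attempts_per_control=20)


# ---- whole-design invariants ----

def test_selected_guides_respect_caps_and_separation(manifest):
    targeting = manifest[~manifest.is_control]
    per_gene = targeting.groupby(["library", "gene_id"]).size()
    caps = {"LibA": 6, "LibI": 6, "LibD": 4}
    for (lib, _), n in per_gene.items():
        assert n <= caps[lib]
    for (_, _), sub in targeting.groupby(["library", "gene_id"]):
        pos = sorted(sub.position)
        assert all(b - a >= 30 for a, b in zip(pos, pos[1:]))


def test_composite_invariant_under_gene_relabeling(toy_genome):
    gene = GeneFeature("orig", "chr1", "+", 1000, 2200, 1030, 2170)
    relabeled = GeneFeature("renamed", "chr1", "+", 1000, 2200, 1030, 2170)
    region = DesignRegion("orig", "interference", "chr1", 1000, 2200, "+")
    cand = enumerate_candidates(region, toy_genome, SPCAS9, tss=gene.tss)[0]
    s1 = score_guide(cand, gene, toy_genome, SPCAS9)
    s2 = score_guide(cand, relabeled, toy_genome, SPCAS9)
    assert (s1.composite, s1.efficiency, s1.position_score) == \
           (s2.composite, s2.efficiency, s2.position_score)
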