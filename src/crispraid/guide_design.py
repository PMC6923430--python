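"""Guide enumeration, filtering, scoring, de-clustering and selection.

Three Cas proteins drive the three modalities: a dead Cas12a fused to an
activation domain (activation, 5' TTTV PAM), a dead SpCas9 repressor
(interference, 3' NGG PAM), and a nuclease-active SaCas9 (deletion,
3' NNGRRT PAM).  For each gene the design region is scanned on both strands
for PAM-adjacent protospacers; candidates are hard-filtered (polyT, polyG,
BsaI), scored on four criteria (targeting efficiency, targeting position,
GC content, off-target), de-clustered so near-identical cut sites do not
crowd the library, and the top six (activation, interference) or four
(deletion) are selected per gene.  Each library also carries non-targeting
random controls.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, replace

import numpy as np

from ._seq import gc_fraction, homopolymer_runs, iupac_regex, revcomp
from .genome_model import DesignRegion, GeneFeature, Genome

MISMATCH_WEIGHTS = (1.0, 0.5, 0.25, 0.125)  # halving per allowed mismatch


@dataclass(frozen=True)
class CasSpec:
    """PAM geometry of one Cas protein.

    ``pam_side`` says where the PAM sits relative to the protospacer on the
    protospacer's own strand: Cas12a reads a 5' PAM, Cas9-family a 3' PAM.
    """

    name: str
    pam: str
    pam_side: str  # "5prime" | "3prime"
    spacer_len: int

    def __post_init__(self) -> None:
        if not self.pam:
            raise ValueError("PAM pattern must be non-empty")
        if self.pam_side not in ("5prime", "3prime"):
            raise ValueError(f"pam_side must be 5prime/3prime, got {self.pam_side!r}")


LBCAS12A = CasSpec("LbCas12a", "TTTV", "5prime", 20)
SPCAS9 = CasSpec("SpCas9", "NGG", "3prime", 20)
# 22-bp spacer + 6-bp NNGRRT PAM = the 28-bp segment removed by the deletion donor.
SACAS9 = CasSpec("SaCas9", "NNGRRT", "3prime", 22)

CAS_BY_MODALITY = {"activation": LBCAS12A, "interference": SPCAS9, "deletion": SACAS9}
LIBRARY_BY_MODALITY = {"activation": "LibA", "interference": "LibI", "deletion": "LibD"}
MODALITY_BY_LIBRARY = {v: k for k, v in LIBRARY_BY_MODALITY.items()}
GUIDES_PER_GENE = {"activation": 6, "interference": 6, "deletion": 4}


@dataclass(frozen=True)
class CandidateGuide:
    """A PAM-adjacent protospacer inside a design region.

    ``spacer_start``/``spacer_end`` are forward-strand genomic half-open
    coordinates of the protospacer; ``protospacer`` and ``pam`` are given on
    the targeted strand.  ``position`` is the cut-site proxy (protospacer
    midpoint, genomic).  ``tss_distance`` is signed along the gene: negative
    upstream of the TSS, positive downstream.
    """

    gene_id: str
    modality: str
    contig: str
    protospacer: str
    pam: str
    strand: str
    spacer_start: int
    spacer_end: int
    tss_distance: int | None = None

    @property
    def position(self) -> int:
        return (self.spacer_start + self.spacer_end) // 2


@dataclass(frozen=True)
class ScoredGuide:
    candidate: CandidateGuide
    efficiency: float
    position_score: float
    gc_score: float
    off_target: float
    composite: float
    rank: int = 0


@dataclass
class FilterRules:
    """Hard exclusion rules applied to every protospacer.

    polyT (Pol III terminator) and polyG (synthesis failure) run thresholds,
    plus forbidden motifs — by default the BsaI recognition site on either
    strand, which would break Golden-Gate cloning.
    """

    polyt_run: int = 4
    polyg_run: int = 5
    forbidden_motifs: tuple[str, ...] = ("GGTCTC", "GAGACC")


@dataclass
class ScoreWeights:
    efficiency: float = 0.3
    position: float = 0.3
    gc: float = 0.1
    off_target: float = 0.3

    def as_array(self) -> np.ndarray:
        w = np.array([self.efficiency, self.position, self.gc, self.off_target], float)
        total = w.sum()
        if total <= 0:
            raise ValueError("score weights must sum to a positive value")
        return w / total


def scan_sequence(seq: str, cas: CasSpec) -> list[tuple[int, int, str, str, str]]:
    """All PAM-adjacent protospacers in ``seq`` on both strands.

    Returns tuples ``(spacer_start, spacer_end, strand, protospacer, pam)``
    with coordinates on the forward strand of ``seq``; overlapping PAM
    matches are all reported (the PAM regex is wrapped in a lookahead).
    """
    pat = iupac_regex(cas.pam)
    overlap = re.compile(f"(?={pat.pattern})")
    plen, slen = len(cas.pam), cas.spacer_len
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for m in overlap.finditer(s):
            p = m.start()
            if cas.pam_side == "3prime":
                lo, hi = p - slen, p
            else:
                lo, hi = p + plen, p + plen + slen
            if lo < 0 or hi > n:
                continue
            spacer, pam = s[lo:hi], s[p:p + plen]
            if strand == "-":
                lo, hi = n - hi, n - lo
            out.append((lo, hi, strand, spacer, pam))
    return sorted(set(out))


def enumerate_candidates(region: DesignRegion, genome: Genome, cas: CasSpec,
                         tss: int | None = None) -> list[CandidateGuide]:
    """Every protospacer fully inside ``region`` adjacent to a matching PAM.

    The PAM itself may extend past the region edge as long as it stays on
    the contig.  Duplicate (position, strand) sites are collapsed.
    """
    plen, slen = len(cas.pam), cas.spacer_len
    if region.end - region.start < slen:
        return []
    # pad by the PAM length so PAMs just outside the region still qualify
    pad_lo = max(0, region.start - plen)
    pad_hi = min(genome.length(region.contig), region.end + plen)
    seq = genome.fetch(region.contig, pad_lo, pad_hi)

    seen: set[tuple[int, str]] = set()
    out: list[CandidateGuide] = []
    for lo, hi, strand, spacer, pam in scan_sequence(seq, cas):
        g_lo, g_hi = lo + pad_lo, hi + pad_lo
        if g_lo < region.start or g_hi > region.end:
            continue  # spacer must sit fully inside the design region
        if (g_lo, strand) in seen:
            continue
        seen.add((g_lo, strand))
        cand = CandidateGuide(region.gene_id, region.modality, region.contig,
                              spacer, pam, strand, g_lo, g_hi)
        if tss is not None:
            dist = cand.position - tss if region.strand == "+" else tss - cand.position
            cand = replace(cand, tss_distance=dist)
        out.append(cand)
    return out


def hard_filter(guide: CandidateGuide, rules: FilterRules | None = None
                ) -> tuple[bool, str | None]:
    """Apply exclusion rules; returns (passed, first failing reason)."""
    rules = rules or FilterRules()
    s = guide.protospacer.upper()
    if "T" * rules.polyt_run in s:
        return False, "polyT"
    if "G" * rules.polyg_run in s:
        return False, "polyG"
    for motif in rules.forbidden_motifs:
        if motif in s:
            return False, "BsaI"
    return True, None


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), np.uint8)


class PamSiteIndex:
    """All PAM-adjacent protospacer windows of a genome, for off-target counting.

    Built once per (genome, Cas); holds the site sequences as a byte matrix so
    Hamming distances to a query spacer vectorize.
    """

    def __init__(self, genome: Genome, cas: CasSpec):
        self.cas = cas
        keys, rows = [], []
        for contig, seq in genome.contigs.items():
            for lo, hi, strand, spacer, _pam in scan_sequence(seq, cas):
                keys.append((contig, lo, strand))
                rows.append(_encode(spacer))
        self.keys = keys
        self.row_of = {key: i for i, key in enumerate(keys)}
        self.matrix = (np.vstack(rows) if rows
                       else np.empty((0, cas.spacer_len), np.uint8))

    def mismatch_counts(self, spacer: str, exclude: tuple[str, int, str],
                        max_mismatch: int) -> np.ndarray:
        """n_m for m = 0..max_mismatch, excluding the on-target site."""
        query = _encode(spacer)
        mism = (self.matrix != query).sum(axis=1)
        counts = np.bincount(mism[mism <= max_mismatch],
                             minlength=max_mismatch + 1)[:max_mismatch + 1].copy()
        row = self.row_of.get(exclude)
        if row is not None and mism[row] <= max_mismatch:
            counts[mism[row]] -= 1
        return counts


_SITE_INDEX_CACHE: dict[tuple[int, str], PamSiteIndex] = {}


def _site_index(genome: Genome, cas: CasSpec) -> PamSiteIndex:
    key = (id(genome), cas.name)
    if key not in _SITE_INDEX_CACHE:
        _SITE_INDEX_CACHE[key] = PamSiteIndex(genome, cas)
    return _SITE_INDEX_CACHE[key]


def off_target_score(guide: CandidateGuide, genome: Genome, cas: CasSpec,
                     max_mismatch: int = 3,
                     index: PamSiteIndex | None = None) -> float:
    """Whole-spacer mismatch-count score in [0, 1].

    1.0 when the spacer has no second PAM-adjacent genomic site within
    ``max_mismatch`` mismatches; otherwise ``1 / (1 + sum_m w_m n_m)`` with
    weights halving per mismatch (1, 0.5, 0.25, 0.125) and the on-target
    site excluded from the counts.
    """
    site = genome.fetch(guide.contig, guide.spacer_start, guide.spacer_end)
    expect = site if guide.strand == "+" else revcomp(site)
    if expect != guide.protospacer:
        raise ValueError(
            f"guide {guide.gene_id}@{guide.spacer_start}: genome does not carry the "
            f"recorded protospacer (index corruption)")
    index = index or _site_index(genome, cas)
    counts = index.mismatch_counts(guide.protospacer,
                                   (guide.contig, guide.spacer_start, guide.strand),
                                   max_mismatch)
    weighted = sum(w * n for w, n in zip(MISMATCH_WEIGHTS, counts))
    return 1.0 / (1.0 + weighted)


def efficiency_score(spacer: str, cas: CasSpec) -> float:
    """Sequence-composition heuristic in [0, 1].

    Starts at 0.9, loses 0.15 per homopolymer run of length >= 3 (synthesis
    and transcription liabilities), and gains 0.1 for a G/C at the 3' end of
    the spacer for 3'-PAM (Cas9-type) proteins, where a PAM-proximal G/C
    favours cleavage.
    """
    score = 0.9 - 0.15 * homopolymer_runs(spacer, 3)
    if cas.pam_side == "3prime" and spacer[-1] in "GC":
        score += 0.1
    return float(min(1.0, max(0.0, score)))


# (window_lo, window_hi, decay) per modality, in bp relative to the TSS:
# full score inside the window, linear decay to zero `decay` bp past an edge.
POSITION_WINDOWS = {"activation": (-400, -100, 200), "interference": (-50, 300, 200)}


def position_score(guide: CandidateGuide, gene: GeneFeature) -> float:
    """Placement score in [0, 1] for the modality's effective window."""
    if guide.modality == "deletion":
        # first half of the CDS scores 1, then linear decay to 0 at the CDS end
        cds_len = gene.cds_end - gene.cds_start
        if gene.strand == "+":
            offset = guide.position - gene.cds_start
        else:
            offset = gene.cds_end - 1 - guide.position
        frac = min(1.0, max(0.0, offset / max(1, cds_len)))
        return 1.0 if frac <= 0.5 else max(0.0, (1.0 - frac) / 0.5)
    lo, hi, decay = POSITION_WINDOWS[guide.modality]
    d = guide.tss_distance
    if d is None:
        d = (guide.position - gene.tss if gene.strand == "+"
             else gene.tss - guide.position)
    if lo <= d <= hi:
        return 1.0
    gap = lo - d if d < lo else d - hi
    return max(0.0, 1.0 - gap / decay)


def gc_score(spacer: str) -> float:
    return float(min(1.0, max(0.0, 1.0 - 2.0 * abs(gc_fraction(spacer) - 0.5))))


def score_guide(guide: CandidateGuide, gene: GeneFeature, genome: Genome,
                cas: CasSpec, weights: ScoreWeights | None = None,
                max_mismatch: int = 3,
                index: PamSiteIndex | None = None) -> ScoredGuide:
    """Combine the four criteria into a composite score (weights sum to 1)."""
    weights = weights or ScoreWeights()
    comp = np.array([
        efficiency_score(guide.protospacer, cas),
        position_score(guide, gene),
        gc_score(guide.protospacer),
        off_target_score(guide, genome, cas, max_mismatch, index),
    ])
    composite = float(comp @ weights.as_array())
    return ScoredGuide(guide, *map(float, comp), composite)


def _order_key(sg: ScoredGuide):
    # descending composite; ties by off-target (desc) then genomic position (asc)
    return (-sg.composite, -sg.off_target, sg.candidate.position)


def rank_guides(scored: list[ScoredGuide]) -> list[ScoredGuide]:
    """Sort by composite (best first) and assign dense ranks starting at 1."""
    ordered = sorted(scored, key=_order_key)
    out, rank, prev = [], 0, None
    for sg in ordered:
        if sg.composite != prev:
            rank += 1
            prev = sg.composite
        out.append(replace(sg, rank=rank))
    return out


def cluster_dedup(scored: list[ScoredGuide], min_separation: int = 30
                  ) -> list[ScoredGuide]:
    """Greedy de-clustering: walk guides best-first, keep one whose cut-site
    proxy is >= ``min_separation`` bp from every kept guide of the same
    gene and modality."""
    kept: list[ScoredGuide] = []
    positions: dict[tuple[str, str], list[int]] = {}
    for sg in sorted(scored, key=_order_key):
        key = (sg.candidate.gene_id, sg.candidate.modality)
        pos = sg.candidate.position
        if all(abs(pos - p) >= min_separation for p in positions.get(key, ())):
            kept.append(sg)
            positions.setdefault(key, []).append(pos)
    return kept


def select_top(scored: list[ScoredGuide], modality: str,
               per_gene: dict[str, int] | None = None
               ) -> tuple[list[ScoredGuide], bool]:
    """Top-N guides by composite (N = 6/6/4 by modality).

    Returns the ranked selection and a shortfall flag set when fewer
    candidates than N were available.
    """
    n = (per_gene or GUIDES_PER_GENE)[modality]
    ranked = rank_guides(scored)
    return ranked[:n], len(ranked) < n


def make_controls(n: int, genome: Genome, cas: CasSpec, seed: int,
                  rules: FilterRules | None = None,
                  max_attempts_per_control: int = 1000) -> list[str]:
    """Non-targeting control spacers: random sequences of the Cas spacer
    length with zero exact genomic matches on either strand and no hard-filter
    violation.  Deterministic under ``seed``."""
    rules = rules or FilterRules()
    rng = random.Random(seed)
    contigs = list(genome.contigs.values())
    controls: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(controls) < n:
        attempts += 1
        if attempts > max_attempts_per_control * n:
            raise RuntimeError(
                f"could not find {n} non-targeting controls in {attempts} attempts")
        spacer = "".join(rng.choice("ACGT") for _ in range(cas.spacer_len))
        if spacer in seen:
            continue
        probe = CandidateGuide("control", "control", "", spacer, "", "+", 0,
                               cas.spacer_len)
        if not hard_filter(probe, rules)[0]:
            continue
        rc = revcomp(spacer)
        if any(spacer in c or rc in c for c in contigs):
            continue
        seen.add(spacer)
        controls.append(spacer)
    return controls
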