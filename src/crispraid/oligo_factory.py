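"""Chip-ready oligo construction and in-silico Golden-Gate assembly.

Each selected guide becomes one array-synthesized oligo: a left adapter
(priming sequence + BsaI site cutting inward), the variable segment, and a
right adapter (BsaI site + priming sequence).  For the deletion library the
variable segment carries an HDR donor — the two homology arms fused across
the deleted interval — 5' of the spacer, so a single sequencing read covers
donor and spacer.  BsaI digestion releases the variable segment with 4-nt
overhangs that match the drop-out in the expression-cassette backbone
(promoter … [drop-out] … scaffold … terminator); ligation is scar-free, so
no BsaI recognition site survives in any product.

Adapter, promoter, scaffold and terminator sequences are configurable
templates.  The shipped defaults are synthetic stand-ins generated from a
fixed seed (BsaI-free, library-distinct overhangs); all length checks are
template-relative.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .genome_model import Genome
from .guide_design import CandidateGuide, ScoredGuide

BSAI_SITE = "GGTCTC"          # top-strand recognition; cuts N1, 4-nt 5' overhang
BSAI_SITE_RC = "GAGACC"       # bottom-strand site as read on the top strand
OVERHANG_LEN = 4


class AssemblyError(ValueError):
    """Raised when in-silico digestion/ligation cannot proceed."""


def _bsai_free_random(rng: random.Random, length: int, gc: float = 0.45) -> str:
    """Random sequence with no BsaI site on either strand."""
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    while True:
        seq = "".join(rng.choices("ACGT", weights=weights, k=length))
        if BSAI_SITE not in seq and BSAI_SITE_RC not in seq:
            return seq


def _make_default_templates() -> dict:
    """Synthetic default templates, deterministic under a fixed seed.

    Scaffold lengths follow the three libraries' structural-sequence lengths
    (23 / 82 / 127 bp); each scaffold starts with a distinct 4-mer that
    serves as the library-specific right overhang.
    """
    rng = random.Random(73)
    snr52p = _bsai_free_random(rng, 60)
    sup4t = _bsai_free_random(rng, 40)
    scaffolds = {}
    for lib, length, lead in (("LibA", 23, "AATC"), ("LibI", 82, "CCGA"),
                              ("LibD", 127, "TGCA")):
        scaffolds[lib] = lead + _bsai_free_random(rng, length - OVERHANG_LEN)
    primers = {lib: (_bsai_free_random(rng, 18), _bsai_free_random(rng, 18))
               for lib in ("LibA", "LibI", "LibD")}
    return {"snr52p": snr52p, "sup4t": sup4t, "scaffolds": scaffolds,
            "primers": primers}


DEFAULT_TEMPLATES = _make_default_templates()


@dataclass(frozen=True)
class AdapterSet:
    """Left/right adapters for one library; both must carry a BsaI site
    oriented to cut inward (left: GGTCTC reading toward the insert; right:
    the bottom-strand site GAGACC)."""

    library: str
    left: str
    right: str

    def __post_init__(self) -> None:
        if BSAI_SITE not in self.left:
            raise AssemblyError(f"{self.library} left adapter lacks a BsaI site")
        if BSAI_SITE_RC not in self.right:
            raise AssemblyError(f"{self.library} right adapter lacks a BsaI site")

    @property
    def left_overhang(self) -> str:
        cut = self.left.index(BSAI_SITE) + len(BSAI_SITE) + 1
        return self.left[cut:cut + OVERHANG_LEN]

    @property
    def right_overhang(self) -> str:
        cut = self.right.index(BSAI_SITE_RC) - 1
        return self.right[cut - OVERHANG_LEN:cut]


@dataclass(frozen=True)
class CassetteTemplate:
    """Expression-cassette backbone: promoter … BsaI drop-out … scaffold …
    terminator.  The promoter's last 4 bases and the scaffold's first 4 are
    the ligation overhangs."""

    library: str
    snr52p: str
    scaffold: str
    sup4t: str

    @property
    def left_overhang(self) -> str:
        return self.snr52p[-OVERHANG_LEN:]

    @property
    def right_overhang(self) -> str:
        return self.scaffold[:OVERHANG_LEN]

    @property
    def sequence(self) -> str:
        """Undigested backbone with the BsaI drop-out in place."""
        dropout = "A" + BSAI_SITE_RC + "TCTTCGAATCA" + BSAI_SITE + "A"
        return self.snr52p + dropout + self.scaffold + self.sup4t


def default_adapters(library: str, templates: dict = DEFAULT_TEMPLATES) -> AdapterSet:
    fwd, rev = templates["primers"][library]
    oh_l = templates["snr52p"][-OVERHANG_LEN:]
    oh_r = templates["scaffolds"][library][:OVERHANG_LEN]
    return AdapterSet(library,
                      left=fwd + BSAI_SITE + "A" + oh_l,
                      right=oh_r + "T" + BSAI_SITE_RC + rev)


def default_backbone(library: str, templates: dict = DEFAULT_TEMPLATES) -> CassetteTemplate:
    return CassetteTemplate(library, templates["snr52p"],
                            templates["scaffolds"][library], templates["sup4t"])


@dataclass(frozen=True)
class DonorDesign:
    """HDR donor encoding a fixed-length deletion: the two homology arms
    flank the deleted interval (protospacer + PAM) exactly."""

    gene_id: str
    contig: str
    deleted_start: int
    deleted_end: int
    upstream_arm: str
    downstream_arm: str

    @property
    def deleted_length(self) -> int:
        return self.deleted_end - self.deleted_start

    @property
    def sequence(self) -> str:
        """The donor as synthesized: arms fused across the deletion."""
        return self.upstream_arm + self.downstream_arm


def _as_candidate(guide: ScoredGuide | CandidateGuide) -> CandidateGuide:
    return guide.candidate if isinstance(guide, ScoredGuide) else guide


def pam_genomic_span(guide: CandidateGuide, pam_side: str = "3prime") -> tuple[int, int]:
    """Forward-strand genomic interval occupied by the guide's PAM."""
    plen = len(guide.pam)
    downstream = (pam_side == "3prime") == (guide.strand == "+")
    if downstream:
        return guide.spacer_end, guide.spacer_end + plen
    return guide.spacer_start - plen, guide.spacer_start


def build_deletion_donor(guide: ScoredGuide | CandidateGuide, genome: Genome,
                         arm_len: int = 50) -> DonorDesign:
    """Donor whose arms flank the protospacer+PAM interval (28 bp under the
    default 22-bp spacer + 6-bp PAM)."""
    cand = _as_candidate(guide)
    if cand.modality != "deletion":
        raise ValueError(f"donor requested for non-deletion guide {cand.gene_id}")
    pam_lo, pam_hi = pam_genomic_span(cand)
    del_lo = min(cand.spacer_start, pam_lo)
    del_hi = max(cand.spacer_end, pam_hi)
    if del_lo - arm_len < 0 or del_hi + arm_len > genome.length(cand.contig):
        raise ValueError(
            f"{cand.gene_id}: homology arm extends beyond contig {cand.contig}")
    return DonorDesign(
        gene_id=cand.gene_id, contig=cand.contig,
        deleted_start=del_lo, deleted_end=del_hi,
        upstream_arm=genome.fetch(cand.contig, del_lo - arm_len, del_lo),
        downstream_arm=genome.fetch(cand.contig, del_hi, del_hi + arm_len),
    )


def apply_hdr(genome: Genome, donor: DonorDesign) -> Genome:
    """Exact arm-anchored splice: remove the deleted interval from the contig.

    Both arms must match the genome exactly at their recorded positions
    (homology-directed repair tolerates no mismatches in this model).
    """
    seq = genome.contigs[donor.contig]
    lo, hi, arm = donor.deleted_start, donor.deleted_end, len(donor.upstream_arm)
    if seq[lo - arm:lo] != donor.upstream_arm or seq[hi:hi + arm] != donor.downstream_arm:
        raise AssemblyError(f"{donor.gene_id}: donor arms do not match the genome")
    edited = dict(genome.contigs)
    edited[donor.contig] = seq[:lo] + seq[hi:]
    return Genome(edited)


@dataclass(frozen=True)
class OligoRecord:
    """One chip oligo with its segment layout (half-open offsets)."""

    guide_id: str
    library: str
    sequence: str
    segments: dict[str, tuple[int, int]] = field(hash=False)

    def segment(self, name: str) -> str:
        lo, hi = self.segments[name]
        return self.sequence[lo:hi]

    @property
    def variable_segment(self) -> str:
        lo = self.segments["left_adapter"][1]
        hi = self.segments["right_adapter"][0]
        return self.sequence[lo:hi]


def _bsai_positions(seq: str) -> list[int]:
    return sorted([i for i in range(len(seq)) if seq.startswith(BSAI_SITE, i)]
                  + [i for i in range(len(seq)) if seq.startswith(BSAI_SITE_RC, i)])


def build_oligo(guide: ScoredGuide | CandidateGuide, guide_id: str,
                donor: DonorDesign | None, adapters: AdapterSet) -> OligoRecord:
    """Assemble one oligo string; donor arms precede the spacer for the
    deletion library, and no BsaI site may appear in or at the edges of the
    variable segment."""
    cand = _as_candidate(guide)
    lib = adapters.library
    if lib == "LibD" and donor is None:
        raise ValueError(f"{guide_id}: deletion-library oligo requires a donor")
    if lib != "LibD" and donor is not None:
        raise ValueError(f"{guide_id}: donor supplied for non-deletion library {lib}")

    parts: list[tuple[str, str]] = [("left_adapter", adapters.left)]
    if donor is not None:
        parts += [("upstream_arm", donor.upstream_arm),
                  ("downstream_arm", donor.downstream_arm)]
    parts += [("spacer", cand.protospacer), ("right_adapter", adapters.right)]

    segments, pos, chunks = {}, 0, []
    for name, seg in parts:
        segments[name] = (pos, pos + len(seg))
        chunks.append(seg)
        pos += len(seg)
    seq = "".join(chunks)

    allowed = {adapters.left.index(BSAI_SITE),
               segments["right_adapter"][0] + adapters.right.index(BSAI_SITE_RC)}
    for hit in _bsai_positions(seq):
        if hit in allowed:
            continue
        junction = next((name for name, (lo, hi) in segments.items()
                         if lo - len(BSAI_SITE) < hit < hi), "?")
        raise AssemblyError(
            f"{guide_id}: unexpected BsaI site at position {hit} (segment {junction})")
    return OligoRecord(guide_id, lib, seq, segments)


def digest_oligo(oligo: OligoRecord) -> str:
    """BsaI digestion product: the variable segment flanked by its two
    4-nt overhangs."""
    seq = oligo.sequence
    try:
        left_cut = seq.index(BSAI_SITE) + len(BSAI_SITE) + 1
        right_cut = seq.index(BSAI_SITE_RC, left_cut) - 1
    except ValueError as exc:
        raise AssemblyError(f"{oligo.guide_id}: oligo lacks paired BsaI sites") from exc
    if right_cut - OVERHANG_LEN <= left_cut:
        raise AssemblyError(f"{oligo.guide_id}: BsaI sites too close to excise insert")
    return seq[left_cut:right_cut]


def golden_gate_assemble(oligo: OligoRecord, backbone: CassetteTemplate) -> str:
    """Digest + ligate: the backbone drop-out is replaced by the oligo's
    variable segment.  Overhangs must match; the product carries no BsaI
    recognition site (scar-free)."""
    fragment = digest_oligo(oligo)
    if fragment[:OVERHANG_LEN] != backbone.left_overhang:
        raise AssemblyError(
            f"{oligo.guide_id}: left overhang {fragment[:OVERHANG_LEN]} does not "
            f"match backbone {backbone.library} ({backbone.left_overhang})")
    if fragment[-OVERHANG_LEN:] != backbone.right_overhang:
        raise AssemblyError(
            f"{oligo.guide_id}: right overhang {fragment[-OVERHANG_LEN:]} does not "
            f"match backbone {backbone.library} ({backbone.right_overhang})")
    product = (backbone.snr52p + fragment[OVERHANG_LEN:-OVERHANG_LEN]
               + backbone.scaffold + backbone.sup4t)
    if _bsai_positions(product):
        raise AssemblyError(f"{oligo.guide_id}: BsaI site survives in the cassette")
    return product


DEFAULT_VECTOR = "TTGACAGCTAGCTCAGTCCTAGGTATAATGCTAGC"  # minimal synthetic stuffer


def assemble_double_cassette(cassette1: str, cassette2: str,
                             vector: str = DEFAULT_VECTOR) -> str:
    """Two expression cassettes in one vector, fixed order and orientation
    (the two cassette positions are distinct in the assembly)."""
    for i, cassette in enumerate((cassette1, cassette2), start=1):
        if _bsai_positions(cassette):
            raise AssemblyError(f"cassette {i} still carries a BsaI site")
    return vector + cassette1 + cassette2
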