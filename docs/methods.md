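# Methods

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open on the forward strand; GFF3
and the TSV feature table are 1-based inclusive on input and output. A
gene's TSS is the first transcribed base (`start` on +, `end − 1` on −).
RNA genes without an annotated CDS carry their gene span as the CDS span.
Protospacers are reported on the targeted strand; a guide's cut-site proxy
is the genomic midpoint of its protospacer — a deliberate simplification
(true Cas9 blunt cuts sit ~3 bp from the PAM, Cas12a cuts are staggered and
PAM-distal) that only enters cluster de-duplication and position scoring,
where a ±10 bp shift is immaterial at the 30-bp separation default.

## Design regions

* activation: `[TSS − promoter_span, TSS)` strand-oriented, default
  **400 bp** — a typical effective CRISPRa window upstream of the core
  promoter;
* interference: gene span plus a **200 bp** upstream margin covering the
  core promoter, where CRISPRi blocks initiation and early elongation;
* deletion: the CDS exactly.

Regions are clipped to contig bounds and, by default, *not* trimmed at
neighbouring genes (flag `RegionParams.trim_at_neighbors` reserved). A
consequence of untrimmed promoters is that divergently transcribed gene
pairs can offer the identical genomic site to two genes; because each
library must contain unique guide sequences, the site is assigned to the
first gene encountered and the second gene takes its next-best candidate.

## Cas geometry

| library | protein  | PAM     | side | spacer |
|---------|----------|---------|------|--------|
| LibA    | LbCas12a | TTTV    | 5′   | 20 bp  |
| LibI    | SpCas9   | NGG     | 3′   | 20 bp  |
| LibD    | SaCas9   | NNGRRT  | 3′   | 22 bp  |

The 22-bp SaCas9 spacer is chosen so spacer + PAM = 28 bp, the length the
deletion donor removes. All values are configurable via `CasSpec`.

## Scoring

Composite = weighted sum of four components, weights (0.3, 0.3, 0.1, 0.3)
for (efficiency, position, GC, off-target), normalized to sum to 1.

* **Efficiency** is a transparent sequence heuristic, not a learned model:
  0.9 baseline, −0.15 per homopolymer run ≥ 3 (synthesis/transcription
  liability), +0.1 for a 3′-terminal G/C on 3′-PAM proteins, clipped to
  [0, 1].
* **Position**: full score inside the modality window (activation
  −400..−100 bp from the TSS; interference −50..+300), decaying linearly to
  zero 200 bp past a window edge; deletion guides score 1 in the first half
  of the CDS and decay linearly to 0 at the CDS end (earlier frameshifts
  truncate more of the protein).
* **GC**: `1 − 2·|GC − 0.5|`, i.e. 0.5 GC is ideal, extremes score 0.
* **Off-target**: `1 / (1 + Σ_m w_m·n_m)` where `n_m` is the number of
  *other* PAM-adjacent genomic sites at exactly m mismatches to the whole
  spacer (m ≤ 3) and the weights halve per mismatch (1, 0.5, 0.25, 0.125).
  No PAM-proximal seed weighting by default — whole-spacer mismatch counting
  is the simplest defensible model; the per-site matrix (`PamSiteIndex`)
  makes it exact and fast on multi-kb genomes.

Hard filters run before scoring: polyT run ≥ 4 (Pol III terminator),
polyG run ≥ 5 (synthesis failure), and the BsaI recognition site on either
strand (breaks Golden-Gate cloning). Cluster de-duplication is greedy
best-first with a 30-bp minimum cut-site separation per gene and modality;
ties in composite break by off-target score, then by ascending genomic
position, making the whole design deterministic. Selection keeps the top
6/6/4 per gene and flags genes with fewer candidates ("shortfall") rather
than failing.

Non-targeting controls are rejection-sampled: random spacers of the Cas
length with zero exact genomic matches on either strand and no hard-filter
violation; 100 per library by default, deterministic under the seed.

## Oligos, donors, assembly

The deletion donor's arms are the 50 bp immediately flanking the
protospacer+PAM interval; in-silico HDR is an exact arm-anchored splice (no
mismatches tolerated), so `apply_hdr` shortens the contig by exactly 28 bp.
Oligos are left adapter + (donor arms, deletion library only) + spacer +
right adapter, the donor 5′ of the spacer so a single read can cover both.
Deletion-library controls receive synthetic (non-genomic) stuffer arms so
all LibD oligos stay the same length — uniform length within each library
is what keeps array synthesis and PCR unbiased. With 50-bp arms and the
22-bp spacer the LibD variable segment is 122 bp; the shipped scaffold
lengths (23/82/127 bp) follow the three libraries' structural-sequence
lengths.

Golden-Gate assembly is simulated at the sticky-end level: BsaI cuts one
base downstream of its recognition site leaving 4-nt 5′ overhangs; the
fragment's overhangs must equal the backbone's (the promoter's last 4 bases
and the scaffold's first 4, which differ per library — loading an oligo
into the wrong backbone raises an overhang-mismatch error). Products are
verified scar-free (zero BsaI sites). Adapter, promoter, scaffold and
terminator defaults are synthetic stand-ins generated from a fixed seed and
verified BsaI-free; every length check is template-relative, so real
sequences can be dropped in.

## Barcodes and counting

A guide's barcode is its spacer followed by the library's scaffold, padded
or truncated to 43 bp; distinct scaffolds make the three libraries
separable in one index, and collisions abort index construction naming the
pair. Simulated reads place the barcode between a promoter tail and a
terminator head at a fixed column, so fixed-column and anchor-search
extraction agree on error-free reads — the real amplicon geometry (one
single-end lane) is not modelled beyond this. Matching is exact hash lookup
by default; optional Hamming rescue (≤ 2) enumerates the substitution
neighbourhood and requires a unique best hit. A k-mer scan
(`find_barcodes`) recovers barcodes from assembled cassettes and
double-cassette plasmids regardless of position.

## Enrichment

Counts are normalized to each library's total mapped reads. Hits need
≥ 1 raw read in all six libraries and fold ≥ 5 in every replicate pair;
no pseudocounts are added — the read floor already guarantees positive
denominators, preserving the stated order of operations. The mean fold is
arithmetic (geometric behind a flag). No p-values: the method ranks by
fold only, and statistical testing is out of scope.

## Simulator

`make_toy_genome` places genes on alternating strands over i.i.d. random
sequence (default GC 0.40, 20 genes of 600–1200 bp with 500–800 bp
intergenic gaps — wide enough for the promoter windows); CDSs are inset
30 bp as toy UTRs. Untreated abundances are symmetric Dirichlet with
concentration 5 (moderate library skew; no abundance distribution is
prescribed by the protocol, so this is a package choice); stressed
abundances are untreated × true fold, renormalized — note this
renormalization biases recovered folds slightly below the injected value,
proportionally to the total spiked mass. Replicates are independent
multinomials at the configured depth (default 1e5 reads/library; the
deep-screen checks use 1e6). Synthesis and sequencing errors are
substitution-only by default so fixed-column extraction stays valid; indel
modes are out of scope. Every output byte is determined by (seed, config).

What the simulator does *not* emulate: growth-competition dynamics, PCR
jackpotting, indels/truncations in synthesis, quality-score structure, or
real promoter/terminator sequences. Passing tests therefore demonstrate
the correctness of the design rules, extraction, counting and filtering
arithmetic — not performance on real sequencing artefacts.

## Problem sizes used in tests

The default suite designs against a 20-gene (~31 kb) toy genome (~600
guides incl. controls), counts ~1e5 simulated reads for the extraction
checks, and uses count-level simulation at 1e6 reads/library (5 seeds) for
spiked-recovery and fold-recovery checks; oracle-equivalence checks run
exhaustive brute-force scans on ≤ 31 kb of sequence. These sizes exercise
every code path at full fidelity; all stages scale linearly in genome size
and read count.

## Known limitations

* The efficiency heuristic is intentionally simple; published on-target
  models (or the original supplementary weights) can replace it by
  configuring `ScoreWeights` and swapping `efficiency_score`.
* Off-target counting is exhaustive over PAM-adjacent sites, fine for
  toy-to-megabase genomes but not optimized for mammalian scale.
* One CDS interval per gene (no introns); overlap trimming between
  neighbouring genes is not implemented.
* Hamming rescue at distance 2 enumerates ~8k neighbours per read — use 0
  or 1 for deep lanes.
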