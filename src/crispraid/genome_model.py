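"""Genome and annotation model with modality-specific design regions.

Coordinate convention: all internal coordinates are 0-based half-open
``[start, end)`` on the forward strand of the contig.  GFF3 and the simple
TSV feature table use 1-based inclusive coordinates on input and output.

Design regions per modality:

* ``activation`` — the promoter window upstream of the TSS (CRISPRa acts
  through a DNA-binding dead Cas recruiting an activation domain upstream of
  the core promoter);
* ``interference`` — the gene body plus an upstream margin covering the core
  promoter (CRISPRi blocks initiation/elongation);
* ``deletion`` — the CDS exactly (a cut plus HDR donor removes coding
  sequence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from ._seq import revcomp

logger = logging.getLogger(__name__)

MODALITIES = ("activation", "interference", "deletion")

TSV_COLUMNS = [
    "gene_id", "contig", "strand", "gene_start", "gene_end",
    "cds_start", "cds_end", "class",
]


@dataclass
class Genome:
    """Uppercase DNA sequences keyed by contig id."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {cid!r} contains non-DNA characters {sorted(bad)}")
            self.contigs[cid] = seq

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand slice, half-open."""
        return self.contigs[contig][start:end]

    def revcomp(self) -> "Genome":
        return Genome({cid: revcomp(seq) for cid, seq in self.contigs.items()})


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene, internal half-open coordinates.

    ``tss`` is the index of the first transcribed base: ``start`` for a
    plus-strand gene, ``end - 1`` for a minus-strand gene.  RNA genes without
    an annotated CDS carry the gene span as their CDS span.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    cds_start: int
    cds_end: int
    gene_class: str = "ORF"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty gene span")
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise ValueError(f"{self.gene_id}: CDS span outside gene span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class DesignRegion:
    """Half-open genomic interval handed to the guide enumerator."""

    gene_id: str
    modality: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}/{self.modality}: empty design region")


@dataclass
class RegionParams:
    """Tunable geometry of the design regions (bp).

    promoter_span: activation window upstream of the TSS.
    interference_upstream: margin ahead of the gene span for interference.
    trim_at_neighbors: clip regions at adjacent gene spans (off by default).
    """

    promoter_span: int = 400
    interference_upstream: int = 200
    trim_at_neighbors: bool = False


def load_genome(path: str | Path) -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`; sequences are uppercased."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(contigs)


def _feature_from_tsv_row(row: dict[str, str]) -> GeneFeature:
    start = int(row["gene_start"]) - 1          # 1-based incl -> 0-based half-open
    end = int(row["gene_end"])
    cds_s, cds_e = row.get("cds_start", ""), row.get("cds_end", "")
    if cds_s in ("", ".", "NA") or cds_e in ("", ".", "NA"):
        cds_start, cds_end = start, end          # RNA gene: CDS := gene span
    else:
        cds_start, cds_end = int(cds_s) - 1, int(cds_e)
    return GeneFeature(
        gene_id=row["gene_id"], contig=row["contig"], strand=row["strand"],
        start=start, end=end, cds_start=cds_start, cds_end=cds_end,
        gene_class=row.get("class", "ORF") or "ORF",
    )


def _load_annotation_tsv(path: Path) -> list[GeneFeature]:
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(TSV_COLUMNS[:5]) - set(header)
        if missing:
            raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                features.append(_feature_from_tsv_row(dict(zip(header, fields))))
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable feature line: {exc}") from exc
    return features


def _load_annotation_gff3(path: Path) -> list[GeneFeature]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            contig, _, ftype, start1, end1, _, strand, _, attrs = cols
            if ftype not in ("gene", "CDS", "ncRNA_gene", "rRNA_gene", "tRNA_gene",
                            "snRNA_gene", "snoRNA_gene"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("ID") or attr.get("Parent") or attr.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: feature without ID/Parent attribute")
            gid = gid.split(":")[-1]
            rec = genes.setdefault(gid, {"contig": contig, "strand": strand,
                                         "class": "ORF", "gene": None, "cds": None})
            if ftype == "CDS":
                lo, hi = rec["cds"] or (start, end)
                rec["cds"] = (min(lo, start), max(hi, end))
            else:
                rec["gene"] = (start, end)
                rec["contig"], rec["strand"] = contig, strand
                if ftype != "gene":
                    rec["class"] = "RNA-gene"
    features = []
    for gid, rec in genes.items():
        if rec["gene"] is None:
            rec["gene"] = rec["cds"]
        start, end = rec["gene"]
        cds_start, cds_end = rec["cds"] or (start, end)
        features.append(GeneFeature(gid, rec["contig"], rec["strand"], start, end,
                                    cds_start, cds_end, rec["class"]))
    return features


def load_annotation(path: str | Path, genome: Genome) -> list[GeneFeature]:
    """Load gene features from GFF3 or the simple TSV feature table.

    Features on unknown contigs or extending past a contig end are skipped
    with a warning; unparseable lines raise with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (first.split("\t")[0] not in ("gene_id",)
                                     and len(first.split("\t")) == 9):
        features = _load_annotation_gff3(path)
    else:
        features = _load_annotation_tsv(path)

    kept = []
    for feat in features:
        if feat.contig not in genome:
            logger.warning("skipping %s: unknown contig %r", feat.gene_id, feat.contig)
            continue
        if feat.end > genome.length(feat.contig):
            logger.warning("skipping %s: extends past end of contig %r",
                           feat.gene_id, feat.contig)
            continue
        kept.append(feat)
    return kept


def write_annotation_tsv(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as the 1-based inclusive TSV table (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for f in features:
            fh.write("\t".join(map(str, [
                f.gene_id, f.contig, f.strand, f.start + 1, f.end,
                f.cds_start + 1, f.cds_end, f.gene_class,
            ])) + "\n")


def design_region(gene: GeneFeature, modality: str, genome: Genome,
                  params: RegionParams | None = None) -> DesignRegion:
    """Compute the modality-specific design region for one gene.

    Intervals are clipped to the contig; a gene at a contig edge yields a
    shortened region, never negative coordinates.
    """
    params = params or RegionParams()
    if modality == "activation":
        # Promoter window upstream of the TSS, strand-oriented.
        if gene.strand == "+":
            start, end = gene.tss - params.promoter_span, gene.tss
        else:
            start, end = gene.tss + 1, gene.tss + 1 + params.promoter_span
    elif modality == "interference":
        if gene.strand == "+":
            start, end = gene.start - params.interference_upstream, gene.end
        else:
            start, end = gene.start, gene.end + params.interference_upstream
    elif modality == "deletion":
        start, end = gene.cds_start, gene.cds_end
    else:
        raise ValueError(f"unknown modality {modality!r}")

    start = max(0, start)
    end = min(genome.length(gene.contig), end)
    return DesignRegion(gene.gene_id, modality, gene.contig, start, end, gene.strand)
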