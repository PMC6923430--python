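"""Synthetic genomes, oligo pools and screen read sets with known truth.

Everything downstream of this module is testable without any download: a
toy annotated genome (genes on alternating strands with promoter-sized
intergenic gaps), array-synthesis error models (independent per-base
substitutions, so longer oligos are intact less often), and pooled-screen
reads drawn from a guide-abundance mixture with spiked fitness effects.

Untreated guide abundances follow a symmetric Dirichlet (moderate library
skew); stressed abundances are the untreated ones multiplied by each
guide's true fold and renormalized; replicate libraries are independent
multinomial draws at the configured depth.  Reads embed each guide's 43-bp
barcode between a promoter tail and a terminator head so both extraction
modes of the quantifier apply.  All outputs are fully determined by
(seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneFeature, Genome, write_annotation_tsv
from .oligo_factory import DEFAULT_TEMPLATES
from .screen_quant import BARCODE_LEN, CountTable, barcode_for

BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the simulator (seed is mandatory).

    Defaults emulate the screen setup: biological triplicates of untreated
    vs stressed libraries, ~1e5 reads per library for extraction tests,
    1% per-base oligo synthesis error, moderate Dirichlet skew.
    """

    seed: int
    n_genes: int = 20
    gene_len: tuple[int, int] = (600, 1200)
    intergenic_len: tuple[int, int] = (500, 800)
    gc: float = 0.40
    oligo_error_rate: float = 0.01
    read_depth: int = 100_000
    n_replicates: int = 3
    dirichlet_conc: float = 5.0
    seq_error_rate: float = 0.0
    read_len: int = 100
    spiked_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in (("gc", self.gc), ("oligo_error_rate", self.oligo_error_rate),
                        ("seq_error_rate", self.seq_error_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")
        if self.gene_len[0] > self.gene_len[1] or self.gene_len[0] < 200:
            raise ValueError("infeasible gene length range")
        if self.intergenic_len[0] > self.intergenic_len[1] or self.intergenic_len[0] < 100:
            raise ValueError("infeasible intergenic length range")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def make_toy_genome(config: SimConfig) -> tuple[Genome, list[GeneFeature]]:
    """One-contig genome with ``n_genes`` on alternating strands.

    Each gene span is inset 30 bp from its annotated CDS ends (toy UTRs);
    intergenic gaps are wide enough to hold the default promoter window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    cursor = int(rng.integers(*config.intergenic_len))
    features = []
    for i in range(config.n_genes):
        glen = int(rng.integers(config.gene_len[0], config.gene_len[1] + 1))
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + glen
        features.append(GeneFeature(
            gene_id=f"GENE{i + 1:04d}", contig="chr1", strand=strand,
            start=start, end=end, cds_start=start + 30, cds_end=end - 30,
            gene_class="ORF"))
        cursor = end + int(rng.integers(*config.intergenic_len))
    seq = _random_dna(rng, cursor + 200, config.gc)
    return Genome({"chr1": seq}), features


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.contigs.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_toy_genome(config: SimConfig, fasta_path: str | Path,
                     annotation_path: str | Path) -> tuple[Genome, list[GeneFeature]]:
    genome, features = make_toy_genome(config)
    write_genome_fasta(genome, fasta_path)
    write_annotation_tsv(features, annotation_path)
    return genome, features


def _substitute(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def corrupt_oligos(oligos: Sequence[str], error_rate: float, seed: int) -> list[str]:
    """Independent per-base substitutions (array-synthesis error model)."""
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("synthesis error rate must be in [0, 0.05]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    return [_substitute(o, rng, error_rate) for o in oligos]


def _abundances(manifest: pd.DataFrame, config: SimConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = len(manifest)
    base = rng.dirichlet(np.full(n, config.dirichlet_conc))
    folds = manifest["guide_id"].map(
        lambda g: config.spiked_effects.get(g, 1.0)).to_numpy(float)
    stressed = base * folds
    stressed /= stressed.sum()
    return base, stressed


def simulate_counts(manifest: pd.DataFrame, config: SimConfig
                    ) -> tuple[CountTable, pd.DataFrame]:
    """Count-level screen simulation (no reads): multinomial sampling of the
    untreated/stressed abundance mixtures at the configured depth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    base, stressed = _abundances(manifest, config, rng)
    cols, data = [], []
    for i in range(1, config.n_replicates + 1):
        cols.append(f"untreated_{i}")
        data.append(rng.multinomial(config.read_depth, base))
    for i in range(1, config.n_replicates + 1):
        cols.append(f"stressed_{i}")
        data.append(rng.multinomial(config.read_depth, stressed))
    counts = pd.DataFrame(np.column_stack(data),
                          index=pd.Index(manifest.guide_id, name="guide_id"),
                          columns=cols)
    stats = pd.DataFrame({c: {"total": config.read_depth,
                              "extracted": config.read_depth,
                              "mapped": config.read_depth, "unmapped": 0}
                          for c in cols})
    truth = pd.DataFrame(
        {"guide_id": list(config.spiked_effects),
         "true_fold": [config.spiked_effects[g] for g in config.spiked_effects]})
    return CountTable(counts=counts, stats=stats), truth


def _read_for_barcode(barcode: str, templates: dict, read_len: int,
                      anchor_len: int = 15) -> str:
    left = templates["snr52p"][-anchor_len:]
    right = templates["sup4t"]
    read = left + barcode + right
    if len(read) < read_len:
        read += "A" * (read_len - len(read))
    return read[:read_len]


def simulate_screen(manifest: pd.DataFrame, config: SimConfig,
                    outdir: str | Path,
                    templates: dict = DEFAULT_TEMPLATES) -> dict:
    """Read-level screen simulation: six FASTQ files plus a truth table.

    Returns {"fastqs": {library: path}, "truth": path, "counts": CountTable}
    where the CountTable holds the true per-guide read counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(manifest) > config.read_depth:
        import warnings
        warnings.warn("read depth below library size: expect guide dropout",
                      stacklevel=2)
    table, truth = simulate_counts(manifest, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    barcodes = [barcode_for(s, lib, templates, BARCODE_LEN)
                for s, lib in zip(manifest.protospacer, manifest.library)]

    fastqs = {}
    qual = "I" * config.read_len
    for lib_id in table.libraries:
        path = outdir / f"{lib_id}.fastq"
        counts = table.counts[lib_id].to_numpy()
        with open(path, "w") as fh:
            serial = 0
            for bc, n in zip(barcodes, counts):
                template = _read_for_barcode(bc, templates, config.read_len)
                for _ in range(int(n)):
                    serial += 1
                    read = _substitute(template, rng, config.seq_error_rate)
                    fh.write(f"@{lib_id}:{serial}\n{read}\n+\n{qual}\n")
        fastqs[lib_id] = str(path)

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"fastqs": fastqs, "truth": str(truth_path), "counts": table}
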