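"""Barcode extraction, matching and counting for pooled-screen FASTQs.

Each library member is identified by a 43-bp barcode lying between the
promoter and terminator of its expression cassette: the spacer followed by
as much of the library-specific scaffold as fills the window.  Because the
three scaffolds differ, one index distinguishes the activation,
interference and deletion libraries in a single pooled sample.

Matching is exact hash lookup by default (43-bp barcodes against ~1e5
references need no gapped alignment), with optional Hamming-distance rescue
(unique best hit within budget; ambiguity leaves a read unmapped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

from .oligo_factory import DEFAULT_TEMPLATES

logger = logging.getLogger(__name__)

BARCODE_LEN = 43


@dataclass
class ReadLayout:
    """Where the barcode sits in a read.

    ``fixed-column`` slices ``var_len`` bases at ``offset``; ``anchor-search``
    takes the sequence strictly between the first occurrence of the left
    anchor (3' end of the promoter) and the first subsequent occurrence of
    the right anchor (5' start of the terminator).
    """

    left_anchor: str
    right_anchor: str
    var_len: int = BARCODE_LEN
    mode: str = "fixed-column"  # or "anchor-search"
    offset: int = 0

    def __post_init__(self) -> None:
        if self.var_len <= 0:
            raise ValueError("expected variable length must be positive")
        if self.mode not in ("fixed-column", "anchor-search"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")
        if self.mode == "anchor-search" and not (self.left_anchor and self.right_anchor):
            raise ValueError("anchor-search mode requires both anchors")


def default_layout(templates: dict = DEFAULT_TEMPLATES, anchor_len: int = 15,
                   mode: str = "fixed-column") -> ReadLayout:
    """Layout matching the simulated read geometry: promoter tail, barcode,
    terminator head."""
    return ReadLayout(left_anchor=templates["snr52p"][-anchor_len:],
                      right_anchor=templates["sup4t"][:anchor_len],
                      mode=mode, offset=anchor_len)


def barcode_for(spacer: str, library: str,
                templates: dict = DEFAULT_TEMPLATES,
                var_len: int = BARCODE_LEN) -> str:
    """Spacer + library scaffold prefix, padded/truncated to the window."""
    bc = (spacer + templates["scaffolds"][library])[:var_len]
    if len(bc) < var_len:
        bc = (bc + templates["sup4t"])[:var_len]
    return bc


class BarcodeCollisionError(ValueError):
    def __init__(self, barcode: str, first: str, second: str):
        super().__init__(
            f"barcode collision: {first!r} and {second!r} share {barcode!r}")
        self.pair = (first, second)


@dataclass
class GuideIndex:
    """barcode -> guide-id map over all libraries; collisions abort."""

    lookup: dict[str, str]
    guide_library: dict[str, str]
    guide_gene: dict[str, str]
    var_len: int = BARCODE_LEN

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame,
                      templates: dict = DEFAULT_TEMPLATES,
                      var_len: int = BARCODE_LEN) -> "GuideIndex":
        """Build from a library manifest (guide_id, library, protospacer,
        gene_id columns)."""
        lookup: dict[str, str] = {}
        for row in manifest.itertuples():
            bc = barcode_for(row.protospacer, row.library, templates, var_len)
            if bc in lookup:
                raise BarcodeCollisionError(bc, lookup[bc], row.guide_id)
            lookup[bc] = row.guide_id
        return cls(lookup=lookup,
                   guide_library=dict(zip(manifest.guide_id, manifest.library)),
                   guide_gene=dict(zip(manifest.guide_id, manifest.gene_id)),
                   var_len=var_len)

    def __len__(self) -> int:
        return len(self.lookup)


def extract_barcode(seq: str, layout: ReadLayout) -> str | None:
    """Pull the barcode out of one read, or None (tallied as unextracted)."""
    seq = seq.upper()
    if layout.mode == "fixed-column":
        if len(seq) < layout.offset + layout.var_len:
            return None
        return seq[layout.offset:layout.offset + layout.var_len]
    lpos = seq.find(layout.left_anchor)
    if lpos < 0:
        return None
    start = lpos + len(layout.left_anchor)
    rpos = seq.find(layout.right_anchor, start)
    if rpos < 0:
        return None
    bc = seq[start:rpos]
    return bc if len(bc) == layout.var_len else None


def _neighbours(barcode: str, distance: int) -> Iterator[str]:
    """All sequences within exactly `distance` substitutions of `barcode`."""
    for positions in combinations(range(len(barcode)), distance):
        alts = [[b for b in "ACGT" if b != barcode[p]] for p in positions]
        for combo in product(*alts):
            chars = list(barcode)
            for p, b in zip(positions, combo):
                chars[p] = b
            yield "".join(chars)


def match_barcode(barcode: str, index: GuideIndex, max_mismatch: int = 0
                  ) -> str | None:
    """Assign a barcode to a guide: exact lookup, then (optionally) a unique
    best hit within the mismatch budget; ambiguity -> unmapped (None)."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    hit = index.lookup.get(barcode)
    if hit is not None or max_mismatch == 0:
        return hit
    for d in range(1, max_mismatch + 1):
        hits = {index.lookup[nb] for nb in _neighbours(barcode, d)
                if nb in index.lookup}
        if len(hits) == 1:
            return hits.pop()
        if hits:  # ambiguous at the best distance
            return None
    return None


@dataclass
class CountTable:
    """Per-guide raw counts across sequencing libraries, plus read tallies."""

    counts: pd.DataFrame                       # guides x libraries, int
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # stats rows: total, extracted, mapped, unmapped per library column

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        import json

        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            if not self.stats.empty:
                fh.write(f"# stats: {json.dumps(self.stats.to_dict())}\n")
            self.counts.rename_axis("guide_id").reset_index().to_csv(
                fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        import json

        stats = pd.DataFrame()
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# stats: "):
                    stats = pd.DataFrame(json.loads(line[len("# stats: "):]))
        df = pd.read_csv(path, sep="\t", comment="#").set_index("guide_id")
        return cls(counts=df.astype(int), stats=stats)


def _iter_reads(path: str | Path) -> Iterator[str]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.sequence


def count_screen(fastqs: Mapping[str, str | Path], index: GuideIndex,
                 layout: ReadLayout, max_mismatch: int = 0,
                 try_revcomp: bool = False) -> CountTable:
    """Count reads per designed guide in each sequencing library.

    Unmapped reads are discarded but tallied; an empty FASTQ yields a zero
    column with a warning.
    """
    from ._seq import revcomp

    guide_ids = list(index.guide_library)
    pos = {g: i for i, g in enumerate(guide_ids)}
    counts = np.zeros((len(guide_ids), len(fastqs)), dtype=np.int64)
    stats = {}
    for col, (lib_id, path) in enumerate(fastqs.items()):
        total = extracted = mapped = 0
        for seq in _iter_reads(path):
            total += 1
            bc = extract_barcode(seq, layout)
            if bc is None and try_revcomp:
                bc = extract_barcode(revcomp(seq), layout)
            if bc is None:
                continue
            extracted += 1
            guide = match_barcode(bc, index, max_mismatch)
            if guide is None:
                continue
            mapped += 1
            counts[pos[guide], col] += 1
        if total == 0:
            logger.warning("FASTQ for library %r is empty", lib_id)
        stats[lib_id] = {"total": total, "extracted": extracted,
                         "mapped": mapped, "unmapped": extracted - mapped}
    return CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"),
                            columns=list(fastqs)),
        stats=pd.DataFrame(stats))


def count_sequences(reads_by_library: Mapping[str, Iterable[str]],
                    index: GuideIndex, layout: ReadLayout,
                    max_mismatch: int = 0) -> CountTable:
    """As :func:`count_screen` but over in-memory read sequences."""
    guide_ids = list(index.guide_library)
    pos = {g: i for i, g in enumerate(guide_ids)}
    counts = np.zeros((len(guide_ids), len(reads_by_library)), dtype=np.int64)
    stats = {}
    for col, (lib_id, reads) in enumerate(reads_by_library.items()):
        total = extracted = mapped = 0
        for seq in reads:
            total += 1
            bc = extract_barcode(seq, layout)
            if bc is None:
                continue
            extracted += 1
            guide = match_barcode(bc, index, max_mismatch)
            if guide is None:
                continue
            mapped += 1
            counts[pos[guide], col] += 1
        stats[lib_id] = {"total": total, "extracted": extracted,
                         "mapped": mapped, "unmapped": extracted - mapped}
    return CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"),
                            columns=list(reads_by_library)),
        stats=pd.DataFrame(stats))


def find_barcodes(sequence: str, index: GuideIndex) -> list[str]:
    """All designed barcodes embedded in a longer sequence (e.g. an assembled
    cassette or double-cassette plasmid), in positional order."""
    seq, k = sequence.upper(), index.var_len
    hits = []
    for i in range(len(seq) - k + 1):
        guide = index.lookup.get(seq[i:i + k])
        if guide is not None:
            hits.append(guide)
    return hits


def qc_metrics(table: CountTable, manifest: pd.DataFrame,
               clones: Mapping[str, float] | None = None) -> dict:
    """Library QC: mapping ratio per sequencing library; guide / gene
    coverage per designed library; fold coverage given clone counts.

    * mapping ratio = mapped / extracted reads (None when nothing extracted);
    * guide coverage = fraction of designed guides seen with >= 1 read
      (summed over sequencing libraries);
    * gene coverage = fraction of genes with >= 1 covered guide (controls
      excluded);
    * fold coverage = clones / number of designed guides.
    """
    report: dict = {"mapping_ratio": {}, "per_library": {}}
    for lib_id in table.libraries:
        if table.stats.empty or lib_id not in table.stats.columns:
            report["mapping_ratio"][lib_id] = None
            continue
        col = table.stats[lib_id]
        report["mapping_ratio"][lib_id] = (
            None if col["extracted"] == 0 else col["mapped"] / col["extracted"])

    seen = table.counts.sum(axis=1)
    for design_lib, sub in manifest.groupby("library"):
        covered = seen.reindex(sub.guide_id).fillna(0) > 0
        entry = {"n_guides": len(sub),
                 "grna_coverage": float(covered.mean()) if len(sub) else None}
        is_ctrl = (sub["is_control"].astype(bool) if "is_control" in sub
                   else pd.Series(False, index=sub.index))
        genes = sub.loc[~is_ctrl]
        if len(genes):
            by_gene = pd.DataFrame({"gene": genes.gene_id.to_numpy(),
                                    "covered": covered.loc[genes.guide_id].to_numpy()})
            entry["gene_coverage"] = float(by_gene.groupby("gene").covered.any().mean())
        else:
            entry["gene_coverage"] = None
        if clones and design_lib in clones:
            entry["fold_coverage"] = clones[design_lib] / len(sub)
        report["per_library"][design_lib] = entry
    return report


def combined_index_size(library_sizes: Iterable[int]) -> int:
    """Size of the single matching index spanning all designed libraries."""
    return int(sum(library_sizes))
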