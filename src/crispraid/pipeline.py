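"""End-to-end library design: genome + annotation -> manifest + oligo pool.

Thin orchestration over :mod:`genome_model`, :mod:`guide_design` and
:mod:`oligo_factory`: per gene and modality it derives the design region,
enumerates and hard-filters candidates, vets that each candidate yields a
buildable, assembly-clean oligo (for deletion guides this includes the HDR
donor), scores, de-clusters, selects the top 6/6/4, and appends the
non-targeting controls for each library.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import guide_design as gd
from . import oligo_factory as of
from .genome_model import GeneFeature, Genome, RegionParams, design_region

MANIFEST_COLUMNS = [
    "guide_id", "gene_id", "modality", "library", "cas", "contig", "position",
    "strand", "protospacer", "pam", "efficiency", "position_score", "gc_score",
    "off_target", "composite", "rank", "is_control",
]


@dataclass
class DesignConfig:
    """Every tunable of the design stage, with the shipped defaults."""

    seed: int = 0
    region_params: RegionParams = field(default_factory=RegionParams)
    rules: gd.FilterRules = field(default_factory=gd.FilterRules)
    weights: gd.ScoreWeights = field(default_factory=gd.ScoreWeights)
    min_separation: int = 30
    max_mismatch: int = 3
    controls_per_library: int = 100
    arm_len: int = 50
    guides_per_gene: dict[str, int] = field(
        default_factory=lambda: dict(gd.GUIDES_PER_GENE))


@dataclass
class DesignResult:
    manifest: pd.DataFrame
    oligos: list[of.OligoRecord]
    donors: dict[str, of.DonorDesign]
    report: dict

    def write_manifest(self, path: str | Path,
                       header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.manifest.to_csv(fh, sep="\t", index=False)

    def write_oligos_tsv(self, path: str | Path) -> None:
        rows = [{"oligo_id": o.guide_id, "library": o.library,
                 "sequence": o.sequence,
                 "segments": ";".join(f"{k}:{lo}-{hi}"
                                      for k, (lo, hi) in o.segments.items())}
                for o in self.oligos]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def write_oligos_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for o in self.oligos:
                fh.write(f">{o.guide_id} {o.library}\n{o.sequence}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "is_control" in df:
        df["is_control"] = df["is_control"].astype(bool)
    return df


def _vet_candidate(cand: gd.CandidateGuide, genome: Genome, library: str,
                   adapters: of.AdapterSet, arm_len: int
                   ) -> of.DonorDesign | None | bool:
    """Check the candidate produces a clean oligo; returns the donor for
    deletion guides, None for others, False when unbuildable."""
    donor = None
    if library == "LibD":
        try:
            donor = of.build_deletion_donor(cand, genome, arm_len)
        except ValueError:
            return False
    try:
        of.build_oligo(cand, "vet", donor, adapters)
    except (of.AssemblyError, ValueError):
        return False
    return donor


def design_library(genome: Genome, features: list[GeneFeature],
                   config: DesignConfig | None = None) -> DesignResult:
    config = config or DesignConfig()
    rows: list[dict] = []
    oligos: list[of.OligoRecord] = []
    donors: dict[str, of.DonorDesign] = {}
    report: dict = {"per_modality_totals": {}, "shortfalls": {}, "skipped": []}

    for modality, cas in gd.CAS_BY_MODALITY.items():
        library = gd.LIBRARY_BY_MODALITY[modality]
        adapters = of.default_adapters(library)
        backbone_scaffold_ok = of.default_backbone(library)  # validates template
        assert backbone_scaffold_ok.library == library
        index = gd.PamSiteIndex(genome, cas)
        tag = modality[0]
        total = 0
        # each library holds unique guide sequences: a genomic site shared by
        # two genes (e.g. divergent promoters) is assigned to the first gene
        used_spacers: set[str] = set()
        for gene in features:
            try:
                region = design_region(gene, modality, genome, config.region_params)
            except ValueError:
                report["skipped"].append((gene.gene_id, modality, "no design region"))
                continue
            cands = gd.enumerate_candidates(region, genome, cas, tss=gene.tss)
            cands = [c for c in cands if gd.hard_filter(c, config.rules)[0]
                     and c.protospacer not in used_spacers]
            vetted = []
            for cand in cands:
                donor = _vet_candidate(cand, genome, library, adapters,
                                       config.arm_len)
                if donor is False:
                    continue
                vetted.append((cand, donor))
            scored = [gd.score_guide(c, gene, genome, cas, config.weights,
                                     config.max_mismatch, index)
                      for c, _ in vetted]
            donor_by_cand = {id(sg.candidate): d
                             for sg, (_, d) in zip(scored, vetted)}
            kept = gd.cluster_dedup(scored, config.min_separation)
            selected, shortfall = gd.select_top(kept, modality,
                                                config.guides_per_gene)
            if shortfall:
                report["shortfalls"].setdefault(modality, []).append(gene.gene_id)
            for k, sg in enumerate(selected, start=1):
                guide_id = f"{gene.gene_id}_{tag}{k}"
                donor = donor_by_cand[id(sg.candidate)]
                oligos.append(of.build_oligo(sg, guide_id, donor, adapters))
                if donor is not None:
                    donors[guide_id] = donor
                rows.append(_manifest_row(guide_id, sg, gene.gene_id, modality,
                                          library, cas))
                used_spacers.add(sg.candidate.protospacer)
                total += 1
        # non-targeting controls for this library
        lib_offset = {"LibA": 1, "LibI": 2, "LibD": 3}[library]
        stuffer_rng = random.Random(config.seed * 31 + len(library))
        # over-sample candidates: a random spacer can still create a BsaI
        # site at an adapter junction, which disqualifies its oligo
        pool = gd.make_controls(config.controls_per_library + 25, genome, cas,
                                seed=config.seed * 7919 + lib_offset,
                                rules=config.rules)
        kept_controls: list[tuple[str, gd.CandidateGuide,
                                  of.DonorDesign | None, of.OligoRecord]] = []
        for spacer in pool:
            if len(kept_controls) == config.controls_per_library:
                break
            guide_id = f"ctrl_{library}_{len(kept_controls) + 1:03d}"
            cand = gd.CandidateGuide("control", modality, "", spacer, "", "+",
                                     0, len(spacer))
            donor = None
            if library == "LibD":
                # synthetic non-genomic stuffer arms keep all LibD oligos equal
                # length; controls have no genomic target to repair
                donor = of.DonorDesign(
                    gene_id=guide_id, contig="", deleted_start=0,
                    deleted_end=cas.spacer_len + len(cas.pam),
                    upstream_arm=of._bsai_free_random(stuffer_rng, config.arm_len),
                    downstream_arm=of._bsai_free_random(stuffer_rng, config.arm_len))
            try:
                oligo = of.build_oligo(cand, guide_id, donor, adapters)
            except of.AssemblyError:
                continue
            kept_controls.append((guide_id, cand, donor, oligo))
        if len(kept_controls) < config.controls_per_library:
            raise RuntimeError(
                f"{library}: could not build {config.controls_per_library} "
                f"assembly-clean controls")
        controls = [spacer for _, c, _, _ in kept_controls
                    for spacer in [c.protospacer]]
        for guide_id, cand, donor, oligo in kept_controls:
            spacer = cand.protospacer
            oligos.append(oligo)
            rows.append({
                "guide_id": guide_id, "gene_id": "control", "modality": modality,
                "library": library, "cas": cas.name, "contig": "", "position": -1,
                "strand": ".", "protospacer": spacer, "pam": "",
                "efficiency": float("nan"), "position_score": float("nan"),
                "gc_score": float("nan"), "off_target": float("nan"),
                "composite": float("nan"), "rank": 0, "is_control": True,
            })
        report["per_modality_totals"][modality] = {
            "targeting": total, "controls": len(controls)}

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return DesignResult(manifest=manifest, oligos=oligos, donors=donors,
                        report=report)


def _manifest_row(guide_id: str, sg: gd.ScoredGuide, gene_id: str, modality: str,
                  library: str, cas: gd.CasSpec) -> dict:
    c = sg.candidate
    return {
        "guide_id": guide_id, "gene_id": gene_id, "modality": modality,
        "library": library, "cas": cas.name, "contig": c.contig,
        "position": c.position, "strand": c.strand, "protospacer": c.protospacer,
        "pam": c.pam, "efficiency": sg.efficiency,
        "position_score": sg.position_score, "gc_score": sg.gc_score,
        "off_target": sg.off_target, "composite": sg.composite, "rank": sg.rank,
        "is_control": False,
    }
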