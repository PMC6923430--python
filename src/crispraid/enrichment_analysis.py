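"""Normalization, hit filtering and fold-enrichment ranking.

The screen compares triplicate stressed libraries against triplicate
untreated ones.  Per-guide read counts are normalized to the total mapped
reads of their library; a guide is a hit when it has at least one raw read
in every library (read floor) and at least five-fold enrichment
(normalized stressed / normalized untreated) in every replicate pair.  Hits
are ranked by the arithmetic mean fold over replicates — no p-values, the
screen ranks by fold only.  No pseudocounts are added: the read floor
guarantees positive denominators for every reported fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

Pairing = Sequence[tuple[str, str]]  # (untreated_library, stressed_library) pairs


@dataclass
class FilterConfig:
    """Hit-calling thresholds.

    read_floor: minimum raw reads required in every library (default 1).
    fold_floor: minimum per-replicate fold enrichment (default 5).
    pairing: replicate pairing untreated_i <-> stressed_i.
    """

    pairing: Pairing = field(default_factory=tuple)
    read_floor: int = 1
    fold_floor: float = 5.0
    geometric_mean: bool = False

    def __post_init__(self) -> None:
        if self.read_floor <= 0 or self.fold_floor <= 0:
            raise ValueError("floors must be positive")
        flat = [lib for pair in self.pairing for lib in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("replicate pairing must be a bijection")


def default_pairing(n_replicates: int = 3) -> Pairing:
    return tuple((f"untreated_{i}", f"stressed_{i}")
                 for i in range(1, n_replicates + 1))


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library fractional abundance: raw / library total."""
    totals = counts.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"library {empty.index[0]!r} has zero total reads")
    return counts / totals


def fold_enrichment(norm: pd.DataFrame, pairing: Pairing) -> pd.DataFrame:
    """Per-replicate folds (stressed_i / untreated_i) and their mean.

    Returns columns fold_1..fold_k and mean_fold.  Zero-abundance untreated
    entries yield inf/nan folds; the read floor filter is what makes
    reported folds well defined.
    """
    if not pairing:
        raise ValueError("empty replicate pairing")
    missing = [lib for pair in pairing for lib in pair if lib not in norm.columns]
    if missing:
        raise ValueError(f"missing replicate libraries: {missing}")
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (unt, stress) in enumerate(pairing, start=1):
            out[f"fold_{i}"] = norm[stress].to_numpy() / norm[unt].to_numpy()
    folds = pd.DataFrame(out, index=norm.index)
    folds["mean_fold"] = folds.mean(axis=1)
    return folds


def filter_hits(counts: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Apply the read floor and the per-replicate fold floor.

    Returns a frame with the normalized abundances, folds, mean fold and the
    two pass flags; ``is_hit`` is their conjunction.
    """
    libs = [lib for pair in config.pairing for lib in pair]
    norm = normalize(counts[libs])
    folds = fold_enrichment(norm, config.pairing)
    read_ok = (counts[libs] >= config.read_floor).all(axis=1)
    fold_cols = [c for c in folds.columns if c.startswith("fold_")]
    fold_ok = (folds[fold_cols] >= config.fold_floor).all(axis=1)
    if config.geometric_mean:
        with np.errstate(divide="ignore"):
            folds["mean_fold"] = np.exp(np.log(folds[fold_cols]).mean(axis=1))
    out = pd.concat([norm.add_prefix("norm_"), folds], axis=1)
    out["passes_read_floor"] = read_ok
    out["passes_fold_floor"] = fold_ok
    out["is_hit"] = read_ok & fold_ok
    return out


def enrichment_table(counts: pd.DataFrame, manifest: pd.DataFrame,
                     config: FilterConfig) -> pd.DataFrame:
    """Full per-guide enrichment report joined with guide annotation."""
    records = filter_hits(counts, config)
    anno = manifest.set_index("guide_id")[
        [c for c in ("gene_id", "modality", "library", "is_control")
         if c in manifest.columns]]
    return anno.join(records, how="right")


def rank_hits(records: pd.DataFrame, per_gene: bool = False) -> pd.DataFrame:
    """Order hits by descending mean fold (ties by guide id).

    With ``per_gene`` the report collapses to each gene's best guide plus a
    count of supporting hit guides.
    """
    hits = records.loc[records["is_hit"]].copy()
    hits = hits.sort_index(kind="stable")
    hits = hits.sort_values("mean_fold", ascending=False, kind="stable")
    if not per_gene:
        hits.insert(0, "rank", np.arange(1, len(hits) + 1))
        return hits
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "best_guide", "mean_fold",
                                     "n_supporting_guides"])
    grouped = []
    for gene, sub in hits.groupby("gene_id", sort=False):
        best = sub.iloc[0]
        grouped.append({"gene_id": gene, "best_guide": sub.index[0],
                        "modality": best.get("modality"),
                        "mean_fold": best["mean_fold"],
                        "n_supporting_guides": len(sub)})
    out = pd.DataFrame(grouped).sort_values(
        ["mean_fold", "gene_id"], ascending=[False, True], kind="stable")
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.reset_index(drop=True)
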