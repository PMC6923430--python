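"""Double-guide combination spaces and library coverage.

When two expression cassettes are assembled into one vector, the pair space
over N single guides is N^2 (the two cassette positions are distinct, so
pairs are ordered by default).  Transformation efficiency caps how much of
that space a physical library samples: with ~1e5 singles the ordered space
is ~1e10, and 1e6-1e7 transformants cover only 0.01-0.1% of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pair_space(n_a: int, n_i: int, n_d: int, mode: str = "ordered") -> int:
    """Number of guide pairs over the pooled singles N = nA + nI + nD."""
    if min(n_a, n_i, n_d) < 0:
        raise ValueError("library sizes must be non-negative")
    n = n_a + n_i + n_d
    if mode == "ordered":
        return n * n
    if mode == "unordered":
        return n * (n + 1) // 2  # unordered with replacement
    raise ValueError(f"mode must be ordered/unordered, got {mode!r}")


def coverage(transformants: float, space: int) -> float:
    """Fraction of the pair space sampled, clipped to 1."""
    if space <= 0:
        raise ValueError("pair space must be positive")
    if transformants < 0:
        raise ValueError("transformant count must be non-negative")
    return min(transformants / space, 1.0)


def sample_library(manifest: pd.DataFrame, transformants: int, seed: int
                   ) -> pd.DataFrame:
    """Uniform sampling with replacement of ordered guide pairs.

    Emulates transforming a double-cassette plasmid pool: each transformant
    carries one ordered (position-1, position-2) pair.  Deterministic under
    ``seed``.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(seed)
    guides = manifest["guide_id"].to_numpy()
    idx = rng.integers(0, len(guides), size=(int(transformants), 2))
    return pd.DataFrame({"guide_1": guides[idx[:, 0]], "guide_2": guides[idx[:, 1]]})


def expected_distinct_fraction(transformants: float, space: int) -> float:
    """Occupancy closed form: E[distinct pairs]/space = 1 - exp(-t/space)."""
    if space <= 0:
        raise ValueError("pair space must be positive")
    return float(1.0 - np.exp(-transformants / space))


def space_report(n_a: int, n_i: int, n_d: int,
                 transformants: list[float] | None = None) -> dict:
    """JSON-ready summary of spaces and coverages."""
    ordered = pair_space(n_a, n_i, n_d, "ordered")
    unordered = pair_space(n_a, n_i, n_d, "unordered")
    report = {
        "singles": {"LibA": n_a, "LibI": n_i, "LibD": n_d,
                    "total": n_a + n_i + n_d},
        "pair_space": {"ordered": ordered, "unordered": unordered},
        "coverage": {},
    }
    for t in transformants or []:
        report["coverage"][f"{t:g}"] = {
            "fraction": coverage(t, ordered),
            "percent": 100.0 * coverage(t, ordered),
            "expected_distinct_fraction": expected_distinct_fraction(t, ordered),
        }
    return report
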