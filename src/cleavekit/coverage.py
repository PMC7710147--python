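"""Coverage masks, multi-enzyme merging, and phosphosite comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-12  # pooled-variance guard for degenerate groups


class CoverageError(ValueError):
    pass


@dataclass
class CoverageMask:
    protein_id: str
    covered: np.ndarray  # boolean, one element per residue

    def __post_init__(self) -> None:
        self.covered = np.asarray(self.covered, dtype=bool)

    @property
    def length(self) -> int:
        return int(self.covered.size)

    @property
    def n_covered(self) -> int:
        return int(self.covered.sum())

    @classmethod
    def empty(cls, protein_id: str, length: int) -> "CoverageMask":
        return cls(protein_id, np.zeros(length, dtype=bool))


@dataclass(frozen=True)
class PhosphoSite:
    protein_id: str
    position: int
    residue: str
    localization_probability: float
    enzyme: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in "STY":
            raise CoverageError(
                f"phosphosite residue must be S/T/Y, got {self.residue!r}"
            )
        if not 0.0 <= self.localization_probability <= 1.0:
            raise CoverageError("localization probability outside [0,1]")


def coverage_mask(record, peptides) -> CoverageMask:
    """Mark every residue within at least one peptide span.

    Peptides may carry 1-based ``start``/``end`` coordinates; otherwise all
    exact sequence matches in the record are covered.
    """
    mask = np.zeros(len(record.sequence), dtype=bool)
    if isinstance(peptides, pd.DataFrame):
        rows = peptides.to_dict("records")
    else:
        rows = [
            {
                "sequence": getattr(p, "sequence", p),
                "start": getattr(p, "start", None),
                "end": getattr(p, "end", None),
                "protein_id": getattr(p, "protein_id", None),
            }
            for p in peptides
        ]
    for row in rows:
        pid = row.get("protein_id")
        if pid is not None and not pd.isna(pid) and pid != record.id:
            continue
        start, end = row.get("start"), row.get("end")
        if start is not None and end is not None and not (
            pd.isna(start) or pd.isna(end)
        ):
            mask[int(start) - 1 : int(end)] = True
            continue
        seq = row["sequence"]
        pos = record.sequence.find(seq)
        while pos >= 0:
            mask[pos : pos + len(seq)] = True
            pos = record.sequence.find(seq, pos + 1)
    return CoverageMask(record.id, mask)


def merge_masks(masks) -> CoverageMask:
    """Element-wise OR of same-protein masks (commutative, idempotent)."""
    masks = list(masks)
    if not masks:
        raise CoverageError("no masks to merge")
    lengths = {m.length for m in masks}
    if len(lengths) != 1:
        raise CoverageError(f"mask lengths differ: {sorted(lengths)}")
    merged = np.zeros(masks[0].length, dtype=bool)
    for m in masks:
        merged |= m.covered
    return CoverageMask(masks[0].protein_id, merged)


def percent_coverage(mask: CoverageMask, ndigits: int = 0) -> float:
    """100 × covered/length, rounded half-up to ``ndigits``."""
    if mask.length == 0:
        raise CoverageError("empty mask")
    pct = 100.0 * mask.n_covered / mask.length
    factor = 10**ndigits
    rounded = math.floor(pct * factor + 0.5) / factor
    return int(rounded) if ndigits <= 0 else rounded


def complementarity(per_label_items: dict) -> dict[tuple, int]:
    """Exclusive/shared counts over any number of labelled item sets.

    Keys of the result are sorted label tuples; the value counts items
    found in exactly that set of labels.
    """
    sets = {label: set(items) for label, items in per_label_items.items()}
    labels = sorted(sets)
    out: dict[tuple, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                *(sets[o] for o in labels if o not in combo), set()
            )
            out[combo] = len(inside - outside)
    return out


def diagnostic_position_coverage(mask: CoverageMask, positions) -> float:
    """Fraction of the listed 1-based positions that are covered."""
    positions = list(positions)
    if not positions:
        raise CoverageError("empty diagnostic position list")
    for pos in positions:
        if not 1 <= pos <= mask.length:
            raise CoverageError(f"position {pos} outside [1, {mask.length}]")
    return float(
        sum(1 for pos in positions if mask.covered[pos - 1]) / len(positions)
    )


def filter_class1(sites, threshold: float = 0.75):
    """Sites with localization probability >= threshold (inclusive)."""
    def loc(site):
        if isinstance(site, dict):
            return site["localization_probability"]
        return site.localization_probability

    if isinstance(sites, pd.DataFrame):
        return sites[sites["localization_probability"] >= threshold]
    return [s for s in sites if loc(s) >= threshold]


def compare_localization(sites_a, sites_b):
    """One-tailed two-sample pooled-variance t test (mean_a > mean_b).

    Returns a dict with group means, t, degrees of freedom and the
    one-tailed p value. Zero pooled variance is guarded by an epsilon.
    """
    def values(sites):
        if isinstance(sites, pd.DataFrame):
            return sites["localization_probability"].to_numpy(dtype=float)
        return np.array(
            [
                s["localization_probability"]
                if isinstance(s, dict)
                else s.localization_probability
                for s in sites
            ],
            dtype=float,
        )

    a, b = values(sites_a), values(sites_b)
    if a.size < 2 or b.size < 2:
        raise CoverageError("each group needs at least 2 sites")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    pooled = max(pooled, _EPS)
    t = (a.mean() - b.mean()) / math.sqrt(pooled * (1 / na + 1 / nb))
    p = float(stats.t.sf(t, df))
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": int(na),
        "n_b": int(nb),
        "t": float(t),
        "df": int(df),
        "p_value": p,
    }


def mask_to_dict(mask: CoverageMask) -> dict:
    return {
        "protein_id": mask.protein_id,
        "length": mask.length,
        "covered_positions": [
            int(i + 1) for i in np.flatnonzero(mask.covered)
        ],
    }
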