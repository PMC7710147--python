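"""Database-independent assembly of de novo peptide reads.

Filter by score, deduplicate, merge per-enzyme sets combinatorially, align
each peptide to a reference at the position minimizing mismatches (with
optional I/L equivalence), and report coverage per enzyme combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .coverage import CoverageMask


class DenovoError(ValueError):
    pass


@dataclass(frozen=True)
class DenovoPeptide:
    sequence: str
    score: float
    enzyme: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise DenovoError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class Placement:
    sequence: str
    start: int  # 1-based
    mismatches: int
    il_equivalent: bool


def _to_peptides(items) -> list[DenovoPeptide]:
    if isinstance(items, pd.DataFrame):
        return [
            DenovoPeptide(
                row["sequence"], float(row["score"]), row.get("enzyme")
            )
            for row in items.to_dict("records")
        ]
    return [
        p if isinstance(p, DenovoPeptide) else DenovoPeptide(*p)
        for p in items
    ]


def filter_denovo(peptides, min_score: float = 90.0) -> list[DenovoPeptide]:
    """Keep score >= min_score (inclusive); deduplicate keeping the max score."""
    best: dict[str, DenovoPeptide] = {}
    for pep in _to_peptides(peptides):
        if pep.score < min_score:
            continue
        prev = best.get(pep.sequence)
        if prev is None or pep.score > prev.score:
            best[pep.sequence] = pep
    return [best[s] for s in sorted(best)]


def merge_enzyme_sets(per_label, combination) -> list[DenovoPeptide]:
    """Union with dedup of the listed labels' peptide sets."""
    pooled: list[DenovoPeptide] = []
    for label in combination:
        if label not in per_label:
            raise DenovoError(f"unknown enzyme label {label!r}")
        pooled.extend(_to_peptides(per_label[label]))
    return filter_denovo(pooled, min_score=0.0)


def all_combinations(labels):
    """All non-empty label subsets, sorted by size then lexicographically."""
    labels = sorted(labels)
    out = []
    for r in range(1, len(labels) + 1):
        out.extend(combinations(labels, r))
    return out


_IL_FOLD = str.maketrans("L", "I")


def _encode(seq: str, il_equivalent: bool) -> np.ndarray:
    if il_equivalent:
        seq = seq.translate(_IL_FOLD)
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_to_reference(
    peptides,
    reference: str,
    max_mismatch: int = 0,
    il_equivalent: bool = True,
):
    """Place each peptide at the reference offset minimizing mismatches.

    Ties break to the smallest start. Peptides whose best placement exceeds
    ``max_mismatch`` (or that are longer than the reference) are reported
    as unplaced. Returns ``(placements, mask, unplaced)``.
    """
    if not reference:
        raise DenovoError("empty reference")
    ref = _encode(reference, il_equivalent)
    n = ref.size
    mask = np.zeros(n, dtype=bool)
    placements: list[Placement] = []
    unplaced: list[DenovoPeptide] = []
    for pep in _to_peptides(peptides):
        query = _encode(pep.sequence, il_equivalent)
        m = query.size
        if m > n:
            unplaced.append(pep)
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, m)
        mismatches = (windows != query).sum(axis=1)
        best = int(mismatches.argmin())  # argmin takes the smallest index
        if mismatches[best] > max_mismatch:
            unplaced.append(pep)
            continue
        placements.append(
            Placement(
                sequence=pep.sequence,
                start=best + 1,
                mismatches=int(mismatches[best]),
                il_equivalent=il_equivalent,
            )
        )
        mask[best : best + m] = True
    return placements, CoverageMask("reference", mask), unplaced


def combination_coverage_table(
    per_label,
    reference: str,
    min_score: float = 90.0,
    max_mismatch: int = 0,
    il_equivalent: bool = True,
) -> pd.DataFrame:
    """Percent coverage of the reference for every non-empty label subset."""
    filtered = {
        label: filter_denovo(items, min_score)
        for label, items in per_label.items()
    }
    rows = []
    for combo in all_combinations(filtered):
        merged = merge_enzyme_sets(filtered, combo)
        _, mask, _ = align_to_reference(
            merged, reference, max_mismatch, il_equivalent
        )
        rows.append(
            {
                "combination": "+".join(combo),
                "n_enzymes": len(combo),
                "n_peptides": len(merged),
                "coverage_percent": 100.0 * mask.n_covered / mask.length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["combination", "n_enzymes", "n_peptides", "coverage_percent"],
    )


def placements_to_table(placements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence": p.sequence,
                "start": p.start,
                "end": p.start + len(p.sequence) - 1,
                "mismatches": p.mismatches,
                "il_equivalent": p.il_equivalent,
            }
            for p in placements
        ],
        columns=["sequence", "start", "end", "mismatches", "il_equivalent"],
    )
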