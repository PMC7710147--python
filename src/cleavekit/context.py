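"""Sequence-context analysis of cleaved vs missed sites.

Windows are aligned on the scissile bond using P-notation: P1 is the site
residue immediately N-terminal of the bond, P1' the residue immediately
C-terminal. Bond-relative offsets are negative on the P side (-1 = P1,
-2 = P2, ...) and positive on the prime side (+1 = P1', +2 = P2', ...).
Positions outside the protein hold a gap symbol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import GAP_SYMBOL
from .digestion import EnzymeSpec, cleavage_sites


class ContextError(ValueError):
    pass


@dataclass(frozen=True)
class ContextWindow:
    site_residue: str
    label: str  # "cleaved" or "missed"
    residues: tuple[tuple[int, str], ...]  # (bond-relative offset, residue)

    def residue_at(self, offset: int) -> str:
        for off, aa in self.residues:
            if off == offset:
                return aa
        raise KeyError(offset)


def _window(sequence: str, p1: int, half_width: int):
    out = []
    n = len(sequence)
    for off in range(-half_width, half_width + 1):
        if off == 0:
            continue
        pos = p1 + off + 1 if off < 0 else p1 + off
        aa = sequence[pos - 1] if 1 <= pos <= n else GAP_SYMBOL
        out.append((off, aa))
    return tuple(out)


def _locate(peptide_row, proteins_by_id, sorted_ids):
    """Return (record, start) for a peptide row; None when unmappable."""
    seq = peptide_row["sequence"]
    pid = peptide_row.get("protein_id")
    if pid in proteins_by_id and "start" in peptide_row and not pd.isna(
        peptide_row.get("start")
    ):
        return proteins_by_id[pid], int(peptide_row["start"])
    hits = []
    for rid in sorted_ids:
        pos = proteins_by_id[rid].sequence.find(seq)
        if pos >= 0:
            hits.append((rid, pos + 1))
    if not hits:
        return None
    return proteins_by_id[hits[0][0]], hits[0][1]


def extract_windows(
    proteins,
    peptides,
    enzyme: EnzymeSpec,
    half_width: int = 6,
):
    """Split observed peptides into cleaved- and missed-site context windows.

    Cleaved windows come from peptide C-termini that sit on an enzymatic
    site (protein C-termini are excluded: there is no bond to cleave);
    missed windows from enzymatic residues internal to a peptide. Peptides
    that cannot be mapped to any protein are counted and skipped; ambiguous
    matches resolve to the first protein id in sorted order.

    Returns ``(cleaved, missed, n_skipped)``.
    """
    proteins_by_id = {r.id: r for r in proteins}
    sorted_ids = sorted(proteins_by_id)
    if isinstance(peptides, pd.DataFrame):
        rows = peptides.to_dict("records")
    else:
        rows = [
            {"sequence": getattr(p, "sequence", p),
             "protein_id": getattr(p, "protein_id", None)}
            for p in peptides
        ]
    cleaved: list[ContextWindow] = []
    missed: list[ContextWindow] = []
    skipped = 0
    site_cache: dict[str, set[int]] = {}
    for row in rows:
        located = _locate(row, proteins_by_id, sorted_ids)
        if located is None:
            skipped += 1
            continue
        record, start = located
        seq = record.sequence
        end = start + len(row["sequence"]) - 1
        sites = site_cache.get(record.id)
        if sites is None:
            sites = set(cleavage_sites(record, enzyme))
            site_cache[record.id] = sites
        if end in sites:  # excludes protein C-terminus by construction
            cleaved.append(
                ContextWindow(
                    site_residue=seq[end - 1],
                    label="cleaved",
                    residues=_window(seq, end, half_width),
                )
            )
        for p in range(start, end):
            if p in sites:
                missed.append(
                    ContextWindow(
                        site_residue=seq[p - 1],
                        label="missed",
                        residues=_window(seq, p, half_width),
                    )
                )
    return cleaved, missed, skipped


def position_frequencies(windows) -> pd.DataFrame:
    """Per (offset, residue) foreground frequencies over non-gap residues."""
    counts: dict[int, dict[str, int]] = {}
    for w in windows:
        for off, aa in w.residues:
            if aa == GAP_SYMBOL:
                continue
            per_offset = counts.setdefault(off, {})
            per_offset[aa] = per_offset.get(aa, 0) + 1
    rows = []
    for off in sorted(counts):
        total = sum(counts[off].values())
        for aa, c in sorted(counts[off].items()):
            rows.append(
                {"offset": off, "residue": aa, "count": c,
                 "n": total, "frequency": c / total}
            )
    return pd.DataFrame(rows, columns=["offset", "residue", "count", "n", "frequency"])


def motif_enrichment(
    windows,
    background_freq: dict[str, float],
    alpha: float = 0.05,
    correction: str | None = None,
    min_exact_count: int = 5,
) -> pd.DataFrame:
    """Position-wise residue enrichment against a background distribution.

    Each (offset, residue) cell is a two-sided one-sample proportion test of
    the foreground count against the background probability: a normal
    approximation, switching to the exact binomial when the observed count
    is below ``min_exact_count``. ``correction='bonferroni'`` divides alpha
    by the number of cells.
    """
    windows = list(windows)
    if len(windows) < 20:
        raise ContextError("need at least 20 windows for motif statistics")
    total_bg = sum(background_freq.values())
    if abs(total_bg - 1.0) > 1e-6:
        raise ContextError(f"background frequencies sum to {total_bg}")
    freq = position_frequencies(windows)
    for aa in freq["residue"].unique():
        if aa not in background_freq:
            raise ContextError(f"background lacks residue {aa!r}")
    n_cells = len(freq)
    threshold = alpha / n_cells if correction == "bonferroni" else alpha
    pvals, diffs = [], []
    for row in freq.to_dict("records"):
        p0 = background_freq[row["residue"]]
        phat = row["frequency"]
        if row["count"] < min_exact_count:
            p = stats.binomtest(int(row["count"]), int(row["n"]), p0).pvalue
        else:
            se = np.sqrt(p0 * (1 - p0) / row["n"])
            z = (phat - p0) / se
            p = 2.0 * stats.norm.sf(abs(z))
        pvals.append(p)
        diffs.append(phat - p0)
    out = freq.copy()
    out["background"] = [background_freq[aa] for aa in out["residue"]]
    out["difference"] = diffs
    out["p_value"] = pvals
    out["significant"] = [p < threshold for p in pvals]
    return out


def cleaved_missed_ratio(cleaved, missed):
    """#cleaved / #missed per site residue, with the reciprocal alongside.

    Zero missed (or cleaved) counts report an infinity sentinel and raise a
    ``UserWarning``.
    """
    residues = sorted(
        {w.site_residue for w in cleaved} | {w.site_residue for w in missed}
    )
    out = {}
    for aa in residues:
        n_cleaved = sum(1 for w in cleaved if w.site_residue == aa)
        n_missed = sum(1 for w in missed if w.site_residue == aa)
        if n_missed == 0 or n_cleaved == 0:
            warnings.warn(
                f"degenerate cleaved/missed counts for {aa}: "
                f"{n_cleaved}/{n_missed}",
                UserWarning,
                stacklevel=2,
            )
        ratio = n_cleaved / n_missed if n_missed else float("inf")
        reciprocal = n_missed / n_cleaved if n_cleaved else float("inf")
        out[aa] = {
            "cleaved": n_cleaved,
            "missed": n_missed,
            "cleaved_to_missed": ratio,
            "missed_to_cleaved": reciprocal,
        }
    return out
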