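"""Terminal-residue frequencies, specificity fraction, missed-cleavage stats.

Inputs are identified-peptide lists: a pandas DataFrame with at least a
``sequence`` column, a list of :class:`IdentifiedPeptide`, or a list of
plain sequences. Peptides are deduplicated to unique sequences before
profiling by default; a PSM-level mode keeps duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import ALLOWED_RESIDUES
from .digestion import EnzymeSpec


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class IdentifiedPeptide:
    sequence: str
    protein_id: str | None = None
    score: float | None = None
    preceding_residue: str | None = None
    following_residue: str | None = None
    label: str | None = None
    is_protein_cterm: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProfileError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in ALLOWED_RESIDUES:
                raise ProfileError(
                    f"illegal residue {aa!r} in peptide {self.sequence!r}"
                )


@dataclass
class SpecificityProfile:
    terminal: dict[str, float]
    n_peptides: int
    specific_fraction: float
    mc_distribution: dict[int, float]
    label: str | None = None
    extras: dict = field(default_factory=dict)


def _to_frame(peptides) -> pd.DataFrame:
    if isinstance(peptides, pd.DataFrame):
        df = peptides.copy()
    elif len(peptides) and isinstance(peptides[0], str):
        df = pd.DataFrame({"sequence": list(peptides)})
    else:
        df = pd.DataFrame(
            {
                "sequence": [p.sequence for p in peptides],
                "is_protein_cterm": [
                    getattr(p, "is_protein_cterm", False) for p in peptides
                ],
                "following_residue": [
                    getattr(p, "following_residue", None) for p in peptides
                ],
            }
        )
    if "sequence" not in df.columns or df.empty:
        raise ProfileError("peptide table is empty or lacks a sequence column")
    return df


def _dedup(df: pd.DataFrame, unique: bool) -> pd.DataFrame:
    return df.drop_duplicates(subset="sequence") if unique else df


def terminal_frequency(
    peptides,
    terminus: str = "C",
    exclude_protein_terminal: bool = False,
    unique: bool = True,
) -> dict[str, float]:
    """Fraction of peptides whose terminal residue is each amino acid."""
    df = _dedup(_to_frame(peptides), unique)
    if exclude_protein_terminal and "following_residue" in df.columns:
        # protein-terminal peptides have no following residue
        df = df[df["following_residue"].isin(list(ALLOWED_RESIDUES))]
    if df.empty:
        raise ProfileError("no peptides after filtering")
    idx = -1 if terminus.upper() == "C" else 0
    residues = df["sequence"].str[idx]
    counts = residues.value_counts()
    n = int(counts.sum())
    return {aa: int(c) / n for aa, c in sorted(counts.items())}


def specificity_fraction(peptides, enzyme: EnzymeSpec, unique: bool = True) -> float:
    """Fraction of peptides whose rule-side terminal residue is an enzyme residue."""
    df = _dedup(_to_frame(peptides), unique)
    idx = -1 if enzyme.side == "C" else 0
    residues = df["sequence"].str[idx]
    return float(residues.isin(sorted(enzyme.cleave_after)).mean())


def count_internal_sites(sequence: str, enzyme: EnzymeSpec) -> int:
    """Missed cleavages inferred from the sequence alone.

    For C-side enzymes these are enzyme residues excluding the C-terminal
    one; the proline restriction is evaluated within the peptide. For
    N-side enzymes, enzyme residues excluding the N-terminal one.
    """
    n = len(sequence)
    count = 0
    if enzyme.side == "C":
        for i in range(n - 1):
            if sequence[i] in enzyme.cleave_after:
                if enzyme.restrict_before_proline and sequence[i + 1] == "P":
                    continue
                count += 1
    else:
        for i in range(1, n):
            if sequence[i] in enzyme.cleave_after:
                count += 1
    return count


def missed_cleavage_distribution(
    peptides,
    enzyme: EnzymeSpec,
    cap: int = 4,
    unique: bool = True,
) -> dict[int, float]:
    """Distribution of per-peptide missed-cleavage counts, pooled above ``cap``."""
    df = _dedup(_to_frame(peptides), unique)
    counts: dict[int, int] = {}
    for seq in df["sequence"]:
        mc = min(count_internal_sites(seq, enzyme), cap)
        counts[mc] = counts.get(mc, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ProfileError("no peptides")
    return {mc: c / n for mc, c in sorted(counts.items())}


def profile(
    peptides,
    enzyme: EnzymeSpec,
    label: str | None = None,
    mc_cap: int = 4,
    unique: bool = True,
) -> SpecificityProfile:
    df = _dedup(_to_frame(peptides), unique)
    return SpecificityProfile(
        terminal=terminal_frequency(df, unique=False),
        n_peptides=len(df),
        specific_fraction=specificity_fraction(df, enzyme, unique=False),
        mc_distribution=missed_cleavage_distribution(
            df, enzyme, cap=mc_cap, unique=False
        ),
        label=label,
    )


def average_profiles(profiles) -> SpecificityProfile:
    """Average profile vectors across labelled replicates."""
    profiles = list(profiles)
    if not profiles:
        raise ProfileError("no profiles to average")
    k = len(profiles)
    terminal: dict[str, float] = {}
    mc: dict[int, float] = {}
    for p in profiles:
        for aa, f in p.terminal.items():
            terminal[aa] = terminal.get(aa, 0.0) + f / k
        for c, f in p.mc_distribution.items():
            mc[c] = mc.get(c, 0.0) + f / k
    return SpecificityProfile(
        terminal=dict(sorted(terminal.items())),
        n_peptides=sum(p.n_peptides for p in profiles),
        specific_fraction=sum(p.specific_fraction for p in profiles) / k,
        mc_distribution=dict(sorted(mc.items())),
        label="average",
    )


def profile_to_dict(p: SpecificityProfile) -> dict:
    return {
        "label": p.label,
        "n_peptides": p.n_peptides,
        "terminal": p.terminal,
        "specific_fraction": p.specific_fraction,
        "mc_distribution": {str(k): v for k, v in p.mc_distribution.items()},
    }


def read_peptide_table(path) -> pd.DataFrame:
    """Read a TSV identified-peptide table (must contain ``sequence``)."""
    df = pd.read_csv(path, sep="\t")
    if "sequence" not in df.columns:
        raise ProfileError(f"{path}: no 'sequence' column")
    return df
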