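"""FASTA I/O, cleavage rules, in-silico digestion and peptide masses.

Coordinate convention: everything stored or reported is 1-based inclusive;
internal slicing uses 0-based half-open indices. A header range annotation
("a-b" as the last pipe-delimited token) only sets ``start_offset`` for
reporting — it never shifts internal indexing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from .constants import (
    ALLOWED_RESIDUES,
    MOD_MASS,
    RESIDUE_MASS,
    WATER_MASS,
)

_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


class DigestionError(ValueError):
    """Raised on invalid sequences, enzymes or mass bookkeeping."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus reporting metadata.

    ``start_offset`` is the 1-based coordinate of the first residue in the
    parent protein, parsed from header ranges such as ``1663-2318``.
    ``mod_positions`` maps 1-based positions to modification names
    (e.g. ``"Hyp"``).
    """

    id: str
    sequence: str
    description: str = ""
    start_offset: int = 1
    mod_positions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DigestionError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise DigestionError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {i}"
                )
        for pos, name in self.mod_positions.items():
            if not 1 <= pos <= len(self.sequence):
                raise DigestionError(
                    f"record {self.id!r}: modification {name!r} at position "
                    f"{pos} outside [1, {len(self.sequence)}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def declared_length(self) -> int | None:
        """Length implied by a parsed header range, if any."""
        return getattr(self, "_declared_length", None)


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease cleavage rule.

    ``side`` is ``"C"`` when the scissile bond follows the named residue
    (trypsin-like) and ``"N"`` when it precedes it (Asp-N-like).
    """

    name: str
    cleave_after: frozenset[str]
    side: str = "C"
    treat_hyp_as_site: bool = False
    restrict_before_proline: bool = False
    max_missed: int = 0
    min_len: int = 1
    max_len: int = 50

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise DigestionError(f"enzyme {self.name!r}: empty residue set")
        if self.side not in ("C", "N"):
            raise DigestionError(f"enzyme {self.name!r}: side must be C or N")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise DigestionError(f"enzyme {self.name!r}: invalid length bounds")
        if not 0 <= self.max_missed <= 20:
            raise DigestionError(f"enzyme {self.name!r}: max_missed out of range")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))

    def with_(self, **kwargs) -> "EnzymeSpec":
        return replace(self, **kwargs)


ENZYME_PRESETS: dict[str, EnzymeSpec] = {
    "proalanase": EnzymeSpec(
        "proalanase", frozenset("PA"), treat_hyp_as_site=True, max_missed=4
    ),
    "trypsin_p": EnzymeSpec("trypsin_p", frozenset("KR"), max_missed=2),
    "trypsin": EnzymeSpec(
        "trypsin", frozenset("KR"), restrict_before_proline=True, max_missed=2
    ),
    "gluc": EnzymeSpec("gluc", frozenset("DE"), max_missed=4),
    "aspn": EnzymeSpec("aspn", frozenset("D"), side="N", max_missed=4),
    "pasg": EnzymeSpec("pasg", frozenset("PASG"), max_missed=10),
}


def get_enzyme(name: str, **overrides) -> EnzymeSpec:
    """Look up a bundled preset, optionally overriding fields."""
    try:
        enzyme = ENZYME_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme preset {name!r}; available: "
            f"{sorted(ENZYME_PRESETS)}"
        ) from None
    return enzyme.with_(**overrides) if overrides else enzyme


@dataclass(frozen=True)
class Peptide:
    """A digest product located on its source record (1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    nterm_specific: bool = True
    cterm_specific: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    If the last pipe-delimited header token is ``a-b`` with integers
    ``a <= b``, it is taken as a residue range and ``start_offset`` is set
    to ``a``. A mismatch between the declared and actual length raises a
    ``UserWarning`` but keeps the record.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        start_offset = 1
        declared = None
        tokens = entry.id.split("|")
        m = _RANGE_RE.match(tokens[-1]) if tokens else None
        if m:
            a, b = int(m.group(1)), int(m.group(2))
            if a <= b:
                start_offset = a
                declared = b - a + 1
        record = ProteinRecord(
            id=entry.id,
            sequence=seq,
            description=entry.description,
            start_offset=start_offset,
        )
        if declared is not None:
            object.__setattr__(record, "_declared_length", declared)
            if declared != len(seq):
                warnings.warn(
                    f"record {record.id!r}: header range declares "
                    f"{declared} residues but sequence has {len(seq)}",
                    UserWarning,
                    stacklevel=2,
                )
        records.append(record)
    if not records:
        raise DigestionError(f"no FASTA records found in {path}")
    return records


def parse_header_range(header: str) -> tuple[int, int | None]:
    """Return ``(start_offset, declared_length)`` from a FASTA header id."""
    tokens = header.split("|")
    m = _RANGE_RE.match(tokens[-1]) if tokens else None
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if a <= b:
            return a, b - a + 1
    return 1, None


def cleavage_sites(record: ProteinRecord, enzyme: EnzymeSpec) -> list[int]:
    """Ordered 1-based P1 positions of scissile bonds in ``record``.

    A position ``p`` means the bond between residues ``p`` and ``p+1``;
    ``p == len(record)`` is excluded because there is no bond after the
    last residue.
    """
    seq = record.sequence
    n = len(seq)
    sites: list[int] = []
    hyp_positions = {
        pos for pos, name in record.mod_positions.items() if name == "Hyp"
    }
    for p in range(1, n):  # bond between p and p+1
        if enzyme.side == "C":
            residue = seq[p - 1]
            is_site = residue in enzyme.cleave_after
            if (
                not is_site
                and enzyme.treat_hyp_as_site
                and p in hyp_positions
                and "P" in enzyme.cleave_after
            ):
                is_site = True
            if is_site and enzyme.restrict_before_proline and seq[p] == "P":
                is_site = False
        else:  # N-side: bond precedes the named residue
            is_site = seq[p] in enzyme.cleave_after
        if is_site:
            sites.append(p)
    return sites


def count_missed(start: int, end: int, sites: list[int]) -> int:
    """Missed cleavages of the span [start, end]: internal sites only.

    A site at ``end`` is the (specific) C-terminal bond, so sites count
    when ``start <= p < end``.
    """
    return sum(1 for p in sites if start <= p < end)


def digest(record: ProteinRecord, enzyme: EnzymeSpec) -> list[Peptide]:
    """All fully-specific peptides with 0..max_missed missed cleavages.

    Output is ordered by (start, end). Length bounds from the enzyme spec
    are applied; protein termini count as specific termini.
    """
    sites = cleavage_sites(record, enzyme)
    boundaries = [0] + sites + [len(record)]
    peptides: list[Peptide] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + enzyme.max_missed + 2, len(boundaries))):
            start0, end = boundaries[i], boundaries[j]
            length = end - start0
            if not enzyme.min_len <= length <= enzyme.max_len:
                continue
            peptides.append(
                Peptide(
                    protein_id=record.id,
                    start=start0 + 1,
                    end=end,
                    sequence=record.sequence[start0:end],
                    missed_cleavages=j - i - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def semi_specific_peptides(
    record: ProteinRecord,
    enzyme: EnzymeSpec,
    max_nonspecific_extension: int,
) -> list[Peptide]:
    """Peptides with exactly one enzymatic terminus.

    The nonspecific terminus must lie within ``max_nonspecific_extension``
    residues of the enclosing enzymatic boundary (equivalently: at most
    that many residues are trimmed off a fully-specific span). Length
    bounds and ``max_missed`` apply to the emitted peptide. Ordered by
    (start, end); an extension bound of 0 yields nothing.
    """
    if max_nonspecific_extension <= 0:
        return []
    sites = cleavage_sites(record, enzyme)
    site_set = set(sites)
    n = len(record)
    boundaries = sorted({0, n} | site_set)

    def prev_boundary(pos: int) -> int:
        return max(b for b in boundaries if b <= pos)

    def next_boundary(pos: int) -> int:
        return min(b for b in boundaries if b >= pos)

    out: list[Peptide] = []
    seen: set[tuple[int, int]] = set()
    for start in range(1, n + 1):
        ns = start == 1 or (start - 1) in site_set
        for end in range(start + enzyme.min_len - 1,
                         min(start + enzyme.max_len - 1, n) + 1):
            cs = end == n or end in site_set
            if ns == cs:
                continue
            if not ns and (start - 1) - prev_boundary(start - 1) > \
                    max_nonspecific_extension:
                continue
            if not cs and next_boundary(end) - end > max_nonspecific_extension:
                continue
            mc = count_missed(start, end, sites)
            if mc > enzyme.max_missed:
                continue
            if (start, end) in seen:
                continue
            seen.add((start, end))
            out.append(
                Peptide(
                    protein_id=record.id,
                    start=start,
                    end=end,
                    sequence=record.sequence[start - 1 : end],
                    missed_cleavages=mc,
                    nterm_specific=ns,
                    cterm_specific=cs,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def peptide_mass(sequence: str, mods=None) -> float:
    """Monoisotopic neutral mass in Da of ``sequence`` plus modifications.

    ``mods`` is a multiset of modification names: either a mapping
    name -> count or an iterable of names. Unknown residues (including X)
    or modification names raise :class:`DigestionError`.
    """
    if not sequence:
        raise DigestionError("cannot compute mass of empty sequence")
    total = WATER_MASS
    for i, aa in enumerate(sequence, start=1):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise DigestionError(
                f"residue {aa!r} at position {i} has no defined mass"
            ) from None
    if mods:
        items = mods.items() if hasattr(mods, "items") else ((m, 1) for m in mods)
        for name, count in items:
            try:
                total += MOD_MASS[name] * count
            except KeyError:
                raise DigestionError(f"unknown modification {name!r}") from None
    return round(total, 6)


def record_peptide_mass(record: ProteinRecord, peptide: Peptide) -> float:
    """Mass of a located peptide including the record's modifications."""
    mods = [
        name
        for pos, name in record.mod_positions.items()
        if peptide.start <= pos <= peptide.end
    ]
    return peptide_mass(peptide.sequence, mods)


def length_distribution(peptides, threshold: int | None = None):
    """Histogram of peptide lengths and the fraction below ``threshold``.

    Accepts sequences or :class:`Peptide` objects. Returns
    ``(fractions, frac_below)``; ``frac_below`` is None when no threshold
    is given.
    """
    lengths = [len(p) for p in peptides]
    if not lengths:
        raise DigestionError("length_distribution of empty peptide list")
    n = len(lengths)
    fractions: dict[int, float] = {}
    for length in sorted(set(lengths)):
        fractions[length] = lengths.count(length) / n
    frac_below = None
    if threshold is not None:
        frac_below = sum(1 for length in lengths if length < threshold) / n
    return fractions, frac_below


def residue_composition(records) -> dict[str, float]:
    """Residue frequency map over one or more records (X excluded)."""
    counts: dict[str, int] = {}
    for record in records:
        for aa in record.sequence:
            if aa == "X":
                continue
            counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise DigestionError("no countable residues")
    return {aa: c / total for aa, c in sorted(counts.items())}


def peptides_to_table(peptides, record: ProteinRecord | None = None) -> pd.DataFrame:
    """TSV-ready table: one row per peptide with coordinates and mass."""
    rows = []
    for pep in peptides:
        if record is not None:
            try:
                mass = record_peptide_mass(record, pep)
            except DigestionError:
                mass = float("nan")
        else:
            try:
                mass = peptide_mass(pep.sequence)
            except DigestionError:
                mass = float("nan")
        rows.append(
            {
                "protein_id": pep.protein_id,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "missed_cleavages": pep.missed_cleavages,
                "nterm_specific": pep.nterm_specific,
                "cterm_specific": pep.cterm_specific,
                "mass": mass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "start",
            "end",
            "sequence",
            "missed_cleavages",
            "nterm_specific",
            "cterm_specific",
            "mass",
        ],
    )
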