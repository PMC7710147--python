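"""Low-pH disulfide mapping: species enumeration, ppm matching, ISR triads.

Masses are neutral monoisotopic. Each disulfide bond removes two hydrogens
(:data:`~cleavekit.constants.DISULFIDE_DELTA`); nonreduced digests carry no
carbamidomethyl fixed modification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import DISULFIDE_DELTA, PROTON_MASS
from .digestion import (
    DigestionError,
    EnzymeSpec,
    Peptide,
    ProteinRecord,
    digest,
    peptide_mass,
    semi_specific_peptides,
)

#: A cysteine location: (chain/protein id, 1-based position).
CysSite = tuple[str, int]


@dataclass(frozen=True)
class CysPeptide:
    """A cysteine-containing digest product with its unalkylated mass."""

    peptide: Peptide
    mass: float
    cys_positions: tuple[int, ...]  # absolute 1-based positions in the chain

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


@dataclass(frozen=True)
class DisulfideSpecies:
    """One or two cysteine peptides joined by ``n_bonds`` disulfide bonds."""

    peptides: tuple[CysPeptide, ...]
    n_bonds: int
    kind: str  # "intra" or "inter"
    mass: float
    cys_pairs: tuple[frozenset, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        for cp in self.peptides:
            if cp.n_cys < 1:
                raise ValueError("every constituent must contain a cysteine")


@dataclass(frozen=True)
class PrecursorObservation:
    """An observed precursor: m/z + charge, with derived neutral mass."""

    mz: float
    charge: int
    rt: str | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")

    @property
    def neutral_mass(self) -> float:
        return self.mz * self.charge - self.charge * PROTON_MASS


def neutral_to_mz(mass: float, charge: int) -> float:
    return (mass + charge * PROTON_MASS) / charge


def linked_mass(peptide_masses, n_bonds: int) -> float:
    """Neutral mass of a disulfide-linked species: sum − 2H per bond."""
    return round(sum(peptide_masses) - DISULFIDE_DELTA * n_bonds, 6)


def enumerate_cys_peptides(
    records,
    enzyme: EnzymeSpec,
    semi_specific: bool = False,
    max_nonspecific_extension: int = 5,
) -> list[CysPeptide]:
    """Cysteine-containing digest products with unalkylated masses."""
    out: list[CysPeptide] = []
    for record in records:
        peps = list(digest(record, enzyme))
        if semi_specific:
            peps += semi_specific_peptides(
                record, enzyme, max_nonspecific_extension
            )
        for pep in peps:
            if "C" not in pep.sequence:
                continue
            cys = tuple(
                pep.start + i
                for i, aa in enumerate(pep.sequence)
                if aa == "C"
            )
            try:
                mass = peptide_mass(pep.sequence)
            except DigestionError:
                continue  # X-containing peptide: no defined mass
            out.append(CysPeptide(pep, mass, cys))
    return out


def enumerate_linked_species(
    cys_peptides,
    max_bonds: int = 1,
    allow_intra: bool = True,
    pair_cap: int = 10**6,
) -> list[DisulfideSpecies]:
    """All intra- and inter-peptide disulfide species up to ``max_bonds``.

    Pairs are unordered and homodimers are included, giving n(n+1)/2 pair
    candidates before cysteine-count pruning. Exceeding ``pair_cap`` raises
    with advice to tighten the enzyme settings.
    """
    peptides = list(cys_peptides)
    n = len(peptides)
    n_pairs = n * (n + 1) // 2
    if n_pairs > pair_cap:
        raise DigestionError(
            f"{n_pairs} candidate peptide pairs exceed the cap of {pair_cap}; "
            "use stricter enzyme settings (fewer missed cleavages or tighter "
            "length bounds) or raise pair_cap"
        )
    species: list[DisulfideSpecies] = []
    if allow_intra:
        for cp in peptides:
            for b in range(1, min(max_bonds, cp.n_cys // 2) + 1):
                species.append(
                    DisulfideSpecies(
                        peptides=(cp,),
                        n_bonds=b,
                        kind="intra",
                        mass=linked_mass([cp.mass], b),
                    )
                )
    for i in range(n):
        for j in range(i, n):
            a, b_pep = peptides[i], peptides[j]
            max_b = min(max_bonds, a.n_cys, b_pep.n_cys)
            for b in range(1, max_b + 1):
                species.append(
                    DisulfideSpecies(
                        peptides=(a, b_pep),
                        n_bonds=b,
                        kind="inter",
                        mass=linked_mass([a.mass, b_pep.mass], b),
                    )
                )
    return species


def species_from_connectivity(
    records,
    connectivity,
    enzyme: EnzymeSpec,
) -> list[DisulfideSpecies]:
    """Ground-truth species implied by a cysteine connectivity map.

    ``connectivity`` is an iterable of bonds, each a pair of
    ``(chain_id, position)`` cysteine sites. Chains are digested with zero
    missed cleavages so every cysteine lies in exactly one fragment; bonds
    joining the same fragment pair merge into one species with n_bonds > 1.
    """
    by_id = {r.id: r for r in records}
    full = enzyme.with_(max_missed=0, min_len=1, max_len=10**6)
    peptide_of: dict[CysSite, CysPeptide] = {}
    for record in by_id.values():
        for pep in digest(record, full):
            if "C" not in pep.sequence:
                continue
            cys = tuple(
                pep.start + i for i, aa in enumerate(pep.sequence) if aa == "C"
            )
            cp = CysPeptide(pep, peptide_mass(pep.sequence), cys)
            for pos in cys:
                peptide_of[(record.id, pos)] = cp

    grouped: dict[tuple, list[frozenset]] = {}
    for bond in connectivity:
        (ca, pa), (cb, pb) = bond
        for cid, pos in ((ca, pa), (cb, pb)):
            record = by_id.get(cid)
            if record is None:
                raise DigestionError(f"connectivity names unknown chain {cid!r}")
            if record.sequence[pos - 1] != "C":
                raise DigestionError(
                    f"position {pos} of chain {cid!r} is not a cysteine"
                )
        pep_a = peptide_of[(ca, pa)]
        pep_b = peptide_of[(cb, pb)]
        key = tuple(
            sorted(
                {(p.peptide.protein_id, p.peptide.start, p.peptide.end)
                 for p in (pep_a, pep_b)}
            )
        )
        grouped.setdefault(key, []).append(
            frozenset({(ca, pa), (cb, pb)})
        )

    species: list[DisulfideSpecies] = []
    for key, bonds in grouped.items():
        constituents = tuple(
            sorted(
                {id(p): p for bond in bonds
                 for p in _peptides_for_bond(bond, peptide_of)}.values(),
                key=lambda cp: (cp.peptide.protein_id, cp.peptide.start),
            )
        )
        kind = "intra" if len(constituents) == 1 else "inter"
        species.append(
            DisulfideSpecies(
                peptides=constituents,
                n_bonds=len(bonds),
                kind=kind,
                mass=linked_mass([cp.mass for cp in constituents], len(bonds)),
                cys_pairs=tuple(bonds),
            )
        )
    return species


def _peptides_for_bond(bond, peptide_of):
    return [peptide_of[site] for site in bond]


@dataclass(frozen=True)
class Match:
    observation: PrecursorObservation
    species: DisulfideSpecies
    ppm_error: float


def match_precursors(
    observations,
    species,
    ppm_tol: float = 5.0,
):
    """Match observed precursors to candidate species within ``ppm_tol``.

    Returns ``(matches, unmatched)``; matches per observation are sorted by
    absolute ppm error. Symmetric in input ordering.
    """
    matches: list[Match] = []
    unmatched: list[PrecursorObservation] = []
    candidates = sorted(species, key=lambda s: s.mass)
    for obs in observations:
        m = obs.neutral_mass
        hits = []
        for sp in candidates:
            ppm = (m - sp.mass) / sp.mass * 1e6
            if abs(ppm) <= ppm_tol:
                hits.append(Match(obs, sp, ppm))
        hits.sort(key=lambda h: abs(h.ppm_error))
        if hits:
            matches.extend(hits)
        else:
            unmatched.append(obs)
    return matches, unmatched


def isr_triad_check(
    linked: float,
    reduced_a: float,
    reduced_b: float,
    n_bonds: int = 1,
    tol_ppm: float = 5.0,
) -> bool:
    """Validate an in-source-reduction triad.

    True iff the linked mass equals the sum of the two reduced constituent
    masses minus 2H per bond, within ``tol_ppm`` of the linked mass.
    """
    expected = reduced_a + reduced_b - DISULFIDE_DELTA * n_bonds
    return abs(linked - expected) <= tol_ppm * 1e-6 * linked


def scrambling_flags(matches, expected_connectivity):
    """Flag matched species whose implied Cys pairing is non-native.

    ``expected_connectivity`` is an iterable of bonds (pairs of CysSite).
    A species is flagged when no expected bond joins its constituents'
    cysteine sets (for intra species: no expected bond within the peptide).
    """
    expected = {frozenset(bond) for bond in expected_connectivity}
    flagged: list[Match] = []
    for match in matches:
        sp = match.species
        if len(sp.peptides) == 1:
            cp = sp.peptides[0]
            sites = {
                (cp.peptide.protein_id, pos) for pos in cp.cys_positions
            }
            ok = any(bond <= sites for bond in expected)
        else:
            a, b = sp.peptides
            sites_a = {(a.peptide.protein_id, p) for p in a.cys_positions}
            sites_b = {(b.peptide.protein_id, p) for p in b.cys_positions}
            ok = any(
                (len(bond & sites_a) == 1 and len(bond & sites_b) == 1)
                for bond in expected
            )
        if not ok:
            flagged.append(match)
    return flagged


def matches_to_table(matches) -> pd.DataFrame:
    rows = []
    for m in matches:
        sp = m.species
        rows.append(
            {
                "mz": m.observation.mz,
                "charge": m.observation.charge,
                "observed_mass": m.observation.neutral_mass,
                "species_mass": sp.mass,
                "ppm_error": m.ppm_error,
                "kind": sp.kind,
                "n_bonds": sp.n_bonds,
                "peptides": ";".join(
                    f"{cp.peptide.protein_id}:{cp.peptide.start}-{cp.peptide.end}"
                    for cp in sp.peptides
                ),
                "cys_sites": ";".join(
                    f"{cp.peptide.protein_id}:{pos}"
                    for cp in sp.peptides
                    for pos in cp.cys_positions
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mz", "charge", "observed_mass", "species_mass", "ppm_error",
            "kind", "n_bonds", "peptides", "cys_sites",
        ],
    )
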