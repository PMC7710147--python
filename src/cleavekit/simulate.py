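"""Seeded generators for every synthetic input the pipeline consumes.

Two cleavage simulation modes exist on purpose. The mechanistic mode fires
each candidate site independently from per-residue probabilities (optionally
modulated by basophilic sequence context), so cleaved/missed ratios are
emergent. The terminal-composition mode samples peptides so that the
C-terminal residue distribution directly matches a preset, making the
headline terminal frequencies controllable expectations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import BACKGROUND_FREQUENCIES, BASOPHILIC_RESIDUES
from .digestion import EnzymeSpec, ProteinRecord, digest
from .disulfide import (
    DisulfideSpecies,
    PrecursorObservation,
    neutral_to_mz,
    species_from_connectivity,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# proteome generation


def generate_proteome(
    n_proteins: int,
    mean_length: int,
    composition: dict[str, float] | None = None,
    seed: int | None = None,
) -> list[ProteinRecord]:
    """Random proteins with ids SYN0001..; reproducible for a fixed seed.

    Lengths are fixed at ``mean_length``; ``composition`` defaults to the
    bundled background frequencies and must sum to 1.
    """
    if n_proteins < 1:
        raise SimulationError("n_proteins must be >= 1")
    comp = composition or BACKGROUND_FREQUENCIES
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-6:
        raise SimulationError(f"composition sums to {total}, expected 1")
    letters = sorted(comp)
    probs = np.array([comp[aa] for aa in letters]) / total
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(letters, size=mean_length, p=probs))
        records.append(ProteinRecord(id=f"SYN{i + 1:04d}", sequence=seq))
    return records


# ---------------------------------------------------------------------------
# mechanistic cleavage simulation


@dataclass(frozen=True)
class ContextModifier:
    """Multiply a site's cleavage probability when a context residue matches.

    ``offset`` is bond-relative: +k is the k-th residue C-terminal of the
    scissile bond (Pk'), -k the k-th residue N-terminal of it (Pk, with P1
    the site residue itself).
    """

    site_residues: frozenset[str]
    offset: int
    residues: frozenset[str]
    multiplier: float


@dataclass(frozen=True)
class CleavageModel:
    base_prob: dict[str, float] = field(
        default_factory=lambda: {"P": 2 / 3, "A": 1 / 3}
    )
    context_multipliers: tuple[ContextModifier, ...] = (
        ContextModifier(frozenset("P"), +2, BASOPHILIC_RESIDUES, 0.5),
        ContextModifier(frozenset("A"), -2, BASOPHILIC_RESIDUES, 2.0),
    )
    detectable_len: tuple[int, int] = (7, 35)
    nonspecific_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for aa, p in self.base_prob.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"base_prob[{aa!r}]={p} outside [0,1]")
        lo, hi = self.detectable_len
        if not (1 <= lo <= hi <= 100):
            raise SimulationError("detectable_len must lie within [1, 100]")


def site_probability(sequence: str, p1: int, model: CleavageModel) -> float:
    """Cleavage probability of the bond after 1-based position ``p1``."""
    residue = sequence[p1 - 1]
    prob = model.base_prob.get(residue, 0.0)
    for mod in model.context_multipliers:
        if residue not in mod.site_residues:
            continue
        # bond-relative -> sequence coordinates: +k is p1+k, -k is p1-k+1
        pos = p1 + mod.offset if mod.offset > 0 else p1 + mod.offset + 1
        if 1 <= pos <= len(sequence) and sequence[pos - 1] in mod.residues:
            prob *= mod.multiplier
    return min(max(prob, 0.0), 1.0)


@dataclass
class MechanisticResult:
    """Detectable fragments plus ground-truth per-site labels."""

    peptides: pd.DataFrame  # protein_id, start, end, sequence
    sites: pd.DataFrame  # protein_id, position, residue, cleaved, observed
    params: dict


def simulate_mechanistic(
    proteins,
    model: CleavageModel,
    seed: int | None = None,
) -> MechanisticResult:
    """Fire each candidate site independently and emit detectable fragments.

    A cleaved site is observed when the fragment ending at it is detectable;
    a missed site when the fragment spanning it is detectable.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    lo, hi = model.detectable_len
    pep_rows, site_rows = [], []
    for record in proteins:
        seq = record.sequence
        n = len(seq)
        candidates = [
            p for p in range(1, n)
            if model.base_prob.get(seq[p - 1], 0.0) > 0.0
        ]
        probs = np.array(
            [site_probability(seq, p, model) for p in candidates]
        )
        fired = (
            rng.random(len(candidates)) < probs
            if candidates
            else np.zeros(0, dtype=bool)
        )
        cuts = [p for p, f in zip(candidates, fired) if f]
        boundaries = [0] + cuts + [n]
        detectable_span: dict[tuple[int, int], bool] = {}
        for i in range(len(boundaries) - 1):
            s0, e = boundaries[i], boundaries[i + 1]
            ok = lo <= e - s0 <= hi
            detectable_span[(s0 + 1, e)] = ok
            if ok:
                pep_rows.append(
                    {
                        "protein_id": record.id,
                        "start": s0 + 1,
                        "end": e,
                        "sequence": seq[s0:e],
                    }
                )
        spans = sorted(detectable_span)
        for p, f in zip(candidates, fired):
            # cleaved: fragment ends at p; missed: fragment strictly spans p
            if f:
                span = next(s for s in spans if s[1] == p)
            else:
                span = next(s for s in spans if s[0] <= p < s[1])
            site_rows.append(
                {
                    "protein_id": record.id,
                    "position": p,
                    "residue": seq[p - 1],
                    "cleaved": bool(f),
                    "observed": detectable_span[span],
                }
            )
    peptides = pd.DataFrame(
        pep_rows, columns=["protein_id", "start", "end", "sequence"]
    )
    sites = pd.DataFrame(
        site_rows,
        columns=["protein_id", "position", "residue", "cleaved", "observed"],
    )
    params = {
        "mode": "mechanistic",
        "base_prob": dict(model.base_prob),
        "detectable_len": list(model.detectable_len),
        "n_context_multipliers": len(model.context_multipliers),
        "seed": model.seed if seed is None else seed,
    }
    return MechanisticResult(peptides, sites, params)


# ---------------------------------------------------------------------------
# terminal-composition simulation


def terminal_preset(name: str) -> dict[str, float]:
    """C-terminal residue distributions for the bundled pH presets.

    pH1_5 puts 0.49 on P and 0.34 on A; pH2_5 puts 0.35 and 0.30. The
    remaining mass is shared by the other residues proportionally to the
    bundled background frequencies.
    """
    presets = {"pH1_5": (0.49, 0.34), "pH2_5": (0.35, 0.30)}
    try:
        p_frac, a_frac = presets[name]
    except KeyError:
        raise KeyError(
            f"unknown terminal preset {name!r}; available: {sorted(presets)}"
        ) from None
    rest = 1.0 - p_frac - a_frac
    others = {
        aa: f for aa, f in BACKGROUND_FREQUENCIES.items() if aa not in "PA"
    }
    norm = sum(others.values())
    dist = {aa: rest * f / norm for aa, f in others.items()}
    dist["P"] = p_frac
    dist["A"] = a_frac
    total = sum(dist.values())
    return {aa: p / total for aa, p in sorted(dist.items())}


def simulate_terminal_composition(
    proteins,
    preset,
    n_peptides: int,
    nonspecific_rate: float = 1.0,
    seed: int | None = None,
    length_range: tuple[int, int] = (7, 35),
    allow_duplicates: bool = False,
) -> pd.DataFrame:
    """Sample peptides whose C-terminal residue distribution matches a preset.

    ``preset`` is a preset name or a residue->probability map. With
    probability ``1 - nonspecific_rate`` the N-terminus is snapped to an
    enzymatic boundary (after P/A or the protein start) when one exists in
    the allowed length window; otherwise it is placed uniformly. Unique
    sequences are emitted by default (duplicate draws are rejected and
    redrawn); ``allow_duplicates`` keeps every draw, emulating PSM-level
    lists. Use a proteome large relative to ``n_peptides`` so that the
    uniqueness constraint does not distort the terminal distribution.
    """
    if n_peptides < 100:
        raise SimulationError("n_peptides must be >= 100")
    dist = terminal_preset(preset) if isinstance(preset, str) else dict(preset)
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"preset probabilities sum to {total}")
    lo, hi = length_range
    rng = np.random.default_rng(seed)

    # index of eligible C-terminal positions per residue
    index: dict[str, list[tuple[int, int]]] = {aa: [] for aa in dist}
    for pi, record in enumerate(proteins):
        seq = record.sequence
        for pos in range(lo, len(seq) + 1):  # end positions supporting min_len
            aa = seq[pos - 1]
            if aa in index:
                index[aa].append((pi, pos))
    for aa, p in dist.items():
        if p > 0 and not index[aa]:
            raise SimulationError(
                f"preset residue {aa!r} absent from the proteome (or only "
                f"within the first {lo - 1} positions)"
            )

    letters = sorted(dist)
    probs = np.array([dist[aa] for aa in letters])
    probs = probs / probs.sum()
    rows = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 50 * n_peptides
    while len(rows) < n_peptides:
        attempts += 1
        if attempts > max_attempts:
            raise SimulationError(
                f"could not draw {n_peptides} unique peptides in "
                f"{max_attempts} attempts; enlarge the proteome or pass "
                "allow_duplicates=True"
            )
        aa = letters[rng.choice(len(letters), p=probs)]
        occ = index[aa]
        pi, end = occ[rng.integers(len(occ))]
        seq = proteins[pi].sequence
        max_len = min(hi, end)
        specific = rng.random() >= nonspecific_rate
        start = None
        if specific:
            starts = [
                s for s in range(end - max_len + 1, end - lo + 2)
                if s == 1 or seq[s - 2] in "PA"
            ]
            if starts:
                start = starts[rng.integers(len(starts))]
        if start is None:
            length = int(rng.integers(lo, max_len + 1))
            start = end - length + 1
        peptide = seq[start - 1 : end]
        if not allow_duplicates:
            if peptide in seen:
                continue
            seen.add(peptide)
        rows.append(
            {
                "protein_id": proteins[pi].id,
                "start": start,
                "end": end,
                "sequence": peptide,
                "preceding_residue": seq[start - 2] if start > 1 else "-",
                "following_residue": seq[end] if end < len(seq) else "-",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "sequence",
            "preceding_residue", "following_residue",
        ],
    )


# ---------------------------------------------------------------------------
# phosphosite simulation


@dataclass
class PhosphoSimulation:
    tables: dict[str, pd.DataFrame]
    true_positions: list[int]
    params: dict


def simulate_phosphosites(
    record: ProteinRecord,
    n_true_sites: int,
    loc_prob_dists: dict | None = None,
    per_enzyme_observability: dict[str, float] | None = None,
    seed: int | None = None,
) -> PhosphoSimulation:
    """Simulate per-enzyme phosphosite tables with localization probabilities.

    ``loc_prob_dists`` maps enzyme label to either a Beta ``(a, b)`` tuple
    or a float point mass; defaults are Beta(8,2) for enzyme "A" and
    Beta(4,2) for enzyme "B". Each enzyme observes each true site with its
    observability probability.
    """
    dists = loc_prob_dists or {"A": (8.0, 2.0), "B": (4.0, 2.0)}
    observability = per_enzyme_observability or {k: 1.0 for k in dists}
    rng = np.random.default_rng(seed)
    sty = [
        i + 1 for i, aa in enumerate(record.sequence) if aa in "STY"
    ]
    if n_true_sites > len(sty):
        raise SimulationError(
            f"record has only {len(sty)} S/T/Y residues, "
            f"cannot place {n_true_sites} sites"
        )
    positions = sorted(
        rng.choice(sty, size=n_true_sites, replace=False).tolist()
    )
    tables = {}
    for label, dist in dists.items():
        obs_p = observability.get(label, 1.0)
        rows = []
        for pos in positions:
            if rng.random() >= obs_p:
                continue
            if isinstance(dist, (int, float)):
                loc = float(dist)
            else:
                a, b = dist
                loc = float(rng.beta(a, b))
            rows.append(
                {
                    "protein_id": record.id,
                    "position": pos,
                    "residue": record.sequence[pos - 1],
                    "localization_probability": loc,
                    "enzyme": label,
                }
            )
        tables[label] = pd.DataFrame(
            rows,
            columns=[
                "protein_id", "position", "residue",
                "localization_probability", "enzyme",
            ],
        )
    params = {
        "mode": "phosphosites",
        "n_true_sites": n_true_sites,
        "seed": seed,
        "dists": {k: list(v) if not isinstance(v, (int, float)) else v
                  for k, v in dists.items()},
        "observability": dict(observability),
    }
    return PhosphoSimulation(tables, positions, params)


# ---------------------------------------------------------------------------
# disulfide digest simulation


@dataclass
class DisulfideSimulation:
    observations: list[PrecursorObservation]
    species: list[DisulfideSpecies]
    truth: pd.DataFrame  # observation index -> species index + form
    connectivity: list
    params: dict


def simulate_disulfide_digest(
    chains,
    connectivity,
    enzyme: EnzymeSpec,
    ppm_noise: float = 0.0,
    include_reduced_forms: bool = False,
    seed: int | None = None,
    charge: int = 2,
    scramble_pairs: int = 0,
) -> DisulfideSimulation:
    """Observed precursor masses for a nonreduced disulfide digest.

    Each ground-truth species contributes its linked mass and, when
    ``include_reduced_forms`` is on, both constituent reduced masses (the
    in-source-reduction triad). Masses receive Gaussian relative noise of
    ``ppm_noise`` ppm. ``scramble_pairs`` swaps partner cysteines between
    that many bond pairs to emulate disulfide scrambling.
    """
    rng = np.random.default_rng(seed)
    connectivity = [tuple(bond) for bond in connectivity]
    effective = list(connectivity)
    if scramble_pairs:
        if len(effective) < 2 * scramble_pairs:
            raise SimulationError("not enough bonds to scramble")
        for k in range(scramble_pairs):
            i, j = 2 * k, 2 * k + 1
            (a1, a2), (b1, b2) = effective[i], effective[j]
            effective[i], effective[j] = (a1, b2), (b1, a2)
    species = species_from_connectivity(chains, effective, enzyme)
    observations, truth_rows = [], []

    def emit(mass: float, si: int, form: str) -> None:
        noisy = mass * (1.0 + rng.normal(0.0, ppm_noise * 1e-6)) \
            if ppm_noise > 0 else mass
        obs = PrecursorObservation(
            mz=neutral_to_mz(noisy, charge), charge=charge
        )
        truth_rows.append(
            {"obs_index": len(observations), "species_index": si, "form": form}
        )
        observations.append(obs)

    for si, sp in enumerate(species):
        emit(sp.mass, si, "linked")
        if include_reduced_forms:
            if len(sp.peptides) == 1:
                emit(sp.peptides[0].mass, si, "reduced_a")
            else:
                emit(sp.peptides[0].mass, si, "reduced_a")
                emit(sp.peptides[1].mass, si, "reduced_b")
    params = {
        "mode": "disulfide",
        "ppm_noise": ppm_noise,
        "include_reduced_forms": include_reduced_forms,
        "scramble_pairs": scramble_pairs,
        "charge": charge,
        "seed": seed,
    }
    return DisulfideSimulation(
        observations,
        species,
        pd.DataFrame(truth_rows, columns=["obs_index", "species_index", "form"]),
        effective,
        params,
    )


# ---------------------------------------------------------------------------
# de novo read simulation


@dataclass
class DenovoSimulation:
    tables: dict[str, pd.DataFrame]  # label -> sequence, score, enzyme
    true_masks: dict[str, np.ndarray]
    params: dict


def simulate_denovo_reads(
    record: ProteinRecord,
    enzymes: dict[str, EnzymeSpec],
    coverage_target: float = 1.0,
    score_dist: tuple[float, float] | float = (95.0, 3.0),
    error_rate: float = 0.0,
    seed: int | None = None,
    max_reads_per_enzyme: int | None = None,
) -> DenovoSimulation:
    """Per-enzyme de novo peptide lists with scores and ground-truth masks.

    Reads are digest products sampled with replacement until the achievable
    coverage target is hit; substitution errors are applied per residue at
    ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    letters = sorted(BACKGROUND_FREQUENCIES)
    tables, masks = {}, {}
    for label, enzyme in enzymes.items():
        candidates = digest(record, enzyme)
        mask = np.zeros(len(record), dtype=bool)
        achievable = np.zeros(len(record), dtype=bool)
        for pep in candidates:
            achievable[pep.start - 1 : pep.end] = True
        target = coverage_target * achievable.sum()
        cap = max_reads_per_enzyme or max(20 * len(candidates), 50)
        rows = []
        while candidates and len(rows) < cap and mask.sum() < target:
            pep = candidates[rng.integers(len(candidates))]
            mask[pep.start - 1 : pep.end] = True
            seq = list(pep.sequence)
            if error_rate > 0:
                for i in range(len(seq)):
                    if rng.random() < error_rate:
                        seq[i] = letters[rng.integers(len(letters))]
            if isinstance(score_dist, (int, float)):
                score = float(score_dist)
            else:
                mu, sd = score_dist
                score = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
            rows.append(
                {"sequence": "".join(seq), "score": score, "enzyme": label}
            )
        tables[label] = pd.DataFrame(
            rows, columns=["sequence", "score", "enzyme"]
        )
        masks[label] = mask
    params = {
        "mode": "denovo",
        "coverage_target": coverage_target,
        "error_rate": error_rate,
        "seed": seed,
    }
    return DenovoSimulation(tables, masks, params)


# ---------------------------------------------------------------------------
# table output with parameter sidecars


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> Path:
    """Write a TSV plus a ``<path>.params.json`` sidecar with the params."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(params, indent=2, sort_keys=True))
    return path
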