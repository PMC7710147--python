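import numpy as np
import pandas as pd
import pytest

from cleavekit.coverage import compare_localization
from cleavekit.digestion import ProteinRecord, digest, get_enzyme
from cleavekit.simulate import (
    CleavageModel,
    SimulationError,
    generate_proteome,
    simulate_denovo_reads,
    simulate_disulfide_digest,
    simulate_mechanistic,
    simulate_phosphosites,
    simulate_terminal_composition,
    site_probability,
    terminal_preset,
    write_table,
)


class TestGenerateProteome:
    def test_deterministic(self):
        a = generate_proteome(10, 300, seed=7)
        b = generate_proteome(10, 300, seed=7)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.id for r in a] == [f"SYN{i:04d}" for i in range(1, 11)]

    def test_poly_a(self):
        (record,) = generate_proteome(1, 50, composition={"A": 1.0}, seed=0)
        assert record.sequence == "A" * 50

    def test_656_standin(self):
        (record,) = generate_proteome(1, 656, seed=1)
        assert len(record) == 656

    def test_bad_composition(self):
        with pytest.raises(SimulationError, match="sums to"):
            generate_proteome(1, 10, composition={"A": 0.5}, seed=0)


class TestTerminalPreset:
    @pytest.mark.parametrize("name,p,a", [("pH1_5", 0.49, 0.34),
                                          ("pH2_5", 0.35, 0.30)])
    def test_presets_sum_to_one(self, name, p, a):
        dist = terminal_preset(name)
        assert dist["P"] == pytest.approx(p, abs=1e-9)
        assert dist["A"] == pytest.approx(a, abs=1e-9)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown terminal preset"):
            terminal_preset("pH9")


@pytest.fixture(scope="module")
def proteome():
    return generate_proteome(200, 500, seed=42)


@pytest.fixture(scope="module")
def sty_record():
    return generate_proteome(1, 2000, seed=9)[0]


class TestTerminalComposition:
    def test_point_mass_preset(self, proteome):
        table = simulate_terminal_composition(
            proteome, {"P": 1.0}, 200, seed=1
        )
        assert (table["sequence"].str[-1] == "P").all()

    def test_ph15_within_three_sigma(self, proteome):
        table = simulate_terminal_composition(proteome, "pH1_5", 5000, seed=42)
        frac = (table["sequence"].str[-1] == "P").mean()
        sigma = np.sqrt(0.49 * 0.51 / 5000)
        assert abs(frac - 0.49) < 3 * sigma + 0.01  # + uniqueness slack

    def test_deterministic(self, proteome):
        a = simulate_terminal_composition(proteome, "pH1_5", 300, seed=5)
        b = simulate_terminal_composition(proteome, "pH1_5", 300, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unique_sequences_by_default(self, proteome):
        table = simulate_terminal_composition(proteome, "pH1_5", 1000, seed=3)
        assert table["sequence"].is_unique

    def test_missing_residue_errors(self):
        (record,) = generate_proteome(1, 100, composition={"G": 1.0}, seed=0)
        with pytest.raises(SimulationError, match="absent"):
            simulate_terminal_composition([record], {"P": 1.0}, 100, seed=0)

    def test_small_n_rejected(self, proteome):
        with pytest.raises(SimulationError, match=">= 100"):
            simulate_terminal_composition(proteome, "pH1_5", 50, seed=0)

    def test_kl_divergence_small_at_50k(self):
        proteome = generate_proteome(500, 500, seed=11)
        table = simulate_terminal_composition(
            proteome, "pH1_5", 50_000, seed=11, allow_duplicates=True
        )
        dist = terminal_preset("pH1_5")
        emp = table["sequence"].str[-1].value_counts(normalize=True)
        kl = sum(
            q * np.log(q / dist[aa]) for aa, q in emp.items() if dist[aa] > 0
        )
        assert 0 <= kl < 0.01


class TestMechanistic:
    def test_all_probabilities_one_reduces_to_digest(self):
        proteome = generate_proteome(5, 200, seed=3)
        model = CleavageModel(
            base_prob={"P": 1.0, "A": 1.0},
            context_multipliers=(),
            detectable_len=(1, 100),
        )
        enzyme = get_enzyme("proalanase", max_missed=0, min_len=1, max_len=100)
        for record in proteome:
            result = simulate_mechanistic([record], model, seed=0)
            expected = {
                (p.start, p.end) for p in digest(record, enzyme)
            }
            got = set(
                zip(result.peptides["start"], result.peptides["end"])
            )
            assert got == expected

    def test_ground_truth_ratios(self):
        proteome = generate_proteome(40, 500, seed=7)
        model = CleavageModel(context_multipliers=())
        result = simulate_mechanistic(proteome, model, seed=7)
        sites = result.sites
        p_sites = sites[sites["residue"] == "P"]
        a_sites = sites[sites["residue"] == "A"]
        assert len(p_sites) >= 300 and len(a_sites) >= 300
        p_ratio = p_sites["cleaved"].sum() / (~p_sites["cleaved"]).sum()
        a_ratio = (~a_sites["cleaved"]).sum() / a_sites["cleaved"].sum()
        assert p_ratio == pytest.approx(2.0, rel=0.15)
        assert a_ratio == pytest.approx(2.0, rel=0.15)

    def test_context_multiplier_changes_probability(self):
        model = CleavageModel()
        # +2 (P2') basophilic residue halves P-site probability
        assert site_probability("GPAK", 2, model) == pytest.approx(2 / 3 / 2)
        assert site_probability("GPAG", 2, model) == pytest.approx(2 / 3)
        # -2 (P2) basophilic residue doubles A-site probability
        assert site_probability("KAGG", 2, model) == pytest.approx(2 / 3)
        assert site_probability("GAGG", 2, model) == pytest.approx(1 / 3)

    def test_probability_clipped(self):
        model = CleavageModel(
            base_prob={"A": 0.9},
            context_multipliers=(
                CleavageModel().context_multipliers[1].__class__(
                    frozenset("A"), -2, frozenset("K"), 5.0
                ),
            ),
        )
        assert site_probability("KAGG", 2, model) == 1.0

    def test_detectable_length_filter(self):
        proteome = generate_proteome(10, 300, seed=1)
        result = simulate_mechanistic(
            proteome, CleavageModel(context_multipliers=()), seed=1
        )
        lengths = result.peptides["sequence"].str.len()
        assert lengths.between(7, 35).all()

    def test_invalid_model(self):
        with pytest.raises(SimulationError):
            CleavageModel(base_prob={"P": 1.5})
        with pytest.raises(SimulationError):
            CleavageModel(detectable_len=(0, 35))


class TestPhosphosites:
    def test_full_observability_identical_sites(self, sty_record):
        result = simulate_phosphosites(
            sty_record, 50,
            per_enzyme_observability={"A": 1.0, "B": 1.0},
            seed=2,
        )
        assert list(result.tables["A"]["position"]) == result.true_positions
        assert list(result.tables["B"]["position"]) == result.true_positions

    def test_point_mass_all_class1(self, sty_record):
        result = simulate_phosphosites(
            sty_record, 30, loc_prob_dists={"A": 1.0, "B": 1.0}, seed=3
        )
        for table in result.tables.values():
            assert (table["localization_probability"] >= 0.75).all()

    def test_default_betas_separate_at_n200(self, sty_record):
        result = simulate_phosphosites(sty_record, 200, seed=4)
        stats = compare_localization(result.tables["A"], result.tables["B"])
        assert stats["mean_a"] > stats["mean_b"]
        assert stats["p_value"] < 0.05

    def test_too_many_sites(self):
        record = ProteinRecord(id="g", sequence="GGGGSGGG")
        with pytest.raises(SimulationError, match="cannot place"):
            simulate_phosphosites(record, 5, seed=0)


def _two_chain_fixture():
    heavy = ProteinRecord(
        id="chainH", sequence="GGCGKP" + "GCGCGA" + "GGCGRP" + "GGKGGW"
    )
    light = ProteinRecord(id="chainL", sequence="GGCGMP" + "GGCGFA")
    connectivity = [
        (("chainH", 3), ("chainL", 3)),
        (("chainH", 15), ("chainL", 9)),
        (("chainH", 8), ("chainH", 10)),
    ]
    return [heavy, light], connectivity


class TestDisulfideSimulation:
    def test_noiseless_masses_exact(self):
        chains, connectivity = _two_chain_fixture()
        enzyme = get_enzyme("proalanase")
        result = simulate_disulfide_digest(
            chains, connectivity, enzyme, ppm_noise=0.0, seed=0
        )
        for row in result.truth.to_dict("records"):
            species = result.species[row["species_index"]]
            obs = result.observations[row["obs_index"]]
            if row["form"] == "linked":
                total = sum(cp.mass for cp in species.peptides)
                expected = total - 2.015650 * species.n_bonds
                assert obs.neutral_mass == pytest.approx(expected, abs=1e-5)

    def test_isr_triads_have_three_masses(self):
        chains, connectivity = _two_chain_fixture()
        result = simulate_disulfide_digest(
            chains, connectivity, get_enzyme("proalanase"),
            include_reduced_forms=True, seed=0,
        )
        counts = result.truth.groupby("species_index")["form"].count()
        for si, species in enumerate(result.species):
            expected = 3 if len(species.peptides) == 2 else 2
            assert counts[si] == expected

    def test_reproducible(self):
        chains, connectivity = _two_chain_fixture()
        kwargs = dict(ppm_noise=3.0, include_reduced_forms=True, seed=5)
        a = simulate_disulfide_digest(
            chains, connectivity, get_enzyme("proalanase"), **kwargs
        )
        b = simulate_disulfide_digest(
            chains, connectivity, get_enzyme("proalanase"), **kwargs
        )
        assert [o.mz for o in a.observations] == [o.mz for o in b.observations]


class TestDenovoSimulation:
    def test_error_free_reads_are_substrings(self):
        (record,) = generate_proteome(1, 400, seed=6)
        result = simulate_denovo_reads(
            record,
            {"proalanase": get_enzyme("proalanase", max_missed=2, min_len=7)},
            error_rate=0.0,
            seed=6,
        )
        for seq in result.tables["proalanase"]["sequence"]:
            assert seq in record.sequence

    def test_scores_bounded(self):
        (record,) = generate_proteome(1, 300, seed=8)
        result = simulate_denovo_reads(
            record,
            {"tryp": get_enzyme("trypsin_p", min_len=7)},
            score_dist=(95.0, 10.0),
            seed=8,
        )
        scores = result.tables["tryp"]["score"]
        assert scores.between(0, 100).all()

    def test_reproducible(self):
        (record,) = generate_proteome(1, 300, seed=9)
        enzymes = {"pa": get_enzyme("proalanase", max_missed=1, min_len=7)}
        a = simulate_denovo_reads(record, enzymes, seed=9)
        b = simulate_denovo_reads(record, enzymes, seed=9)
        pd.testing.assert_frame_equal(a.tables["pa"], b.tables["pa"])


def test_write_table_emits_sidecar(tmp_path):
    df = pd.DataFrame({"sequence": ["AAP", "KGP"]})
    path = write_table(df, tmp_path / "peps.tsv", {"seed": 1, "mode": "x"})
    assert path.exists()
    sidecar = tmp_path / "peps.tsv.params.json"
    assert sidecar.exists()
    assert '"seed": 1' in sidecar.read_text()
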