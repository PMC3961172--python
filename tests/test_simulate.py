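"""Forward pedigree simulation: transmission, ascertainment, recovery of the
analytic inter-lineage relative risks."""

import json
import math

import numpy as np
import pytest

from famasym.asymmetry import read_family_history, tabulate, discordant_or
from famasym.mechanisms import (
    ImprintingModel,
    MaternalEffectModel,
    interlineage_rr,
    sibling_rr,
)
from famasym.simulate import (
    Pedigree,
    SimConfig,
    ascertain,
    ascertainment_mask,
    empirical_rr,
    halfsib_recurrence_sim,
    lineage_pair_counts,
    simulate,
    write_outputs,
)


def _log_or_and_se(a, b):
    return math.log(a / b), math.sqrt(1 / a + 1 / b)


class TestConfigValidation:
    def test_unknown_mechanism(self):
        with pytest.raises(ValueError):
            SimConfig(mechanism="telepathic")

    def test_effect_parameters_required(self):
        with pytest.raises(ValueError):
            SimConfig(mechanism="maternal_effect", q=0.2)
        with pytest.raises(ValueError):
            SimConfig(mechanism="imprinting")
        with pytest.raises(ValueError):
            SimConfig(mechanism="mitochondrial")

    def test_penetrance_overflow(self):
        with pytest.raises(ValueError, match="overflow"):
            SimConfig(mechanism="maternal_effect", q=0.2, s1=4, f=0.1)

    def test_log_additive_default(self):
        cfg = SimConfig(mechanism="maternal_effect", q=0.2, s1=3)
        assert cfg.s2 == 9.0


class TestTransmission:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(mechanism="maternal_effect", q=0.2, s1=4,
                        n_families=2000, seed=42)
        c1, c2 = simulate(cfg), simulate(cfg)
        for role in cfg.roles:
            assert np.array_equal(c1.affected[role], c2.affected[role])
            assert np.array_equal(c1.mat[role], c2.mat[role])

    def test_every_generation_stays_in_hwe(self):
        """Random mating preserves HWE in each simulated tier."""
        q = 0.3
        cfg = SimConfig(mechanism="null", q=q, n_families=200_000, seed=1)
        cohort = simulate(cfg)
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        for role in ("MMM", "MM", "M", "F", "S1", "S2"):
            g = cohort.genotype(role)
            freqs = np.bincount(g, minlength=3) / len(cohort)
            assert freqs == pytest.approx(hwe, abs=5e-3)

    def test_alleles_trace_to_parents(self):
        cfg = SimConfig(mechanism="null", q=0.5, n_families=5000, seed=3)
        cohort = simulate(cfg)
        # the child's maternal allele must be one the mother carries
        mother_has = cohort.mat["M"] | cohort.pat["M"]
        assert np.all(~cohort.mat["S1"] | mother_has)
        mother_lacks_both = ~cohort.mat["M"] & ~cohort.pat["M"]
        assert not np.any(cohort.mat["S1"] & mother_lacks_both)

    def test_mitochondria_follow_the_matriline(self):
        cfg = SimConfig(mechanism="mitochondrial", r_mito=1.3,
                        n_families=5000, seed=4)
        cohort = simulate(cfg)
        assert np.array_equal(cohort.mito["S1"], cohort.mito["MMM"])
        assert np.array_equal(cohort.mito["S2"], cohort.mito["M"])
        assert np.array_equal(cohort.mito["F"], cohort.mito["FM"])


class TestAscertainment:
    def test_schemes_partition_families(self):
        cfg = SimConfig(mechanism="null", f=0.3, n_families=20_000, seed=5)
        cohort = simulate(cfg)
        proband = ascertainment_mask(cohort, "proband")
        sister = ascertainment_mask(cohort, "sister_study")
        s1, s2 = cohort.affected["S1"], cohort.affected["S2"]
        assert np.array_equal(proband, s1 | s2)
        # all-affected sibships are in under proband, out under sister_study
        all_aff = s1 & s2
        assert all_aff.any()
        assert not np.any(sister & all_aff)
        assert np.array_equal(sister, (s1 | s2) & ~(s1 & s2))

    def test_null_ascertained_fraction_matches_binomial(self):
        f = 0.05
        cfg = SimConfig(mechanism="null", f=f, n_families=100_000, seed=6)
        cohort = simulate(cfg)
        frac = ascertainment_mask(cohort, "sister_study").mean()
        expected = 2 * f * (1 - f)
        se = math.sqrt(expected * (1 - expected) / len(cohort))
        assert abs(frac - expected) < 4 * se

    def test_sister_scheme_needs_two_sisters(self):
        cfg = SimConfig(mechanism="null", n_sisters=1, ascertainment="proband",
                        n_families=100, seed=0)
        cohort = simulate(cfg)
        with pytest.raises(ValueError, match="two sisters"):
            ascertainment_mask(cohort, "sister_study")

    def test_records_carry_grandparent_flags(self):
        cfg = SimConfig(mechanism="null", f=0.2, n_families=2000, seed=7)
        cohort = simulate(cfg)
        records = ascertain(cohort, "sister_study")
        mask = ascertainment_mask(cohort, "sister_study")
        assert len(records) == int(mask.sum())
        idx = int(np.flatnonzero(mask)[0])
        rec = records[0]
        assert rec.family_id == f"fam{idx}"
        assert rec.mm_affected == int(cohort.affected["MM"][idx])
        assert rec.ff_affected == int(cohort.affected["FF"][idx])

    def test_materialized_pedigrees_accepted_and_checked(self):
        cfg = SimConfig(mechanism="null", f=0.5, n_families=30, seed=8)
        cohort = simulate(cfg)
        peds = [cohort[i] for i in range(len(cohort))]
        assert len(ascertain(peds, "proband")) == int(
            ascertainment_mask(cohort, "proband").sum()
        )
        broken = Pedigree(
            family_id="x",
            members={k: v for k, v in peds[0].members.items() if k != "MM"},
        )
        with pytest.raises(ValueError, match="lacks grandparent"):
            ascertain([broken], "proband")


class TestAnalyticRecovery:
    """Ascertained discordant ORs track the analytic predictions.

    Sizes here are kept moderate; assertions use 3 Monte Carlo standard
    errors from realized counts.
    """

    def test_null_mechanism_is_symmetric(self):
        cfg = SimConfig(mechanism="null", n_families=200_000, seed=9)
        a, b = lineage_pair_counts(simulate(cfg))
        log_or, se = _log_or_and_se(a, b)
        assert abs(log_or) < 3 * se

    def test_maternal_effect_grandmother_or(self):
        cfg = SimConfig(mechanism="maternal_effect", q=0.2, s1=4,
                        n_families=500_000, seed=10)
        a, b = lineage_pair_counts(simulate(cfg))
        log_or, se = _log_or_and_se(a, b)
        target = math.log(interlineage_rr(MaternalEffectModel(0.2, 4), 2))
        assert abs(log_or - target) < 3 * se

    def test_retrospective_parent_rr_matches_analytic(self):
        cfg = SimConfig(mechanism="maternal_effect", q=0.2, s1=4, f=0.05,
                        n_families=300_000, seed=11)
        est = empirical_rr(simulate(cfg), "parent", "retrospective")
        target = interlineage_rr(MaternalEffectModel(0.2, 4), 1)
        assert abs(math.log(est.value) - math.log(target)) < 3 * est.se_log

    def test_result1_grandparent_directions_agree(self):
        """Looking up (grandmothers of cases) and down (grandchildren of
        affected grandmothers) give the same inter-lineage RR."""
        cfg = SimConfig(mechanism="imprinting", q=0.2, i_rr=5, f=0.05,
                        n_families=300_000, seed=12)
        cohort = simulate(cfg)
        retro = empirical_rr(cohort, "grandparent", "retrospective")
        prosp = empirical_rr(cohort, "grandparent", "prospective")
        gap_se = math.hypot(retro.se_log, prosp.se_log)
        assert abs(math.log(retro.value) - math.log(prosp.value)) < 3 * gap_se

    def test_son_relationship_unsupported(self):
        cfg = SimConfig(mechanism="null", n_families=100, seed=0)
        with pytest.raises(ValueError, match="son"):
            empirical_rr(simulate(cfg), "son", "prospective")

    def test_paternity_errors_attenuate_paternal_line_signal(self):
        """With a paternally expressed imprinted locus the asymmetry runs
        through the father link, so misattributed paternity pulls the
        grandmother OR toward 1."""
        totals = {0.0: [0, 0], 0.2: [0, 0]}
        for seed in (21, 22, 23):
            for rate in totals:
                cfg = SimConfig(
                    mechanism="imprinting", q=0.2, i_rr=10,
                    expressed_copy="paternal", f=0.05,
                    paternity_error_rate=rate, n_families=300_000, seed=seed,
                )
                a, b = lineage_pair_counts(simulate(cfg))
                totals[rate][0] += a
                totals[rate][1] += b
        log_clean = math.log(totals[0.0][0] / totals[0.0][1])
        log_noisy = math.log(totals[0.2][0] / totals[0.2][1])
        assert log_clean < 0  # excess on the paternal side
        assert abs(log_noisy) < abs(log_clean)

    def test_half_sibling_pattern_under_maternal_effect(self):
        model = MaternalEffectModel(q=0.2, s1=4)
        full = sibling_rr(model, "full")
        for rel, target in [
            ("full", full), ("maternal_half", full), ("paternal_half", 1.0),
        ]:
            est = halfsib_recurrence_sim(
                q=0.2, s1=4, f=0.05, relationship=rel,
                n_pairs=400_000, seed=13,
            )
            assert abs(math.log(est.value) - math.log(target)) < 3 * est.se_log


class TestOutputs:
    def test_round_trip_family_history(self, tmp_path):
        cfg = SimConfig(mechanism="null", f=0.2, n_families=500, seed=14)
        cohort = simulate(cfg)
        records = ascertain(cohort)
        paths = write_outputs(cohort, records, tmp_path / "run")
        read_back = read_family_history(paths["family_history"])
        assert [r.family_id for r in read_back] == [r.family_id for r in records]
        assert [r.mm_affected for r in read_back] == [r.mm_affected for r in records]
        a = sum(r.grandmother_discordant and r.mm_affected for r in read_back)
        b = sum(r.grandmother_discordant and r.fm_affected for r in read_back)
        table = tabulate(read_back, ["all"])
        assert (a, b) == (
            int(table.counts.loc["all", "n_maternal_only"]),
            int(table.counts.loc["all", "n_paternal_only"]),
        )
        if a and b:
            discordant_or(a, b)  # parseable end to end

    def test_ped_file_lists_parents_before_children(self, tmp_path):
        cfg = SimConfig(mechanism="null", n_families=5, seed=15)
        cohort = simulate(cfg)
        paths = write_outputs(cohort, ascertain(cohort), tmp_path / "run")
        seen = set()
        for line in paths["pedigrees"].read_text().splitlines():
            fam, iid, father, mother, sex, pheno, geno = line.split("\t")
            for parent in (father, mother):
                if parent != "0":
                    assert parent in seen, f"{parent} referenced before defined"
            seen.add(iid)
            assert sex in ("1", "2")
            assert int(geno) in (0, 1, 2)

    def test_manifest_reflects_config(self, tmp_path):
        cfg = SimConfig(mechanism="mitochondrial", r_mito=1.3,
                        n_families=50, seed=77)
        cohort = simulate(cfg)
        paths = write_outputs(cohort, ascertain(cohort), tmp_path / "run")
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 77
        assert manifest["config"]["mechanism"] == "mitochondrial"
        assert manifest["n_families"] == 50


class TestPedigreeMaterialization:
    def test_individual_fields_consistent_with_arrays(self):
        cfg = SimConfig(mechanism="maternal_effect", q=0.3, s1=2,
                        n_families=50, seed=16)
        cohort = simulate(cfg)
        ped = cohort[7]
        for role in cfg.roles:
            ind = ped[role]
            assert ind.genotype == int(cohort.genotype(role)[7])
            assert ind.affected == bool(cohort.affected[role][7])
        assert ped["S1"].mother_id == "fam7_M"
        assert ped["M"].mother_id == "fam7_MM"
        assert ped["MMM"].mother_id is None
        assert ped["MMM"].founder_mother_genotype in (0, 1, 2)
        assert ped["MM"].founder_mother_genotype is None
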