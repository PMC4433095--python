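"""Multi-breed simulator: drift model, family structure, architectures."""

import numpy as np
import pandas as pd
import pytest

from bayesalphabet.qc import encode_centered_ten
from bayesalphabet.simulate import (
    BreedSpec,
    FamilyStructure,
    TraitArchitecture,
    assign_qtl_effects,
    default_cg_design,
    inject_missingness,
    qtl_variance_shares,
    simulate_breed_frequencies,
    simulate_dataset,
    simulate_phenotypes,
    simulate_population,
)


def _breed(name, n, F=0.1, ancestry=None):
    return BreedSpec(name, n, ancestry or {name: 1.0}, divergence=F)


def pairwise_fst(freqs: pd.DataFrame, breeds) -> float:
    """Hudson-style two-population F_ST averaged over SNPs and breed pairs
    (independent re-computation from the generated table)."""
    cols = [b.name for b in breeds]
    vals = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            p1, p2 = freqs[cols[i]].to_numpy(), freqs[cols[j]].to_numpy()
            num = (p1 - p2) ** 2
            den = p1 * (1 - p2) + p2 * (1 - p1)
            vals.append(np.mean(num / den))
    return float(np.mean(vals))


class TestBreedFrequencies:
    def test_no_drift_identity(self):
        breeds = [_breed("A", 10, F=0.0), _breed("B", 10, F=0.0)]
        fq = simulate_breed_frequencies(50, breeds, seed=1)
        assert np.array_equal(fq["A"], fq["ancestral"])
        assert np.array_equal(fq["B"], fq["ancestral"])

    def test_fst_matches_divergence(self):
        breeds = [_breed(f"B{i}", 10, F=0.1) for i in range(5)]
        fq = simulate_breed_frequencies(1000, breeds, seed=7)
        # Balding-Nichols: E[(p1-p2)^2] = 2 F p0 q0; pairwise F_ST ~ F
        assert pairwise_fst(fq, breeds) == pytest.approx(0.1, abs=0.03)

    def test_deterministic(self):
        breeds = [_breed("A", 5)]
        a = simulate_breed_frequencies(100, breeds, seed=3)
        b = simulate_breed_frequencies(100, breeds, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_f_one_rejected(self):
        with pytest.raises(ValueError):
            BreedSpec("A", 5, {"A": 1.0}, divergence=1.0)

    def test_bad_ancestry_weights(self):
        with pytest.raises(ValueError, match="sum"):
            BreedSpec("A", 5, {"A": 0.7})


class TestPopulation:
    def test_family_fractions_near_targets(self):
        fam = FamilyStructure(0.37, 0.45)
        breeds = [_breed("Angus", 3240)]
        fq = simulate_breed_frequencies(10, breeds, seed=1)
        _, ped = simulate_population(breeds, fam, fq, seed=2)
        sizes = ped.groupby("sire_id").size()
        assert (sizes == 1).mean() == pytest.approx(0.37, abs=0.05)
        assert sizes[sizes <= 10].sum() / sizes.sum() == pytest.approx(0.45, abs=0.05)

    def test_pure_ancestry_recovers_frequencies(self):
        # dam ancestry = sire breed, F = 0: progeny frequency ~ ancestral
        breeds = [BreedSpec("X", 3000, {"X": 1.0}, divergence=0.0)]
        fq = simulate_breed_frequencies(80, breeds, seed=11)
        gm, _ = simulate_population(breeds, FamilyStructure(), fq, seed=12)
        p_hat = gm.allele_frequencies()
        p0 = fq["X"].to_numpy()
        # 4 binomial SE of the mean frequency (half-sib correlation inflates
        # the effective SE; bound is conservative by construction)
        se = 4.0 * np.sqrt(p0 * (1 - p0) / (2 * gm.n_animals))
        frac_inside = np.mean(np.abs(p_hat - p0) <= se)
        assert frac_inside > 0.9

    def test_empty_breed_absent(self):
        breeds = [_breed("A", 200), _breed("B", 0)]
        fq = simulate_breed_frequencies(10, breeds, seed=1)
        gm, ped = simulate_population(breeds, FamilyStructure(), fq, seed=3)
        assert set(ped["breed"]) == {"A"}
        assert gm.n_animals == 200

    def test_missing_frequency_column_rejected(self):
        breeds = [_breed("A", 10, ancestry={"A": 0.5, "Ghost": 0.5})]
        fq = simulate_breed_frequencies(10, [_breed("A", 10)], seed=1)
        with pytest.raises(ValueError, match="Ghost"):
            simulate_population(breeds, FamilyStructure(), fq, seed=1)

    def test_infeasible_sire_count(self):
        breeds = [BreedSpec("A", 5, {"A": 1.0}, n_sires=10)]
        fq = simulate_breed_frequencies(5, breeds, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_population(breeds, FamilyStructure(), fq, seed=1)


@pytest.fixture(scope="module")
def small_population():
    breeds = [_breed("Angus", 600), _breed("Hereford", 600)]
    fq = simulate_breed_frequencies(400, breeds, seed=21)
    gm, ped = simulate_population(breeds, FamilyStructure(), fq, seed=22)
    return gm, ped


class TestQTLEffects:
    def test_h2_recovered_infinitesimal(self, small_population):
        gm, ped = small_population
        gm = gm.copy()
        arch = TraitArchitecture(n_qtl=400, target_h2=0.26)
        alpha, g = assign_qtl_effects(arch, gm, seed=31)
        pheno = simulate_phenotypes(g, arch, default_cg_design(ped, 32), seed=33)
        ve = pheno.attrs["ve"]
        h2_emp = g.var() / (g.var() + ve)
        assert h2_emp == pytest.approx(0.26, abs=0.02)

    def test_large_effect_share(self, small_population):
        gm, _ = small_population
        gm = gm.copy()
        arch = TraitArchitecture(
            n_qtl=50, target_h2=0.4, effect_dist="mixture",
            large_effect_fraction_of_vg=0.25,
        )
        alpha, g = assign_qtl_effects(arch, gm, seed=41)
        shares = qtl_variance_shares(alpha, gm)
        assert shares.max() == pytest.approx(0.25, abs=0.05)

    def test_null_architecture(self, small_population):
        gm, _ = small_population
        arch = TraitArchitecture(n_qtl=0, target_h2=0.3)
        alpha, g = assign_qtl_effects(arch, gm.copy(), seed=1)
        assert not alpha.any() and not g.any()

    def test_breed_specific_contract(self, small_population):
        gm, _ = small_population
        gm = gm.copy()
        arch = TraitArchitecture(
            n_qtl=10, target_h2=0.3, breed_specific_qtl=[(3, "Angus")]
        )
        assign_qtl_effects(arch, gm, seed=51)
        in_breed = gm.breed == "Angus"
        col = gm.dosages[:, 3]
        p_in = col[in_breed].sum() / (2 * in_breed.sum())
        assert min(p_in, 1 - p_in) >= 0.05
        assert np.all(col[~in_breed] == 0.0)

    def test_breed_specific_impossible(self, small_population):
        gm, _ = small_population
        arch = TraitArchitecture(
            n_qtl=5, target_h2=0.3, breed_specific_qtl=[(0, "Brahman")]
        )
        with pytest.raises(ValueError, match="no animals"):
            assign_qtl_effects(arch, gm.copy(), seed=1)


class TestPhenotypes:
    def test_noise_free_limit(self, small_population):
        gm, ped = small_population
        gm = gm.copy()
        arch = TraitArchitecture(n_qtl=50, target_h2=1.0, cg_effect_sd=0.0)
        _, g = assign_qtl_effects(arch, gm, seed=61)
        pheno = simulate_phenotypes(g, arch, default_cg_design(ped, 62), seed=63, mu=4.4)
        assert np.allclose(pheno["y"] - 4.4, g)

    def test_regression_slope_one(self, small_population):
        gm, ped = small_population
        gm = gm.copy()
        arch = TraitArchitecture(n_qtl=200, target_h2=0.26, cg_effect_sd=0.0)
        _, g = assign_qtl_effects(arch, gm, seed=71)
        pheno = simulate_phenotypes(g, arch, default_cg_design(ped, 72), seed=73)
        slope = np.polyfit(g, pheno["y"].to_numpy(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_shared_cg_effect(self, small_population):
        gm, ped = small_population
        arch = TraitArchitecture(n_qtl=0, target_h2=0.0, cg_effect_sd=1.0)
        design = default_cg_design(ped, 82)
        pheno = simulate_phenotypes(np.zeros(gm.n_animals), arch, design, seed=83)
        per_group = pheno.groupby("cg", observed=True)["cg_true"].nunique()
        assert (per_group == 1).all()

    def test_h2_zero_with_signal_rejected(self, small_population):
        gm, ped = small_population
        arch = TraitArchitecture(n_qtl=0, target_h2=0.0)
        with pytest.raises(ValueError, match="undefined"):
            simulate_phenotypes(
                np.ones(gm.n_animals), arch, default_cg_design(ped, 1), seed=1
            )


class TestMissingness:
    def test_zero_rate_empty_mask(self, small_population):
        gm, _ = small_population
        out = inject_missingness(gm, 0.0, 0.0, seed=1)
        assert out.n_missing == 0

    def test_study_rate_realized(self):
        gm = simulate_dataset(
            TraitArchitecture(n_qtl=10, target_h2=0.3),
            n_snps=500,
            breeds=[_breed("A", 400)],
            seed=5,
            missing_rate=0.0,
        )[0]
        out = inject_missingness(gm, 0.0089, 0.0, seed=9)
        realized = out.n_missing / out.mask.size
        assert realized == pytest.approx(0.0089, abs=0.002)

    def test_mask_deterministic_and_nondestructive(self, small_population):
        gm, _ = small_population
        a = inject_missingness(gm, 0.05, 0.01, seed=4)
        b = inject_missingness(gm, 0.05, 0.01, seed=4)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.dosages, gm.dosages)
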