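"""Multi-breed crossbred population and trait simulator.

Emulates the statistical structure of a commercial multi-breed beef
population: purebred sires of several breeds mated to commercial dams of
mixed ancestry, singleton-heavy paternal half-sib families, contemporary
groups formed as herd x breed x sex x harvest-date cells, and trait
architectures ranging from infinitesimal (every SNP causal, Gaussian
effects) to oligogenic with breed-specific large-effect QTL.

Breed divergence follows the Balding-Nichols model: each SNP has an
ancestral frequency p0 ~ Uniform(0.05, 0.95) and each breed draws its
frequency from Beta(p0 (1-F)/F, (1-p0)(1-F)/F), so F is Wright's
fixation-index analogue of drift since the breeds split.  SNPs are
simulated unlinked; the regression models fitted downstream ignore map
positions, so no linkage map is needed.

Family sizes are drawn from a zero-truncated negative binomial whose two
parameters are solved so that the singleton-sire fraction and the fraction
of animals in small (<= 10 progeny) families hit their targets; defaults
reproduce the study-population structure (37% singleton sire groups, 45%
of animals in families of <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

__version_tag__ = "bayesalphabet-sim-1"

#: Default sire-breed composition mirroring a five-breed commercial
#: carcass-merit population (post-QC progeny counts).  British-breed sires
#: are mated to dams of mostly their own ancestry; Continental sires to
#: commercial cows of high Angus percentage.
DEFAULT_BREEDS = None  # filled below, needs BreedSpec


@dataclass
class BreedSpec:
    """One sire breed in the crossing design.

    ``dam_ancestry`` gives the gamete-level mixture weights over breed
    allele-frequency columns for the commercial dam population; weights must
    sum to 1.  ``divergence`` is the Balding-Nichols F (0 <= F < 1).
    ``n_sires`` may be None, in which case the number of sires emerges from
    the family-size distribution.
    """

    name: str
    n_progeny: int
    dam_ancestry: dict
    divergence: float = 0.05
    n_sires: int | None = None

    def __post_init__(self):
        if self.n_progeny < 0 or (self.n_sires is not None and self.n_sires < 0):
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence F must satisfy 0 <= F < 1")
        total = sum(self.dam_ancestry.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dam_ancestry weights sum to {total}, expected 1")


def _default_breeds() -> list[BreedSpec]:
    british = lambda b: {b: 0.75, "Angus": 0.25} if b != "Angus" else {"Angus": 1.0}
    continental = lambda b: {b: 0.5, "Angus": 0.5}
    return [
        BreedSpec("Angus", 651, british("Angus")),
        BreedSpec("Charolais", 695, continental("Charolais")),
        BreedSpec("Hereford", 1095, british("Hereford")),
        BreedSpec("Limousin", 283, continental("Limousin")),
        BreedSpec("Simmental", 516, continental("Simmental")),
    ]


@dataclass
class FamilyStructure:
    """Paternal half-sib family-size targets.

    ``singleton_sire_fraction``: fraction of sires with exactly one progeny.
    ``small_family_fraction``: fraction of animals in families of <= 10.
    ``max_family_size`` caps single draws (repair, not rejection).
    """

    singleton_sire_fraction: float = 0.37
    small_family_fraction: float = 0.45
    max_family_size: int = 200

    def __post_init__(self):
        for name in ("singleton_sire_fraction", "small_family_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.max_family_size < 1:
            raise ValueError("max_family_size must be >= 1")


@dataclass
class TraitArchitecture:
    """Genetic architecture of a simulated trait.

    ``n_qtl`` loci receive nonzero effects; ``effect_dist`` is "gaussian"
    (equal-variance effects) or "mixture" (point-mass mixture with a
    designated large-effect component carrying
    ``large_effect_fraction_of_vg`` of the genetic variance).
    ``breed_specific_qtl`` lists (locus index, breed name) pairs forced to
    segregate (MAF >= 0.05) only in the named breed.  ``target_h2`` is the
    narrow-sense heritability on a unit-phenotypic-variance scale;
    ``cg_effect_sd`` the contemporary-group effect SD in trait units.
    """

    n_qtl: int
    target_h2: float
    effect_dist: str = "gaussian"
    large_effect_fraction_of_vg: float = 0.0
    breed_specific_qtl: list = field(default_factory=list)
    cg_effect_sd: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 outside [0, 1]")
        if not 0.0 <= self.large_effect_fraction_of_vg <= 1.0:
            raise ValueError("large_effect_fraction_of_vg outside [0, 1]")
        if self.effect_dist not in ("gaussian", "mixture"):
            raise ValueError("effect_dist must be 'gaussian' or 'mixture'")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")


# ---------------------------------------------------------------------------
# allele frequencies


def simulate_breed_frequencies(
    n_snps: int, breeds: list[BreedSpec], seed: int
) -> pd.DataFrame:
    """Per-breed allele-frequency table under the Balding-Nichols model.

    Returns a DataFrame indexed by SNP id with an ``ancestral`` column (p0)
    and one column per breed.  F = 0 breeds copy p0 exactly.  Frequencies
    are clipped to (0.0001, 0.9999) to stay inside the open interval.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    table = {"ancestral": p0}
    for spec in breeds:
        F = spec.divergence
        if F == 0.0:
            table[spec.name] = p0.copy()
        else:
            a = p0 * (1.0 - F) / F
            b = (1.0 - p0) * (1.0 - F) / F
            table[spec.name] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)
    idx = [f"SNP{j:06d}" for j in range(n_snps)]
    return pd.DataFrame(table, index=pd.Index(idx, name="snp_id"))


# ---------------------------------------------------------------------------
# family sizes


_FAMILY_NB_R = 0.4  # shape of the non-singleton family-size tail


@lru_cache(maxsize=8)
def _family_params(singleton: float, small: float, cap: int) -> float:
    """Solve the NB success probability of the singleton-inflated family
    model: P(X = 1) = ``singleton`` exactly; X | X >= 2 follows a negative
    binomial truncated to [2, cap]; p is chosen so the fraction of animals
    in families of <= 10 equals ``small``."""
    x = np.arange(2, max(cap, 11) + 1)

    def small_frac(p):
        q = stats.nbinom.pmf(x, _FAMILY_NB_R, p)
        q = q / q.sum()
        m2 = (x * q).sum()
        small_mass = (x[x <= 10] * q[x <= 10]).sum()
        num = singleton * 1.0 + (1.0 - singleton) * small_mass
        den = singleton * 1.0 + (1.0 - singleton) * m2
        return num / den

    lo, hi = 1e-4, 0.95
    f_lo, f_hi = small_frac(lo), small_frac(hi)
    if not f_lo <= small <= f_hi:
        raise ValueError(
            f"infeasible family constraints: singleton={singleton}, "
            f"small_family={small} (reachable range "
            f"[{f_lo:.3f}, {f_hi:.3f}])"
        )
    return float(optimize.brentq(lambda p: small_frac(p) - small, lo, hi))


def _family_sizes(n_progeny: int, family: FamilyStructure, rng) -> np.ndarray:
    """Draw half-sib family sizes summing exactly to ``n_progeny``."""
    if n_progeny == 0:
        return np.array([], dtype=int)
    p = _family_params(
        family.singleton_sire_fraction,
        family.small_family_fraction,
        family.max_family_size,
    )
    sizes = []
    total = 0
    while total < n_progeny:
        if rng.random() < family.singleton_sire_fraction:
            x = 1
        else:
            x = 0
            while not 2 <= x <= family.max_family_size:
                x = int(rng.negative_binomial(_FAMILY_NB_R, p))
        x = min(x, n_progeny - total)
        sizes.append(x)
        total += x
    return np.array(sizes, dtype=int)


# ---------------------------------------------------------------------------
# population


def simulate_population(
    breeds: list[BreedSpec],
    family: FamilyStructure,
    freqs: pd.DataFrame,
    seed: int,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate sires, dam gametes and progeny genotypes.

    Sire genotypes are drawn under HWE from the sire breed's frequencies;
    each progeny receives one gamete from its sire and one from the dam
    population, whose allele frequency is the ``dam_ancestry``-weighted
    mixture of breed frequencies.  Returns the progeny
    :class:`~bayesalphabet.genotypes.GenotypeMatrix` (dosage coding, empty
    mask) and a pedigree table (animal_id, sire_id, breed).
    """
    for spec in breeds:
        missing = [b for b in spec.dam_ancestry if b not in freqs.columns]
        if missing:
            raise ValueError(
                f"frequency table lacks breeds {missing} referenced by "
                f"dam_ancestry of {spec.name}"
            )
    rng = np.random.default_rng(seed)
    k = len(freqs)
    dosages, animal_ids, breed_lab, sire_lab = [], [], [], []
    ped = []
    for spec in breeds:
        if spec.n_progeny == 0:
            continue
        sizes = _family_sizes(spec.n_progeny, family, rng)
        if spec.n_sires is not None and len(sizes) != spec.n_sires:
            sizes = _repair_sizes(sizes, spec.n_sires, spec.n_progeny)
        p_sire = freqs[spec.name].to_numpy()
        w = np.zeros(k)
        for b, wt in spec.dam_ancestry.items():
            w += wt * freqs[b].to_numpy()
        p_dam = np.clip(w, 1e-6, 1 - 1e-6)
        for s_idx, fam_n in enumerate(sizes):
            sire_id = f"{spec.name[:3].upper()}_S{s_idx:04d}"
            sire_geno = rng.binomial(2, p_sire)
            # paternal gamete: Bernoulli(dosage / 2) per locus per progeny
            pat = rng.binomial(1, np.tile(sire_geno / 2.0, (fam_n, 1)))
            mat = rng.binomial(1, np.tile(p_dam, (fam_n, 1)))
            prog = pat + mat
            for m in range(fam_n):
                aid = f"{spec.name[:3].upper()}{len(animal_ids):06d}"
                animal_ids.append(aid)
                breed_lab.append(spec.name)
                sire_lab.append(sire_id)
                ped.append((aid, sire_id, spec.name))
            dosages.append(prog)
    if not dosages:
        raise ValueError("no progeny simulated (all breeds empty)")
    gm = GenotypeMatrix(
        dosages=np.vstack(dosages).astype(np.float64),
        snp_ids=freqs.index.to_numpy(dtype=object),
        animal_ids=np.array(animal_ids, dtype=object),
        breed=np.array(breed_lab, dtype=object),
        sire=np.array(sire_lab, dtype=object),
    )
    pedigree = pd.DataFrame(ped, columns=["animal_id", "sire_id", "breed"])
    return gm, pedigree


def _repair_sizes(sizes: np.ndarray, n_sires: int, n_progeny: int) -> np.ndarray:
    """Force the drawn family-size vector to exactly ``n_sires`` families."""
    if n_sires > n_progeny:
        raise ValueError(
            f"infeasible family constraints: {n_sires} sires for "
            f"{n_progeny} progeny"
        )
    sizes = sizes.copy()
    while len(sizes) > n_sires:
        # merge the two smallest families
        order = np.argsort(sizes)
        sizes[order[1]] += sizes[order[0]]
        sizes = np.delete(sizes, order[0])
    while len(sizes) < n_sires:
        # split one progeny off the largest family
        j = int(np.argmax(sizes))
        if sizes[j] < 2:
            raise ValueError("infeasible family constraints: cannot split")
        sizes[j] -= 1
        sizes = np.append(sizes, 1)
    return sizes


def family_size_histogram(pedigree: pd.DataFrame) -> pd.Series:
    """Realized family-size counts (index: family size, value: n sires)."""
    return pedigree.groupby("sire_id").size().value_counts().sort_index()


# ---------------------------------------------------------------------------
# QTL effects


def assign_qtl_effects(
    arch: TraitArchitecture, gm: GenotypeMatrix, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample QTL positions and allele-substitution effects; return
    (alpha, g) with ``g_i = sum_j z_ij alpha_j`` on the centered-ten coding.

    Effects are rescaled so the empirical var(g) equals ``target_h2`` on a
    unit-phenotypic-variance scale (Vp = 1 convention; the residual variance
    added later by :func:`simulate_phenotypes` completes the ratio).  For
    each breed-specific QTL the genotype column is rewritten in place: the
    named breed is resampled until its within-breed MAF >= 0.05 and every
    other breed is fixed at dosage 0.
    """
    k = gm.n_snps
    if arch.n_qtl > k:
        raise ValueError("architecture requests more QTL than SNPs")
    rng = np.random.default_rng(seed)
    alpha = np.zeros(k)
    if arch.n_qtl == 0:
        return alpha, np.zeros(gm.n_animals)

    forced = []
    for locus, breed in arch.breed_specific_qtl:
        if locus >= k:
            raise ValueError(f"breed-specific locus {locus} out of range")
        in_breed = gm.breed == breed
        if not in_breed.any():
            raise ValueError(
                f"breed-specific locus impossible: no animals of breed {breed}"
            )
        _force_breed_specific(gm, locus, in_breed, rng)
        forced.append(locus)

    free = np.setdiff1d(np.arange(k), np.array(forced, dtype=int))
    extra = arch.n_qtl - len(forced)
    if extra < 0:
        raise ValueError("more breed-specific QTL than n_qtl")
    qtl = np.concatenate(
        [np.array(forced, dtype=int), rng.choice(free, size=extra, replace=False)]
    ).astype(int)

    alpha[qtl] = rng.standard_normal(arch.n_qtl)
    z = gm.values_centered_ten()
    col_var = z[:, qtl].var(axis=0)

    if arch.effect_dist == "mixture" and arch.large_effect_fraction_of_vg > 0:
        # first breed-specific locus, else the first sampled QTL, is "large"
        large = qtl[0]
        small = qtl[qtl != large]
        v_small = (alpha[small] ** 2 * z[:, small].var(axis=0)).sum()
        v_large = alpha[large] ** 2 * z[:, large].var()
        f = arch.large_effect_fraction_of_vg
        if v_large > 0 and v_small > 0 and f < 1:
            alpha[large] *= np.sqrt(f * v_small / ((1.0 - f) * v_large))

    g = z @ alpha
    vg = g.var()
    if vg > 0 and arch.target_h2 > 0:
        scale = np.sqrt(arch.target_h2 / vg)
        alpha *= scale
        g *= scale
    return alpha, g


def _force_breed_specific(gm, locus, in_breed, rng):
    """Rewrite one genotype column: polymorphic (MAF >= 0.05) within the
    target breed, dosage 0 everywhere else."""
    n_in = int(in_breed.sum())
    for _ in range(200):
        p = rng.uniform(0.2, 0.8)
        d = rng.binomial(2, p, size=n_in).astype(float)
        freq = d.sum() / (2 * n_in)
        if min(freq, 1 - freq) >= 0.05:
            break
    else:  # pragma: no cover - 200 draws at p in (0.2, 0.8) cannot all fail
        raise ValueError("breed-specific locus impossible: no candidate draw")
    gm.dosages[:, locus] = 0.0
    gm.dosages[in_breed, locus] = d
    gm.mask[:, locus] = False


def qtl_variance_shares(alpha: np.ndarray, gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus share of genetic variance under HWE/no-LD: each locus
    contributes alpha_j^2 * 100 * 2 p_j q_j on the centered-ten coding."""
    p = (
        gm.allele_frequencies()
        if gm.coding == "dosage"
        else (gm.dosages / 10.0 + 1.0).mean(axis=0) / 2.0
    )
    v = alpha**2 * 100.0 * 2.0 * p * (1.0 - p)
    total = v.sum()
    return v / total if total > 0 else v


# ---------------------------------------------------------------------------
# contemporary groups and phenotypes


def default_cg_design(
    pedigree: pd.DataFrame,
    seed: int,
    n_herds: int = 4,
    n_dates: int = 2,
) -> pd.DataFrame:
    """Assign herd, sex and harvest date uniformly at random per animal;
    breed comes from the pedigree.  Contemporary groups downstream are the
    nonempty cells of herd x breed x sex x date."""
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    return pd.DataFrame(
        {
            "animal_id": pedigree["animal_id"].to_numpy(),
            "sire_id": pedigree["sire_id"].to_numpy(),
            "breed": pedigree["breed"].to_numpy(),
            "herd": rng.integers(0, n_herds, n).astype(str),
            "sex": rng.choice(["S", "H"], n),
            "date": rng.integers(0, n_dates, n).astype(str),
        }
    )


def simulate_phenotypes(
    g: np.ndarray,
    arch: TraitArchitecture,
    cg_design: pd.DataFrame,
    seed: int,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Phenotypes y = mu + cg + g + e with Ve = var(g) (1 - h2) / h2.

    ``cg_design`` must hold one row per animal with herd/breed/sex/date
    labels.  Contemporary-group effects are N(0, cg_effect_sd^2), one draw
    per nonempty cell.  The returned table carries the true genetic value
    and cg effect per animal so recovery tests need not re-derive truth;
    residual variance and mu are stored in ``DataFrame.attrs``.
    """
    g = np.asarray(g, dtype=float)
    n = len(g)
    if len(cg_design) != n:
        raise ValueError("cg_design must have one row per animal")
    vg = g.var()
    if arch.target_h2 == 0.0 and np.any(g != 0):
        raise ValueError("h2 = 0 with nonzero genetic values: Ve undefined")
    if vg == 0.0:
        ve = 1.0 if arch.target_h2 < 1.0 else 0.0
    elif arch.target_h2 == 1.0:
        ve = 0.0
    else:
        ve = vg * (1.0 - arch.target_h2) / arch.target_h2

    rng = np.random.default_rng(seed)
    key = (
        cg_design["herd"].astype(str)
        + "|" + cg_design["breed"].astype(str)
        + "|" + cg_design["sex"].astype(str)
        + "|" + cg_design["date"].astype(str)
    )
    groups = pd.Categorical(key)
    effects = rng.normal(0.0, arch.cg_effect_sd, size=len(groups.categories))
    cg = effects[groups.codes]
    e = rng.normal(0.0, np.sqrt(ve), size=n) if ve > 0 else np.zeros(n)

    out = cg_design.copy()
    out["cg"] = np.asarray(groups)
    out["y"] = mu + cg + g + e
    out["g_true"] = g
    out["cg_true"] = cg
    out.attrs["ve"] = float(ve)
    out.attrs["mu"] = float(mu)
    out.attrs["h2"] = float(arch.target_h2)
    return out


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(
    gm: GenotypeMatrix, animal_rate: float, snp_rate: float, seed: int
) -> GenotypeMatrix:
    """Flag entries missing at combined rate 1 - (1-animal_rate)(1-snp_rate).

    The underlying dosage store is never altered; only the mask changes.
    """
    for r in (animal_rate, snp_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("missingness rates must be in [0, 1)")
    rate = 1.0 - (1.0 - animal_rate) * (1.0 - snp_rate)
    out = gm.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    out.mask |= rng.random(out.dosages.shape) < rate
    return out


# ---------------------------------------------------------------------------
# one-call dataset helper


def simulate_dataset(
    arch: TraitArchitecture,
    n_snps: int = 2000,
    breeds: list[BreedSpec] | None = None,
    family: FamilyStructure | None = None,
    seed: int = 0,
    missing_rate: float = 0.0089,
    divergence: float | None = None,
):
    """Convenience wrapper: frequencies -> population -> QTL -> phenotypes.

    Returns (genotypes, phenotype table, alpha).  Default breed sizes follow
    the five-breed study population; pass smaller ``BreedSpec`` lists for
    desk-scale runs.
    """
    if breeds is None:
        breeds = _default_breeds()
    if divergence is not None:
        for b in breeds:
            b.divergence = divergence
    family = family or FamilyStructure()
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4, s5 = rng.integers(0, 2**31 - 1, size=5)
    freqs = simulate_breed_frequencies(n_snps, breeds, int(s1))
    gm, ped = simulate_population(breeds, family, freqs, int(s2))
    alpha, g = assign_qtl_effects(arch, gm, int(s3))
    design = default_cg_design(ped, int(s4))
    pheno = simulate_phenotypes(g, arch, design, int(s5))
    if missing_rate > 0:
        gm = inject_missingness(gm, missing_rate, 0.0, int(rng.integers(2**31 - 1)))
    return gm, pheno, alpha
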