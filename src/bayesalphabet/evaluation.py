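"""Training/validation evaluation of genomic predictions.

Animals are repeatedly split at random ("bootstrap replicates" in the
genomic-selection sense: repeated disjoint splits, not resampling with
replacement) over a grid of training fractions; each model is trained on
identical replicate splits, validated by the Pearson correlation r between
DGV and (pre-corrected) phenotype, and standardized to a realized accuracy
r / sqrt(h2) — sqrt(h2) being the ceiling of a phenotype-DGV correlation.
The best-fit training fraction minimizes the coefficient of variation of r
across replicates among fractions above one half.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import ModelConfig
from .genotypes import GenotypeMatrix
from .model import BayesAlphabet

#: Bonferroni family size shipped for the cross-model comparison report
#: (6 model pairs x 6 traits).
BONFERRONI_FAMILY = 36


class AccuracyWarning(UserWarning):
    pass


def allocate(n_animals: int, fraction: float, seed: int):
    """Random disjoint-exhaustive split; training size is round-half-up of
    n * fraction.  Returns sorted (training, validation) index arrays."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_t = int(np.floor(n_animals * fraction + 0.5))
    if n_t < 2 or n_animals - n_t < 1:
        raise ValueError("split leaves too few animals")
    perm = np.random.default_rng(seed).permutation(n_animals)
    return np.sort(perm[:n_t]), np.sort(perm[n_t:])


def predict_dgv(genotypes, effects: pd.Series) -> np.ndarray:
    """DGV_i = sum_j z_ij u_hat_j on the centered-ten coding.

    With a :class:`GenotypeMatrix` the SNP panels are aligned by id and a
    mismatch is reported with the offending ids.
    """
    if isinstance(genotypes, GenotypeMatrix):
        genotypes._require("centered-ten")
        if not np.array_equal(genotypes.snp_ids, effects.index.to_numpy()):
            extra = set(genotypes.snp_ids) ^ set(effects.index)
            raise ValueError(
                f"SNP sets differ between genotypes and effects: "
                f"{sorted(map(str, list(extra)))[:10]}"
            )
        Z = genotypes.dosages
    else:
        Z = np.asarray(genotypes, dtype=float)
    return Z @ effects.to_numpy()


def validation_correlation(dgv, y_adj) -> float:
    """Pearson correlation between DGV and adjusted phenotype."""
    dgv = np.asarray(dgv, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    if dgv.shape[0] < 3:
        raise ValueError("need at least 3 validation animals")
    if dgv.std() == 0 or y_adj.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(dgv, y_adj)[0, 1])


def realized_accuracy(r: float, h2: float) -> float:
    """r / sqrt(h2).  Values above 1 are reported as-is with a warning —
    they signal an understated h2, not an error."""
    if h2 <= 0 or h2 > 1:
        raise ValueError("h2 must be in (0, 1]")
    acc = r / np.sqrt(h2)
    if acc > 1.0:
        warnings.warn(
            f"realized accuracy {acc:.3f} outside the parameter space [0-1]",
            AccuracyWarning,
            stacklevel=2,
        )
    return float(acc)


def replicate_summary(values) -> tuple[float, float, float]:
    """(mean, sd, CV) across replicates; CV = sd / mean, undefined at
    mean 0."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = values.mean()
    sd = values.std(ddof=1)
    if mean == 0:
        raise ValueError("mean 0: CV undefined")
    return float(mean), float(sd), float(sd / mean)


def select_best_fit(cv_by_fraction: dict) -> float:
    """Smallest CV among training fractions strictly above 0.5; ties go to
    the larger fraction."""
    eligible = {f: cv for f, cv in cv_by_fraction.items() if f > 0.5}
    if not eligible:
        raise ValueError("no training fraction above 0.5 in the grid")
    return max(
        sorted(eligible), key=lambda f: (-eligible[f], f)
    )


def per_breed_accuracy(
    dgv, y_adj, breeds, h2_by_breed: dict
) -> pd.DataFrame:
    """Validation correlation and realized accuracy within each sire-breed
    subset, standardized by that breed's h2.  Breeds with fewer than 3
    validation animals are skipped with a notice."""
    breeds = np.asarray(breeds)
    rows = []
    for b in pd.unique(breeds):
        idx = breeds == b
        if idx.sum() < 3:
            warnings.warn(
                f"breed {b}: {int(idx.sum())} validation animals, skipped",
                AccuracyWarning,
                stacklevel=2,
            )
            continue
        if b not in h2_by_breed:
            raise KeyError(f"no h2 entry for breed {b}")
        r = validation_correlation(np.asarray(dgv)[idx], np.asarray(y_adj)[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AccuracyWarning)
            acc = realized_accuracy(r, h2_by_breed[b])
        rows.append((b, int(idx.sum()), r, acc))
    return pd.DataFrame(rows, columns=["breed", "n", "r", "accuracy"])


def paired_model_ttest(
    r_model1, r_model2, family_size: int = BONFERRONI_FAMILY
) -> dict:
    """Classical paired t-test on per-replicate validation correlations.

    The replicate splits must be identical between models.  Returns the
    mean difference (model1 - model2), t statistic (df = n - 1), two-sided
    p, and the Bonferroni-corrected significance threshold
    0.05 / family_size.
    """
    a = np.asarray(r_model1, dtype=float)
    b = np.asarray(r_model2, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors of >= 2 replicates")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sp_stats.t.sf(abs(t), df=n - 1)
    return {
        "mean_diff": float(d.mean()),
        "t": float(t),
        "p": float(p),
        "df": n - 1,
        "bonferroni_alpha": 0.05 / family_size,
        "significant": bool(p < 0.05 / family_size),
    }


# ---------------------------------------------------------------------------
# bootstrap cross-validation driver


@dataclass
class CVReport:
    """Tidy per-replicate results plus summaries.

    ``table`` columns: model, fraction, replicate, n_train, n_val, r, h2
    (the training analysis's own posterior-mean h2).
    """

    table: pd.DataFrame
    master_seed: int

    def correlations(self, model: str, fraction: float) -> np.ndarray:
        sub = self.table[
            (self.table["model"] == model) & (self.table["fraction"] == fraction)
        ].sort_values("replicate")
        return sub["r"].to_numpy()

    def cv_by_fraction(self, model: str) -> dict:
        out = {}
        for f, grp in self.table[self.table["model"] == model].groupby("fraction"):
            _, _, cv = replicate_summary(grp["r"].to_numpy())
            out[float(f)] = cv
        return out

    def best_fit(self, model: str) -> float:
        return select_best_fit(self.cv_by_fraction(model))

    def summary(self, h2_source: dict | None = None) -> pd.DataFrame:
        """Mean r, sd, CV and realized accuracy per model x fraction.
        ``h2_source`` maps model name -> h2 used for standardization; by
        default each analysis's own mean posterior h2 is used."""
        rows = []
        for (m, f), grp in self.table.groupby(["model", "fraction"]):
            mean, sd, cv = replicate_summary(grp["r"].to_numpy())
            h2 = (
                h2_source[m]
                if h2_source is not None
                else float(grp["h2"].mean())
            )
            rows.append(
                (
                    m,
                    float(f),
                    int(grp["n_train"].iloc[0]),
                    int(grp["n_val"].iloc[0]),
                    mean,
                    sd,
                    cv,
                    h2,
                    mean / np.sqrt(h2),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "model",
                "fraction",
                "n_train",
                "n_val",
                "mean_r",
                "sd_r",
                "cv",
                "h2",
                "realized_accuracy",
            ],
        ).sort_values(["model", "fraction"], ignore_index=True)


def replicate_seed(master_seed: int, fraction: float, replicate: int) -> int:
    """Deterministic per-replicate split seed, shared across models so every
    model sees byte-identical training/validation indices."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(round(fraction * 1000)), int(replicate)]
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def cross_validate(
    y_adj: np.ndarray,
    genotypes,
    configs: dict[str, ModelConfig],
    fractions=(0.6, 0.65, 0.7),
    n_replicates: int = 20,
    seed: int = 0,
    breeds=None,
) -> CVReport:
    """Fit every configured model on every replicate split of every
    fraction; validation r is computed on the held-out animals.

    ``genotypes`` may be a centered-ten GenotypeMatrix or coded array.
    """
    if isinstance(genotypes, GenotypeMatrix):
        genotypes._require("centered-ten")
        Z = genotypes.dosages
        snp_ids = genotypes.snp_ids
    else:
        Z = np.asarray(genotypes, dtype=float)
        snp_ids = None
    y_adj = np.asarray(y_adj, dtype=float)
    n = y_adj.shape[0]
    rows = []
    for f in fractions:
        for rep in range(n_replicates):
            split_seed = replicate_seed(seed, f, rep)
            tr, va = allocate(n, f, split_seed)
            for name, cfg in configs.items():
                name_tag = zlib.crc32(name.encode()) % 997
                fit_seed = (split_seed * 1009 + name_tag) % (2**31 - 1)
                res = BayesAlphabet(
                    y_adj[tr], Z[tr], cfg, snp_ids=snp_ids
                ).fit(seed=fit_seed)
                dgv = Z[va] @ res.params.to_numpy()
                r = validation_correlation(dgv, y_adj[va])
                rows.append(
                    (name, float(f), rep, len(tr), len(va), r, res.h2)
                )
    table = pd.DataFrame(
        rows,
        columns=["model", "fraction", "replicate", "n_train", "n_val", "r", "h2"],
    )
    return CVReport(table=table, master_seed=seed)
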