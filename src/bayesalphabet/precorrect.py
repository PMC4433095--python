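"""Contemporary-group pre-correction of phenotypes.

Contemporary groups are the nonempty cells of herd x breed x sex x
harvest-date.  Their effects (plus the mean) are estimated once, in a
single all-animals BayesCpi fit that keeps the markers in the model — so
genetic signal is not absorbed into the group effects — and phenotypes are
then adjusted by subtracting the posterior-mean fixed-effect part.  The
adjusted phenotypes feed every downstream training/validation split
without refitting group effects per subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .model import BayesAlphabet

FACTORS = ("herd", "breed", "sex", "date")


@dataclass
class ContemporaryGroupDesign:
    """Animal -> contemporary-group incidence built from four factors."""

    factors: pd.DataFrame  # per-animal herd/breed/sex/date labels
    group_labels: pd.Index  # sorted distinct nonempty cells
    codes: np.ndarray  # per-animal group index

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def design_matrix(self) -> np.ndarray:
        """Intercept + drop-first dummy columns (full rank by construction:
        every group is nonempty)."""
        n = len(self.codes)
        X = np.zeros((n, self.n_groups))
        X[:, 0] = 1.0
        for g in range(1, self.n_groups):
            X[self.codes == g, g] = 1.0
        return X


def build_groups(factor_table: pd.DataFrame) -> ContemporaryGroupDesign:
    """Form contemporary groups as the interaction of herd, breed, sex and
    date.  Group ids are stable under row permutation (labels are sorted);
    missing factor levels are reported per animal."""
    missing_cols = [c for c in FACTORS if c not in factor_table.columns]
    if missing_cols:
        raise ValueError(f"factor table lacks columns {missing_cols}")
    sub = factor_table[list(FACTORS)].astype(object)
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = list(factor_table.index[bad][:10])
        raise ValueError(f"missing factor labels for animals {rows}")
    key = sub.apply(lambda col: col.astype(str)).agg("|".join, axis=1)
    cats = pd.Categorical(key, categories=sorted(key.unique()))
    return ContemporaryGroupDesign(
        factors=sub,
        group_labels=pd.Index(cats.categories, name="group"),
        codes=np.asarray(cats.codes),
    )


def precorrect(
    y: np.ndarray,
    genotypes,
    design: ContemporaryGroupDesign,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, object]:
    """Estimate mean + contemporary-group effects in one BayesCpi fit and
    return (adjusted phenotypes, group-effect table, fit results).

    The adjustment is a pure per-group translation:
    ``y_adj = y - posterior_mean(intercept + group effect)``.
    """
    config = config or ModelConfig(model="Cpi", pi=0.5)
    if config.model != "Cpi":
        raise ValueError("pre-correction is defined as a BayesCpi analysis")
    X = design.design_matrix()
    model = BayesAlphabet(y, genotypes, config, exog=X)
    res = model.fit(seed=seed)
    # mean + group effect per group, applied by lookup so the adjustment is
    # exactly constant within a contemporary group
    group_effect = np.concatenate(
        [[res.fixed_effects[0]], res.fixed_effects[0] + res.fixed_effects[1:]]
    )
    y_adj = np.asarray(y, dtype=float) - group_effect[design.codes]
    effects = pd.DataFrame(
        {
            "group": design.group_labels,
            "effect": group_effect,
            "n_animals": np.bincount(design.codes, minlength=design.n_groups),
        }
    )
    return y_adj, effects, res
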