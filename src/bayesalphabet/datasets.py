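"""Packaged reference values for the six beef carcass traits.

These constants describe the 3240-animal, five-sire-breed commercial
carcass study this package is modelled on: per-trait chain starting values,
within-breed REML heritabilities, and the published best-fit validation
summaries used in worked examples.  Traits: WBSF (Warner-Bratzler shear
force, kg), REA (ribeye area, cm2), MARB (marbling score), FT (backfat
thickness, cm), HCW (hot carcass weight, kg), YG (yield grade).
"""

from __future__ import annotations

import pandas as pd

from .config import ModelConfig

#: (trait, model) -> (pi, va_start, ve_start): published chain starting
#: values.  Cpi/C used weighted within-breed REML components; A/B95 used
#: separate uninformed values for some traits (see informed_start).
START_VALUES = {
    ("WBSF", "Cpi"): (0.99, 0.416, 0.624),
    ("WBSF", "C"): (0.0, 0.416, 0.624),
    ("WBSF", "A"): (0.0, 0.16, 0.55),
    ("WBSF", "B"): (0.95, 0.16, 0.55),
    ("REA", "Cpi"): (0.95, 25.629, 40.170),
    ("REA", "C"): (0.0, 25.629, 40.170),
    ("REA", "A"): (0.0, 21.0, 44.0),
    ("REA", "B"): (0.95, 21.0, 44.0),
    ("MARB", "Cpi"): (0.9, 3500.0, 2600.0),
    ("MARB", "C"): (0.0, 3500.0, 2600.0),
    ("MARB", "A"): (0.0, 3500.0, 2600.0),
    ("MARB", "B"): (0.95, 3500.0, 2600.0),
    ("FT", "Cpi"): (0.95, 0.092, 0.063),
    ("FT", "C"): (0.0, 0.092, 0.063),
    ("FT", "A"): (0.0, 0.011, 0.136),
    ("FT", "B"): (0.95, 0.011, 0.136),
    ("HCW", "Cpi"): (0.9, 373.06, 571.19),
    ("HCW", "C"): (0.0, 373.06, 571.19),
    ("HCW", "A"): (0.0, 610.0, 615.0),
    ("HCW", "B"): (0.95, 610.0, 615.0),
    ("YG", "Cpi"): (0.9, 0.2049, 0.2049),
    ("YG", "C"): (0.0, 0.2049, 0.2049),
    ("YG", "A"): (0.0, 0.035, 0.358),
    ("YG", "B"): (0.95, 0.035, 0.358),
}

TRAITS = ("WBSF", "REA", "MARB", "FT", "HCW", "YG")
BREEDS = ("Angus", "Charolais", "Hereford", "Limousin", "Simmental")

#: Within-breed REML heritabilities from GBLUP analyses, used to
#: standardize within-breed validation correlations.
WITHIN_BREED_H2 = pd.DataFrame(
    {
        "Angus": [0.52, 0.61, 0.51, 0.40, 0.31, 0.39],
        "Charolais": [0.46, 0.21, 0.57, 0.50, 0.65, 0.50],
        "Hereford": [0.17, 0.23, 0.49, 0.28, 0.37, 0.23],
        "Limousin": [0.09, 0.55, 0.41, 0.94, 0.51, 0.79],
        "Simmental": [0.08, 0.29, 0.87, 0.65, 0.11, 0.45],
    },
    index=list(TRAITS),
)

#: Best-fit validation summaries per trait and model: training/validation
#: sizes, posterior-mean pi and h2, validation correlation r, and realized
#: accuracies standardized three ways (within-analysis h2, best-fit BayesCpi
#: h2, best-fit BayesC0 h2).
BESTFIT_RESULTS = pd.DataFrame(
    [
        ("WBSF", 2268, 972, "Cpi", 0.9998, 0.12, 0.298, 0.854, 0.862, 0.585),
        ("WBSF", 2268, 972, "C", 0.0, 0.26, 0.276, 0.547, 0.796, 0.541),
        ("WBSF", 2268, 972, "A", 0.0, 0.29, 0.314, 0.586, 0.906, 0.616),
        ("WBSF", 2268, 972, "B", 0.95, 0.28, 0.319, 0.605, 0.921, 0.626),
        ("REA", 1927, 1286, "Cpi", 0.9931, 0.32, 0.336, 0.600, 0.594, 0.585),
        ("REA", 1927, 1286, "C", 0.0, 0.33, 0.345, 0.599, 0.609, 0.600),
        ("REA", 1927, 1286, "A", 0.0, 0.38, 0.343, 0.560, 0.606, 0.597),
        ("REA", 1927, 1286, "B", 0.95, 0.36, 0.344, 0.573, 0.608, 0.599),
        ("MARB", 1657, 1106, "Cpi", 0.7432, 0.62, 0.595, 0.757, 0.756, 0.762),
        ("MARB", 1657, 1106, "C", 0.0, 0.62, 0.595, 0.759, 0.756, 0.762),
        ("MARB", 1657, 1106, "A", 0.0, 0.72, 0.590, 0.697, 0.750, 0.756),
        ("MARB", 1657, 1106, "B", 0.95, 0.67, 0.592, 0.722, 0.752, 0.758),
        ("FT", 1887, 1259, "Cpi", 0.9999, 0.06, 0.206, 0.815, 0.842, 0.397),
        ("FT", 1887, 1259, "C", 0.0, 0.27, 0.267, 0.517, 1.091, 0.514),
        ("FT", 1887, 1259, "A", 0.0, 0.11, 0.242, 0.746, 0.990, 0.467),
        ("FT", 1887, 1259, "B", 0.95, 0.11, 0.249, 0.741, 1.017, 0.480),
        ("HCW", 1931, 1288, "Cpi", 0.9539, 0.49, 0.536, 0.763, 0.763, 0.766),
        ("HCW", 1931, 1288, "C", 0.0, 0.48, 0.543, 0.785, 0.772, 0.776),
        ("HCW", 1931, 1288, "A", 0.0, 0.63, 0.536, 0.677, 0.762, 0.765),
        ("HCW", 1931, 1288, "B", 0.95, 0.59, 0.532, 0.693, 0.756, 0.760),
        ("YG", 2219, 951, "Cpi", 0.9998, 0.08, 0.217, 0.757, 0.753, 0.412),
        ("YG", 2219, 951, "C", 0.0, 0.28, 0.264, 0.502, 0.914, 0.500),
        ("YG", 2219, 951, "A", 0.0, 0.13, 0.256, 0.714, 0.888, 0.486),
        ("YG", 2219, 951, "B", 0.95, 0.136, 0.260, 0.705, 0.901, 0.493),
    ],
    columns=[
        "trait",
        "n_train",
        "n_val",
        "model",
        "pi",
        "h2",
        "r",
        "accuracy_within",
        "accuracy_cpi",
        "accuracy_c0",
    ],
)


def default_config(trait: str, model: str, **overrides) -> ModelConfig:
    """Shipped per-trait default :class:`ModelConfig` (starting values as
    published for the carcass study)."""
    try:
        pi, va, ve = START_VALUES[(trait, model)]
    except KeyError:
        raise KeyError(f"no shipped defaults for trait={trait!r}, model={model!r}")
    kw = dict(model=model, pi=pi, va_start=va, ve_start=ve)
    kw.update(overrides)
    return ModelConfig(**kw)
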