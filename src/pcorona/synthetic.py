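"""Synthetic corona-like datasets with planted, recoverable signal.

The generator emulates the statistical shape of published protein-corona
screens: a few hundred nanoparticle-incubation records described by a
mix of categorical factors (particle chemistry, surface modification,
medium, ...) and numerical factors (sizes, zeta potential, PDI,
protocol settings), and per-protein relative-abundance (RPA) targets
that are strictly positive, right-skewed and long-tailed.

RPA is generated through a lognormal link: for protein *j*,

    log RPA_ij = mu_j + s * [ sum_f beta_{jf} g_f(x_if)
                              + gamma_j 1{cat_i = L_j} z_i ] + eps_ij,
    eps_ij ~ Normal(0, noise_sd),

where only a small designated set of *informative* factors carries
nonzero effects (numeric factors enter through their rescaled value z,
categorical ones through per-level offsets) and ``s`` is the
``skewness_scale``.  When the informative set contains both a
categorical and a numeric factor, each protein additionally gets one
synergy term: a randomly chosen level L_j of the categorical factor
amplifies the numeric factor's effect with strength gamma_j.  This
mirrors how corona formation works in practice — a particular surface
chemistry strongly amplifies plasma-concentration-dependent adsorption
of a given protein — and it is what gives the target its long right
tail: the high-abundance rows are the rare conjunction of that coating
with high plasma concentration, so they are sparse in feature space
yet fully predictable.  Exponentiating the roughly unit-variance
Gaussian predictor yields the positive skew the downstream resampling
stages are designed for, and the planted coefficients give
feature-importance analysis a known answer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateInputError
from .io_model import CoronaDataset

# The canonical 21-factor schema: 8 categorical factors with plausible
# level sets, 13 numerical factors with plausible (low, high) ranges.
CATEGORICAL_SCHEMA: dict[str, tuple[str, ...]] = {
    "NP_type": ("metal", "metal_oxide", "polymer", "silica", "carbon"),
    "NP_core": ("Ag", "Au", "TiO2", "SiO2", "Fe3O4", "polystyrene"),
    "surface_modification": ("none", "PEG", "COOH", "NH2", "citrate"),
    "modification_type": ("none", "covalent", "adsorbed"),
    "NP_shape": ("sphere", "rod", "plate", "irregular"),
    "dispersion_medium": ("water", "PBS", "DMEM", "RPMI"),
    "protein_source": ("human_plasma", "human_serum", "FBS", "mouse_plasma"),
    "incubation_culture": ("static", "agitated"),
}

NUMERICAL_SCHEMA: dict[str, tuple[float, float]] = {
    "size_TEM": (5.0, 400.0),  # nm
    "size_DLS": (10.0, 600.0),  # nm
    "zeta_potential": (-50.0, 50.0),  # mV
    "PDI": (0.05, 0.7),
    "dispersion_medium_pH": (5.0, 9.0),
    "centrifugation_speed": (5000.0, 20000.0),  # g
    "centrifugation_time": (10.0, 60.0),  # min
    "centrifugation_temperature": (4.0, 25.0),  # degC
    "centrifugation_repetitions": (1.0, 5.0),
    "incubation_plasma_concentration": (5.0, 100.0),  # %
    "incubation_NP_concentration": (10.0, 1000.0),  # ug/ml
    "incubation_time": (0.5, 24.0),  # h
    "incubation_temperature": (4.0, 40.0),  # degC
}

DEFAULT_INFORMATIVE = ("incubation_plasma_concentration", "PDI", "surface_modification")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; the defaults are the study conditions."""

    n_rows: int = 652
    n_categorical: int = 8
    n_numerical: int = 13
    n_proteins: int = 60
    informative_factors: tuple[str, ...] = DEFAULT_INFORMATIVE
    skewness_scale: float = 1.2
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative_factors", tuple(self.informative_factors))
        if self.n_rows < 20:
            raise ConfigError(f"n_rows must be >= 20, got {self.n_rows}")
        if self.skewness_scale <= 0:
            raise ConfigError("skewness_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_categorical < 0 or self.n_numerical < 1 or self.n_proteins < 1:
            raise ConfigError("factor and protein counts must be positive")


@dataclass
class GroundTruth:
    """The planted generative model, for recovery tests.

    ``coefficients`` maps ``(protein_id, factor)`` to the effect: a
    float slope for numeric factors, a level→offset dict for
    categorical ones.  Only informative factors appear.
    """

    coefficients: dict[tuple[str, str], float | dict[str, float]]
    intercepts: dict[str, float] = field(default_factory=dict)
    link: str = "log RPA = intercept + skewness_scale * sum(effects) + Normal(0, noise_sd)"


def _factor_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    cat = list(CATEGORICAL_SCHEMA)[: config.n_categorical]
    cat += [f"cat_{i:02d}" for i in range(len(cat), config.n_categorical)]
    num = list(NUMERICAL_SCHEMA)[: config.n_numerical]
    num += [f"num_{i:02d}" for i in range(len(num), config.n_numerical)]
    return cat, num


def generate_dataset(config: SyntheticConfig) -> tuple[CoronaDataset, GroundTruth]:
    """Draw a corona-like dataset; deterministic given ``config.seed``.

    Categorical factors are sampled uniformly over their level sets
    (2–6 levels each); numerical factors uniformly over plausible
    ranges; RPA targets follow the lognormal link described in the
    module docstring.
    """
    cat_names, num_names = _factor_names(config)
    unknown = set(config.informative_factors) - set(cat_names) - set(num_names)
    if unknown:
        raise ConfigError(f"informative factors not in the generated schema: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    n = config.n_rows

    factors = pd.DataFrame(index=range(n))
    levels_of: dict[str, tuple[str, ...]] = {}
    for name in cat_names:
        levels = CATEGORICAL_SCHEMA.get(name)
        if levels is None:
            k = int(rng.integers(2, 7))
            levels = tuple(f"L{i}" for i in range(k))
        levels_of[name] = levels
        factors[name] = rng.choice(levels, size=n)

    ranges_of: dict[str, tuple[float, float]] = {}
    for name in num_names:
        lo, hi = NUMERICAL_SCHEMA.get(name, (0.0, 1.0))
        ranges_of[name] = (lo, hi)
        factors[name] = rng.uniform(lo, hi, size=n)

    protein_ids = [f"protein_{j:02d}" for j in range(config.n_proteins)]
    coefficients: dict[tuple[str, str], float | dict[str, float]] = {}
    intercepts: dict[str, float] = {}
    rpa = np.empty((n, config.n_proteins))

    info_cat = [f for f in config.informative_factors if f in levels_of]
    info_num = [f for f in config.informative_factors if f not in levels_of]

    for j, pid in enumerate(protein_ids):
        linpred = np.zeros(n)
        for f in info_cat:
            offsets = {lv: float(rng.normal(0.0, 0.6)) for lv in levels_of[f]}
            coefficients[(pid, f)] = offsets
            linpred += factors[f].map(offsets).to_numpy(dtype=float)
        for f in info_num:
            beta = float(rng.uniform(0.8, 1.6) * rng.choice([-1.0, 1.0]))
            if f == "incubation_plasma_concentration":
                beta = abs(beta)  # more plasma protein available -> more adsorbed
            coefficients[(pid, f)] = beta
            lo, hi = ranges_of[f]
            z = (factors[f].to_numpy() - lo) / (hi - lo)
            linpred += beta * (z - 0.5)
        if info_cat and info_num:
            # one coating level amplifies the first numeric factor's effect
            cat_f, num_f = info_cat[0], info_num[0]
            level = str(rng.choice(levels_of[cat_f]))
            gamma = float(rng.uniform(2.5, 3.5))
            coefficients[(pid, f"{cat_f}*{num_f}")] = {"level": level, "gamma": gamma}
            lo, hi = ranges_of[num_f]
            z = (factors[num_f].to_numpy() - lo) / (hi - lo)
            linpred += gamma * (factors[cat_f] == level).to_numpy(dtype=float) * z
        mu = float(rng.uniform(-0.5, 0.5))
        intercepts[pid] = mu
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        rpa[:, j] = np.exp(mu + config.skewness_scale * linpred + noise)

    dataset = CoronaDataset(
        factors=factors,
        rpa=pd.DataFrame(rpa, columns=protein_ids),
        factor_kinds={**{c: "categorical" for c in cat_names}, **{c: "numerical" for c in num_names}},
    )
    return dataset, GroundTruth(coefficients=coefficients, intercepts=intercepts)


def skewness(values: np.ndarray) -> float:
    """Sample skewness: the standardized third central moment.

    Computed as m3 / m2^(3/2) with biased (population) central moments,
    the convention used for distribution-shape diagnostics.  Raises on
    fewer than three values or zero variance.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise DegenerateInputError(f"skewness needs >=3 values, got {v.size}")
    centered = v - v.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        raise DegenerateInputError("skewness undefined for a constant vector")
    return float(np.mean(centered**3) / m2**1.5)
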