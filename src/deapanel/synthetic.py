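"""Synthetic jurisdiction-year panels with a known production frontier.

The real panel behind this kind of analysis (242 Mexican health
jurisdictions, 2009-2020, administrative input/output rates per 10,000
inhabitants) is not publicly deposited, so this module generates panels
with the same schema and magnitudes but a *known* technology and known
context-driven inefficiency:

* each jurisdiction has a latent resource scale ``s_j`` (resource-rich
  places have more of everything), and each of the 16 input rates is the
  published-magnitude mean for that year times ``s_j`` times idiosyncratic
  lognormal noise — inputs are therefore strongly correlated, as real
  staffing/infrastructure rates are;
* the frontier is Cobb-Douglas on two input aggregates (infrastructure
  sum, human-resources sum): g(x) = A * xI^a1 * xL^a2 with a1 + a2 < 1,
  so the true technology has variable returns to scale;
* inefficiency enters multiplicatively: treated = g(x) * exp(-u) * exp(v)
  with u >= 0, so the true Farrell output distance is exp(u) exactly;
* u = m_t * (softplus(beta . z) + halfnormal(sigma_u)): a signed link
  from standardized context variables z (marginalization raises
  inefficiency, primary-care coverage lowers it, ...) plus an
  idiosyncratic half-normal term, all scaled by a hump-shaped year
  profile m_t (inefficiency falls to a 2016 minimum, then partially
  rebounds);
* the second output is a jittered share of the first (controlled cases
  are ~40% of treated cases).

Every draw comes from one seeded generator in a fixed order, so a
(config, seed) pair reproduces the panel bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 16 DEA input columns: 4 infrastructure + 12 human-resources rates per 10,000
INFRA_COLS = [
    "general_medical_offices",
    "emergency_medical_offices",
    "emergency_beds_nonhospital",
    "recovery_beds_nonhospital",
]
HR_COLS = [
    "general_practitioners",
    "medical_interns",
    "physicians_admin",
    "general_nurses",
    "nurse_specialists",
    "nurse_interns",
    "nurses_admin",
    "chemists",
    "social_workers",
    "nutritionists",
    "lab_technicians",
    "dietician_technicians",
]
INPUT_COLS = INFRA_COLS + HR_COLS
OUTPUT_COLS = ["treated_patients", "controlled_patients"]
CONTEXT_COLS = [
    "marginalization",
    "phc_coverage",
    "indigenous_pct",
    "demand",
    "gini",
    "gov_support",
    "employment",
]

#: published-magnitude input means (rates per 10,000) at 2009, 2015, 2020;
#: yearly base means are piecewise-linear between these anchors
INPUT_ANCHORS: dict[str, tuple[float, float, float]] = {
    "general_medical_offices": (2.41, 2.30, 2.13),
    "emergency_medical_offices": (0.02, 0.0, 0.0),
    "emergency_beds_nonhospital": (0.72, 0.07, 0.04),
    "recovery_beds_nonhospital": (0.28, 0.19, 0.06),
    "general_practitioners": (2.14, 2.29, 2.22),
    "medical_interns": (1.23, 1.00, 0.83),
    "physicians_admin": (0.14, 0.11, 0.11),
    "general_nurses": (1.75, 1.78, 1.89),
    "nurse_specialists": (0.01, 0.03, 0.06),
    "nurse_interns": (0.61, 0.90, 0.89),
    "nurses_admin": (0.09, 0.10, 0.10),
    "chemists": (0.04, 0.07, 0.05),
    "social_workers": (0.03, 0.06, 0.07),
    "nutritionists": (0.02, 0.10, 0.11),
    "lab_technicians": (0.07, 0.06, 0.06),
    "dietician_technicians": (0.01, 0.01, 0.01),
}

_ANCHOR_YEARS = (2009, 2015, 2020)

#: default signed links from standardized context to inefficiency u;
#: marginalization is deliberately the dominant driver
DEFAULT_CONTEXT_EFFECTS: dict[str, float] = {
    "marginalization": 0.55,
    "phc_coverage": -0.30,
    "indigenous_pct": 0.35,
    "demand": 0.25,
    "gini": 0.12,
    "gov_support": 0.08,
    "employment": -0.10,
}

#: regional shift of the marginalization mean (southern regions poorer)
_REGION_MARG_SHIFT = [12.0, 7.0, 3.0, -2.0, -6.0, -10.0]
#: regional multiplier for the indigenous-population share
_REGION_INDIG_FACTOR = [1.9, 1.4, 1.0, 0.75, 0.55, 0.4]


def _anchor_interp(year: np.ndarray, anchors: tuple[float, float, float]) -> np.ndarray:
    return np.interp(year, _ANCHOR_YEARS, anchors)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study's magnitudes."""

    n_jurisdictions: int = 242
    years: tuple[int, int] = (2009, 2020)
    n_regions: int = 6
    frontier_scale: float = 820.0
    frontier_elasticities: tuple[float, float] = (0.22, 0.38)
    context_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_EFFECTS)
    )
    inefficiency_scale: float = 0.12  # sigma_u of the half-normal term
    noise_scale: float = 0.05  # sigma_v of the two-sided noise
    controlled_share: float = 0.40
    controlled_share_sd: float = 0.05
    size_sd: float = 0.56  # lognormal sigma of the latent resource scale
    input_noise: float = 0.15  # idiosyncratic lognormal sigma per input
    year_effect: float = 0.48  # depth of the 2016 dip in the u-multiplier
    region_context_effects: dict[int, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_jurisdictions < 1:
            raise ValueError("n_jurisdictions must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (first, last) range")
        alpha = np.asarray(self.frontier_elasticities, dtype=float)
        if np.any(alpha <= 0) or alpha.sum() >= 1.0:
            raise ValueError(
                "frontier elasticities must be positive and sum to < 1 (VRS)"
            )
        if self.frontier_scale <= 0:
            raise ValueError("frontier_scale must be positive")
        if self.inefficiency_scale <= 0:
            raise ValueError("inefficiency_scale (sigma_u) must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale (sigma_v) must be >= 0")
        if not 0.0 < self.controlled_share < 1.0:
            raise ValueError("controlled_share must be in (0, 1)")
        unknown = set(self.context_effects) - set(CONTEXT_COLS)
        if unknown:
            raise ValueError(f"unknown context variables {sorted(unknown)}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def year_inefficiency_multiplier(year: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Hump-shaped multiplier on u: 1.0 in 2009, minimal in 2016, partial rebound."""
    y0, y1 = config.years
    peak = min(max(2016, y0), y1)
    year = np.asarray(year, dtype=float)
    down = np.clip((year - y0) / max(peak - y0, 1), 0.0, 1.0)
    up = np.clip((year - peak) / max(y1 - peak, 1), 0.0, 1.0)
    return 1.0 - config.year_effect * down + 0.6 * config.year_effect * up


def frontier_output(inputs: pd.DataFrame | np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """True frontier g(x) = A * (sum infra)^a1 * (sum HR)^a2."""
    if isinstance(inputs, pd.DataFrame):
        x_infra = inputs[INFRA_COLS].to_numpy(float).sum(axis=1)
        x_hr = inputs[HR_COLS].to_numpy(float).sum(axis=1)
    else:
        arr = np.atleast_2d(np.asarray(inputs, dtype=float))
        x_infra = arr[:, : len(INFRA_COLS)].sum(axis=1)
        x_hr = arr[:, len(INFRA_COLS) :].sum(axis=1)
    a1, a2 = config.frontier_elasticities
    return config.frontier_scale * x_infra**a1 * x_hr**a2


def true_efficiency(record, config: SyntheticConfig, u: float) -> float:
    """Efficiency implied by an inefficiency draw: exp(-u), in (0, 1].

    With sigma_v = 0 this equals observed treated output divided by the
    frontier output at the record's inputs.
    """
    if u < 0:
        raise ValueError("inefficiency u must be >= 0")
    return float(np.exp(-u))


def _context_effect_matrix(config: SyntheticConfig, region: np.ndarray) -> np.ndarray:
    """Per-record beta matrix (n_records x 7), honouring regional overrides."""
    base = np.array([config.context_effects.get(c, 0.0) for c in CONTEXT_COLS])
    beta = np.tile(base, (len(region), 1))
    if config.region_context_effects:
        for reg, effects in config.region_context_effects.items():
            row = np.array([effects.get(c, 0.0) for c in CONTEXT_COLS])
            beta[region == reg] = row
    return beta


def generate_panel(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (panel, truth) tables for the configured jurisdictions x years.

    The truth table stores the exact Farrell distance exp(u) and
    efficiency exp(-u) of every record, for recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_jurisdictions
    years = np.asarray(config.year_list)
    T = len(years)
    ids = np.array([f"J{j + 1:03d}" for j in range(n)])
    region = 1 + (np.arange(n) * config.n_regions) // n  # contiguous blocks

    # latent resource scale, E[s] = 1
    s = np.exp(rng.normal(0.0, config.size_sd, n) - config.size_sd**2 / 2)

    # --- context (per jurisdiction, constant unless noted) ---
    marg_shift = np.array(
        [_REGION_MARG_SHIFT[(r - 1) % len(_REGION_MARG_SHIFT)] for r in region]
    )
    indig_factor = np.array(
        [_REGION_INDIG_FACTOR[(r - 1) % len(_REGION_INDIG_FACTOR)] for r in region]
    )
    marginalization = np.clip(rng.normal(28.7 + marg_shift, 10.0, n), 0.0, 100.0)
    phc_base = rng.normal(0.0, 16.0, n)
    indigenous = np.clip(100.0 * rng.beta(0.25, 2.5, n) * indig_factor, 0.0, 100.0)
    demand_rel = rng.gamma(2.8, 1.0 / 2.8, n)  # mean 1, CV ~ 0.6
    gini = np.clip(rng.normal(0.40, 0.03, n), 0.05, 0.95)
    gov_support = np.clip(rng.gamma(0.82, 8.93, n), 0.0, 100.0)
    employment = np.clip(rng.normal(90.6, 7.2, n), 40.0, 100.0)

    # --- expand to records (jurisdiction-major, year-minor order) ---
    rec_year = np.repeat(years[None, :], n, axis=0).ravel()
    rec_id = np.repeat(ids, T)
    rec_region = np.repeat(region, T)
    rep = lambda a: np.repeat(a, T)

    phc = np.clip(
        _anchor_interp(rec_year, (45.7, 59.83, 54.23)) + rep(phc_base), 1.0, 100.0
    )
    demand = rep(demand_rel) * _anchor_interp(rec_year, (10.58, 9.65, 4.58))

    context = pd.DataFrame(
        {
            "marginalization": rep(marginalization),
            "phc_coverage": phc,
            "indigenous_pct": rep(indigenous),
            "demand": demand,
            "gini": rep(gini),
            "gov_support": rep(gov_support),
            "employment": rep(employment),
        }
    )

    # --- inputs: base mean x latent scale x lognormal noise, E = base ---
    sx = config.input_noise
    noise = np.exp(rng.normal(0.0, sx, (n * T, len(INPUT_COLS))) - sx**2 / 2)
    inputs = pd.DataFrame(index=range(n * T), columns=INPUT_COLS, dtype=float)
    for k, col in enumerate(INPUT_COLS):
        base = _anchor_interp(rec_year, INPUT_ANCHORS[col])
        inputs[col] = base * rep(s) * noise[:, k]

    # --- inefficiency and outputs ---
    z = (context - context.mean()) / context.std(ddof=0).replace(0.0, 1.0)
    beta = _context_effect_matrix(config, rec_region)
    link = (beta * z.to_numpy()).sum(axis=1)
    # an all-zero beta row means "no context-driven inefficiency": the link
    # is 0 exactly, not softplus(0) = log 2
    active = (beta != 0).any(axis=1)
    u_idio = np.abs(rng.normal(0.0, config.inefficiency_scale, n * T))
    m_t = year_inefficiency_multiplier(rec_year, config)
    u = m_t * (np.where(active, _softplus(link), 0.0) + u_idio)

    v = rng.normal(0.0, config.noise_scale, n * T) if config.noise_scale > 0 else np.zeros(n * T)
    g = frontier_output(inputs, config)
    treated = g * np.exp(-u) * np.exp(v)
    share = np.clip(
        rng.normal(config.controlled_share, config.controlled_share_sd, n * T),
        0.02, 0.98,
    )
    controlled = share * treated

    panel = pd.concat(
        [
            pd.DataFrame(
                {"jurisdiction_id": rec_id, "year": rec_year, "region": rec_region}
            ),
            inputs,
            pd.DataFrame(
                {"treated_patients": treated, "controlled_patients": controlled}
            ),
            context,
        ],
        axis=1,
    )
    truth = pd.DataFrame(
        {
            "jurisdiction_id": rec_id,
            "year": rec_year,
            "true_farrell": np.exp(u),
            "true_efficiency": np.exp(-u),
        }
    )

    numeric = panel.drop(columns=["jurisdiction_id"]).to_numpy(float)
    if not np.all(np.isfinite(numeric)) or not np.all(
        np.isfinite(truth.drop(columns=["jurisdiction_id"]).to_numpy(float))
    ):
        raise FloatingPointError(
            f"non-finite draw while generating panel (seed={config.seed}); "
            "check config scales"
        )
    return panel, truth
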