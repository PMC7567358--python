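"""Synthetic pharmacy-claims cohort with the structure the score assumes.

Generates claims, cohort and outcomes tables (plus a truth table) so the
full pipeline — condition mapping, scoring, weight derivation,
stratification, validation — runs without access to administrative data.

The data-generating process mirrors the model behind the score:

* each chronic condition is drawn independently per patient with a fixed
  prevalence (defaults: the published cohort prevalences, e.g. diabetes
  9.8%, cardiovascular/cerebrovascular disease 57.1%);
* a flagged patient receives enough prescriptions of that condition's
  drugs in each lookback year to clear the flagging threshold; an
  "occasional user" (a patient without the condition) may receive
  sub-threshold prescriptions, exercising the threshold logic;
* survival is exponential with per-patient hazard
  ``h_i = h0 * exp(sum_j beta_j x_ij)`` using the published coefficients as
  the truth, with ``h0`` calibrated by root-finding so the marginal 1-year
  mortality hits the target (default 2.4%); follow-up is administratively
  censored at 365 days;
* age (normal, mean 67.5, sd 11.8, truncated at 50) and sex (56.1% female)
  are generated for the derivation module's candidate set but do not enter
  the default truth, which contains condition effects only.

Conditions are independent by default; an optional Gaussian-copula
correlation knob exists because real comorbidities cluster — a documented
departure from any claim of realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mapping import MappingTable, default_mapping
from .scoring import WeightTable, default_weights

__all__ = [
    "SimulationParams",
    "default_prevalences",
    "calibrate_baseline",
    "simulate_flags",
    "simulate_cohort",
]

FOLLOW_UP_DAYS = 365
INDEX_DATE = pd.Timestamp("2018-01-01")
LOOKBACK_YEARS = (2016, 2017)


def default_prevalences() -> pd.Series:
    """Per-condition prevalences of the published cohort (fractions)."""
    with resources.files("mcds.data").joinpath("prevalence_default.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("condition")["prevalence"]


def _default_coefficients() -> pd.Series:
    w = default_weights()
    return w.entries.set_index("condition")["coefficient"]


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults reproduce the published cohort's shape."""

    n_patients: int = 10_000
    condition_prevalence: pd.Series = field(default_factory=default_prevalences)
    true_coefficients: pd.Series = field(default_factory=_default_coefficients)
    baseline_1yr_mortality: float = 0.024
    age_mean: float = 67.5
    age_sd: float = 11.8
    age_min: float = 50.0
    female_fraction: float = 0.561
    occasional_user_fraction: float = 0.05
    condition_correlation: float = 0.0   # Gaussian-copula common factor, 0 = independent
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        prev = self.condition_prevalence
        if ((prev < 0) | (prev > 1)).any():
            raise ValueError("prevalences must lie in [0, 1]")
        if not 0 <= self.baseline_1yr_mortality < 1:
            raise ValueError("baseline_1yr_mortality must lie in [0, 1)")


def calibrate_baseline(flags: np.ndarray, betas: np.ndarray,
                       target_mortality: float, follow_up_days: int = FOLLOW_UP_DAYS
                       ) -> float:
    """Daily baseline hazard h0 with marginal 1-year mortality = target.

    Solves ``mean(1 - exp(-h0 * exp(X beta) * T)) = target`` over the
    simulated covariate distribution by monotone root-finding (Brent).
    With all coefficients zero this reduces to the closed form
    ``-ln(1 - target)/T``.
    """
    if target_mortality == 0.0:
        return 0.0
    rel = np.exp(np.asarray(flags, dtype=float) @ np.asarray(betas, dtype=float))

    def gap(h0: float) -> float:
        return float(np.mean(-np.expm1(-h0 * rel * follow_up_days))) - target_mortality

    lo, hi = 1e-12, 1.0
    if gap(hi) < 0:
        raise ValueError("target mortality unreachable with the given hazard structure")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-15, rtol=1e-12))


def simulate_flags(params: SimulationParams, rng: np.random.Generator
                   ) -> pd.DataFrame:
    """Per-patient binary condition truth flags (patients x conditions)."""
    prev = params.condition_prevalence
    n, k = params.n_patients, len(prev)
    rho = params.condition_correlation
    if rho == 0.0:
        flags = rng.random((n, k)) < prev.to_numpy()
    else:
        # one-factor Gaussian copula: z_ij = sqrt(rho) f_i + sqrt(1-rho) e_ij
        f = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((n, k))
        flags = stats.norm.cdf(z) < prev.to_numpy()
    ids = [f"P{i:07d}" for i in range(n)]
    return pd.DataFrame(flags.astype(np.int8), index=pd.Index(ids, name="patient_id"),
                        columns=prev.index)


def _claims_for_flags(flags: pd.DataFrame, table: MappingTable,
                      occasional_fraction: float, rng: np.random.Generator
                      ) -> pd.DataFrame:
    """Prescription rows: above-threshold for true flags, below for occasional users."""
    rule_of_condition: dict[str, list] = {}
    for rule in table:
        rule_of_condition.setdefault(rule.condition, []).append(rule)

    pid_col: list[np.ndarray] = []
    atc_col: list[np.ndarray] = []
    date_col: list[np.ndarray] = []

    year_starts = {y: pd.Timestamp(f"{y}-01-01") for y in LOOKBACK_YEARS}

    for cond in flags.columns:
        rules = rule_of_condition.get(cond)
        if not rules:
            continue
        rule = rules[0]  # claims are drawn from the first rule's patterns
        thr = rule.min_rx_per_year
        codes = np.array([_pattern_to_code(p, rng, rule.exception_codes)
                          for p in rule.atc_patterns])

        flagged = flags.index[flags[cond] == 1].to_numpy()
        unflagged = flags.index[flags[cond] == 0].to_numpy()
        # occasional users only exist for conditions present in the population,
        # and only where a sub-threshold count is possible at all
        if thr > 1 and len(flagged) > 0:
            occ_mask = rng.random(len(unflagged)) < occasional_fraction
            occasional = unflagged[occ_mask]
        else:
            occasional = np.array([], dtype=object)

        for year in LOOKBACK_YEARS:
            for pids, low, high in ((flagged, thr, thr + 2),
                                    (occasional, 1, thr - 1)):
                if len(pids) == 0 or high < low:
                    continue
                counts = rng.integers(low, high + 1, size=len(pids))
                rep = np.repeat(pids, counts)
                total = counts.sum()
                atc = codes[rng.integers(0, len(codes), size=total)]
                days = rng.integers(0, 365, size=total)
                pid_col.append(rep)
                atc_col.append(atc)
                date_col.append(np.full(total, year_starts[year].value)
                                + days * 86_400_000_000_000)

    if not pid_col:
        return pd.DataFrame(columns=["patient_id", "atc_code", "dispense_date",
                                     "n_packages"])
    claims = pd.DataFrame({
        "patient_id": np.concatenate(pid_col),
        "atc_code": np.concatenate(atc_col),
        "dispense_date": pd.to_datetime(np.concatenate(date_col)),
        "n_packages": 1,
    })
    return claims.sort_values(["patient_id", "dispense_date", "atc_code"],
                              kind="stable").reset_index(drop=True)


def _pattern_to_code(pattern: str, rng: np.random.Generator,
                     exclude: tuple[str, ...] = ()) -> str:
    """Expand an ATC prefix to a full 7-character code (deterministic given rng).

    Codes listed in *exclude* (a rule's exception codes, which belong to
    another condition) are never produced.
    """
    for _ in range(100):
        code = pattern
        if len(code) == 1:
            code += f"{rng.integers(1, 17):02d}"
        if len(code) == 3:
            code += "ABCDX"[rng.integers(0, 5)]
        if len(code) == 4:
            code += "ABCDX"[rng.integers(0, 5)]
        if len(code) == 5:
            code += f"{rng.integers(1, 100):02d}"
        if code not in exclude:
            return code
    raise ValueError(f"cannot expand pattern {pattern!r} outside its exceptions")


def simulate_cohort(params: SimulationParams, table: MappingTable | None = None,
                    *, include_claims: bool = True) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic bundle.

    Returns ``{"claims", "cohort", "outcomes", "truth"}``; *truth* carries
    each patient's condition flags, linear predictor and uncensored death
    day.  Fixing ``params.seed`` fixes every output value.
    ``include_claims=False`` skips the (large) prescription table for runs
    that only need flags and outcomes; the other tables are unchanged.
    """
    rng = np.random.default_rng(params.seed)
    if table is None:
        table = default_mapping()

    flags = simulate_flags(params, rng)
    betas = params.true_coefficients.reindex(flags.columns).fillna(0.0)
    h0 = calibrate_baseline(flags.to_numpy(), betas.to_numpy(),
                            params.baseline_1yr_mortality)

    lp = flags.to_numpy(dtype=float) @ betas.to_numpy()
    hazard = h0 * np.exp(lp)
    n = params.n_patients
    if params.baseline_1yr_mortality == 0.0:
        t_death = np.full(n, np.inf)
    else:
        t_death = rng.exponential(1.0, size=n) / hazard
    death_day = np.ceil(t_death).astype(float)
    died = death_day <= FOLLOW_UP_DAYS

    age = params.age_mean + params.age_sd * rng.standard_normal(n)
    age = np.maximum(age, params.age_min)
    female = rng.random(n) < params.female_fraction

    cohort = pd.DataFrame({
        "patient_id": flags.index,
        "age_at_index": np.round(age).astype(int),
        "sex": np.where(female, "female", "male"),
        "index_date": INDEX_DATE,
    })
    outcomes = pd.DataFrame({
        "patient_id": flags.index,
        "death_date": pd.Series(
            np.where(died, (INDEX_DATE + pd.to_timedelta(
                np.where(died, death_day, 1).astype(int), unit="D")).strftime("%Y-%m-%d"),
                None)),
        "hospitalization_date": pd.Series([None] * n, dtype=object),
    })
    outcomes["death_date"] = pd.to_datetime(outcomes["death_date"])
    outcomes["hospitalization_date"] = pd.to_datetime(outcomes["hospitalization_date"])

    if include_claims:
        claims = _claims_for_flags(flags, table, params.occasional_user_fraction, rng)
    else:
        claims = pd.DataFrame(columns=["patient_id", "atc_code", "dispense_date",
                                       "n_packages"])

    truth = flags.reset_index()
    truth["linear_predictor"] = lp
    truth["death_day_uncensored"] = death_day
    return {"claims": claims, "cohort": cohort, "outcomes": outcomes, "truth": truth}
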