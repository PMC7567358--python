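"""ATC-pattern condition mapping: prescriptions -> binary chronic-condition flags.

A mapping table assigns ATC prefixes to named chronic conditions, each with a
minimum number of prescriptions per calendar year (1 for drugs that
unambiguously identify a diagnosis, 2 as the general rule, 3 for drugs that
are also frequent in minor, non-chronic conditions).  A patient is flagged
for a condition when the prescription count reaches the threshold in at
least one calendar year of the two-year lookback window.

Exception codes implement drug reassignments: a full 7-character ATC code
listed as an exception of a rule never contributes to that rule even though
a prefix matches (e.g. midazolam N05CD08 is excluded from the
benzodiazepine-for-anxiety rule because it belongs to epilepsy).

The default table ships the 33 candidate conditions with best-effort ATC
prefixes (marked ``unverified`` in the provenance column) and is meant to be
overridden with a locally validated mapping file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ConditionRule",
    "MappingTable",
    "load_mapping",
    "default_mapping",
    "match_atc",
    "count_condition_rx",
    "flag_conditions",
    "apply_prevalence_floor",
    "map_conditions",
]


def match_atc(code: str, pattern: str) -> bool:
    """Prefix match in the ATC hierarchy; codes shorter than the pattern never match."""
    return code.startswith(pattern)


@dataclass(frozen=True)
class ConditionRule:
    """One condition with its ATC patterns, per-year threshold and exceptions."""

    condition: str
    atc_patterns: tuple[str, ...]
    min_rx_per_year: int = 2
    exception_codes: tuple[str, ...] = ()
    flag: str = ""

    def __post_init__(self):
        if self.min_rx_per_year < 1:
            raise ValueError("min_rx_per_year must be a positive integer")
        if self.min_rx_per_year > 3:
            warnings.warn(
                f"rule {self.condition!r}: min_rx_per_year={self.min_rx_per_year} is larger "
                "than the documented thresholds (1, 2 or 3)", stacklevel=2)

    def matches(self, code: str) -> bool:
        if code in self.exception_codes:
            return False
        return any(match_atc(code, p) for p in self.atc_patterns)


@dataclass
class MappingTable:
    """Ordered rule set; the row order of the mapping file fixes the flag-vector order."""

    rules: list[ConditionRule] = field(default_factory=list)

    @property
    def conditions(self) -> list[str]:
        return [r.condition for r in self.rules]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def validate_overlaps(self) -> None:
        """Raise if two rules can claim the same code without an exception.

        Two patterns overlap iff one is a prefix of the other; the rule with
        the shorter pattern must then list the longer pattern's codes among
        its exceptions (only full 7-character exceptions can discharge an
        overlap exactly; broader overlaps are always an error).
        """
        for i, a in enumerate(self.rules):
            for b in self.rules[i + 1:]:
                for pa in a.atc_patterns:
                    for pb in b.atc_patterns:
                        if not (pa.startswith(pb) or pb.startswith(pa)):
                            continue
                        short, lng = (pa, pb) if len(pa) <= len(pb) else (pb, pa)
                        holder = a if short in a.atc_patterns else b
                        if len(lng) == 7 and lng in holder.exception_codes:
                            continue
                        raise ValueError(
                            f"rules {a.condition!r} and {b.condition!r} overlap on "
                            f"{short!r}/{lng!r} without an exception")


def load_mapping(path_or_df, *, drop_wrong: bool = True) -> MappingTable:
    """Load a mapping file (columns: condition, atc_pattern, min_rx_per_year,
    exception_codes, flag) into a :class:`MappingTable`.

    Rows flagged ``wrong`` (a drug/condition association known to be
    incorrect) are excluded from the active set unless ``drop_wrong=False``.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, keep_default_na=False)
    for col in ("condition", "atc_pattern", "min_rx_per_year"):
        if col not in df.columns:
            raise ValueError(f"mapping file lacks column {col!r}")
    if "exception_codes" not in df.columns:
        df["exception_codes"] = ""
    if "flag" not in df.columns:
        df["flag"] = ""
    if drop_wrong:
        df = df[df["flag"].astype(str).str.strip() != "wrong"]

    rules: list[ConditionRule] = []
    for cond, grp in df.groupby("condition", sort=False):
        thresholds = grp["min_rx_per_year"].astype(int).unique()
        patterns = tuple(grp["atc_pattern"].astype(str).str.strip().str.upper())
        exceptions: list[str] = []
        for cell in grp["exception_codes"].astype(str):
            exceptions += [c.strip().upper() for c in cell.split(";") if c.strip()]
        if len(thresholds) == 1:
            rules.append(ConditionRule(cond, patterns, int(thresholds[0]),
                                       tuple(dict.fromkeys(exceptions)),
                                       str(grp["flag"].iloc[0])))
        else:
            # Per-pattern thresholds: split the condition into one rule per
            # threshold; flags are still OR-ed over the split rules.
            for thr, sub in grp.groupby(grp["min_rx_per_year"].astype(int), sort=True):
                pats = tuple(sub["atc_pattern"].astype(str).str.strip().str.upper())
                rules.append(ConditionRule(cond, pats, int(thr),
                                           tuple(dict.fromkeys(exceptions)),
                                           str(sub["flag"].iloc[0])))
    table = MappingTable(rules)
    table.validate_overlaps()
    return table


def default_mapping() -> MappingTable:
    """The shipped 33-condition table (ATC lists best-effort, marked unverified)."""
    with resources.files("mcds.data").joinpath("mapping_default.csv").open() as fh:
        return load_mapping(pd.read_csv(fh, keep_default_na=False))


def _assign_rules(codes: pd.Series, table: MappingTable) -> pd.Series:
    """Vectorized rule index per code (-1 where no rule matches)."""
    uniq = pd.Index(codes.unique())
    rule_of = pd.Series(-1, index=uniq, dtype=int)
    for i, rule in enumerate(table.rules):
        hit = pd.Series(False, index=uniq)
        for pat in rule.atc_patterns:
            hit |= uniq.str.startswith(pat)
        if rule.exception_codes:
            hit &= ~uniq.isin(rule.exception_codes)
        taken = rule_of >= 0
        rule_of[hit & ~taken] = i
    return codes.map(rule_of)


def count_condition_rx(claims: pd.DataFrame, table: MappingTable,
                       window: tuple[str, str] = ("2016-01-01", "2018-01-01"),
                       ) -> pd.DataFrame:
    """Per-patient, per-rule, per-calendar-year prescription counts.

    ``window`` is half-open ``[start, end)`` and must span whole calendar
    years.  Records outside the window, with unmatched codes, or listed as
    exceptions contribute nothing.  Counts are claim rows, not packages.
    Returns a long frame with columns ``patient_id, rule_index, year, n_rx``.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if not (start.is_year_start and end.is_year_start):
        raise ValueError("lookback window must span whole calendar years")
    inside = (claims["dispense_date"] >= start) & (claims["dispense_date"] < end)
    sub = claims.loc[inside, ["patient_id", "atc_code", "dispense_date"]].copy()
    sub["rule_index"] = _assign_rules(sub["atc_code"], table)
    sub = sub[sub["rule_index"] >= 0]
    sub["year"] = sub["dispense_date"].dt.year
    counts = (sub.groupby(["patient_id", "rule_index", "year"], sort=False)
              .size().rename("n_rx").reset_index())
    return counts


def flag_conditions(counts: pd.DataFrame, table: MappingTable,
                    patient_ids, *, pool_years: bool = False) -> pd.DataFrame:
    """Binary condition profile per patient from per-year counts.

    A flag is raised when the threshold is met in at least one calendar year
    (``pool_years=True`` instead sums counts over the window before
    comparing).  Patients without any qualifying prescriptions keep an
    all-zero profile; conditions split over several rules (per-pattern
    thresholds) are OR-ed into one column.
    """
    patient_ids = pd.Index(pd.Series(patient_ids, dtype=str).unique(), name="patient_id")
    conditions = list(dict.fromkeys(table.conditions))
    profiles = pd.DataFrame(0, index=patient_ids, columns=conditions, dtype=np.int8)
    if len(counts):
        thresholds = np.array([r.min_rx_per_year for r in table.rules])
        if pool_years:
            pooled = counts.groupby(["patient_id", "rule_index"])["n_rx"].sum().reset_index()
            ok = pooled[pooled["n_rx"] >= thresholds[pooled["rule_index"]]]
        else:
            ok = counts[counts["n_rx"] >= thresholds[counts["rule_index"]]]
        cond_of = np.array(table.conditions)
        rows = profiles.index.get_indexer(ok["patient_id"])
        cols = pd.Index(conditions).get_indexer(cond_of[ok["rule_index"]])
        keep = rows >= 0
        vals = profiles.to_numpy()
        vals[rows[keep], cols[keep]] = 1
        profiles = pd.DataFrame(vals, index=profiles.index, columns=profiles.columns)
    return profiles


def apply_prevalence_floor(profiles: pd.DataFrame, min_cases: int = 2
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Drop conditions flagged in fewer than *min_cases* patients.

    Mirrors the exclusion of conditions that are virtually absent in the
    population (a single case cannot support a coefficient).  Returns the
    reduced profile frame and the list of dropped condition names.
    """
    if min_cases < 0:
        raise ValueError("min_cases must be nonnegative")
    totals = profiles.sum(axis=0)
    dropped = [c for c in profiles.columns if totals[c] < min_cases]
    kept = [c for c in profiles.columns if c not in dropped]
    if not kept:
        raise ValueError(
            f"prevalence floor min_cases={min_cases} removed every condition "
            f"({len(profiles)} patients); check the mapping or the floor")
    return profiles[kept], dropped


def map_conditions(claims: pd.DataFrame, patient_ids, table: MappingTable | None = None,
                   window: tuple[str, str] = ("2016-01-01", "2018-01-01"), *,
                   pool_years: bool = False) -> pd.DataFrame:
    """Convenience pipeline: claims -> per-patient binary condition profiles."""
    if table is None:
        table = default_mapping()
    counts = count_condition_rx(claims, table, window)
    return flag_conditions(counts, table, patient_ids, pool_years=pool_years)
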