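"""Death classification, indirect age standardization, and raw SMRs.

Deaths are classified into method groups from ICD-10 codes; certified
suicides (X60-X84), deaths of undetermined intent (Y10-Y34), suffocation
injuries (W75, W76, W83, W84) and pesticide-poisoning injuries (X48) all
count as suicides, following the convention for Taiwanese vital-registration
data where many such deaths are misclassified suicides.

Expected counts use *internal* indirect standardization: the study region
itself, aggregated over the full period, is the standard population, so the
expected counts sum exactly to the observed total for each method and the
region-wide SMR is 1 by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Method groups in presentation order (excluding the sentinel "not_suicide").
METHODS = ("hanging", "charcoal_burning", "jumping", "drowning", "other")

#: 5-year age bands from 10-14 up to an open-ended 85+ band.
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(10, 85, 5)) + ("85+",)

MIN_AGE = 10

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")

# Specific codes -> method group; everything else in the suicide /
# undetermined ranges falls through to "other".
_SPECIFIC = {
    ("X", 67): "charcoal_burning",
    ("Y", 17): "charcoal_burning",
    ("X", 70): "hanging",
    ("Y", 20): "hanging",
    ("W", 75): "hanging",
    ("W", 76): "hanging",
    ("W", 83): "hanging",
    ("W", 84): "hanging",
    ("X", 71): "drowning",
    ("Y", 21): "drowning",
    ("X", 80): "jumping",
    ("Y", 30): "jumping",
}


class InvalidCodeError(ValueError):
    """Raised for ICD-10 codes that do not parse as letter + two digits."""


def classify_method(icd10_code: str) -> str:
    """Map an ICD-10 code to a suicide-method group.

    Returns one of :data:`METHODS` or ``"not_suicide"``.  A trailing decimal
    suffix (e.g. ``"X70.1"``) is ignored.

    Raises
    ------
    InvalidCodeError
        If the code is not letter + two digits (+ optional decimal suffix).
    """
    if not isinstance(icd10_code, str):
        raise InvalidCodeError(f"ICD-10 code must be a string, got {icd10_code!r}")
    m = _CODE_RE.match(icd10_code.strip().upper())
    if m is None:
        raise InvalidCodeError(f"malformed ICD-10 code: {icd10_code!r}")
    letter, num = m.group(1), int(m.group(2))
    specific = _SPECIFIC.get((letter, num))
    if specific is not None:
        return specific
    if letter == "X" and 60 <= num <= 84:
        return "other"
    if letter == "Y" and 10 <= num <= 34:
        return "other"
    if letter == "X" and num == 48:  # pesticide poisoning of undetermined intent
        return "other"
    return "not_suicide"


@dataclass(frozen=True)
class DeathRecord:
    """A single cause-of-death record."""

    area_id: str
    age: int
    icd10_code: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be nonnegative, got {self.age}")


def filter_eligible(records):
    """Keep records aged >= 10 whose code classifies as a suicide method.

    Accepts either a sequence of :class:`DeathRecord` or a DataFrame with
    ``age`` and ``icd10_code`` columns; returns the same kind of container
    with a ``method`` classification attached (DataFrame input gains a
    ``method`` column).
    """
    if isinstance(records, pd.DataFrame):
        out = records.copy()
        out["method"] = [classify_method(c) for c in out["icd10_code"]]
        keep = (out["age"] >= MIN_AGE) & (out["method"] != "not_suicide")
        return out.loc[keep].reset_index(drop=True)
    return [
        r
        for r in records
        if r.age >= MIN_AGE and classify_method(r.icd10_code) != "not_suicide"
    ]


def age_to_band(age: int, bands=AGE_BANDS) -> str:
    """Assign an age in years to its 5-year band (open-ended top band)."""
    if age < MIN_AGE:
        raise ValueError(f"age {age} below study minimum of {MIN_AGE}")
    top_lo = int(bands[-1].rstrip("+"))
    if age >= top_lo:
        return bands[-1]
    idx = (age - MIN_AGE) // 5
    return bands[idx]


def expected_counts(populations: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """Expected deaths per area and method by internal indirect standardization.

    Parameters
    ----------
    populations
        Person-periods at risk, indexed by area_id with one column per age
        band (all bands present in ``deaths`` must appear).
    deaths
        Long-format counts with columns ``area_id``, ``age_band``, ``method``
        and ``count``.

    Returns
    -------
    DataFrame indexed by area_id, one column per method, where
    ``E[i, m] = sum_a n[i, a] * D[a, m] / N[a]`` with ``D`` and ``N`` the
    region-wide band totals.  Columns sum to the region-wide death total.
    """
    if populations.index.has_duplicates:
        raise ValueError("duplicate area_id in populations")
    band_totals = populations.sum(axis=0)  # N_a
    death_band = (
        deaths.groupby(["age_band", "method"])["count"].sum().unstack(fill_value=0)
    )  # D_{a,m}
    missing = set(death_band.index) - set(populations.columns)
    if missing:
        raise ValueError(f"deaths recorded in age bands absent from populations: {sorted(missing)}")
    death_band = death_band.reindex(populations.columns, fill_value=0)
    empty = (band_totals <= 0) & (death_band.sum(axis=1) > 0)
    if empty.any():
        bad = list(band_totals.index[empty])
        raise ValueError(f"deaths in age bands with zero population: {bad}")
    rates = death_band.div(band_totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    expected = populations.to_numpy(dtype=float) @ rates.to_numpy(dtype=float)
    return pd.DataFrame(expected, index=populations.index, columns=rates.columns)


def raw_smr(observed, expected):
    """Observed / expected; expects strictly positive expected counts."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected count must be positive to form an SMR")
    out = observed / expected
    return out if out.ndim else float(out)


@dataclass
class AreaFrame:
    """The analysis table: per-area observed and expected counts by method,
    plus covariates and (optionally) the person-period population table."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    covariates: pd.DataFrame
    population: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observed.index.equals(self.expected.index):
            raise ValueError("observed and expected must share an area index")
        if not self.observed.index.equals(self.covariates.index):
            raise ValueError("covariates must share the area index")

    @property
    def area_ids(self) -> pd.Index:
        return self.observed.index

    @property
    def methods(self) -> list[str]:
        return list(self.observed.columns)

    @property
    def n_areas(self) -> int:
        return len(self.observed)

    def counts(self, method: str) -> tuple[np.ndarray, np.ndarray]:
        """(O, E) arrays for one method, or the all-method sum for 'overall'."""
        if method == "overall":
            return (
                self.observed.sum(axis=1).to_numpy(dtype=float),
                self.expected.sum(axis=1).to_numpy(dtype=float),
            )
        return (
            self.observed[method].to_numpy(dtype=float),
            self.expected[method].to_numpy(dtype=float),
        )

    def raw_smr(self, method: str) -> pd.Series:
        o, e = self.counts(method)
        return pd.Series(raw_smr(o, e), index=self.area_ids, name=f"smr_{method}")

    def validate(self, rtol: float = 1e-9) -> None:
        """Check the internal-standardization identity sum(E) == sum(O)."""
        for m in self.methods:
            o, e = self.observed[m].sum(), self.expected[m].sum()
            if o > 0 and abs(e - o) > rtol * max(o, 1.0):
                raise AssertionError(f"sum(E) != sum(O) for method {m!r}: {e} vs {o}")


def build_area_frame(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    covariates: pd.DataFrame,
    bands=AGE_BANDS,
) -> AreaFrame:
    """Classify, filter, tabulate and standardize raw inputs into an AreaFrame.

    ``deaths`` has columns area_id, age, icd10_code and optionally count;
    ``populations`` is indexed by area_id with age-band columns;
    ``covariates`` is indexed by area_id.
    """
    deaths = deaths.copy()
    if "count" not in deaths.columns:
        deaths["count"] = 1
    deaths = filter_eligible(deaths)
    deaths["age_band"] = [age_to_band(a, bands) for a in deaths["age"]]
    tab = (
        deaths.groupby(["area_id", "method"])["count"].sum().unstack(fill_value=0)
    )
    observed = tab.reindex(index=populations.index, columns=list(METHODS), fill_value=0)
    observed = observed.fillna(0).astype(int)
    long = deaths.groupby(["area_id", "age_band", "method"], as_index=False)["count"].sum()
    expected = expected_counts(populations[list(bands)], long)
    expected = expected.reindex(columns=list(METHODS), fill_value=0.0)
    covariates = covariates.reindex(populations.index)
    return AreaFrame(observed=observed, expected=expected, covariates=covariates,
                     population=populations)
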