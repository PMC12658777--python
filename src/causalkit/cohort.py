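"""Cohort construction: placeholder recoding, variable retention scoring,
extreme-contrast treatment binarization, and outcome normalization/selection.

Registry exports encode many flavours of missingness (not collected, refused,
logical skip, unknown) as integer placeholder codes.  The functions here
recode those to NaN, score each variable on completeness and data quality,
drop variables failing the missingness/quality rules, convert a continuous
exposure into a binary extreme-contrast treatment, and min-max normalize
candidate outcomes, excluding those too invariant or too incomplete to
support effect estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "VariableReport",
    "ContrastSpec",
    "OutcomeReport",
    "DegenerateContrastError",
    "recode_special_codes",
    "score_and_filter_variables",
    "binarize_extreme_contrast",
    "normalize_and_select_outcomes",
]


class DegenerateContrastError(ValueError):
    """An extreme-contrast cut excluded every subject."""


@dataclass
class VariableReport:
    """Retention audit for one variable.

    completeness = proportion non-missing; quality = proportion valid
    (neither missing nor a placeholder code); retention_score = unweighted
    mean of the two, reported so alternative combiners are auditable.
    """

    name: str
    completeness: float
    quality: float
    retention_score: float
    kept: bool
    drop_reason: str = "none"  # {none, missingness, quality}


@dataclass(frozen=True)
class ContrastSpec:
    """Cut points for extreme-contrast binarization of a continuous exposure.

    Values <= low_cut fall in one tail, >= high_cut in the other; strictly
    intermediate values are excluded.  Cuts are inclusive.  ``treated_side``
    names the tail labelled T=1.
    """

    low_cut: float
    high_cut: float
    treated_side: str = "low"  # {"low", "high"}
    units: str = "days"

    def __post_init__(self):
        if not self.low_cut < self.high_cut:
            raise ValueError("low_cut must be < high_cut")
        if self.treated_side not in ("low", "high"):
            raise ValueError("treated_side must be 'low' or 'high'")


@dataclass
class CohortTable:
    """A rectangular cohort with optional per-variable metadata."""

    frame: pd.DataFrame
    variable_reports: list = field(default_factory=list)

    def __len__(self):
        return len(self.frame)


def _as_frame(table) -> pd.DataFrame:
    return table.frame if isinstance(table, CohortTable) else table


def recode_special_codes(table, codes) -> pd.DataFrame:
    """Replace every cell whose value is in ``codes`` with NaN.

    Cell count and all non-placeholder values are preserved.
    """
    codes = set(codes)
    if not codes:
        raise ValueError("codes must be nonempty")
    df = _as_frame(table)
    return df.mask(df.isin(list(codes)))


def score_and_filter_variables(
    table,
    miss_max: float = 0.60,
    invalid_max: float = 0.90,
    special_codes=(),
    exclude=(),
):
    """Score every variable on completeness/quality and drop failures.

    A variable is dropped when its missingness exceeds ``miss_max`` or its
    invalid proportion (missing or placeholder) exceeds ``invalid_max``.
    ``exclude`` is an optional user-supplied list of variables to remove up
    front on clinical-relevance/redundancy grounds (an expert judgment, not
    an algorithm).  Returns ``(filtered DataFrame, [VariableReport])``.
    """
    for thr in (miss_max, invalid_max):
        if not (0 < thr < 1):
            raise ValueError("thresholds must lie in (0, 1)")
    df = _as_frame(table)
    df = df.drop(columns=[c for c in exclude if c in df.columns])
    codes = set(special_codes)

    reports = []
    kept_cols = []
    n = len(df)
    for col in df.columns:
        s = df[col]
        missing = s.isna()
        placeholder = s.isin(list(codes)) if codes else pd.Series(False, index=s.index)
        completeness = 1.0 if n == 0 else float((~missing).mean())
        invalid = 0.0 if n == 0 else float((missing | placeholder).mean())
        quality = 1.0 - invalid
        retention = 0.5 * (completeness + quality)
        missingness = 1.0 - completeness
        if missingness > miss_max:
            kept, reason = False, "missingness"
        elif invalid > invalid_max:
            kept, reason = False, "quality"
        else:
            kept, reason = True, "none"
        reports.append(VariableReport(col, completeness, quality, retention, kept, reason))
        if kept:
            kept_cols.append(col)

    if not kept_cols:
        import warnings

        warnings.warn("all variables dropped: empty cohort", stacklevel=2)
    return df[kept_cols], reports


def binarize_extreme_contrast(values, spec: ContrastSpec):
    """Map a continuous exposure to a binary extreme-contrast treatment.

    Returns ``(treatment, included)`` where ``included`` is False for
    subjects strictly between the cuts (and for missing values).  Treatment
    labels follow ``spec.treated_side``; excluded positions carry -1.
    """
    v = np.asarray(values, dtype=float)
    low = v <= spec.low_cut
    high = v >= spec.high_cut
    included = (low | high) & ~np.isnan(v)
    if not included.any():
        raise DegenerateContrastError("every value falls in the excluded intermediate band")
    treatment = np.full(v.shape, -1, dtype=int)
    treated_tail = low if spec.treated_side == "low" else high
    control_tail = high if spec.treated_side == "low" else low
    treatment[included & treated_tail] = 1
    treatment[included & control_tail] = 0
    return treatment, included


@dataclass
class OutcomeReport:
    name: str
    missingness: float
    normalized_sd: float
    kept: bool
    reason: str = "none"  # {none, missingness, low_sd, degenerate}


def normalize_and_select_outcomes(
    table,
    outcome_names,
    sd_min: float = 0.15,
    miss_max: float = 0.30,
    bounds: dict | None = None,
):
    """Min-max scale candidate outcomes to [0, 1] and keep the usable ones.

    An outcome is excluded when its missingness exceeds ``miss_max``, when it
    is constant (degenerate scale), or when its normalized standard deviation
    falls below ``sd_min``.  ``bounds`` may supply theoretical scale bounds
    per outcome (e.g. an ordinal 1-7 functional scale) used instead of the
    empirical min/max for comparability across cohorts.  Returns
    ``(DataFrame of selected normalized outcomes, [OutcomeReport])``.
    """
    df = _as_frame(table)
    bounds = bounds or {}
    selected = {}
    reports = []
    for name in outcome_names:
        y = pd.to_numeric(df[name], errors="coerce")
        missingness = float(y.isna().mean())
        if missingness > miss_max:
            reports.append(OutcomeReport(name, missingness, float("nan"), False, "missingness"))
            continue
        if name in bounds:
            lo, hi = bounds[name]
        else:
            lo, hi = float(y.min()), float(y.max())
        if not hi > lo:
            reports.append(OutcomeReport(name, missingness, 0.0, False, "degenerate"))
            continue
        z = (y - lo) / (hi - lo)
        sd = float(z.std(ddof=1))
        if sd < sd_min:
            reports.append(OutcomeReport(name, missingness, sd, False, "low_sd"))
            continue
        selected[name] = z
        reports.append(OutcomeReport(name, missingness, sd, True, "none"))
    return pd.DataFrame(selected), reports
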