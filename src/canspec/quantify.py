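"""Multi-chip, multi-timepoint quantification and group statistics.

Summaries follow the conventions of adhesion-based viability assays:
mean ΔS_V over cell-detecting sensors per chip and timepoint, covered-area
time courses with fold changes, the colorimetric (CCK-8 / OD450) viability
arithmetic, and unpaired-t / ANOVA comparisons annotated with the
four-level star scheme (ns, * p≤0.05, ** p≤0.01, *** p≤0.001,
**** p≤0.0001). No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectral import AdhesionNoiseMap

__all__ = [
    "ChipTimepointRecord",
    "TimeCourseTable",
    "ViabilityRecord",
    "mean_dsv_over_cells",
    "viability_from_od",
    "fold_change",
    "significance_stars",
    "group_compare",
]

DEFAULT_SCHEDULE = (0.0, 24.0, 48.0, 72.0)


def mean_dsv_over_cells(noise_map: AdhesionNoiseMap, mask: np.ndarray) -> float:
    """Arithmetic mean of raw (unclamped) ΔS_V over mask-true sensors.

    Uses the unclamped values so negative excursions do not bias the mean
    upward. Undefined (error) for an empty mask.
    """
    m = np.asarray(mask, dtype=bool).reshape(-1)
    if m.size != noise_map.spec.n_sensors:
        raise ValueError("mask size does not match the sensor grid")
    if not m.any():
        raise ValueError("mean ΔS_V is undefined for an empty mask")
    return float(noise_map.raw_values[m].mean())


def viability_from_od(sample_od: float, blank_od: float, control_od: float) -> float:
    """Cell viability (%) = (sample − blank) / (control − blank) · 100.

    Unbounded above: proliferating samples can exceed 100%. Invariant to
    a common offset added to all three absorbances.
    """
    if control_od == blank_od:
        raise ValueError("control and blank OD must differ")
    return 100.0 * (sample_od - blank_od) / (control_od - blank_od)


@dataclass(frozen=True)
class ViabilityRecord:
    """One CCK-8 well: raw absorbances and the derived viability."""

    sample_od: float
    blank_od: float
    control_od: float
    viability_pct: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "viability_pct", viability_from_od(self.sample_od, self.blank_od, self.control_od)
        )


def fold_change(area_t1: float, area_t0: float) -> tuple[float, str]:
    """Fold change between a baseline and a later value, direction-labelled.

    Returns ``(ratio, direction)`` with ratio ≥ 1: an increase is reported
    as t1/t0 ("increase"), a decline as t0/t1 ("decline"), equality as
    (1.0, "flat"). With this convention
    ``fold_change(a, b)[0] == fold_change(b, a)[0]``.
    """
    if area_t0 <= 0:
        raise ValueError("baseline must be positive")
    if area_t1 == area_t0:
        return 1.0, "flat"
    if area_t1 > area_t0:
        return area_t1 / area_t0, "increase"
    if area_t1 <= 0:
        raise ValueError("fold change undefined for a non-positive later value")
    return area_t0 / area_t1, "decline"


@dataclass(frozen=True)
class ChipTimepointRecord:
    """One chip at one timepoint: area, mean ΔS_V and sensor count."""

    chip: str
    condition: str  # "untreated" | "treated" (free labels allowed)
    timepoint_h: float
    covered_area_pct: float
    mean_delta_sv: float | None = None  # V²/Hz; None when no cell sensors
    n_cell_sensors: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_sensors == 0 and self.mean_delta_sv is not None:
            raise ValueError("mean_delta_sv is defined only when n_cell_sensors > 0")


@dataclass
class TimeCourseTable:
    """Tidy collection of per-chip, per-timepoint records."""

    records: list[ChipTimepointRecord] = field(default_factory=list)
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE

    def add(self, record: ChipTimepointRecord) -> None:
        if record.timepoint_h not in self.schedule:
            raise ValueError(
                f"timepoint {record.timepoint_h} h not in the declared schedule {self.schedule}"
            )
        if any(
            r.chip == record.chip and r.timepoint_h == record.timepoint_h for r in self.records
        ):
            raise ValueError(
                f"duplicate record for chip {record.chip!r} at {record.timepoint_h} h"
            )
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chip": r.chip,
                    "condition": r.condition,
                    "timepoint_h": r.timepoint_h,
                    "covered_area_pct": r.covered_area_pct,
                    "mean_delta_sv": r.mean_delta_sv,
                    "n_cell_sensors": r.n_cell_sensors,
                }
                for r in self.records
            ]
        )


STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Four-level star annotation: ns, *, **, ***, **** (p ≤ 1e-4)."""
    if np.isnan(p):
        return "na"
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def _ttest_unpaired(a: np.ndarray, b: np.ndarray) -> float:
    """Unpaired two-sided t-test p-value with a defined degenerate limit.

    Zero pooled variance is off the t-distribution's support: equal means
    then give p = 1 (indistinguishable groups), different means p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


def group_compare(
    table: TimeCourseTable,
    design: str = "two_group_t",
    value: str = "covered_area_pct",
) -> pd.DataFrame:
    """Group-comparison statistics over a time-course table.

    Designs:

    * ``two_group_t`` — unpaired t-test untreated vs. treated at each
      timepoint;
    * ``one_way_time`` — one-way ANOVA across timepoints within each
      condition;
    * ``two_way`` — two-way fixed-effects ANOVA (condition, time,
      condition×time interaction).

    Cells of the design with fewer than two records per group yield NA
    p-values with a warning. This is reporting plumbing, not a
    methodological claim.
    """
    df = table.to_dataframe()
    if df.empty:
        raise ValueError("time-course table is empty")
    rows: list[dict] = []
    if design == "two_group_t":
        conditions = sorted(df["condition"].unique())
        if len(conditions) != 2:
            raise ValueError(f"two_group_t needs exactly 2 conditions, found {conditions}")
        for t in sorted(df["timepoint_h"].unique()):
            groups = [
                df[(df["condition"] == c) & (df["timepoint_h"] == t)][value].to_numpy()
                for c in conditions
            ]
            if min(len(g) for g in groups) < 2:
                warnings.warn(f"insufficient replication at {t} h; reporting NA")
                p = float("nan")
            else:
                p = _ttest_unpaired(groups[0], groups[1])
            rows.append(
                {
                    "comparison": f"{conditions[0]} vs {conditions[1]} @ {t:g} h",
                    "test": "unpaired t",
                    "p_value": p,
                    "stars": significance_stars(p),
                }
            )
    elif design == "one_way_time":
        for cond in sorted(df["condition"].unique()):
            sub = df[df["condition"] == cond]
            groups = [
                sub[sub["timepoint_h"] == t][value].to_numpy()
                for t in sorted(sub["timepoint_h"].unique())
            ]
            if len(groups) < 2 or min(len(g) for g in groups) < 2:
                warnings.warn(f"insufficient replication for condition {cond!r}; reporting NA")
                p = float("nan")
            else:
                p = float(stats.f_oneway(*groups).pvalue)
            rows.append(
                {
                    "comparison": f"{cond}: across timepoints",
                    "test": "one-way ANOVA",
                    "p_value": p,
                    "stars": significance_stars(p),
                }
            )
    elif design == "two_way":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        counts = df.groupby(["condition", "timepoint_h"]).size()
        if (counts < 2).any():
            warnings.warn("insufficient replication in some design cells; reporting NA")
            for effect in ("condition", "timepoint", "condition x timepoint"):
                rows.append(
                    {"comparison": effect, "test": "two-way ANOVA", "p_value": float("nan"), "stars": "na"}
                )
        else:
            d = df.rename(columns={value: "y"})
            model = smf.ols("y ~ C(condition) + C(timepoint_h) + C(condition):C(timepoint_h)", d).fit()
            anova = sm.stats.anova_lm(model, typ=2)
            names = {
                "C(condition)": "condition",
                "C(timepoint_h)": "timepoint",
                "C(condition):C(timepoint_h)": "condition x timepoint",
            }
            for key, name in names.items():
                p = float(anova.loc[key, "PR(>F)"])
                rows.append(
                    {"comparison": name, "test": "two-way ANOVA", "p_value": p, "stars": significance_stars(p)}
                )
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(rows)
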