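"""Stratified episode counts, proportions and confidence intervals.

Produces the study-style summary tables: episode counts by calendar year,
sex and ten-year age band, with the proportion admitted through the
emergency department and the proportion undergoing an invasive procedure
(coronary angiography, angioplasty or bypass), each with a binomial 95%
confidence interval. The default interval is the Wald normal approximation,
p ± z·sqrt(p(1−p)/n) with z = Φ⁻¹((1+level)/2) ≈ 1.959964 at 95%, bounds
clipped to [0, 1]; Wilson score intervals are available behind a flag.
Display values are percentages rounded half-up to one decimal; internal
values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .episode_builder import Episode

__all__ = [
    "AGE_BANDS",
    "assign_age_band",
    "ProportionCI",
    "wald_ci",
    "StratumRow",
    "StratumTable",
    "tabulate_by",
    "episodes_to_frame",
    "trend_series",
    "plot_trends",
]

#: Ten-year age bands with an open-ended terminal band.
AGE_BANDS = ["0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "≥80"]

STRATUM_DIMENSIONS = ("year", "sex", "age_band")


def assign_age_band(age_years: int) -> str:
    """Map an age in years to its ten-year band label ("0-9" … "≥80")."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years >= 80:
        return "≥80"
    lo = (age_years // 10) * 10
    return f"{lo}-{lo + 9}"


def _round1(value: float) -> float:
    """Round half-up to one decimal (display convention for percentages).

    Pre-quantizes at 9 decimals so binary float error (e.g. 100*0.3445 ->
    34.449999999999996) does not push an exact midpoint off .x5.
    """
    exact = Decimal(repr(value)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its confidence interval.

    ``proportion``, ``lower`` and ``upper`` hold full-precision fractions in
    [0, 1]; the ``percent`` / ``ci_low`` / ``ci_high`` properties give the
    1-decimal display percentages.
    """

    numerator: int
    denominator: int
    proportion: float
    lower: float
    upper: float
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def percent(self) -> float:
        return _round1(100.0 * self.proportion)

    @property
    def ci_low(self) -> float:
        return _round1(100.0 * self.lower)

    @property
    def ci_high(self) -> float:
        return _round1(100.0 * self.upper)

    def display(self) -> str:
        return f"{self.percent:.1f} ({self.ci_low:.1f}, {self.ci_high:.1f})"


def wald_ci(
    numerator: int,
    denominator: int,
    level: float = 0.95,
    method: str = "wald",
) -> ProportionCI:
    """Binomial proportion CI; Wald by default, Wilson behind the flag.

    Wald: p ± z·sqrt(p(1−p)/n), z the standard-normal quantile at
    (1+level)/2, bounds clipped to [0, 1]. Degenerate proportions (0/n or
    n/n) therefore collapse to a zero-width Wald interval.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    if method == "wald":
        z = norm.ppf(0.5 * (1.0 + level))
        half = z * np.sqrt(p * (1.0 - p) / denominator)
        lower, upper = p - half, p + half
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lower, upper = proportion_confint(numerator, denominator, alpha=1 - level, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ProportionCI(
        numerator=numerator,
        denominator=denominator,
        proportion=p,
        lower=max(0.0, float(lower)),
        upper=min(1.0, float(upper)),
        confidence_level=level,
    )


@dataclass(frozen=True)
class StratumRow:
    """One table row: stratum labels, episode count, ED and invasive CIs.

    ``ed`` and ``invasive`` are None only for an empty stratum (n = 0),
    where the proportions are undefined.
    """

    labels: tuple[tuple[str, str], ...]  # ((dimension, value), ...)
    n_episodes: int
    ed: ProportionCI | None
    invasive: ProportionCI | None

    @property
    def is_total(self) -> bool:
        return all(v == "Total" for _, v in self.labels)


@dataclass(frozen=True)
class StratumTable:
    """Stratified counts with a Total row; see :func:`tabulate_by`."""

    strata: tuple[str, ...]
    rows: tuple[StratumRow, ...]
    confidence_level: float = 0.95

    @property
    def total(self) -> StratumRow:
        return next(r for r in self.rows if r.is_total)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = dict(row.labels)
            rec["n_episodes"] = row.n_episodes
            for name, ci in (("ed", row.ed), ("invasive", row.invasive)):
                rec[f"n_{name}"] = ci.numerator if ci else 0
                rec[f"pct_{name}"] = ci.percent if ci else float("nan")
                rec[f"ci_low_{name}"] = ci.ci_low if ci else float("nan")
                rec[f"ci_high_{name}"] = ci.ci_high if ci else float("nan")
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def episodes_to_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Flatten episodes to the DataFrame tabulation operates on."""
    return pd.DataFrame.from_records(
        [
            {
                "episode_id": e.episode_id,
                "patient_id": e.patient_id,
                "year": e.year,
                "sex": e.sex,
                "age_band": assign_age_band(e.age_years),
                "ed_admission": e.ed_admission,
                "has_invasive": e.has_invasive,
                "n_claims": e.n_claims,
            }
            for e in episodes
        ],
        columns=[
            "episode_id",
            "patient_id",
            "year",
            "sex",
            "age_band",
            "ed_admission",
            "has_invasive",
            "n_claims",
        ],
    )


def _row_from_counts(
    labels: tuple[tuple[str, str], ...],
    n: int,
    n_ed: int,
    n_inv: int,
    level: float,
    method: str,
) -> StratumRow:
    if n == 0:
        return StratumRow(labels=labels, n_episodes=0, ed=None, invasive=None)
    return StratumRow(
        labels=labels,
        n_episodes=n,
        ed=wald_ci(n_ed, n, level, method),
        invasive=wald_ci(n_inv, n, level, method),
    )


def tabulate_by(
    episodes: Iterable[Episode] | pd.DataFrame,
    strata: Sequence[str] = ("year",),
    level: float = 0.95,
    method: str = "wald",
) -> StratumTable:
    """Stratified episode counts with ED and invasive proportions + CIs.

    ``strata`` is drawn from {"year", "sex", "age_band"}; one row per
    observed stratum combination plus a Total row. Episodes with an unknown
    admission route stay in every denominator and count as non-ED in the
    numerator. Stratum counts always sum to the Total row's count.
    """
    strata = tuple(strata)
    for dim in strata:
        if dim not in STRATUM_DIMENSIONS:
            raise ValueError(f"unknown stratum dimension {dim!r}; use {STRATUM_DIMENSIONS}")
    frame = episodes if isinstance(episodes, pd.DataFrame) else episodes_to_frame(episodes)
    rows: list[StratumRow] = []
    if len(frame) and strata:
        grouped = frame.groupby(list(strata), observed=True, sort=True)
        for key, sub in grouped:
            if not isinstance(key, tuple):
                key = (key,)
            labels = tuple((dim, str(k)) for dim, k in zip(strata, key))
            rows.append(
                _row_from_counts(
                    labels,
                    len(sub),
                    int(sub["ed_admission"].sum()),
                    int(sub["has_invasive"].sum()),
                    level,
                    method,
                )
            )
    total_labels = tuple((dim, "Total") for dim in strata) or (("all", "Total"),)
    rows.append(
        _row_from_counts(
            total_labels,
            len(frame),
            int(frame["ed_admission"].sum()) if len(frame) else 0,
            int(frame["has_invasive"].sum()) if len(frame) else 0,
            level,
            method,
        )
    )
    return StratumTable(strata=strata, rows=tuple(rows), confidence_level=level)


def trend_series(table: StratumTable) -> pd.DataFrame:
    """Per-year counts and proportions for trend plotting.

    Requires ``year`` among the table's strata; returns an ordered frame of
    (year, n_total, n_ed, n_invasive, pct_ed, pct_invasive).
    """
    if "year" not in table.strata:
        raise ValueError("trend_series requires a table stratified by year")
    records = []
    for row in table.rows:
        labels = dict(row.labels)
        if labels.get("year", "Total") == "Total":
            continue
        if any(v != "Total" and dim != "year" for dim, v in row.labels):
            continue  # only marginal year rows
        records.append(
            {
                "year": int(labels["year"]),
                "n_total": row.n_episodes,
                "n_ed": row.ed.numerator if row.ed else 0,
                "n_invasive": row.invasive.numerator if row.invasive else 0,
                "pct_ed": row.ed.percent if row.ed else float("nan"),
                "pct_invasive": row.invasive.percent if row.invasive else float("nan"),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["year", "n_total", "n_ed", "n_invasive", "pct_ed", "pct_invasive"],
    ).sort_values("year", ignore_index=True)


def plot_trends(series: pd.DataFrame, path) -> None:
    """Two-panel trend figure: yearly admission counts and proportions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(series["year"], series["n_total"], "o-", label="Total admissions")
    ax1.plot(series["year"], series["n_ed"], "s-", label="Through ED")
    ax1.plot(series["year"], series["n_invasive"], "^-", label="With invasive procedure")
    ax1.set_xlabel("Year")
    ax1.set_ylabel("Admission episodes")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(series["year"], series["pct_ed"], "s-", label="% through ED")
    ax2.plot(series["year"], series["pct_invasive"], "^-", label="% with invasive procedure")
    ax2.set_xlabel("Year")
    ax2.set_ylabel("% of admission episodes")
    ax2.set_ylim(0, 100)
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
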