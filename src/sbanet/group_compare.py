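"""Regime x habitat comparison of network attributes.

The 8 numeric attributes of each (regime, habitat) summary row are treated
as replicate responses of that cell, giving a balanced two-way fixed-effects
layout (with the default design: 2 x 5 cells x 8 = 80 observations). The
omnibus test is a two-way ANOVA with interaction (Type III sums of squares,
which coincide with sequential sums under balance); pairwise follow-up uses
Fisher's least significant difference on the marginal means with the full
model's error term.

Caveat, documented deliberately: pooling attributes measured on different
scales (counts, percentages) as replicates is statistically questionable,
but it is the comparison this pipeline is specified to reproduce.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._constants import HABITATS, REGIMES
from .network_metrics import NUMERIC_ATTRIBUTES, NetworkSummary

ANOVA_SOURCES = (
    "corrected_model",
    "intercept",
    "sites",
    "habitat",
    "sites_x_habitat",
    "error",
    "total",
    "corrected_total",
)


class DesignError(ValueError):
    """The factor layout is not the supported balanced full design."""


@dataclass
class ResponseTable:
    """Long-format balanced response table: one row per observation."""

    regime: np.ndarray  # str array, length N
    habitat: np.ndarray  # str array, length N
    attribute: np.ndarray  # str array, length N
    value: np.ndarray  # float array, length N

    def __len__(self) -> int:
        return len(self.value)

    def cell_values(self, regime: str, habitat: str) -> np.ndarray:
        mask = (self.regime == regime) & (self.habitat == habitat)
        return self.value[mask]


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


@dataclass
class AnovaTable:
    rows: dict[str, AnovaRow]
    r_squared: float
    adj_r_squared: float

    def __getitem__(self, source: str) -> AnovaRow:
        return self.rows[source]


@dataclass
class LsdPair:
    level_i: str
    level_j: str
    mean_diff: float
    standard_error: float
    t: float
    p: float
    significant: bool


@dataclass
class LsdResult:
    factor: str
    alpha: float
    error_df: int
    pairs: list[LsdPair]

    def pair(self, a: str, b: str) -> LsdPair:
        for p in self.pairs:
            if {p.level_i, p.level_j} == {a, b}:
                return p
        raise KeyError(f"no pair ({a}, {b})")


def build_response_table(summaries: list[NetworkSummary]) -> ResponseTable:
    """Melt the numeric attributes of per-stratum summaries into responses.

    Requires exactly one summary per (regime, habitat) cell of the full
    2 x 5 design; hub species lists are dropped.
    """
    seen: set[tuple[str, str]] = set()
    for s in summaries:
        key = (s.regime, s.habitat)
        if key in seen:
            raise DesignError(f"duplicate summary for cell {key}")
        seen.add(key)
    for cell in itertools.product(REGIMES, HABITATS):
        if cell not in seen:
            raise DesignError(f"missing summary for cell {cell}")

    regime, habitat, attribute, value = [], [], [], []
    for s in summaries:
        for attr, val in zip(NUMERIC_ATTRIBUTES, s.numeric_values()):
            regime.append(s.regime)
            habitat.append(s.habitat)
            attribute.append(attr)
            value.append(val)
    return ResponseTable(
        regime=np.array(regime),
        habitat=np.array(habitat),
        attribute=np.array(attribute),
        value=np.array(value, dtype=float),
    )


def _check_balanced(table: ResponseTable) -> tuple[list[str], list[str], int]:
    regimes = sorted(set(table.regime))
    habitats = sorted(set(table.habitat))
    counts = {
        (r, h): int(((table.regime == r) & (table.habitat == h)).sum())
        for r in regimes
        for h in habitats
    }
    sizes = set(counts.values())
    if len(sizes) != 1:
        raise DesignError(f"unbalanced design: cell sizes {sorted(sizes)}")
    reps = sizes.pop()
    if reps < 2:
        raise DesignError(f"need >= 2 replicates per cell, got {reps}")
    return regimes, habitats, reps


def anova_two_way(table: ResponseTable) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Closed-form between-group sums of squares; F against the within-cell
    mean square; R^2 from the corrected model.
    """
    regimes, habitats, reps = _check_balanced(table)
    y = table.value
    n = len(y)
    grand = y.mean()

    ss_intercept = n * grand**2
    ss_total = float((y**2).sum())
    ss_ctotal = float(((y - grand) ** 2).sum())

    per_regime = n // len(regimes)
    per_habitat = n // len(habitats)
    ss_sites = sum(
        per_regime * (y[table.regime == r].mean() - grand) ** 2 for r in regimes
    )
    ss_habitat = sum(
        per_habitat * (y[table.habitat == h].mean() - grand) ** 2
        for h in habitats
    )
    ss_cells = sum(
        reps * (table.cell_values(r, h).mean() - grand) ** 2
        for r in regimes
        for h in habitats
    )
    ss_inter = ss_cells - ss_sites - ss_habitat
    ss_error = ss_ctotal - ss_cells

    df_sites = len(regimes) - 1
    df_habitat = len(habitats) - 1
    df_inter = df_sites * df_habitat
    df_model = df_sites + df_habitat + df_inter
    df_error = n - len(regimes) * len(habitats)

    ms_error = ss_error / df_error

    def effect(source: str, ss: float, df: int) -> AnovaRow:
        ms = ss / df
        if ms_error > 0:
            f = ms / ms_error
            p = float(stats.f.sf(f, df, df_error))
        else:  # zero residual variance: report a degenerate, non-significant test
            f = 0.0 if ss == 0 else float("inf")
            p = 1.0 if ss == 0 else 0.0
        return AnovaRow(source, ss, df, ms, f, p)

    rows = {
        "corrected_model": effect("corrected_model", ss_cells, df_model),
        "intercept": effect("intercept", ss_intercept, 1),
        "sites": effect("sites", ss_sites, df_sites),
        "habitat": effect("habitat", ss_habitat, df_habitat),
        "sites_x_habitat": effect("sites_x_habitat", ss_inter, df_inter),
        "error": AnovaRow("error", ss_error, df_error, ms_error, None, None),
        "total": AnovaRow("total", ss_total, n, None, None, None),
        "corrected_total": AnovaRow(
            "corrected_total", ss_ctotal, n - 1, None, None, None
        ),
    }
    r_squared = ss_cells / ss_ctotal if ss_ctotal > 0 else 0.0
    adj_r_squared = 1.0 - (1.0 - r_squared) * (n - 1) / df_error
    return AnovaTable(rows=rows, r_squared=r_squared, adj_r_squared=adj_r_squared)


def lsd_pairwise(
    table: ResponseTable,
    factor: str = "habitat",
    alpha: float = 0.05,
    anova: AnovaTable | None = None,
) -> LsdResult:
    """Fisher's LSD on the marginal means of one factor.

    Unadjusted pairwise t tests with SE = sqrt(MS_error (1/m_i + 1/m_j))
    on the full model's error degrees of freedom.
    """
    if factor not in ("habitat", "sites"):
        raise DesignError(f"unknown factor {factor!r}")
    if anova is None:
        anova = anova_two_way(table)
    ms_error = anova["error"].ms
    error_df = anova["error"].df

    labels = table.habitat if factor == "habitat" else table.regime
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has fewer than 2 levels")

    pairs = []
    for a, b in itertools.combinations(levels, 2):
        ya, yb = table.value[labels == a], table.value[labels == b]
        diff = float(ya.mean() - yb.mean())
        se = float(np.sqrt(ms_error * (1.0 / len(ya) + 1.0 / len(yb))))
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), error_df))
        pairs.append(LsdPair(a, b, diff, se, t, p, p < alpha))
    return LsdResult(factor=factor, alpha=alpha, error_df=error_df, pairs=pairs)


def format_p(p: float) -> str:
    """Three-decimal display; values below 0.0005 render as '.000'."""
    return f"{p:.3f}".lstrip("0") if p >= 1e-12 else ".000"


def write_anova_csv(anova: AnovaTable, path) -> None:
    display = {
        "corrected_model": "Corrected Model",
        "intercept": "Intercept",
        "sites": "Sites",
        "habitat": "Habitat",
        "sites_x_habitat": "Sites x Habitat",
        "error": "Error",
        "total": "Total",
        "corrected_total": "Corrected total",
    }
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Source", "SS", "df", "MS", "F", "p"])
        for source in ANOVA_SOURCES:
            row = anova[source]
            writer.writerow(
                [
                    display[source],
                    f"{row.ss:.6g}",
                    row.df,
                    "" if row.ms is None else f"{row.ms:.6g}",
                    "" if row.f is None else f"{row.f:.3f}",
                    "" if row.p is None else format_p(row.p),
                ]
            )
        writer.writerow([])
        writer.writerow(
            [
                "R squared",
                f"{anova.r_squared:.3f}",
                "Adjusted R squared",
                f"{anova.adj_r_squared:.3f}",
            ]
        )


def write_lsd_csv(result: LsdResult, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["level_i", "level_j", "mean_diff", "se", "t", "p", "significant"]
        )
        for p in result.pairs:
            writer.writerow(
                [
                    p.level_i,
                    p.level_j,
                    f"{p.mean_diff:.6g}",
                    f"{p.standard_error:.6g}",
                    f"{p.t:.3f}",
                    format_p(p.p),
                    int(p.significant),
                ]
            )
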