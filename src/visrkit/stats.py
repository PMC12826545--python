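"""Cohort-level statistics for the compression study.

Scalar transforms (strain conversion, percent change, baseline
normalization, extreme-angle selection), the nonparametric tests used
throughout the analysis (Kruskal-Wallis across compression levels within
a patient; Wilcoxon rank sum between groups), Bonferroni correction, and
the tidy result tables that summarize a study: DoA by compression, DoA
percent change, angle-averaged normalized values, percent change at all /
minimum / maximum angles, and a per-patient Kruskal-Wallis significance
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CompressionPair",
    "TestResult",
    "strain_from_compression",
    "percent_change",
    "normalize_by_baseline",
    "extreme_angle_values",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "bonferroni_alpha",
    "COMPRESSION_PAIRS",
    "doa_percent_change",
    "normalized_by_compression",
    "percent_change_table",
    "kw_significance_grid",
    "group_comparison",
]


@dataclass(frozen=True)
class CompressionPair:
    from_mm: int
    to_mm: int

    def __post_init__(self) -> None:
        if self.to_mm <= self.from_mm:
            raise ValueError("to_mm must exceed from_mm")

    @property
    def label(self) -> str:
        return f"{self.from_mm}–{self.to_mm}"


COMPRESSION_PAIRS = (CompressionPair(0, 2), CompressionPair(2, 5), CompressionPair(0, 5))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def strain_from_compression(compression_mm: float, focal_depth_mm: float = 20.0) -> float:
    """Percent strain of a surface compression relative to the focal depth."""
    if focal_depth_mm <= 0:
        raise ValueError("focal depth must be positive")
    if compression_mm < 0:
        raise ValueError("compression must be non-negative")
    return 100.0 * compression_mm / focal_depth_mm

def percent_change(v_from: float, v_to: float) -> float:
    """100 × (v_to − v_from) / v_from."""
    if v_from == 0:
        raise ValueError("zero baseline in percent change")
    return 100.0 * (v_to - v_from) / v_from


def normalize_by_baseline(values_by_compression: dict[int, float]) -> dict[int, float]:
    """Scale per-compression values so the 0-mm baseline is exactly 1."""
    if 0 not in values_by_compression:
        raise ValueError("missing 0-mm baseline")
    base = values_by_compression[0]
    if not np.isfinite(base) or base <= 0:
        raise ValueError("baseline must be positive and finite")
    return {c: v / base for c, v in values_by_compression.items()}


def extreme_angle_values(values_by_angle: dict[int, float]):
    """(min_angle, min_value, max_angle, max_value); ties go to the smallest angle."""
    if not values_by_angle:
        raise ValueError("no per-angle values")
    angles = sorted(values_by_angle)
    vals = [values_by_angle[a] for a in angles]
    if any(not np.isfinite(v) for v in vals):
        raise ValueError("per-angle values must be finite")
    imin = int(np.argmin(vals))  # argmin/argmax return the first = smallest angle on ties
    imax = int(np.argmax(vals))
    return angles[imin], vals[imin], angles[imax], vals[imax]


def kruskal_wallis(groups: list[np.ndarray], alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p, k−1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), tuple(g.size for g in groups), alpha)


def wilcoxon_rank_sum(x, y, alpha: float = 0.05) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when both samples have ≤ 10 observations and there
    are no ties (the clinical group sizes sit right at this boundary);
    otherwise the tie-corrected, continuity-corrected normal approximation.
    The reported statistic is the rank sum of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                            use_continuity=True)
    w = float(u) + x.size * (x.size + 1) / 2.0  # rank sum of x
    return TestResult(w, float(p), (x.size, y.size), alpha)


def bonferroni_alpha(base_alpha: float, tests_per_patient: int, n_patients: int) -> float:
    """Family-wise alpha divided across all per-patient tests.

    The per-patient test count is 12 by default elsewhere in the package:
    3 metrics (PD, RE, RV) × 4 imaging angles.
    """
    if base_alpha <= 0 or tests_per_patient <= 0 or n_patients <= 0:
        raise ValueError("all Bonferroni inputs must be positive")
    return base_alpha / (tests_per_patient * n_patients)


# ---------------------------------------------------------------------------
# tidy result tables (operate on the per-acquisition scalar table)
# ---------------------------------------------------------------------------
#
# The scalar table has one row per (subject_id, dense, metric,
# compression_mm, angle_deg) with columns `value` and `n_valid`; the pixel
# table is its distribution-level analog with one row per ROI pixel.


def _check_scalar_table(df: pd.DataFrame) -> None:
    need = {"subject_id", "metric", "compression_mm", "angle_deg", "value"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"scalar table missing columns {sorted(missing)}")


def doa_percent_change(doa_df: pd.DataFrame) -> pd.DataFrame:
    """Within-subject percent change in DoA between compression pairs."""
    rows = []
    for (subj, metric), g in doa_df.groupby(["subject_id", "metric"], sort=True):
        by_comp = g.set_index("compression_mm")["doa"].to_dict()
        for pair in COMPRESSION_PAIRS:
            if pair.from_mm in by_comp and pair.to_mm in by_comp and by_comp[pair.from_mm] > 0:
                pc = percent_change(by_comp[pair.from_mm], by_comp[pair.to_mm])
            else:
                pc = np.nan
            rows.append(
                {"subject_id": subj, "metric": metric, "pair": pair.label, "pct_change_doa": pc}
            )
    return pd.DataFrame(rows, columns=["subject_id", "metric", "pair", "pct_change_doa"])


def normalized_by_compression(scalar_df: pd.DataFrame) -> pd.DataFrame:
    """Angle-averaged metric values normalized by each subject's 0-mm value.

    The four per-angle scalars are averaged with equal weights, then scaled
    so the zero-compression value is exactly 1 for every subject and metric.
    """
    _check_scalar_table(scalar_df)
    avg = (
        scalar_df.groupby(["subject_id", "metric", "compression_mm"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    out = []
    for (subj, metric), g in avg.groupby(["subject_id", "metric"], sort=True):
        vals = dict(zip(g["compression_mm"], g["value"]))
        try:
            norm = normalize_by_baseline(vals)
        except ValueError:
            norm = {c: np.nan for c in vals}
        for c, v in norm.items():
            out.append(
                {"subject_id": subj, "metric": metric, "compression_mm": c, "normalized": v}
            )
    return pd.DataFrame(out)


def percent_change_table(scalar_df: pd.DataFrame, mode: str = "all") -> pd.DataFrame:
    """Percent change of each metric between compression pairs.

    ``mode='all'`` averages the four per-angle values before differencing;
    ``'min'`` / ``'max'`` keep only the angle at which the metric was
    minimized / maximized at the *from* compression of each pair (the
    subject's "minimum angle" / "maximum angle").
    """
    if mode not in {"all", "min", "max"}:
        raise ValueError("mode must be all|min|max")
    _check_scalar_table(scalar_df)
    rows = []
    for (subj, metric), g in scalar_df.groupby(["subject_id", "metric"], sort=True):
        piv = g.pivot_table(index="compression_mm", columns="angle_deg", values="value")
        for pair in COMPRESSION_PAIRS:
            if pair.from_mm not in piv.index or pair.to_mm not in piv.index:
                rows.append({"subject_id": subj, "metric": metric, "pair": pair.label,
                             "pct_change": np.nan, "angle_deg": np.nan})
                continue
            v_from_by_angle = piv.loc[pair.from_mm].dropna().to_dict()
            v_to_by_angle = piv.loc[pair.to_mm].dropna().to_dict()
            if mode == "all":
                v0 = np.mean(list(v_from_by_angle.values()))
                v1 = np.mean(list(v_to_by_angle.values()))
                angle = np.nan
            else:
                a_min, _, a_max, _ = extreme_angle_values(v_from_by_angle)
                angle = a_min if mode == "min" else a_max
                v0, v1 = v_from_by_angle[angle], v_to_by_angle.get(angle, np.nan)
            pc = percent_change(v0, v1) if np.isfinite(v0) and np.isfinite(v1) and v0 != 0 else np.nan
            rows.append({"subject_id": subj, "metric": metric, "pair": pair.label,
                         "pct_change": pc, "angle_deg": angle})
    return pd.DataFrame(rows)


def kw_significance_grid(
    pixel_df: pd.DataFrame,
    base_alpha: float = 0.05,
    tests_per_patient: int = 12,
) -> pd.DataFrame:
    """Per-patient Kruskal-Wallis tests of metric values across compressions.

    One test per (subject, metric, angle) cell, comparing the ROI pixel
    distributions at the three compression levels; ``alpha`` is the
    Bonferroni-corrected threshold over all cells of all patients.
    """
    need = {"subject_id", "metric", "angle_deg", "compression_mm", "value"}
    if need - set(pixel_df.columns):
        raise ValueError("pixel table missing required columns")
    n_patients = pixel_df["subject_id"].nunique()
    alpha = bonferroni_alpha(base_alpha, tests_per_patient, n_patients)
    rows = []
    for (subj, metric, angle), g in pixel_df.groupby(
        ["subject_id", "metric", "angle_deg"], sort=True
    ):
        groups = [sub["value"].to_numpy() for _, sub in g.groupby("compression_mm", sort=True)]
        try:
            res = kruskal_wallis(groups, alpha=alpha)
            rows.append({"subject_id": subj, "metric": metric, "angle_deg": angle,
                         "H": res.statistic, "p": res.p, "alpha": alpha,
                         "significant": res.significant})
        except ValueError:
            rows.append({"subject_id": subj, "metric": metric, "angle_deg": angle,
                         "H": np.nan, "p": np.nan, "alpha": alpha, "significant": False})
    return pd.DataFrame(rows)


def group_comparison(
    df: pd.DataFrame,
    value_col: str,
    dense_col: str = "dense",
    by: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparisons between dense and non-dense groups.

    One test per combination of the ``by`` columns.  Cells where either
    group is empty are emitted with NaN results and ``missing=True`` so a
    degenerate cohort (e.g. no dense subjects) degrades gracefully.
    """
    by = by or []
    cols = by + ["statistic", "p", "n_dense", "n_nondense", "significant", "missing"]
    if df.empty:
        return pd.DataFrame(columns=cols)
    groups = df.groupby(by, sort=True) if by else [((), df)]
    rows = []
    for key, g in groups:
        key = key if isinstance(key, tuple) else (key,)
        x = g.loc[g[dense_col].astype(bool), value_col].dropna().to_numpy()
        y = g.loc[~g[dense_col].astype(bool), value_col].dropna().to_numpy()
        row = dict(zip(by, key))
        if x.size and y.size:
            res = wilcoxon_rank_sum(x, y, alpha=alpha)
            row.update(statistic=res.statistic, p=res.p, n_dense=x.size, n_nondense=y.size,
                       significant=res.significant, missing=False)
        else:
            row.update(statistic=np.nan, p=np.nan, n_dense=x.size, n_nondense=y.size,
                       significant=False, missing=True)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
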