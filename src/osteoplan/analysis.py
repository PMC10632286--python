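"""Study-level realignment analysis and statistics.

Aggregates per-case planning results across segmentation sources (CT bone,
MRI bone, MRI bone+cartilage), computes realignment matrices and their
method differences, and runs the statistical battery: Shapiro–Wilk
normality checks, two-tailed paired t-tests, Pearson correlations, the
two-way random absolute-agreement single-measures intraclass correlation,
and the exponential fit of relative cartilage volume against age.

Note on ICC naming: the implemented form is the two-way random model for
absolute agreement of single measures — conventionally written ICC(2,1),
although reliability reports sometimes label the same model ICC(3,1).  The
function is named by what it computes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    EulerDecomposition,
    RigidTransform,
    decompose_euler,
    realignment_distance,
    relative,
)
from .planner import PlanningResult, compare_planes

__all__ = [
    "RealignmentComparison",
    "StudyReport",
    "REFERENCE_RESIDUAL_ROTATION_DEG",
    "REFERENCE_RESIDUAL_TRANSLATION_MM",
    "realignment",
    "method_difference",
    "icc_two_way_random_absolute_single",
    "shapiro_wilk",
    "paired_t",
    "pearson",
    "exp_fit",
    "build_study_report",
]

# Published residual errors after osteotomy surgery (Vlachopoulos et al.),
# carried as reference constants for the clinical-relevance comparison.
REFERENCE_RESIDUAL_ROTATION_DEG = (5.6, 4.2)  # mean, SD (degrees)
REFERENCE_RESIDUAL_TRANSLATION_MM = (2.0, 1.4)  # mean, SD (mm)


@dataclass(frozen=True)
class RealignmentComparison:
    """Difference between two methods' realignments of the same bone."""

    method_pair: tuple[str, str]
    bone: str
    difference: RigidTransform
    decomposition: EulerDecomposition
    delta_t: float  # mm
    phi_r: float  # rad


@dataclass
class StudyReport:
    """Tables-shaped study summary: per-case rows plus aggregate statistics."""

    rows: pd.DataFrame  # one row per (case, bone, method)
    comparisons: pd.DataFrame  # one row per (case, bone, method pair)
    summary: pd.DataFrame  # mean/SD of ΔT, ΦR and components per method pair
    icc: pd.DataFrame  # per realignment component, across methods
    tests: pd.DataFrame  # Shapiro–Wilk + paired t on T and R differences
    plane_summary: pd.DataFrame  # ΔZ / ψ mean and SD per method pair
    reference_residuals: dict = field(
        default_factory=lambda: {
            "rotation_deg": REFERENCE_RESIDUAL_ROTATION_DEG,
            "translation_mm": REFERENCE_RESIDUAL_TRANSLATION_MM,
        }
    )
    excluded_cases: list = field(default_factory=list)


def realignment(m_prox: RigidTransform, m_dist: RigidTransform) -> RigidTransform:
    """Realignment of the distal relative to the proximal fragment, M_prox⁻¹ × M_dist."""
    return relative(m_prox, m_dist)


def method_difference(
    m_method1: RigidTransform, m_method2: RigidTransform, method_pair=("a", "b"), bone: str = ""
) -> RealignmentComparison:
    """Difference transform M₁⁻¹ × M₂ between two methods' realignments."""
    diff = relative(m_method1, m_method2)
    d1 = decompose_euler(m_method1)
    d2 = decompose_euler(m_method2)
    delta_t, phi_r = realignment_distance(d1, d2)
    return RealignmentComparison(
        method_pair=tuple(method_pair),
        bone=bone,
        difference=diff,
        decomposition=decompose_euler(diff),
        delta_t=delta_t,
        phi_r=phi_r,
    )


def icc_two_way_random_absolute_single(ratings: np.ndarray) -> float:
    """ICC, two-way random model, absolute agreement, single measures.

    `ratings` is an (n subjects × k raters) table with no missing cells.
    From the two-way ANOVA mean squares (rows MS_R, columns MS_C, error
    MS_E):

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

    A table with zero total variance is perfect agreement by convention
    (returns 1.0 with a warning).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (>=2 subjects) x (>=2 raters) table")
    if not np.isfinite(x).all():
        raise ValueError("ratings table has missing/non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total < 1e-30:
        warnings.warn("zero total variance; ICC defined as 1.0")
        return 1.0
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < 1e-300:
        return 1.0
    return float((ms_r - ms_e) / denom)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro–Wilk W and p for normality of a sample (n ≥ 3)."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def paired_t(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test; errors on a zero-variance difference vector."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired t needs two equal-length samples with n >= 2")
    d = x - y
    if np.allclose(d, d[0]):
        if abs(d[0]) < 1e-300:
            return 0.0, 1.0
        raise ValueError("zero-variance difference vector: t statistic undefined")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-tailed p (n ≥ 3)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlation needs two equal-length samples with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def exp_fit(age, rcv) -> tuple[float, float]:
    """Fit rcv ≈ a·exp(b·age) by least squares on log(rcv).

    Used for the relative-cartilage-volume-versus-age trend; decreasing data
    gives b < 0.
    """
    age = np.asarray(age, float)
    rcv = np.asarray(rcv, float)
    if len(age) < 3:
        raise ValueError("exponential fit needs n >= 3")
    if (rcv <= 0).any():
        raise ValueError("exponential fit requires strictly positive rcv")
    b, log_a = np.polyfit(age, np.log(rcv), 1)
    return float(np.exp(log_a)), float(b)


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

_COMPONENTS = ["dx", "dy", "dz", "phi_x", "phi_y", "phi_z"]


def _realignment_row(case: str, bone: str, method: str, result: PlanningResult) -> dict:
    d = decompose_euler(result.realignment)
    return {
        "case": case,
        "bone": bone,
        "method": method,
        "dx": d.dx,
        "dy": d.dy,
        "dz": d.dz,
        "phi_x": d.phi_x,
        "phi_y": d.phi_y,
        "phi_z": d.phi_z,
        "T": d.T,
        "R": d.R,
        "delta_z_plane": result.plane.station,
        "objective": result.objective,
        "wedge_type": result.wedge_type,
    }


def build_study_report(
    cases: dict[str, dict[str, dict[str, PlanningResult]]],
    rcv_by_case: dict[str, float] | None = None,
    ages: dict[str, float] | None = None,
) -> StudyReport:
    """Aggregate planning results into the study-shaped report.

    Parameters
    ----------
    cases : mapping case id → bone → method → PlanningResult
        Cases missing a method for a bone are excluded from that bone's
        comparisons, with a logged warning (mirroring the exclusion of an
        incomplete scan from the study cohort).
    rcv_by_case, ages : optional per-case covariates for the RCV correlation
        and exponential-trend sections.
    """
    rows = []
    comp_rows = []
    excluded = []
    methods_seen = set()
    for case, bones in cases.items():
        for bone, per_method in bones.items():
            if len(per_method) < 2:
                warnings.warn(f"case {case} bone {bone}: fewer than 2 methods; excluded from comparisons")
                excluded.append((case, bone))
            for method, res in per_method.items():
                methods_seen.add(method)
                rows.append(_realignment_row(case, bone, method, res))
            names = sorted(per_method)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    m1, m2 = names[i], names[j]
                    cmp_entry = method_difference(
                        per_method[m1].realignment,
                        per_method[m2].realignment,
                        method_pair=(m1, m2),
                        bone=bone,
                    )
                    pc = compare_planes(per_method[m1], per_method[m2])
                    comp_rows.append(
                        {
                            "case": case,
                            "bone": bone,
                            "pair": f"{m1}-{m2}",
                            "delta_t": cmp_entry.delta_t,
                            "phi_r": cmp_entry.phi_r,
                            **{
                                c: getattr(cmp_entry.decomposition, c)
                                for c in _COMPONENTS
                            },
                            "delta_z": pc.delta_z,
                            "psi_a": pc.psi_a,
                            "psi_z": pc.psi_z,
                        }
                    )
    rows_df = pd.DataFrame(rows)
    comp_df = pd.DataFrame(comp_rows)

    if len(comp_df):
        summary = comp_df.groupby("pair")[["delta_t", "phi_r"] + _COMPONENTS].agg(["mean", "std"])
        plane_summary = comp_df.groupby("pair")[["delta_z", "psi_a", "psi_z"]].agg(["mean", "std"])
    else:
        summary = pd.DataFrame()
        plane_summary = pd.DataFrame()

    # ICC per realignment component: subjects = (case, bone), raters = methods
    icc_rows = []
    if len(rows_df) and len(methods_seen) >= 2:
        pivoted = {
            comp: rows_df.pivot_table(index=["case", "bone"], columns="method", values=comp)
            for comp in _COMPONENTS + ["T", "R"]
        }
        for comp, table in pivoted.items():
            table = table.dropna()
            if len(table) >= 2 and table.shape[1] >= 2:
                icc_rows.append({"component": comp, "icc": icc_two_way_random_absolute_single(table.values)})
    icc_df = pd.DataFrame(icc_rows)

    # Shapiro–Wilk + paired t on T and R between each method pair, both pooled
    # over bones and per bone (which samples entered each test in the source
    # study is ambiguous, so both are reported and labelled)
    test_rows = []
    if len(rows_df):
        scopes = [("pooled", rows_df)] + [
            (f"bone:{b}", g) for b, g in rows_df.groupby("bone")
        ]
        method_list = sorted(methods_seen)
        for scope, df in scopes:
            for comp in ("T", "R"):
                wide = df.pivot_table(index=["case", "bone"], columns="method", values=comp).dropna()
                for i in range(len(method_list)):
                    for j in range(i + 1, len(method_list)):
                        m1, m2 = method_list[i], method_list[j]
                        if m1 not in wide or m2 not in wide or len(wide) < 3:
                            continue
                        diff = wide[m1] - wide[m2]
                        try:
                            w, p_sw = shapiro_wilk(diff.values)
                        except ValueError:
                            continue
                        entry = {
                            "scope": scope,
                            "component": comp,
                            "pair": f"{m1}-{m2}",
                            "shapiro_w": w,
                            "shapiro_p": p_sw,
                            "t": np.nan,
                            "t_p": np.nan,
                        }
                        try:
                            t, p_t = paired_t(wide[m1].values, wide[m2].values)
                            entry["t"], entry["t_p"] = t, p_t
                        except ValueError:
                            pass
                        test_rows.append(entry)
    tests_df = pd.DataFrame(test_rows)

    return StudyReport(
        rows=rows_df,
        comparisons=comp_df,
        summary=summary,
        icc=icc_df,
        tests=tests_df,
        plane_summary=plane_summary,
        excluded_cases=excluded,
    )
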