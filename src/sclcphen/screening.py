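"""Exploration-phase code discovery.

In the exploration sample, every individual HCPCS/CPT code is profiled by
the proportion of SCLC vs NSCLC patients using it at least once in the
exposure window. Three purely descriptive threshold filters follow:

* **candidates** — codes whose absolute difference in usage proportions is
  at least 20 percentage points (non-strict, per "at least 20%");
* **false-positive reducers** — codes used by strictly <5% of SCLC and
  strictly >10% of NSCLC patients (NSCLC-specific; subtracting them removes
  NSCLC patients misclassified as SCLC);
* **false-negative reducers** — codes used by strictly >20% of SCLC and
  strictly <5% of NSCLC patients.

Denominators are all labelled cohort members of the split; patients with no
in-window claims still count in denominators. No inferential testing or
multiplicity correction is applied — the procedure is thresholding, not
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .codesets import CodeSystem
from .phenotype import Window, resolve_window
from .synth import NSCLC, SCLC


@dataclass(frozen=True)
class ScreeningThresholds:
    """The published discovery thresholds (proportions in [0, 1])."""

    candidate_diff: float = 0.20  # non-strict: |p_sclc - p_nsclc| >= diff
    fp_sclc_max: float = 0.05     # strict: p_sclc < max
    fp_nsclc_min: float = 0.10    # strict: p_nsclc > min
    fn_sclc_min: float = 0.20     # strict: p_sclc > min
    fn_nsclc_max: float = 0.05    # strict: p_nsclc < max

    def __post_init__(self) -> None:
        vals = (self.candidate_diff, self.fp_sclc_max, self.fp_nsclc_min,
                self.fn_sclc_min, self.fn_nsclc_max)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("thresholds must lie in [0, 1]")


_ROW_COLUMNS = ["code", "system", "p_sclc", "p_nsclc", "diff",
                "n_sclc_users", "n_nsclc_users"]


def code_flag_matrix(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    window: str | Window = "post180",
    systems: tuple[str, ...] = (CodeSystem.HCPCS_CPT.value,),
) -> pd.DataFrame:
    """Patient × (code, system) boolean usage matrix for in-window claims."""
    window = resolve_window(window)
    idx_map = cohort.set_index("patient_id")["index_date"]
    sub = claims[claims["patient_id"].isin(idx_map.index)]
    if systems:
        sub = sub[sub["system"].isin(systems)]
    sub = sub.copy()
    offset = (sub["service_date"] - sub["patient_id"].map(idx_map)).dt.days
    sub = sub[window.contains(offset)]
    pairs = sub[["patient_id", "code", "system"]].drop_duplicates()
    if pairs.empty:
        return pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    mat = (
        pairs.assign(flag=True)
        .pivot_table(index="patient_id", columns=["code", "system"], values="flag",
                     aggfunc="first", fill_value=False)
        .astype(bool)
    )
    return mat.reindex(pd.Index(cohort["patient_id"], name="patient_id"), fill_value=False)


def utilization_by_label(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    window: str | Window = "post180",
    systems: tuple[str, ...] = (CodeSystem.HCPCS_CPT.value,),
) -> pd.DataFrame:
    """Per-code usage proportions by gold label.

    One row per distinct (code, system) occurring in any in-window claim of a
    cohort member, with label-total denominators and distinct-patient
    numerators.
    """
    mat = code_flag_matrix(cohort, claims, window, systems)
    y = cohort.set_index("patient_id")["gold_label"].reindex(mat.index)
    return _rows_from_matrix(mat, y)


def _rows_from_matrix(mat: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    n_sclc = int((y == SCLC).sum())
    n_nsclc = int((y == NSCLC).sum())
    if mat.shape[1] == 0:
        return pd.DataFrame(columns=_ROW_COLUMNS)
    sclc_users = mat[y == SCLC].sum(axis=0)
    nsclc_users = mat[y == NSCLC].sum(axis=0)
    rows = pd.DataFrame(
        {
            "code": [c for c, _ in mat.columns],
            "system": [s for _, s in mat.columns],
            "n_sclc_users": sclc_users.to_numpy(),
            "n_nsclc_users": nsclc_users.to_numpy(),
        }
    )
    rows["p_sclc"] = rows["n_sclc_users"] / n_sclc if n_sclc else 0.0
    rows["p_nsclc"] = rows["n_nsclc_users"] / n_nsclc if n_nsclc else 0.0
    rows["diff"] = rows["p_sclc"] - rows["p_nsclc"]
    return rows[_ROW_COLUMNS]


def discover_candidates(
    rows: pd.DataFrame, thresholds: ScreeningThresholds | None = None
) -> pd.DataFrame:
    """Codes with |p_sclc - p_nsclc| >= 20pp, sorted by descending difference."""
    t = thresholds or ScreeningThresholds()
    if rows.empty:
        return rows
    out = rows[rows["diff"].abs() >= t.candidate_diff]
    return out.sort_values("diff", ascending=False, kind="stable").reset_index(drop=True)


def discover_fp_reducers(
    rows: pd.DataFrame, thresholds: ScreeningThresholds | None = None
) -> pd.DataFrame:
    """NSCLC-specific codes: p_sclc < 5% and p_nsclc > 10% (both strict)."""
    t = thresholds or ScreeningThresholds()
    if rows.empty:
        return rows
    out = rows[(rows["p_sclc"] < t.fp_sclc_max) & (rows["p_nsclc"] > t.fp_nsclc_min)]
    return out.reset_index(drop=True)


def discover_fn_reducers(
    rows: pd.DataFrame, thresholds: ScreeningThresholds | None = None
) -> pd.DataFrame:
    """SCLC-specific codes: p_sclc > 20% and p_nsclc < 5% (both strict)."""
    t = thresholds or ScreeningThresholds()
    if rows.empty:
        return rows
    out = rows[(rows["p_sclc"] > t.fn_sclc_min) & (rows["p_nsclc"] < t.fn_nsclc_max)]
    return out.reset_index(drop=True)


def screening_report(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    window: str | Window = "post180",
    thresholds: ScreeningThresholds | None = None,
    systems: tuple[str, ...] = (CodeSystem.HCPCS_CPT.value,),
) -> pd.DataFrame:
    """Full screening table with candidate / reducer membership columns."""
    t = thresholds or ScreeningThresholds()
    rows = utilization_by_label(cohort, claims, window, systems)
    if rows.empty:
        return rows.assign(candidate=[], fp_reducer=[], fn_reducer=[])
    rows = rows.sort_values("diff", ascending=False, kind="stable").reset_index(drop=True)
    rows["candidate"] = rows["diff"].abs() >= t.candidate_diff
    rows["fp_reducer"] = (rows["p_sclc"] < t.fp_sclc_max) & (rows["p_nsclc"] > t.fp_nsclc_min)
    rows["fn_reducer"] = (rows["p_sclc"] > t.fn_sclc_min) & (rows["p_nsclc"] < t.fn_nsclc_max)
    return rows


class DifferentialCodeScreener(BaseEstimator):
    """scikit-learn-style selector wrapping the threshold discovery.

    ``fit`` takes a boolean patient × code matrix ``X`` (see
    :func:`code_flag_matrix`) and a gold-label vector ``y``, computes the
    per-code utilization profile and the three discovery lists. ``transform``
    keeps only candidate columns.
    """

    def __init__(self, thresholds: ScreeningThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        t = self.thresholds or ScreeningThresholds()
        self.rows_ = _rows_from_matrix(X, y)
        self.candidates_ = discover_candidates(self.rows_, t)
        self.fp_reducers_ = discover_fp_reducers(self.rows_, t)
        self.fn_reducers_ = discover_fn_reducers(self.rows_, t)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "rows_"):
            raise ValueError("screener is not fitted; call fit first")
        keep = list(zip(self.candidates_["code"], self.candidates_["system"]))
        cols = [c for c in X.columns if tuple(c) in set(keep)]
        return X[cols]
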