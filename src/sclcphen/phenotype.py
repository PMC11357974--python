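"""Rule-based phenotype classification over windowed code-set exposures.

An algorithm is a boolean expression tree whose leaves are code-set exposure
predicates ("any etoposide claim within 180 days of the index date") and
whose internal nodes are AND / OR / NOT. Exposure flags are computed once per
cohort (:func:`build_utilization`) and rules are evaluated on the flag matrix
(:class:`RulePhenotypeClassifier`), predicting SCLC when the expression is
true. Prediction is deliberately deterministic and binary — no scores.

Windows are half-open day intervals anchored at the index date:
``post180`` is ``[index, index+180)`` and ``pre30_post180`` is
``[index-30, index+180)`` (the pre-diagnosis sensitivity analysis). Exposure
capture is defined by the window alone, not by the censoring date: a claim
cannot postdate death, and disenrollment truncation is the generator's (or
the source data's) concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .codesets import CodeSetRegistry, CodeSystem, builtin_registry
from .synth import NSCLC, SCLC

#: Claim settings searched by systemic-therapy predicates: outpatient drug
#: administration (HCPCS/CPT) plus the Part D / DME oral-equivalent routes.
DEFAULT_SETTINGS: frozenset[str] = frozenset({"outpatient", "part_d", "dme"})

#: Predicates whose exposure is searched in every care setting (the EGFR test
#: can be billed from any file).
ALL_SETTINGS_CODESETS: frozenset[str] = frozenset({"egfr_test"})


@dataclass(frozen=True)
class Window:
    """Half-open exposure window ``[index + pre_days, index + post_days)``."""

    pre_days: int = 0
    post_days: int = 180

    def contains(self, offset_days) -> np.ndarray:
        o = np.asarray(offset_days)
        return (o >= self.pre_days) & (o < self.post_days)


WINDOWS: dict[str, Window] = {
    "post180": Window(0, 180),
    "pre30_post180": Window(-30, 180),
}


def resolve_window(window: Union[str, Window]) -> Window:
    if isinstance(window, Window):
        return window
    try:
        return WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r} (expected {sorted(WINDOWS)})") from None


# --- expression trees -------------------------------------------------------

@dataclass(frozen=True)
class Pred:
    """Leaf predicate: in-window exposure to a named code set."""

    codeset: str


@dataclass(frozen=True)
class Not:
    expr: "Expr"


@dataclass(frozen=True)
class And:
    exprs: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.exprs) < 2:
            raise ValueError("AND needs at least two operands")


@dataclass(frozen=True)
class Or:
    exprs: tuple["Expr", ...]

    def __post_init__(self) -> None:
        if len(self.exprs) < 2:
            raise ValueError("OR needs at least two operands")


Expr = Union[Pred, Not, And, Or]


def leaves(expr: Expr) -> frozenset[str]:
    """Names of all code sets referenced by an expression."""
    if isinstance(expr, Pred):
        return frozenset({expr.codeset})
    if isinstance(expr, Not):
        return leaves(expr.expr)
    return frozenset().union(*(leaves(e) for e in expr.exprs))


def evaluate(expr: Expr, flags: pd.DataFrame) -> pd.Series:
    """Evaluate an expression tree on a boolean flag matrix (per patient)."""
    if isinstance(expr, Pred):
        return flags[expr.codeset].astype(bool)
    if isinstance(expr, Not):
        return ~evaluate(expr.expr, flags)
    parts = [evaluate(e, flags) for e in expr.exprs]
    out = parts[0]
    for p in parts[1:]:
        out = (out & p) if isinstance(expr, And) else (out | p)
    return out


def parse_rule(obj) -> Expr:
    """Parse a rule from config form.

    Accepts a code-set name (string leaf), an :class:`Expr`, or a nested
    mapping ``{"and": [...]}`` / ``{"or": [...]}`` / ``{"not": ...}``.
    """
    if isinstance(obj, (Pred, Not, And, Or)):
        return obj
    if isinstance(obj, str):
        return Pred(obj)
    if isinstance(obj, Mapping):
        if len(obj) != 1:
            raise ValueError(f"rule node must have exactly one operator key: {obj!r}")
        (op, args), = obj.items()
        op = op.lower()
        if op == "not":
            return Not(parse_rule(args))
        if op in ("and", "or"):
            if not isinstance(args, Sequence) or isinstance(args, str):
                raise ValueError(f"{op!r} operands must be a list")
            exprs = tuple(parse_rule(a) for a in args)
            return And(exprs) if op == "and" else Or(exprs)
        raise ValueError(f"unknown operator {op!r}")
    raise TypeError(f"cannot parse rule from {type(obj).__name__}")


@dataclass(frozen=True)
class AlgorithmRule:
    """A named classification algorithm."""

    name: str
    expr: Expr


def builtin_rules() -> list[AlgorithmRule]:
    """The published algorithm battery: ten single agents plus four combinations."""
    singles = [
        "carboplatin",
        "cisplatin",
        "etoposide",
        "gcsf",
        "ipilimumab",
        "irinotecan",
        "nivolumab",
        "pegfilgrastim",
        "topotecan",
        "platinum",
    ]
    rules = [AlgorithmRule(s, Pred(s)) for s in singles]
    rules.append(
        AlgorithmRule("etoposide_or_pegfilgrastim", Or((Pred("etoposide"), Pred("pegfilgrastim"))))
    )
    rules.append(AlgorithmRule("etoposide_or_gcsf", Or((Pred("etoposide"), Pred("gcsf")))))
    rules.append(
        AlgorithmRule(
            "etoposide_or_irinotecan_or_topotecan",
            Or((Pred("etoposide"), Pred("irinotecan"), Pred("topotecan"))),
        )
    )
    rules.append(
        AlgorithmRule("etoposide_no_egfr", And((Pred("etoposide"), Not(Pred("egfr_test")))))
    )
    return rules


def get_rule(name: str) -> AlgorithmRule:
    for r in builtin_rules():
        if r.name == name:
            return r
    raise KeyError(f"unknown built-in rule {name!r}")


# --- utilization flags ------------------------------------------------------

def build_utilization(
    cohort: pd.DataFrame,
    claims: pd.DataFrame,
    registry: CodeSetRegistry | None = None,
    window: Union[str, Window] = "post180",
    codesets: Iterable[str] | None = None,
    settings: frozenset[str] | None = DEFAULT_SETTINGS,
    settings_overrides: Mapping[str, frozenset[str] | None] | None = None,
) -> pd.DataFrame:
    """Boolean exposure-flag matrix: one row per cohort member, one column
    per code set.

    A flag is set iff the patient has at least one claim whose code matches
    the set (same coding system), whose setting is allowed for that set, and
    whose service date falls in the member's window. ``settings=None`` means
    all settings; per-set overrides default to searching every setting for
    ``egfr_test``.
    """
    registry = registry or builtin_registry()
    window = resolve_window(window)
    if codesets is None:
        codesets = [
            name
            for name in registry.names()
            if registry[name].system in (CodeSystem.HCPCS_CPT, CodeSystem.NDC)
        ]
    else:
        codesets = list(codesets)
        for name in codesets:
            if name not in registry:
                raise KeyError(f"unknown code set {name!r}")
    overrides = dict.fromkeys(ALL_SETTINGS_CODESETS, None) | dict(settings_overrides or {})

    idx_map = cohort.set_index("patient_id")["index_date"]
    sub = claims[claims["patient_id"].isin(idx_map.index)].copy()
    sub["offset"] = (
        sub["service_date"] - sub["patient_id"].map(idx_map)
    ).dt.days
    sub = sub[window.contains(sub["offset"])]

    norm_cache: dict[CodeSystem, pd.Series] = {}

    def normalized(system: CodeSystem) -> pd.Series:
        if system not in norm_cache:
            codes = sub.loc[sub["system"] == system.value, "code"].astype(str)
            codes = codes.str.strip().str.upper()
            if system is CodeSystem.ICD10CM_DX:
                codes = codes.str.replace(".", "", regex=False)
            elif system is CodeSystem.NDC:
                codes = codes.str.replace("-", "", regex=False).str.lstrip("0")
            norm_cache[system] = codes
        return norm_cache[system]

    flags = pd.DataFrame(index=pd.Index(cohort["patient_id"], name="patient_id"))
    for name in codesets:
        cs = registry[name]
        codes = normalized(cs.system)
        if cs.match_mode == "exact":
            m = codes.isin(cs.codes)
        else:
            m = codes.str.startswith(tuple(cs.codes))
        hits = sub.loc[m[m].index]
        set_settings = overrides.get(name, settings)
        if set_settings is not None:
            hits = hits[hits["setting"].isin(set_settings)]
        flags[name] = flags.index.isin(hits["patient_id"].unique())
    return flags


# --- classifier -------------------------------------------------------------

class RulePhenotypeClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic SCLC/NSCLC classifier over an exposure-flag matrix.

    Parameters
    ----------
    rule:
        A built-in rule name (see :func:`builtin_rules`), an
        :class:`AlgorithmRule`, an expression tree, or nested config form
        such as ``{"and": ["etoposide", {"not": "egfr_test"}]}``.

    The estimator follows scikit-learn conventions: ``fit`` resolves and
    validates the rule against the columns of ``X`` (a boolean DataFrame from
    :func:`build_utilization`) and ``predict`` returns ``"SCLC"`` where the
    expression is true. ``y`` is accepted and ignored — the rule is fixed,
    not learned — which keeps the estimator usable inside sklearn model
    selection for comparing candidate algorithms.
    """

    def __init__(self, rule="etoposide"):
        self.rule = rule

    def _resolve(self) -> AlgorithmRule:
        if isinstance(self.rule, AlgorithmRule):
            return self.rule
        if isinstance(self.rule, str):
            try:
                return get_rule(self.rule)
            except KeyError:
                return AlgorithmRule(self.rule, parse_rule(self.rule))
        expr = parse_rule(self.rule)
        return AlgorithmRule("custom", expr)

    def fit(self, X: pd.DataFrame, y=None):
        rule = self._resolve()
        missing = sorted(leaves(rule.expr) - set(X.columns))
        if missing:
            raise ValueError(f"flag matrix lacks columns for predicates: {missing}")
        self.rule_ = rule
        self.classes_ = np.array([NSCLC, SCLC])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "rule_"):
            raise ValueError("classifier is not fitted; call fit first")
        truth = evaluate(self.rule_.expr, X)
        return np.where(truth.to_numpy(), SCLC, NSCLC)

    def predict_series(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(self.predict(X), index=X.index, name="predicted")


def apply_rule(rule, flags: pd.DataFrame) -> pd.Series:
    """Predicted label per patient (thin wrapper over the classifier)."""
    clf = RulePhenotypeClassifier(rule=rule).fit(flags)
    return clf.predict_series(flags)
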