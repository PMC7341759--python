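"""Clinical phenotype dichotomization and per-feature association tests.

Eight raw clinical characteristics are collapsed into five groups:

* ``tumor_properties`` -- composite of tumor size, vascular invasion and
  stage; poor if ANY available sub-phenotype is poor (size >= 5 cm,
  vascular invasion present, or stage 3/4), good if all available ones
  are good, missing when nothing is available.
* ``grade`` -- poor for Edmondson grade 3/4.
* ``capsule`` -- poor for incomplete or absent encapsulation.
* ``invasion`` -- poor when tumor invasion is present.
* ``survival`` -- overall-survival time/status, analyzed with univariate
  Cox proportional hazards (Breslow ties) on continuous expression.

Association tests use tumor samples only, since the phenotypes describe
the tumor.  The categorical groups use a pooled-variance two-sample t-test
with a |fold change| >= 1.5 and unadjusted p < 0.05 significance rule; a
logistic-regression mode is provided for validation-cohort style analyses.
A feature is potentially oncogenic when it is up-regulated in tumors and
significantly higher in at least one poor-phenotype group (direction
concordant), and a potential tumor suppressor in the mirrored case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
)

from .errors import ConfigError
from .io import ExpressionMatrix, tumor_sample_map

GROUPS = ("tumor_properties", "grade", "capsule", "invasion", "survival")
TTEST_GROUPS = GROUPS[:4]

OK = "ok"
NOT_TESTABLE = "not_testable"
DIVERGED = "diverged"


# ---------------------------------------------------------------------------
# dichotomization


def _label(poor: bool | None) -> str:
    if poor is None:
        return "missing"
    return "poor" if poor else "good"


def _tumor_properties_label(size, vascular, stage) -> str:
    subs = []
    if size is not None and not pd.isna(size):
        subs.append(float(size) >= 5.0)
    if vascular is not None and not pd.isna(vascular):
        subs.append(bool(vascular))
    if stage is not None and not pd.isna(stage):
        subs.append(int(stage) in (3, 4))
    if not subs:
        return "missing"
    return "poor" if any(subs) else "good"


def dichotomize(clinical: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw clinical fields into good/poor labels per group.

    Missing raw values propagate: a composite is poor if any available
    sub-phenotype is poor, good if at least one is available and none is
    poor, and missing otherwise.
    """
    rows = []
    for rec in clinical.to_dict("records"):
        get = rec.get
        grade = get("grade")
        caps = get("encapsulation")
        inv = get("invasion")
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "tumor_properties": _tumor_properties_label(
                    get("tumor_size_cm"), get("vascular_invasion"), get("stage")
                ),
                "grade": _label(None if pd.isna(grade) else int(grade) in (3, 4))
                if grade is not None
                else "missing",
                "capsule": _label(
                    None if caps is None or pd.isna(caps) else caps in ("incomplete", "none")
                ),
                "invasion": _label(None if inv is None or pd.isna(inv) else bool(inv)),
                "os_time": get("os_time"),
                "os_event": get("os_event"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary tests


def group_t_test(poor_values, good_values) -> tuple[float, float]:
    """Pooled-variance two-sample t-test of poor vs good tumor expression.

    Returns ``(fc, p)`` where fc is the signed linear fold change of the
    poor-arm mean over the good-arm mean (log2 domain input).  An arm with
    fewer than 2 samples yields the not-testable sentinel ``(nan, nan)``.
    """
    a = np.asarray(poor_values, dtype=float)
    b = np.asarray(good_values, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    delta = a.mean() - b.mean()
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    r = 2.0 ** delta
    fc = r if r >= 1.0 else -1.0 / r
    if sp2 == 0.0:
        return fc, (1.0 if delta == 0.0 else 0.0)
    t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(fc), float(p)


@dataclass
class CoxResult:
    beta: float
    hr: float
    p: float
    status: str  # ok | not_testable | diverged


def cox_univariate(values, os_time, os_event) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Breslow tie handling).

    ``values`` enters as a continuous covariate.  Requires at least two
    events and a non-constant covariate; monotone likelihood (perfect
    separation of risk) is reported as a divergence flag.
    """
    x = np.asarray(values, dtype=float)
    time = np.asarray(os_time, dtype=float)
    event = np.asarray(os_event, dtype=float)
    mask = np.isfinite(x) & np.isfinite(time) & np.isfinite(event)
    x, time, event = x[mask], time[mask], event[mask]
    if x.size < 3 or event.sum() < 2 or np.ptp(x) == 0.0:
        return CoxResult(float("nan"), float("nan"), float("nan"), NOT_TESTABLE)
    model = PHReg(time, x.reshape(-1, 1), status=event.astype(int), ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit()
        except Exception:
            return CoxResult(float("nan"), float("nan"), float("nan"), DIVERGED)
    beta = float(res.params[0])
    se = float(res.bse[0])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 1e3:
        return CoxResult(beta, float(np.exp(np.clip(beta, -700, 700))), float("nan"), DIVERGED)
    return CoxResult(beta, float(np.exp(beta)), float(res.pvalues[0]), OK)


@dataclass
class LogisticResult:
    beta: float
    odds_ratio: float
    p: float
    status: str


def logistic_univariate(values, binary_label) -> LogisticResult:
    """Univariate logistic regression of a binary label on expression.

    Returns the maximum-likelihood slope with Wald p; complete separation
    is reported as a divergence flag.  Both classes must be present.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(binary_label, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(np.unique(y)) < 2:
        raise ConfigError("logistic_univariate: both classes must be present")
    if np.ptp(x) == 0.0:
        return LogisticResult(float("nan"), float("nan"), float("nan"), NOT_TESTABLE)
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return LogisticResult(float("nan"), float("nan"), float("nan"), DIVERGED)
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 1e3:
        return LogisticResult(beta, float(np.exp(np.clip(beta, -700, 700))), float("nan"), DIVERGED)
    return LogisticResult(beta, float(np.exp(beta)), float(res.pvalues[1]), OK)


# ---------------------------------------------------------------------------
# per-feature association across the five groups


def associate(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    phenotypes: pd.DataFrame,
    features=None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    categorical_mode: str = "ttest",
    groups=GROUPS,
) -> pd.DataFrame:
    """Test each feature's tumor expression against every phenotype group.

    Returns one row per (feature, group) with the signed effect (linear fc
    for t-test groups, hazard ratio for survival, odds ratio in logistic
    mode), the unadjusted p-value, the direction relative to the poor
    phenotype, and the significance call.  Patients with a missing label
    are excluded from that group only (pairwise deletion).
    """
    if categorical_mode not in ("ttest", "logistic"):
        raise ConfigError(f"unknown categorical_mode {categorical_mode!r}")
    tmap = tumor_sample_map(design)
    pheno = phenotypes.set_index("patient_id")
    patients = [p for p in pheno.index if p in tmap]
    tumor_cols = [tmap[p] for p in patients]
    sub = matrix.values[tumor_cols]
    if features is not None:
        sub = sub.loc[list(features)]
    X = sub.to_numpy(dtype=float)
    feature_ids = list(sub.index)
    records = []

    for group in [g for g in TTEST_GROUPS if g in groups]:
        labels = pheno.loc[patients, group].to_numpy()
        poor_idx = np.where(labels == "poor")[0]
        good_idx = np.where(labels == "good")[0]
        if categorical_mode == "ttest":
            records.extend(
                _vectorized_group_ttest(
                    X, feature_ids, group, poor_idx, good_idx, fc_threshold, p_threshold
                )
            )
        else:
            keep = np.concatenate([poor_idx, good_idx])
            y = np.concatenate([np.ones(len(poor_idx)), np.zeros(len(good_idx))])
            for i, fid in enumerate(feature_ids):
                if len(poor_idx) == 0 or len(good_idx) == 0:
                    records.append(_assoc_row(fid, group, np.nan, np.nan, "up_in_poor", False, NOT_TESTABLE))
                    continue
                res = logistic_univariate(X[i, keep], y)
                sig = res.status == OK and res.p < p_threshold
                direction = "up_in_poor" if (np.isfinite(res.beta) and res.beta > 0) else "down_in_poor"
                records.append(_assoc_row(fid, group, res.odds_ratio, res.p, direction, bool(sig), res.status))

    if "survival" in groups:
        times = pd.to_numeric(pheno.loc[patients, "os_time"], errors="coerce").to_numpy(dtype=float)
        events = pd.to_numeric(pheno.loc[patients, "os_event"], errors="coerce").to_numpy(dtype=float)
        for i, fid in enumerate(feature_ids):
            res = cox_univariate(X[i], times, events)
            sig = res.status == OK and res.p < p_threshold and res.hr != 1.0
            direction = "up_in_poor" if (np.isfinite(res.hr) and res.hr > 1.0) else "down_in_poor"
            records.append(_assoc_row(fid, "survival", res.hr, res.p, direction, bool(sig), res.status))

    return pd.DataFrame.from_records(records)


def _assoc_row(fid, group, effect, p, direction, significant, status):
    return {
        "feature_id": fid,
        "group": group,
        "effect": effect,
        "p": p,
        "direction": direction,
        "significant": significant,
        "status": status,
    }


def _vectorized_group_ttest(X, feature_ids, group, poor_idx, good_idx, fc_threshold, p_threshold):
    rows = []
    if len(poor_idx) < 2 or len(good_idx) < 2:
        for fid in feature_ids:
            rows.append(_assoc_row(fid, group, np.nan, np.nan, "up_in_poor", False, NOT_TESTABLE))
        return rows
    A, B = X[:, poor_idx], X[:, good_idx]
    n1, n2 = A.shape[1], B.shape[1]
    m1, m2 = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
    v1, v2 = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
    delta = m1 - m2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    p = np.where(sp2 == 0.0, np.where(delta == 0.0, 1.0, 0.0), p)
    r = 2.0 ** delta
    fc = np.where(r >= 1.0, r, -1.0 / r)
    sig = (np.abs(fc) >= fc_threshold) & (p < p_threshold)
    direction = np.where(delta > 0, "up_in_poor", "down_in_poor")
    for i, fid in enumerate(feature_ids):
        rows.append(
            _assoc_row(fid, group, float(fc[i]), float(p[i]), str(direction[i]), bool(sig[i]), OK)
        )
    return rows


# ---------------------------------------------------------------------------
# oncogenic / suppressor classification


def classify_relevance(de: pd.DataFrame, assoc: pd.DataFrame) -> pd.DataFrame:
    """Label features as potentially oncogenic, tumor-suppressive or neither.

    Oncogenic: up-regulated in tumors and significantly up in at least one
    poor-phenotype group (HR > 1 for survival).  Suppressor: the mirrored
    down/down case.  ``groups`` lists only the direction-concordant
    significant groups, comma-joined.
    """
    sig = assoc[assoc["significant"].astype(bool)]
    by_feature: dict[str, list[tuple[str, str]]] = {}
    for rec in sig.itertuples(index=False):
        by_feature.setdefault(rec.feature_id, []).append((rec.group, rec.direction))
    rows = []
    for rec in de.itertuples(index=False):
        direction = rec.direction
        concordant: list[str] = []
        if rec.is_de and direction in ("up", "down"):
            want = "up_in_poor" if direction == "up" else "down_in_poor"
            concordant = sorted(
                g for g, d in by_feature.get(rec.feature_id, []) if d == want
            )
        if rec.is_de and direction == "up" and concordant:
            cls = "oncogenic"
        elif rec.is_de and direction == "down" and concordant:
            cls = "suppressor"
        else:
            cls = "none"
            concordant = [] if not rec.is_de else concordant
        rows.append(
            {
                "feature_id": rec.feature_id,
                "de_direction": direction,
                "cls": cls,
                "groups": ",".join(concordant),
            }
        )
    return pd.DataFrame(rows)


def parse_groups(groups_field: str) -> frozenset[str]:
    """Parse the comma-joined ``groups`` column back into a set."""
    if not groups_field or (isinstance(groups_field, float) and np.isnan(groups_field)):
        return frozenset()
    return frozenset(g for g in str(groups_field).split(",") if g)
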