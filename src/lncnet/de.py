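"""Paired tumor-vs-non-tumor differential expression.

Per feature: a paired Student t-test on the per-patient T - NT log2
differences, Benjamini-Hochberg FDR across all tested features, and a
signed linear fold change 2**(mean_T - mean_NT) reported as r when
r >= 1 and -1/r otherwise (so |fc| >= 1 always and the sign carries the
up/down direction).  A feature is differentially expressed when
q < fdr_threshold and |fc| >= fc_threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, PairingError
from .io import ExpressionMatrix, paired_columns


def paired_t_test(t_vals, nt_vals) -> tuple[float, float]:
    """Paired two-sided t-test on matched T/NT values.

    Returns ``(t, p)``.  Degenerate differences follow the convention:
    zero spread with non-zero mean gives an infinite-t sentinel with p = 0;
    all-zero differences give t = 0, p = 1.
    """
    a = np.asarray(t_vals, dtype=float)
    b = np.asarray(nt_vals, dtype=float)
    if a.shape != b.shape:
        raise ConfigError("paired_t_test: unequal lengths")
    n = a.size
    if n < 2:
        raise ConfigError("paired_t_test: need at least 2 pairs")
    d = a - b
    m = d.mean()
    s = d.std(ddof=1)
    if s == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        return math_copysign_inf(m), 0.0
    t = m / (s / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def math_copysign_inf(m: float) -> float:
    return float(np.inf) if m > 0 else float(-np.inf)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ConfigError("benjamini_hochberg: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_t: float, mean_nt: float) -> float:
    """Signed linear fold change from log2 means."""
    r = 2.0 ** (float(mean_t) - float(mean_nt))
    return r if r >= 1.0 else -1.0 / r


def _signed_fc(delta_log2: np.ndarray) -> np.ndarray:
    r = 2.0 ** delta_log2
    return np.where(r >= 1.0, r, -1.0 / r)


def run_de(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    strict_fc: bool = False,
    family: str = "joint",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Paired DE over every feature of the matrix.

    ``family`` controls the BH family: ``"joint"`` adjusts lncRNA and mRNA
    p-values together (default), ``"per_biotype"`` adjusts each biotype
    separately and requires ``annotation``.  Features with missing values
    are tested on complete pairs only; fewer than 2 complete pairs leaves
    the feature untested (p and q = NaN, is_de False).
    """
    patients, t_cols, nt_cols = paired_columns(design)
    missing = set(t_cols + nt_cols) - set(matrix.sample_ids)
    if missing:
        raise PairingError(f"design samples absent from matrix: {sorted(missing)}")
    T = matrix.values[t_cols].to_numpy(dtype=float)
    NT = matrix.values[nt_cols].to_numpy(dtype=float)
    D = T - NT
    complete = ~np.isnan(D)
    n = complete.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.nanmean(np.where(complete, D, np.nan), axis=1)
        s = np.nanstd(np.where(complete, D, np.nan), axis=1, ddof=1)
        mean_t = np.nanmean(T, axis=1)
        mean_nt = np.nanmean(NT, axis=1)

    t_stat = np.full(D.shape[0], np.nan)
    p = np.full(D.shape[0], np.nan)
    testable = n >= 2
    zero_sd = testable & (s == 0.0)
    t_stat[zero_sd & (m == 0.0)] = 0.0
    p[zero_sd & (m == 0.0)] = 1.0
    t_stat[zero_sd & (m != 0.0)] = np.where(m[zero_sd & (m != 0.0)] > 0, np.inf, -np.inf)
    p[zero_sd & (m != 0.0)] = 0.0
    ok = testable & (s > 0.0)
    t_stat[ok] = m[ok] / (s[ok] / np.sqrt(n[ok]))
    p[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df=n[ok] - 1)

    delta = mean_t - mean_nt
    fc = _signed_fc(delta)
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))

    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if family == "joint":
        groups = [tested]
    elif family == "per_biotype":
        if annotation is None:
            raise ConfigError("family='per_biotype' requires an annotation table")
        biotype = annotation.set_index("feature_id")["biotype"]
        bt = biotype.reindex(matrix.values.index).to_numpy()
        groups = [tested & (bt == b) for b in ("lncRNA", "protein_coding")]
    else:
        raise ConfigError(f"unknown BH family {family!r}")
    for g in groups:
        if g.any():
            q[g] = benjamini_hochberg(p[g])

    abs_fc = np.abs(fc)
    fc_pass = abs_fc > fc_threshold if strict_fc else abs_fc >= fc_threshold
    is_de = tested & (q < fdr_threshold) & fc_pass

    return pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "mean_T": mean_t,
            "mean_NT": mean_nt,
            "log2fc": delta,
            "fc": fc,
            "t_stat": t_stat,
            "p": p,
            "q": q,
            "direction": direction,
            "is_de": is_de,
            "n_pairs": n,
        }
    ).reset_index(drop=True)
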