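"""All-pairs Pearson correlation between DE lncRNAs and DE mRNAs.

Pairs with |r| at or above a calling threshold (0.9 for the strong
"guilt-by-association" networks, 0.6 for perturbation integration) are
emitted, and each called pair can be annotated as *cis* when the mRNA is
the lncRNA's nearest protein-coding gene on the genome (same chromosome,
minimal interval gap, ties broken by smaller start coordinate).

Correlation is computed across all samples (tumor and non-tumor pooled)
by default, with a tumor-only option.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedCorrelationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ConfigError("pearson: vectors must have equal length >= 3")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise UndefinedCorrelationError("pearson: constant vector")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize so that Z1 @ Z2.T gives Pearson r; flags constants."""
    m = X.mean(axis=1, keepdims=True)
    c = X - m
    norm = np.sqrt((c * c).sum(axis=1, keepdims=True))
    constant = norm[:, 0] == 0.0
    norm[constant] = 1.0
    return c / norm, constant


def correlation_matrix(
    matrix: ExpressionMatrix, row_ids, col_ids, sample_ids=None
) -> pd.DataFrame:
    """Pearson correlations of every row feature against every column feature.

    Constant features get NaN correlations (logged).  ``sample_ids``
    restricts the sample set (e.g. tumor-only).
    """
    values = matrix.values if sample_ids is None else matrix.values[list(sample_ids)]
    if values.shape[1] < 3:
        raise ConfigError("correlation needs at least 3 samples")
    A = values.loc[list(row_ids)].to_numpy(dtype=float)
    B = values.loc[list(col_ids)].to_numpy(dtype=float)
    Za, const_a = _standardize_rows(A)
    Zb, const_b = _standardize_rows(B)
    if const_a.any() or const_b.any():
        n_const = int(const_a.sum() + const_b.sum())
        logger.warning("correlation: %d constant feature(s) skipped", n_const)
    R = Za @ Zb.T
    R[const_a, :] = np.nan
    R[:, const_b] = np.nan
    return pd.DataFrame(R, index=list(row_ids), columns=list(col_ids))


def _de_ids_and_directions(de_or_ids):
    """Accept a DE table (uses is_de rows) or a plain id list."""
    if isinstance(de_or_ids, pd.DataFrame):
        sub = de_or_ids[de_or_ids["is_de"].astype(bool)]
        return list(sub["feature_id"]), dict(zip(sub["feature_id"], sub["direction"]))
    return list(de_or_ids), {}


def call_pairs(
    matrix: ExpressionMatrix,
    de_lnc,
    de_mrna,
    threshold: float = 0.9,
    sample_ids=None,
) -> pd.DataFrame:
    """Emit lncRNA-mRNA pairs with |r| >= threshold.

    ``de_lnc`` and ``de_mrna`` are DE tables (restricted to their is_de
    rows) or plain id lists.  When DE tables are given, each pair also
    records whether the correlation sign is concordant with the two DE
    directions (positive r with same direction, or negative r with
    opposite directions).
    """
    lnc_ids, lnc_dir = _de_ids_and_directions(de_lnc)
    mrna_ids, mrna_dir = _de_ids_and_directions(de_mrna)
    columns = ["lnc_id", "mrna_id", "r", "n_samples", "sign_concordant"]
    if not lnc_ids or not mrna_ids:
        logger.warning("call_pairs: empty DE feature set, no pairs to test")
        return pd.DataFrame(columns=columns)
    R = correlation_matrix(matrix, lnc_ids, mrna_ids, sample_ids=sample_ids)
    n_samples = (
        len(matrix.sample_ids) if sample_ids is None else len(list(sample_ids))
    )
    arr = R.to_numpy()
    with np.errstate(invalid="ignore"):
        hit_l, hit_m = np.where(np.abs(arr) >= threshold)
    rows = []
    for i, j in zip(hit_l.tolist(), hit_m.tolist()):
        lnc, mrna = lnc_ids[i], mrna_ids[j]
        r = float(arr[i, j])
        if lnc_dir and mrna_dir:
            same = lnc_dir.get(lnc) == mrna_dir.get(mrna)
            concordant = (r > 0) == same
        else:
            concordant = None
        rows.append((lnc, mrna, r, n_samples, concordant))
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(["lnc_id", "mrna_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# cis annotation


def nearest_coding_gene(annotation: pd.DataFrame, lnc_ids=None) -> dict:
    """Map each lncRNA to its nearest protein-coding gene.

    Same chromosome only; distance is the interval gap (0 when the two
    intervals overlap); ties break on the smaller candidate start, then
    lexicographic feature id.  lncRNAs with no same-chromosome coding gene
    are absent from the map.
    """
    ann = annotation.set_index("feature_id")
    coding = annotation[annotation["biotype"] == "protein_coding"]
    by_chrom = {c: g for c, g in coding.groupby("chrom")}
    if lnc_ids is None:
        lnc_ids = annotation.loc[annotation["biotype"] == "lncRNA", "feature_id"]
    nearest = {}
    for lnc in lnc_ids:
        if lnc not in ann.index:
            continue
        row = ann.loc[lnc]
        cands = by_chrom.get(row["chrom"])
        if cands is None or cands.empty:
            continue
        starts = cands["start"].to_numpy()
        ends = cands["end"].to_numpy()
        gap = np.maximum(0, np.maximum(starts - row["end"], row["start"] - ends))
        order = sorted(
            range(len(cands)),
            key=lambda k: (gap[k], starts[k], cands["feature_id"].iloc[k]),
        )
        nearest[lnc] = cands["feature_id"].iloc[order[0]]
    return nearest


def annotate_cis(pairs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Add an ``is_cis`` column to a called-pairs table.

    A pair is cis when its mRNA is the lncRNA's nearest protein-coding
    gene.  Pairs whose lncRNA is not annotated keep a missing is_cis
    (logged).
    """
    pairs = pairs.copy()
    if pairs.empty:
        pairs["is_cis"] = pd.Series(dtype=object)
        return pairs
    nearest = nearest_coding_gene(annotation, pairs["lnc_id"].unique())
    known = set(annotation["feature_id"])
    is_cis = []
    n_missing = 0
    for rec in pairs.itertuples(index=False):
        if rec.lnc_id not in known or rec.mrna_id not in known:
            is_cis.append(pd.NA)
            n_missing += 1
        else:
            is_cis.append(nearest.get(rec.lnc_id) == rec.mrna_id)
    if n_missing:
        logger.warning("annotate_cis: %d pair(s) with unannotated features", n_missing)
    pairs["is_cis"] = is_cis
    return pairs
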