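"""Cross-cohort trend concordance and perturbation-experiment integration.

``trend_concordance`` compares signed effects (DE fold changes, clinical
fold changes, log hazard/odds ratios) between a discovery and a
validation cohort over shared feature ids and reports the fraction with
the same sign.  ``perturbation_integrate`` combines an overexpression
experiment's DE table with patient-cohort correlations: genes moved by at
least a fold-change threshold in the perturbed cells AND correlated with
the perturbed lncRNA in the patients, in the same direction, are the
candidate targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class TrendReport:
    category: str
    n_matched: int
    n_same_trend: int
    n_unmatched: int

    @property
    def percent(self) -> float:
        if self.n_matched == 0:
            return float("nan")
        return 100.0 * self.n_same_trend / self.n_matched


def trend_concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    match_on: str = "feature_id",
    effect_col: str = "effect",
    category: str = "all",
    discovery_significant_col: str | None = None,
    require_validation_significant: bool = False,
    validation_significant_col: str | None = None,
) -> TrendReport:
    """Sign agreement of effects between two cohorts over shared features.

    Only discovery-significant features (when a significance column is
    named) present in the validation table enter the denominator; features
    absent from validation are counted as unmatched.  Effects of exactly
    zero have no sign and are excluded (logged).  A strict-replication
    mode additionally requires validation significance.
    """
    disc = discovery
    if discovery_significant_col is not None:
        disc = disc[disc[discovery_significant_col].astype(bool)]
    val = validation
    if require_validation_significant:
        col = validation_significant_col or discovery_significant_col
        if col is None:
            raise ConfigError("strict replication needs a validation significance column")
        val = val[val[col].astype(bool)]
    merged = disc.merge(
        val[[match_on, effect_col]].rename(columns={effect_col: "_val_effect"}),
        on=match_on,
        how="left",
    )
    if merged["_val_effect"].notna().sum() == 0:
        raise ConfigError("trend_concordance: no overlapping ids between cohorts")
    matched = merged[merged["_val_effect"].notna()]
    zero = (matched[effect_col] == 0) | (matched["_val_effect"] == 0)
    if zero.any():
        logger.warning("trend_concordance: %d zero effect(s) excluded", int(zero.sum()))
    matched = matched[~zero]
    same = np.sign(matched[effect_col]) == np.sign(matched["_val_effect"])
    return TrendReport(
        category=category,
        n_matched=int(len(matched)),
        n_same_trend=int(same.sum()),
        n_unmatched=int(len(merged) - len(matched)),
    )


def perturbation_integrate(
    oe_de: pd.DataFrame,
    target_lnc: str,
    pairs_r: pd.DataFrame,
    r_threshold: float = 0.6,
    fc_threshold: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Intersect an overexpression DE table with patient-cohort correlations.

    ``oe_de`` carries columns ``gene`` and ``log2fc`` (overexpressing cells
    vs control); ``pairs_r`` carries ``lnc_id``, ``mrna_id``, ``r``.
    Returns ``(up_list, down_list)``: genes with fold change at least
    +/- ``fc_threshold`` (linear) AND correlation at least +/-
    ``r_threshold`` in the matching direction.
    """
    sub = pairs_r[pairs_r["lnc_id"] == target_lnc]
    if sub.empty:
        raise ConfigError(
            f"perturbation_integrate: lncRNA {target_lnc!r} absent from the correlation table"
        )
    r_by_gene = dict(zip(sub["mrna_id"], sub["r"]))
    log2_thr = np.log2(fc_threshold)
    up, down = [], []
    for rec in oe_de.itertuples(index=False):
        r = r_by_gene.get(rec.gene)
        if r is None:
            continue
        if rec.log2fc >= log2_thr and r >= r_threshold:
            up.append(rec.gene)
        elif rec.log2fc <= -log2_thr and r <= -r_threshold:
            down.append(rec.gene)
    return sorted(set(up)), sorted(set(down))
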