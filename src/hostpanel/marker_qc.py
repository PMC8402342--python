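"""Abundance / dynamic-range marker screening, tiering and pool assembly.

Candidate markers for a rapid isothermal assay must be (a) abundant enough to
detect reliably — the 95th percentile of copy number across the sample bank
must reach ``min_p95_copies`` (default 400, i.e. a 100-copy detection minimum
times the required 4-fold resolution) — and (b) dynamic enough to resolve
disease classes — the p95/p5 fold change must reach ``min_dynamic_fold``
(default 4).  Survivors with at least ``tier1_fold`` (default 5) dynamic
change rank Tier 1, the rest Tier 2.  Markers whose assay amplifies genomic
DNA in addition to mRNA (a wet-lab screen, supplied as a flag) are removed
after tiering.  Surviving original-panel and alternative markers are merged
into an ordered candidate pool for feature selection.

Boundary semantics are strict and read literally from the screening rules:
exclude iff p95 < min_p95_copies; exclude iff fold change < min_dynamic_fold;
Tier 1 iff fold change >= tier1_fold.  Percentiles use the linear
interpolation definition, pooled over all samples regardless of class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

TIER_EXCLUDED = 0  # tier column: 1 = Tier 1, 2 = Tier 2, 0 = excluded


@dataclass
class FilterConfig:
    """Thresholds of the two-step exclusion screen."""

    min_p95_copies: float = 400.0
    min_dynamic_fold: float = 4.0
    tier1_fold: float = 5.0

    def validate(self) -> None:
        if self.min_p95_copies <= 0:
            raise ValueError("min_p95_copies must be > 0")
        if self.tier1_fold < self.min_dynamic_fold:
            raise ValueError("tier1_fold must be >= min_dynamic_fold")


def compute_marker_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-marker median, 5th and 95th percentile and p95/p5 dynamic range.

    Percentiles are pooled over all samples (linear interpolation between
    order statistics).  A marker with p5 = 0 gets ``dynamic_range = inf``: a
    marker spanning zero to high copies is maximally dynamic, and whether it
    is usable is decided by the abundance rule.
    """
    if matrix.shape[0] < 20:
        raise ValueError(
            f"need >= 20 samples for stable percentiles, got {matrix.shape[0]}"
        )
    values = matrix.to_numpy(dtype=float)
    p5, median, p95 = np.percentile(values, [5, 50, 95], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dynamic = np.where(p5 > 0, p95 / np.where(p5 > 0, p5, 1.0), np.inf)
    stats = pd.DataFrame(
        {"p5": p5, "median": median, "p95": p95, "dynamic_range": dynamic},
        index=matrix.columns,
    )
    stats.index.name = "marker"
    return stats


def apply_two_step_exclusion(
    stats: pd.DataFrame,
    cfg: FilterConfig | None = None,
    gdna_pass: Mapping[str, bool] | pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the abundance rule, then the dynamic-range rule, then the gDNA screen.

    Parameters
    ----------
    stats:
        Output of :func:`compute_marker_stats` (or any frame with ``p95`` and
        ``dynamic_range``).
    cfg:
        :class:`FilterConfig`; defaults used when omitted.
    gdna_pass:
        marker -> bool; markers failing the genomic-DNA screen are excluded
        even when both statistical rules pass.  Defaults to all-pass.  Must
        cover exactly the markers in ``stats``.

    Returns
    -------
    DataFrame indexed by marker with the input stats plus ``passed_abundance``,
    ``passed_dynamic``, ``tier`` (1, 2 or 0 = excluded) and ``excluded_reason``
    in {low_abundance, low_dynamic_range, gdna_fail, none}.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    markers = list(stats.index)
    if gdna_pass is None:
        gdna = pd.Series(True, index=markers)
    else:
        gdna = pd.Series(gdna_pass).astype(bool)
        missing = sorted(set(markers) ^ set(gdna.index))
        if missing:
            raise ValueError(f"gdna_pass and stats cover different markers: {missing}")
        gdna = gdna.reindex(markers)

    out = stats.copy()
    out["passed_abundance"] = out["p95"] >= cfg.min_p95_copies
    out["passed_dynamic"] = out["dynamic_range"] >= cfg.min_dynamic_fold
    tier = np.zeros(len(out), dtype=int)
    reason = np.full(len(out), "none", dtype=object)
    for i, m in enumerate(markers):
        if not out["passed_abundance"].iloc[i]:
            reason[i] = "low_abundance"
        elif not out["passed_dynamic"].iloc[i]:
            reason[i] = "low_dynamic_range"
        elif not gdna.iloc[i]:
            reason[i] = "gdna_fail"
        else:
            tier[i] = 1 if out["dynamic_range"].iloc[i] >= cfg.tier1_fold else 2
    out["tier"] = tier
    out["excluded_reason"] = reason
    out["gdna_pass"] = gdna.to_numpy()
    return out


def assemble_candidate_pool(
    original_result: pd.DataFrame,
    alternative_result: pd.DataFrame | None = None,
) -> list[str]:
    """Merge screen survivors into a deterministic, ordered candidate pool.

    Survivors (tier 1 or 2) of the original panel and of the alternative
    candidates are pooled and ordered by (tier, descending dynamic range,
    marker name).  Marker sets must be disjoint; an empty pool is an error.
    """
    frames = [original_result]
    if alternative_result is not None:
        overlap = sorted(set(original_result.index) & set(alternative_result.index))
        if overlap:
            raise ValueError(f"original and alternative marker sets overlap: {overlap}")
        frames.append(alternative_result)
    merged = pd.concat(frames)
    survivors = merged[merged["tier"].isin((1, 2))].copy()
    if survivors.empty:
        raise ValueError("candidate pool is empty: no markers survived the screen")
    survivors = survivors.assign(_name=survivors.index.astype(str)).sort_values(
        by=["tier", "dynamic_range", "_name"], ascending=[True, False, True]
    )
    return [str(m) for m in survivors.index]


class MarkerQCFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the two-step marker screen.

    ``fit`` computes percentile statistics and the screen verdicts on the
    (raw copy-space) training matrix; ``transform`` restricts any matrix to
    the surviving markers in pool order.

    Parameters
    ----------
    config : FilterConfig, optional
    gdna_pass : mapping marker -> bool, optional

    Attributes
    ----------
    stats_ : DataFrame of per-marker percentile statistics.
    result_ : DataFrame with tier and exclusion verdicts.
    pool_ : list of surviving marker ids, in deterministic pool order.
    """

    def __init__(
        self,
        config: FilterConfig | None = None,
        gdna_pass: Mapping[str, bool] | None = None,
    ):
        self.config = config
        self.gdna_pass = gdna_pass

    def fit(self, X: pd.DataFrame, y=None) -> "MarkerQCFilter":
        self.stats_ = compute_marker_stats(X)
        gdna = self.gdna_pass
        if gdna is not None:
            gdna = {m: bool(gdna.get(m, True)) for m in X.columns}
        self.result_ = apply_two_step_exclusion(self.stats_, self.config, gdna)
        self.pool_ = assemble_candidate_pool(self.result_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [m for m in self.pool_ if m not in X.columns]
        if missing:
            raise ValueError(f"markers absent from matrix: {missing}")
        return X[self.pool_]

    def get_support(self) -> np.ndarray:
        """Boolean mask over the fitted markers, True for screen survivors."""
        return self.result_["tier"].isin((1, 2)).to_numpy()
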