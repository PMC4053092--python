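"""Normalization and probe handling applied before signature fitting or scoring.

The training pipeline quantile-normalizes raw intensities across samples and
log2-transforms them.  When a fitted signature is applied to an external
cohort, each sample is independently rank-mapped onto the signature's stored
reference quantiles and z-scored against the training per-probe statistics,
which makes scoring invariant to any monotone transform applied uniformly to
a cohort and independent of which other samples happen to be in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expr_io import DrugResponseSignature, ExpressionMatrix, Scale

__all__ = [
    "NormalizationRecord",
    "quantile_normalize",
    "log2_transform",
    "collapse_probes_by_iqr",
    "standardize_to_reference",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizationRecord:
    method: str  # quantile | log2 | iqr_collapse | reference_standardize
    parameters: dict = field(default_factory=dict)


def _rank_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map each column of ``values`` onto the sorted ``reference`` by rank.

    Average ranks are used for ties, so tied entries share the mean of the
    reference values at their rank positions.  When the column length differs
    from the reference length, ranks are rescaled to quantile positions and
    linearly interpolated.
    """
    n = values.shape[0]
    ranks = rankdata(values, axis=0, method="average")  # in 1..n
    if n == 1:
        pos = np.full_like(ranks, (len(reference) - 1) / 2.0)
    else:
        pos = (ranks - 1.0) * (len(reference) - 1) / (n - 1)
    return np.interp(pos, np.arange(len(reference)), reference)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the across-sample mean empirical distribution.

    After the operation each column's sorted values equal the column-wise
    mean of sorted values; row and column labels are unchanged.
    """
    if m.shape[1] < 1:
        raise ValueError("need at least one sample")
    reference = np.sort(m.values, axis=0).mean(axis=1)
    out = _rank_map(m.values, reference)
    return m.with_values(out, record=NormalizationRecord("quantile"))


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with a positive floor; only defined for linear-scale matrices."""
    if m.scale is Scale.log2:
        raise ValueError("matrix is already on the log2 scale")
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = np.log2(np.maximum(m.values, floor))
    return m.with_values(out, scale=Scale.log2,
                         record=NormalizationRecord("log2", {"floor": floor}))


def collapse_probes_by_iqr(m: ExpressionMatrix, mapping: pd.Series) -> ExpressionMatrix:
    """One row per gene: keep the mapped probe with the largest interquartile range.

    The IQR is the linear-interpolation (type 7) 75th minus 25th percentile
    across samples.  Ties are broken by the lexicographically smallest probe
    id.  Output rows are labelled by gene symbol, sorted lexicographically.
    """
    unmapped = m.probe_ids.difference(pd.Index(mapping.index))
    if len(unmapped):
        raise ValueError(f"probe {unmapped[0]!r} is not in the probe->gene map")
    q75, q25 = np.percentile(m.values, [75, 25], axis=1)
    info = pd.DataFrame({
        "probe_id": m.probe_ids,
        "gene_symbol": mapping.reindex(m.probe_ids).to_numpy(),
        "iqr": q75 - q25,
    })
    winners = (info.sort_values(["iqr", "probe_id"], ascending=[False, True],
                                kind="mergesort")
               .groupby("gene_symbol", sort=True).head(1)
               .sort_values("gene_symbol"))
    data = m.data.loc[winners["probe_id"]]
    data.index = winners["gene_symbol"].to_numpy()
    out = ExpressionMatrix(data, scale=m.scale, history=list(m.history))
    out.history.append(NormalizationRecord("iqr_collapse",
                                           {"n_genes": len(winners)}))
    return out


def standardize_to_reference(cohort: ExpressionMatrix,
                             sig: DrugResponseSignature) -> ExpressionMatrix:
    """Put cohort samples on the signature's training scale, one sample at a time.

    The cohort is restricted to the signature probes; each sample's values
    are rank-mapped onto ``sig.reference_quantiles`` and then per-probe
    centered and scaled by the training row means/SDs.  Probes with zero
    training SD are left unscaled (scale 1) with a logged warning.
    """
    missing = pd.Index(sig.probe_ids).difference(cohort.probe_ids)
    if len(missing):
        raise ValueError(
            f"cohort is missing {len(missing)} signature probe(s): "
            f"{list(missing[:10])}")
    sub = cohort.data.loc[list(sig.probe_ids)]
    mapped = _rank_map(sub.to_numpy(dtype=float), sig.reference_quantiles)
    sds = sig.train_row_sds.copy()
    zero = sds <= 0
    if zero.any():
        log.warning("%d signature probe(s) have zero training SD; scaling by 1",
                    int(zero.sum()))
        sds[zero] = 1.0
    z = (mapped - sig.train_row_means[:, None]) / sds[:, None]
    out = ExpressionMatrix(pd.DataFrame(z, index=sub.index, columns=sub.columns),
                           scale=Scale.log2, history=list(cohort.history))
    out.history.append(NormalizationRecord("reference_standardize",
                                           {"k": sig.k}))
    return out
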