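"""Microarray intensity preprocessing.

The chain mirrors standard single-channel array practice: per-array
min-shift to 1 and log2 transform, quantile normalisation across arrays so
the cumulative intensity distributions coincide, removal of probes that
never rise above the limit of detection (LoD, estimated from negative
controls), removal of probes with negligible dynamic range, and averaging
of replicate probes into gene-level values.  Pipeline order is fixed:
normalise -> detection filter -> range filter -> collapse.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LOW_RANGE_THRESHOLD",
    "normalize_arrays",
    "detection_filter",
    "range_filter",
    "collapse_probes",
    "preprocess_pipeline",
]

#: Minimum (95th - 5th) percentile spread a probe must show, in log2 units
#: (a 1.5-fold range).
LOW_RANGE_THRESHOLD = float(np.log2(1.5))


def normalize_arrays(raw: pd.DataFrame) -> pd.DataFrame:
    """Shift, log-transform, and quantile-normalise raw intensities.

    Each array (column) is shifted by a constant so its minimum intensity is
    exactly 1, then log2-transformed (minimum becomes 0).  With two or more
    arrays, the transformed columns are quantile-normalised: each array's
    sorted values are replaced by the rank-wise mean across arrays, which
    makes the empirical intensity distributions identical while preserving
    within-array rank order.  A single array is only shifted and logged.
    """
    if raw.shape[1] < 1:
        raise ValueError("need at least one array")
    if not np.all(np.isfinite(raw.to_numpy(dtype=np.float64))):
        raise ValueError("raw intensities must be finite")
    x = raw.to_numpy(dtype=np.float64)
    x = x - x.min(axis=0, keepdims=True) + 1.0  # per-array minimum -> 1
    x = np.log2(x)
    if raw.shape[1] == 1:
        warnings.warn("single array: cross-array distribution mapping skipped")
        return pd.DataFrame(x, index=raw.index, columns=raw.columns)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def detection_filter(
    normalized: pd.DataFrame,
    negative_controls: Sequence[str],
    per_array: bool = False,
) -> pd.DataFrame:
    """Drop probes whose 90th percentile never reaches the limit of detection.

    LoD = mean(negative controls) + 1.96 * sd(negative controls), computed
    on the normalised scale.  Control values are pooled across arrays by
    default; ``per_array=True`` instead averages per-array LoD estimates,
    for arrays with strongly differing background spread.  Negative-control
    probes themselves are removed from the output.  With fewer than two
    controls the filter is skipped with a warning.
    """
    controls = [p for p in negative_controls if p in normalized.index]
    if len(controls) < 2:
        warnings.warn("fewer than 2 negative controls: detection filter skipped")
        return normalized.drop(index=controls)
    ctrl = normalized.loc[controls].to_numpy(dtype=np.float64)
    if per_array:
        lod = float(np.mean(ctrl.mean(axis=0) + 1.96 * ctrl.std(axis=0, ddof=1)))
    else:
        lod = float(ctrl.mean() + 1.96 * ctrl.std(ddof=1))
    rest = normalized.drop(index=controls)
    q90 = np.percentile(rest.to_numpy(dtype=np.float64), 90, axis=1)
    kept = rest.loc[q90 >= lod]
    logger.info("detection filter: LoD=%.4f, removed %d/%d probes", lod, len(rest) - len(kept), len(rest))
    return kept


def range_filter(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop probes whose (95th - 5th) percentile spread is below log2(1.5)."""
    if matrix.shape[1] < 2:
        raise ValueError("range filter needs at least 2 samples")
    x = matrix.to_numpy(dtype=np.float64)
    spread = np.percentile(x, 95, axis=1) - np.percentile(x, 5, axis=1)
    kept = matrix.loc[spread >= LOW_RANGE_THRESHOLD]
    logger.info("range filter: removed %d/%d probes", len(matrix) - len(kept), len(matrix))
    return kept


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Average replicate probes into one row per gene.

    Probes without a gene mapping are dropped (count logged).  Rows of the
    result are sorted by gene identifier, so the output does not depend on
    input row order.
    """
    mapping = pd.Series(dict(probe_to_gene))
    mapped = matrix.index.intersection(mapping.index)
    n_unmapped = len(matrix) - len(mapped)
    if n_unmapped:
        logger.info("collapse: dropping %d unmapped probes", n_unmapped)
    sub = matrix.loc[mapped]
    return sub.groupby(mapping.loc[mapped].to_numpy()).mean().sort_index()


def preprocess_pipeline(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Full chain from a raw probe table to a gene-level expression matrix.

    ``raw_table`` columns: ``probe``, ``is_negative_control``, ``gene``,
    then one column per array/sample.  Returns genes x samples, normalised
    log2 scale.
    """
    required = {"probe", "is_negative_control", "gene"}
    if not required.issubset(raw_table.columns):
        raise ValueError(f"raw table must have columns {sorted(required)} plus samples")
    sample_cols = [c for c in raw_table.columns if c not in required]
    if not sample_cols:
        raise ValueError("raw table has no sample columns")
    table = raw_table.set_index("probe")
    intensities = table[sample_cols].astype(np.float64)
    controls = list(table.index[table["is_negative_control"].astype(bool)])
    normalized = normalize_arrays(intensities)
    detected = detection_filter(normalized, controls)
    ranged = range_filter(detected)
    gene_map = table["gene"].dropna()
    gene_map = gene_map[gene_map.astype(str).str.len() > 0]
    return collapse_probes(ranged, gene_map.to_dict())
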