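"""Class comparison along the ordered list and at the single-gene level.

Relative transcriptograms divide the perturbed class's mean profile by the
reference class's, position by position.  Significance per list position
comes from a two-tailed Welch (unequal-variance) t test across the
per-sample transcriptogram values; the false discovery rate for a grid of
P-value cutoffs is estimated by permuting sample labels.  Because adjacent
positions share most of their window genes, neighbouring P values are
strongly dependent: the permutation FDR — not a per-position Bonferroni
correction — is the intended multiplicity control.

The module also carries the single-gene volcano stage (fold change +
Welch P per gene) and mean-expression comparisons of annotated gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FDR_THRESHOLDS",
    "ClassComparison",
    "VolcanoResult",
    "GeneSetResult",
    "positionwise_welch",
    "relative_transcriptogram",
    "permutation_fdr",
    "volcano",
    "gene_set_comparison",
]

#: P-value cutoffs at which permutation FDR is tabulated by default.
DEFAULT_FDR_THRESHOLDS = (0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005)


def _as_matrix(profiles) -> np.ndarray:
    m = profiles.to_numpy(dtype=np.float64) if isinstance(profiles, pd.DataFrame) else np.asarray(
        profiles, dtype=np.float64
    )
    if m.ndim != 2:
        raise ValueError("per-class profiles must be a 2-D (samples x positions) array")
    return m


def positionwise_welch(profiles_a, profiles_b) -> np.ndarray:
    """Two-tailed Welch t-test P value at every list position.

    Inputs are (samples x positions) matrices of per-sample transcriptogram
    values, one per class.  Degrees of freedom follow Welch–Satterthwaite.
    Zero-variance positions are resolved explicitly: if both classes are
    constant, P = 1 when the constants agree and P = 0 (with a warning)
    when they differ.
    """
    a, b = _as_matrix(profiles_a), _as_matrix(profiles_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("profile matrices must cover the same positions")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for a variance estimate")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    degenerate = (a.var(axis=0, ddof=1) == 0.0) & (b.var(axis=0, ddof=1) == 0.0)
    if np.any(degenerate):
        equal_means = a.mean(axis=0) == b.mean(axis=0)
        p = np.where(degenerate & equal_means, 1.0, p)
        if np.any(degenerate & ~equal_means):
            logger.warning(
                "%d positions have zero variance in both classes but unequal means; P set to 0",
                int(np.sum(degenerate & ~equal_means)),
            )
            p = np.where(degenerate & ~equal_means, 0.0, p)
    return np.asarray(p, dtype=np.float64)


@dataclass(frozen=True)
class ClassComparison:
    """Relative transcriptogram of a perturbed class against a reference."""

    positions: np.ndarray
    delta: np.ndarray  # mean_P / mean_R per position
    class_mean_p: np.ndarray
    class_mean_r: np.ndarray
    se_p: np.ndarray
    se_r: np.ndarray
    p_values: np.ndarray
    n_genes: Optional[int] = None
    fdr_table: Optional[pd.Series] = None
    n_permutations: int = 0

    @property
    def relative_positions(self) -> Optional[np.ndarray]:
        return None if self.n_genes is None else self.positions / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "position": self.positions,
                "delta": self.delta,
                "mean_P": self.class_mean_p,
                "se_P": self.se_p,
                "mean_R": self.class_mean_r,
                "se_R": self.se_r,
                "p_value": self.p_values,
            }
        )
        if self.n_genes is not None:
            out.insert(1, "relative_position", self.relative_positions)
        return out


def relative_transcriptogram(
    profiles_p,
    profiles_r,
    positions: Optional[np.ndarray] = None,
    n_genes: Optional[int] = None,
) -> ClassComparison:
    """Compare a perturbed class P against a reference class R.

    Profiles are averaged across the samples of each class; the relative
    transcriptogram is the position-wise ratio of the class means,
    ``delta_i = <k_i^P> / <k_i^R>``, with standard errors of the mean kept
    for plotting.  P values come from :func:`positionwise_welch`.
    """
    p_mat, r_mat = _as_matrix(profiles_p), _as_matrix(profiles_r)
    if positions is None:
        if isinstance(profiles_p, pd.DataFrame):
            positions = profiles_p.columns.to_numpy()
        else:
            positions = np.arange(p_mat.shape[1])
    mean_p, mean_r = p_mat.mean(axis=0), r_mat.mean(axis=0)
    zero = np.flatnonzero(mean_r == 0.0)
    if zero.size:
        raise ZeroDivisionError(
            f"reference class mean is zero at list position {positions[zero[0]]}; "
            "a relative transcriptogram is undefined there"
        )
    return ClassComparison(
        positions=np.asarray(positions),
        delta=mean_p / mean_r,
        class_mean_p=mean_p,
        class_mean_r=mean_r,
        se_p=p_mat.std(axis=0, ddof=1) / np.sqrt(p_mat.shape[0]),
        se_r=r_mat.std(axis=0, ddof=1) / np.sqrt(r_mat.shape[0]),
        p_values=positionwise_welch(p_mat, r_mat),
        n_genes=n_genes,
    )


def permutation_fdr(
    profiles_p,
    profiles_r,
    thresholds: Sequence[float] = DEFAULT_FDR_THRESHOLDS,
    n_perm: int = 500,
    seed: int = 0,
    return_null: bool = False,
):
    """Estimate the FDR of the position-wise tests by sample-label permutation.

    For each permutation, sample labels are reassigned uniformly at random
    among arrangements preserving the class sizes (drawn with replacement
    across permutations, identity not excluded — with 3 + 3 samples only 20
    distinct arrangements exist) and the Welch P values are recomputed.  At
    each cutoff p*:

    ``FDR(p*) = mean_perm #{positions with permuted P <= p*}
                / #{positions with observed P <= p*}``

    The estimate is NaN when no position is observed significant at p*.
    Returns a :class:`pandas.Series` indexed by threshold; with
    ``return_null=True`` also returns the (n_perm x positions) matrix of
    permuted P values for independent re-estimation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    p_mat, r_mat = _as_matrix(profiles_p), _as_matrix(profiles_r)
    n_p = p_mat.shape[0]
    pooled = np.vstack([p_mat, r_mat])
    observed = positionwise_welch(p_mat, r_mat)
    rng = np.random.default_rng(seed)
    null_p = np.empty((n_perm, pooled.shape[1]))
    for k in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null_p[k] = positionwise_welch(pooled[perm[:n_p]], pooled[perm[n_p:]])
    thresholds = tuple(thresholds)
    fdr = {}
    for t in thresholds:
        n_obs = int(np.sum(observed <= t))
        if n_obs == 0:
            fdr[t] = np.nan
        else:
            fdr[t] = float(np.mean(np.sum(null_p <= t, axis=1)) / n_obs)
    table = pd.Series(fdr, name="fdr")
    table.index.name = "threshold"
    return (table, null_p) if return_null else table


@dataclass(frozen=True)
class VolcanoResult:
    """Per-gene fold changes and Welch P values with significance flags."""

    table: pd.DataFrame  # index: gene; columns: fold_change, log2_fc, p_value, significant
    fc_threshold: float
    p_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def volcano(
    expression: pd.DataFrame,
    labels: pd.Series,
    class_a: str,
    class_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    scale: str = "log2",
) -> VolcanoResult:
    """Single-gene comparison of two classes: fold change vs Welch P.

    The fold change is the ratio of class-mean expression on the *linear*
    scale: for ``scale='log2'`` (the default for normalised intensities)
    ``FC = 2**(mean_a - mean_b)``; for ``scale='linear'`` the plain ratio of
    means, which requires strictly positive class means.  A gene is flagged
    significant when FC exceeds the threshold in either direction
    (``FC > fc_threshold`` or ``FC < 1/fc_threshold``) and P is below
    ``p_threshold``; the defaults are FC > 2 and P < 0.01.
    """
    for cls in (class_a, class_b):
        if not (labels == cls).any():
            raise ValueError(f"class {cls!r} has no samples")
    a_cols = labels.index[labels == class_a].intersection(expression.columns)
    b_cols = labels.index[labels == class_b].intersection(expression.columns)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("both classes need >= 2 samples")
    a = expression[a_cols].to_numpy(dtype=np.float64)
    b = expression[b_cols].to_numpy(dtype=np.float64)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    if scale == "log2":
        log2_fc = mean_a - mean_b
        fc = 2.0 ** log2_fc
    elif scale == "linear":
        if np.any(mean_a <= 0) or np.any(mean_b <= 0):
            raise ValueError(
                "fold change needs strictly positive class means on the linear scale; "
                "log-scale data should use scale='log2'"
            )
        fc = mean_a / mean_b
        log2_fc = np.log2(fc)
    else:
        raise ValueError("scale must be 'log2' or 'linear'")
    p = positionwise_welch(a.T, b.T)
    significant = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (p < p_threshold)
    table = pd.DataFrame(
        {"fold_change": fc, "log2_fc": log2_fc, "p_value": p, "significant": significant},
        index=expression.index,
    )
    return VolcanoResult(table=table, fc_threshold=fc_threshold, p_threshold=p_threshold)


@dataclass(frozen=True)
class GeneSetResult:
    """Mean expression of one annotated gene set per class, with Welch tests."""

    set_name: str
    n_members: int
    class_means: pd.Series  # class -> mean over member genes and samples
    class_sems: pd.Series  # class -> s.e.m. over the per-sample set means
    p_values: pd.DataFrame  # symmetric class x class Welch P values
    per_sample_means: pd.DataFrame = field(repr=False)  # class x replicate layout, long form

    def significance_marker(self, class_a: str, class_b: str) -> str:
        """Figure-style asterisks: '**' for P < 0.01, '*' for P < 0.05."""
        p = self.p_values.loc[class_a, class_b]
        return "**" if p < 0.01 else "*" if p < 0.05 else ""


def gene_set_comparison(
    expression: pd.DataFrame,
    labels: pd.Series,
    gene_set: Iterable[str],
    classes: Optional[Sequence[str]] = None,
    set_name: str = "",
) -> GeneSetResult:
    """Compare the mean expression of a gene set between classes.

    Each sample is reduced to its mean over the member genes; classes are
    compared by a two-tailed Welch t test on those per-sample means (three
    values per class in a triplicate design).
    """
    members = [g for g in expression.index if g in set(gene_set)]
    if not members:
        raise ValueError(f"gene set {set_name!r} shares no genes with the expression matrix")
    if classes is None:
        classes = list(pd.unique(labels))
    sample_means = expression.loc[members].mean(axis=0)  # one value per sample
    per_class: dict[str, np.ndarray] = {}
    for cls in classes:
        cols = labels.index[labels == cls].intersection(expression.columns)
        if len(cols) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples")
        per_class[cls] = sample_means[cols].to_numpy(dtype=np.float64)
    class_means = pd.Series({c: v.mean() for c, v in per_class.items()})
    class_sems = pd.Series({c: v.std(ddof=1) / np.sqrt(len(v)) for c, v in per_class.items()})
    pmat = pd.DataFrame(1.0, index=list(classes), columns=list(classes))
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            p = positionwise_welch(per_class[ca][:, None], per_class[cb][:, None])[0]
            pmat.loc[ca, cb] = pmat.loc[cb, ca] = p
    long = pd.DataFrame(
        [(c, k, v) for c, arr in per_class.items() for k, v in enumerate(arr)],
        columns=["class", "replicate", "set_mean"],
    )
    return GeneSetResult(
        set_name=set_name,
        n_members=len(members),
        class_means=class_means,
        class_sems=class_sems,
        p_values=pmat,
        per_sample_means=long,
    )
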