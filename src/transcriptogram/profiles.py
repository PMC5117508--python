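"""Windowed profiles along the ordered gene list.

Expression values (or binary term-membership indicators) are mapped onto
the ordered list and smoothed with a centred running average of window size
``2r + 1`` (default radius r = 30).  Window positions whose window would
leave the list are dropped, not padded: the profile covers 1-based list
positions ``r+1 .. N-r-1`` and has ``N - 2r - 1`` elements.  A term profile
value of 1 therefore means every gene in the window belongs to the term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RADIUS",
    "Profile",
    "OrderedExpression",
    "WindowTooLargeError",
    "term_indicator",
    "smooth",
    "enrichment_profile",
    "transcriptogram",
    "transcriptogram_matrix",
]

DEFAULT_RADIUS = 30


class WindowTooLargeError(ValueError):
    """The smoothing window does not fit inside the ordered list."""


@dataclass(frozen=True)
class Profile:
    """A per-position vector over the interior of the ordered list."""

    values: np.ndarray
    positions: np.ndarray  # 1-based list positions, r+1 .. N-r-1
    radius: int
    n_genes: int

    def __post_init__(self) -> None:
        if len(self.values) != len(self.positions):
            raise ValueError("values and positions must have equal length")
        if len(self.values) != self.n_genes - 2 * self.radius - 1:
            raise ValueError("profile length must equal N - 2r - 1")

    @property
    def relative_positions(self) -> np.ndarray:
        """Positions as fractions i/N of the list length (paper-style x axis)."""
        return self.positions / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "relative_position": self.relative_positions,
                "value": self.values,
            }
        )


def term_indicator(ordered_genes: Sequence[str], term_genes: Iterable[str]) -> np.ndarray:
    """Binary membership vector h over the ordered list.

    ``h[i] = 1`` when the gene at list position i belongs to the term; term
    genes absent from the list are ignored.  An empty intersection yields an
    all-zero vector with a warning.
    """
    term = set(term_genes)
    h = np.fromiter((g in term for g in ordered_genes), count=len(ordered_genes), dtype=np.int64)
    if h.sum() == 0:
        warnings.warn("term has no genes on the ordered list; indicator is all zeros")
    return h


def smooth(vector: Sequence[float], r: int = DEFAULT_RADIUS, n_genes: int | None = None) -> Profile:
    """Centred running average with window 2r + 1; edge positions dropped.

    ``k_i = (1/(2r+1)) * sum_{j=-r..r} h_{i+j}`` for 1-based positions
    ``i = r+1 .. N-r-1``.
    """
    v = np.asarray(vector, dtype=np.float64)
    n = n_genes if n_genes is not None else len(v)
    if len(v) != n:
        raise ValueError("vector length must equal N")
    if r < 0:
        raise ValueError("radius must be >= 0")
    if n <= 2 * r + 1:
        raise WindowTooLargeError(f"window 2r+1={2*r+1} does not fit a list of {n} genes")
    window = 2 * r + 1
    sums = np.convolve(v, np.ones(window), mode="valid")[: n - window]
    return Profile(
        values=sums / window,
        positions=np.arange(r + 1, n - r),
        radius=r,
        n_genes=n,
    )


def enrichment_profile(
    ordered_genes: Sequence[str], term_genes: Iterable[str], r: int = DEFAULT_RADIUS
) -> Profile:
    """Term-enrichment density profile: smoothed membership indicator.

    Values lie in [0, 1]; a value of exactly 1 at position i means every
    gene in the radius-r window around i participates in the term.
    """
    return smooth(term_indicator(ordered_genes, term_genes), r=r)


@dataclass(frozen=True)
class OrderedExpression:
    """Expression matrix aligned row-by-row to the ordered gene list.

    ``expression`` has one row per ordered gene (NaN rows for list genes
    missing from the measured data) and one column per sample; ``labels``
    maps each sample to its class.
    """

    ordered_genes: tuple[str, ...]
    expression: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.expression.index) != list(self.ordered_genes):
            raise ValueError("expression rows must match the ordered gene list")
        missing = [s for s in self.expression.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without a class label: {missing}")

    @classmethod
    def align(
        cls,
        ordered_genes: Sequence[str],
        expression: pd.DataFrame,
        labels: pd.Series,
    ) -> "OrderedExpression":
        """Map measured genes onto the ordered list.

        Measured genes absent from the list are dropped (count logged);
        list genes without measurements become NaN rows, which the windowed
        average later renormalises over available genes.
        """
        ordered_genes = tuple(ordered_genes)
        dropped = expression.index.difference(ordered_genes)
        if len(dropped):
            logger.info("dropping %d measured genes absent from the ordered list", len(dropped))
        aligned = expression.reindex(list(ordered_genes))
        return cls(ordered_genes=ordered_genes, expression=aligned, labels=labels.copy())

    @property
    def n_genes(self) -> int:
        return len(self.ordered_genes)

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def samples_of(self, class_label: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == class_label]


def transcriptogram(
    ordered_expression: OrderedExpression, sample: str, r: int = DEFAULT_RADIUS
) -> Profile:
    """Windowed mean expression of one sample along the ordered list.

    Windows average over the genes actually measured: the divisor is the
    number of non-missing genes in the window.  A window with less than 50%
    coverage is a hard error, because its mean would no longer represent
    the list neighbourhood.
    """
    if sample not in ordered_expression.expression.columns:
        raise KeyError(f"unknown sample {sample!r}")
    v = ordered_expression.expression[sample].to_numpy(dtype=np.float64)
    n = len(v)
    if r < 0:
        raise ValueError("radius must be >= 0")
    if n <= 2 * r + 1:
        raise WindowTooLargeError(f"window 2r+1={2*r+1} does not fit a list of {n} genes")
    window = 2 * r + 1
    present = np.isfinite(v)
    sums = np.convolve(np.where(present, v, 0.0), np.ones(window), "valid")[: n - window]
    counts = np.convolve(present.astype(np.float64), np.ones(window), "valid")[: n - window]
    if np.any(counts < 0.5 * window):
        worst = int(np.argmin(counts))
        raise ValueError(
            f"window at list position {worst + r + 1} has {int(counts[worst])}/{window} "
            "measured genes (< 50% coverage)"
        )
    return Profile(values=sums / counts, positions=np.arange(r + 1, n - r), radius=r, n_genes=n)


def transcriptogram_matrix(
    ordered_expression: OrderedExpression, r: int = DEFAULT_RADIUS
) -> pd.DataFrame:
    """Transcriptograms of all samples: rows = samples, columns = positions."""
    rows = {s: transcriptogram(ordered_expression, s, r=r).values for s in ordered_expression.samples}
    first = transcriptogram(ordered_expression, ordered_expression.samples[0], r=r)
    return pd.DataFrame.from_dict(rows, orient="index", columns=first.positions)
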