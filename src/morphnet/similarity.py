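"""Histogram-distribution similarity between cortical parcels.

For each pair of parcels the vertex values of the two parcels are pooled,
the pooled [min, max] range is divided into ``n_bins`` equal-width bins
(default 30), each parcel's vertex frequencies are counted over those
shared bins, and the similarity is the Pearson correlation of the two
frequency vectors.  Repeating this over all parcel pairs yields one
symmetric P x P similarity matrix per subject and measure.

Bins are left-closed/right-open, except the last bin which is closed so
that the pooled maximum is counted.  Frequencies are raw counts; Pearson
correlation is location/scale invariant, so proportions would give the
identical similarity (asserted as a property test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from morphnet.errors import DegenerateRangeError, ValidationError
from morphnet.morphometry_io import SubjectMorphometry

DEFAULT_N_BINS = 30


@dataclass(frozen=True)
class PairHistogram:
    """Shared-bin frequency histograms of one parcel pair."""

    bin_edges: np.ndarray  # n_bins + 1 strictly increasing edges
    freq_a: np.ndarray  # integer counts, sums to |values_a|
    freq_b: np.ndarray


@dataclass
class SimilarityMatrix:
    """P x P matrix of pairwise histogram-distribution similarities."""

    subject_id: str
    measure: str
    labels: tuple[str, ...]
    matrix: np.ndarray
    n_bins: int = DEFAULT_N_BINS
    n_degenerate_pairs: int = 0  # pairs mapped to similarity 0

    @property
    def n_parcels(self) -> int:
        return len(self.labels)


def pooled_bin_edges(values_a, values_b, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width bin edges spanning the pooled range of two value multisets.

    Returns ``n_bins + 1`` edges from min to max of the union of the two
    arrays.  Raises :class:`DegenerateRangeError` when the pooled range has
    zero width (all pooled values identical).
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValidationError("both value multisets must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo = min(values_a.min(), values_b.min())
    hi = max(values_a.max(), values_b.max())
    if lo == hi:
        raise DegenerateRangeError(
            f"pooled range [{lo}, {hi}] has zero width; histogram undefined"
        )
    return np.linspace(lo, hi, n_bins + 1)


def pair_frequencies(values_a, values_b, edges: np.ndarray) -> PairHistogram:
    """Count both parcels' vertices over the shared bin edges.

    Every value falls in exactly one bin; the final bin is closed so the
    pooled maximum is counted (this is numpy's histogram convention).
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    for name, v in (("a", values_a), ("b", values_b)):
        if v.min() < edges[0] or v.max() > edges[-1]:
            raise ValidationError(
                f"values_{name} fall outside the bin range "
                f"[{edges[0]}, {edges[-1]}]; edges must come from the pooled range"
            )
    freq_a, _ = np.histogram(values_a, bins=edges)
    freq_b, _ = np.histogram(values_b, bins=edges)
    return PairHistogram(bin_edges=edges, freq_a=freq_a, freq_b=freq_b)


def distribution_similarity(
    values_a, values_b, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Pearson correlation of two parcels' shared-bin frequency vectors.

    Degenerate cases — zero-width pooled range, or a frequency vector that
    is constant across bins (zero variance) — return 0.0 with a warning
    rather than dropping the pair, keeping similarity matrices complete.
    """
    try:
        edges = pooled_bin_edges(values_a, values_b, n_bins)
    except DegenerateRangeError:
        warnings.warn(
            "degenerate pooled range; similarity set to 0", stacklevel=2
        )
        return 0.0
    hist = pair_frequencies(values_a, values_b, edges)
    fa = hist.freq_a.astype(float)
    fb = hist.freq_b.astype(float)
    if fa.std() == 0.0 or fb.std() == 0.0:
        warnings.warn(
            "constant frequency vector; similarity set to 0", stacklevel=2
        )
        return 0.0
    r = float(np.corrcoef(fa, fb)[0, 1])
    # clamp numerical overshoot
    return float(min(1.0, max(-1.0, r)))


def build_similarity_matrix(
    sm: SubjectMorphometry, measure: str, n_bins: int = DEFAULT_N_BINS
) -> SimilarityMatrix:
    """All-pairs distribution similarity for one subject and one measure.

    The matrix is exactly symmetric (each pair computed once and mirrored)
    with unit diagonal; row order is the subject's parcellation order.
    """
    labels = sm.parcellation.labels
    p = len(labels)
    if p < 3:
        raise ValidationError(
            f"subject {sm.subject_id}: need >= 3 parcels, got {p}"
        )
    mat = np.eye(p)
    n_degenerate = 0
    for i in range(p):
        vi = sm.values[labels[i]][measure]
        for j in range(i + 1, p):
            vj = sm.values[labels[j]][measure]
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    r = distribution_similarity(vi, vj, n_bins)
                except ValidationError as exc:
                    raise ValidationError(
                        f"subject {sm.subject_id}, pair "
                        f"({labels[i]}, {labels[j]}): {exc}"
                    ) from exc
                n_degenerate += len(caught)
            mat[i, j] = mat[j, i] = r
    return SimilarityMatrix(
        subject_id=sm.subject_id,
        measure=measure,
        labels=labels,
        matrix=mat,
        n_bins=n_bins,
        n_degenerate_pairs=n_degenerate,
    )
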