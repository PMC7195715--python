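"""Sequencing-depth normalization and low-expression filtering.

Size factors follow the median-of-ratios estimator: each sample's factor is
the median, over genes expressed in every sample, of that sample's count
divided by the gene's geometric mean across samples.  Factors are *not*
re-scaled to unit geometric mean; simulation pipelines set them to 1 exactly.
"""

from __future__ import annotations

import numpy as np

from .io_design import CountMatrix, ValidationError


def estimate_size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one positive real per sample.

    Reference genes are the rows with strictly positive counts in every
    sample; their geometric means define per-gene pseudo-references.
    """
    k = counts.counts.astype(float)
    ref = np.all(k > 0, axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "pre-filter low-count genes before normalization"
        )
    logk = np.log(k[ref])
    log_geo = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geo, axis=0))
    return s


def filter_low_counts(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    max_low_samples: int = 10,
) -> CountMatrix:
    """Drop genes with CPM below ``cpm_threshold`` in more than
    ``max_low_samples`` samples.  CPM uses raw library sizes (column sums)."""
    k = counts.counts.astype(float)
    libsize = k.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValidationError("a sample has zero total counts")
    cpm = 1e6 * k / libsize
    n_low = (cpm < cpm_threshold).sum(axis=1)
    keep = n_low <= max_low_samples
    if not keep.any():
        raise ValidationError("low-count filter removed every gene")
    return CountMatrix(
        [g for g, m in zip(counts.gene_ids, keep) if m],
        list(counts.sample_ids),
        counts.counts[keep],
    )


def normalized_counts(counts: CountMatrix, s: np.ndarray) -> np.ndarray:
    """Counts divided sample-wise by their size factors: K_ij / s_j."""
    s = np.asarray(s, dtype=float)
    if s.shape != (counts.n_samples,) or np.any(s <= 0):
        raise ValidationError("size factors must be positive, one per sample")
    return counts.counts / s
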