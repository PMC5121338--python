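"""Per-sample size factors anchored on spike-in controls.

External spike-ins (e.g. the ERCC mixes) are added at fixed amounts per
library, so their counts should differ between samples only by sequencing
depth. The estimator is median-of-ratios restricted to spike rows: each
sample's factor is the median, over spike genes, of that sample's count
divided by the gene's geometric mean across samples. A total-count
fallback covers datasets without usable spikes. Factors are always
rescaled to geometric mean 1 so normalized abundances stay on the scale
of the original counts.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .io import CountMatrix, ValidationError

__all__ = ["SizeFactors", "spike_size_factors", "total_count_factors", "apply_factors"]

#: sample_id -> positive scale factor, geometric mean 1 within a dataset
SizeFactors = Dict[str, float]


def _rescale_geomean(raw: np.ndarray) -> np.ndarray:
    return raw / np.exp(np.mean(np.log(raw)))


def spike_size_factors(counts: CountMatrix, min_spikes: int = 3) -> SizeFactors:
    """Median-of-ratios size factors computed on spike-in rows only.

    Requires at least ``min_spikes`` spike genes with nonzero counts in
    every sample; raises otherwise, advising the total-count fallback.
    """
    mask = counts.spike_mask
    spikes = counts.counts[mask].astype(float)
    usable = spikes[(spikes > 0).all(axis=1)]
    if usable.shape[0] < min_spikes:
        raise ValidationError(
            f"only {usable.shape[0]} spike-in genes have nonzero counts in every sample "
            f"(need >= {min_spikes}); fall back to total_count_factors"
        )
    geomeans = np.exp(np.mean(np.log(usable), axis=1))
    ratios = usable / geomeans[:, None]
    factors = _rescale_geomean(np.median(ratios, axis=0))
    return dict(zip(counts.sample_ids, factors))


def total_count_factors(counts: CountMatrix) -> SizeFactors:
    """Library-size factors proportional to the non-spike column totals."""
    totals = counts.counts[~counts.spike_mask].sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [sid for sid, t in zip(counts.sample_ids, totals) if t <= 0]
        raise ValidationError(f"sample(s) with zero non-spike library total: {bad}")
    factors = _rescale_geomean(totals)
    return dict(zip(counts.sample_ids, factors))


def apply_factors(counts: CountMatrix, factors: SizeFactors) -> np.ndarray:
    """Divide each sample column by its size factor.

    Returns a float matrix aligned with ``counts``; spike rows are kept
    (callers exclude them via ``counts.spike_mask``).
    """
    missing = [sid for sid in counts.sample_ids if sid not in factors]
    if missing:
        raise ValidationError(f"no size factor for sample(s): {missing}")
    f = np.array([factors[sid] for sid in counts.sample_ids], dtype=float)
    if np.any(f <= 0):
        raise ValidationError("size factors must be positive")
    return counts.counts / f[None, :]
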