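"""Bootstrap resampling of Poisson count sinograms.

A count sinogram is expanded to an event list (one bin index per recorded
count), the list is resampled uniformly with replacement, and the resampled
list is rebinned.  The replicate therefore has exactly the same total count
as the data and is distributed Multinomial(sum(m), m / sum(m)) around it.
For large totals the replicate is drawn directly from that multinomial,
which is distributionally identical to the list procedure.
"""

from __future__ import annotations

import numpy as np

from .simulate import stream

__all__ = [
    "sinogram_to_list",
    "list_to_sinogram",
    "resample_list",
    "bootstrap_sinogram",
    "bootstrap_replicates",
]

# above this total, draw the multinomial directly instead of materialising
# the event list
_LIST_LIMIT = 200_000


def _check_counts(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if not np.issubdtype(m.dtype, np.integer):
        if not np.all(m == np.round(m)):
            raise ValueError("count sinogram must hold integers")
        m = m.astype(np.int64)
    if np.any(m < 0):
        raise ValueError("count sinogram must be non-negative")
    return m


def sinogram_to_list(m: np.ndarray) -> np.ndarray:
    """Expand counts to a list of flattened bin indices, row-major,
    repeats contiguous: bin i with n counts contributes index i n times."""
    m = _check_counts(m)
    return np.repeat(np.arange(m.size), m.ravel())


def list_to_sinogram(events: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Rebin an event list onto a sinogram of the given shape."""
    events = np.asarray(events, dtype=np.int64)
    n_bins = int(np.prod(shape))
    if events.size and (events.min() < 0 or events.max() >= n_bins):
        raise ValueError("event index out of range for sinogram shape")
    return np.bincount(events, minlength=n_bins).reshape(shape).astype(np.int64)


def resample_list(events: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample len(events) entries uniformly with replacement."""
    events = np.asarray(events, dtype=np.int64)
    if events.size == 0:
        raise ValueError("cannot resample an empty event list")
    rng = stream(seed, "bootstrap")
    return rng.choice(events, size=events.size, replace=True)


def bootstrap_sinogram(m: np.ndarray, seed: int = 0) -> np.ndarray:
    """One bootstrap replicate of a count sinogram (total exactly preserved)."""
    m = _check_counts(m)
    total = int(m.sum())
    if total == 0:
        raise ValueError("cannot bootstrap an all-zero sinogram")
    if total <= _LIST_LIMIT:
        return list_to_sinogram(resample_list(sinogram_to_list(m), seed), m.shape)
    rng = stream(seed, "bootstrap")
    return rng.multinomial(total, m.ravel() / total).reshape(m.shape).astype(np.int64)


def bootstrap_replicates(m: np.ndarray, n: int, seed: int = 0) -> list[np.ndarray]:
    """n replicates with distinct derived seeds (generated once, held fixed)."""
    if n < 1:
        raise ValueError("need at least one replicate")
    return [bootstrap_sinogram(m, seed=seed * 1000 + r) for r in range(n)]
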