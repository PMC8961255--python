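"""Nonparametric predictive inference (NPI) primitives and the NPI bootstrap.

NPI rests on Hill's post-data assumption ``A(n)``: given ``n`` ordered,
tie-free observations ``x_(1) < ... < x_(n)`` and finite support bounds
``L < x_(1)`` and ``R > x_(n)``, the next observation is equally likely to
fall in any of the ``n + 1`` open intervals between consecutive cut points.
The NPI bootstrap (NPI-B) extends this to ``m`` future observations by
applying ``A(n)``, ``A(n+1)``, ... consecutively: each future value is drawn
by selecting one of the current intervals uniformly at random, sampling a
point uniformly inside it, and inserting that point into the working set so
that the next draw chooses among one more interval.

Unlike Efron's bootstrap, NPI-B draws are not restricted to already observed
values, which is essential for predictive (rather than estimative) inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sample",
    "Bounds",
    "IntervalPartition",
    "FutureSample",
    "break_ties",
    "compute_bounds",
    "interval_partition",
    "npi_b_sample",
    "npi_b_sample_matrix",
]

#: Relative tie-breaking offset, as a fraction of the sample range.
DEFAULT_EPSILON_SCALE = 1e-9


@dataclass(frozen=True)
class Sample:
    """One group of univariate measurements, stored sorted ascending.

    Parameters
    ----------
    label : str
        Group identifier (e.g. a dose label).
    values : array-like of float
        Measurements; stored sorted. Ties are permitted here but must be
        broken (see :func:`break_ties`) before NPI interval construction.
    """

    label: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.ndim != 1 or v.size == 0:
            raise ValueError("a Sample requires a non-empty 1-d value array")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in sample {self.label!r}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def has_ties(self) -> bool:
        return bool(np.any(np.diff(self.values) == 0))


@dataclass(frozen=True)
class Bounds:
    """Finite support endpoints ``[L, R]`` for one group."""

    L: float
    R: float

    def __post_init__(self) -> None:
        if not self.L < self.R:
            raise ValueError(f"degenerate bounds: L={self.L} >= R={self.R}")


@dataclass(frozen=True)
class IntervalPartition:
    """The ``n + 2`` cut points ``L, x_(1), ..., x_(n), R`` and the
    ``n + 1`` open intervals they delimit."""

    cut_points: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cut_points, dtype=float)
        if c.size < 3 or np.any(np.diff(c) <= 0):
            raise ValueError("cut points must be strictly increasing, >= 3 of them")
        object.__setattr__(self, "cut_points", c)

    @property
    def n_intervals(self) -> int:
        return self.cut_points.size - 1

    @property
    def intervals(self) -> list[tuple[float, float]]:
        c = self.cut_points
        return list(zip(c[:-1], c[1:]))


@dataclass(frozen=True)
class FutureSample:
    """``m`` future observations drawn by NPI-B, in draw order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def m(self) -> int:
        return self.values.size


def break_ties(sample: Sample, epsilon: float | None = None) -> Sample:
    """Perturb tied values by tiny increments so the order is strict.

    Within a run of ``k`` equal values the ``i``-th occurrence is shifted by
    ``i * epsilon`` (``i = 0..k-1``), so no value moves by more than
    ``n * epsilon`` and previously-distinct values keep their order.

    Parameters
    ----------
    sample : Sample
    epsilon : float, optional
        Must be positive and small relative to the smallest nonzero gap.
        Defaults to ``1e-9`` times the sample range (or ``1e-9`` for an
        all-constant sample).

    Returns
    -------
    Sample
        A new sample with strictly ascending values; the input is returned
        unchanged when it is already tie-free.
    """
    v = sample.values
    if not sample.has_ties:
        return sample
    gaps = np.diff(v)
    pos = gaps[gaps > 0]
    if epsilon is None:
        rng_width = float(v[-1] - v[0])
        epsilon = DEFAULT_EPSILON_SCALE * (rng_width if rng_width > 0 else 1.0)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive to break ties")
    if pos.size and epsilon >= pos.min() / (sample.n + 1):
        raise ValueError(
            "epsilon too large: must be below the smallest nonzero gap / (n+1)"
        )
    out = v.copy()
    i = 0
    while i < out.size:
        j = i
        while j + 1 < out.size and v[j + 1] == v[i]:
            j += 1
        out[i : j + 1] += epsilon * np.arange(j - i + 1)
        i = j + 1
    return Sample(sample.label, out)


def _ensure_strict(sample: Sample) -> Sample:
    if sample.has_ties:
        warnings.warn(
            f"sample {sample.label!r} has tied values; breaking ties "
            f"automatically with epsilon = 1e-9 * range",
            stacklevel=3,
        )
        sample = break_ties(sample)
    return sample


def compute_bounds(sample: Sample) -> Bounds:
    """Finite support bounds from the maximum consecutive gap.

    ``L = x_(1) - max_i(x_(i) - x_(i-1))`` and
    ``R = x_(n) + max_i(x_(i) - x_(i-1))`` for ``i = 2..n``, so that the two
    outer intervals have the width of the widest interior gap.
    """
    sample = _ensure_strict(sample)
    if sample.n < 2:
        raise ValueError("bounds require at least two observations")
    v = sample.values
    gap = float(np.max(np.diff(v)))
    return Bounds(L=float(v[0]) - gap, R=float(v[-1]) + gap)


def interval_partition(sample: Sample, bounds: Bounds | None = None) -> IntervalPartition:
    """The ``A(n)`` partition ``(L, x_(1)), ..., (x_(n), R)`` for one sample."""
    sample = _ensure_strict(sample)
    if bounds is None:
        bounds = compute_bounds(sample)
    v = sample.values
    if not (bounds.L < v[0] and bounds.R > v[-1]):
        raise ValueError("bounds must strictly contain the sample")
    return IntervalPartition(np.concatenate(([bounds.L], v, [bounds.R])))


def npi_b_sample_matrix(
    values: np.ndarray,
    bounds: Bounds,
    m: int,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``size`` independent NPI-B future samples, each of length ``m``.

    Each replicate runs the sequential scheme: pick one of the current
    intervals uniformly, draw a uniform point inside it, split that interval
    at the drawn point, repeat. The bounds stay fixed throughout; only the
    partition refines. Because interval selection is uniform over the current
    set, intervals are stored unordered and the split appends the right half
    in a new slot — this vectorises the scheme exactly, with no approximation.

    Returns
    -------
    ndarray of shape ``(size, m)``
        Future values in draw order, all strictly inside ``(L, R)``.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if m < 0 or size < 0:
        raise ValueError("m and size must be non-negative")
    if not (bounds.L < v[0] and bounds.R > v[-1]):
        raise ValueError("bounds must strictly contain the sample")
    out = np.empty((size, m))
    if m == 0 or size == 0:
        return out
    cuts = np.concatenate(([bounds.L], v, [bounds.R]))
    lefts = np.empty((size, n + 1 + m))
    rights = np.empty((size, n + 1 + m))
    lefts[:, : n + 1] = cuts[:-1]
    rights[:, : n + 1] = cuts[1:]
    rows = np.arange(size)
    for k in range(m):
        j = rng.integers(0, n + 1 + k, size=size)
        lo = lefts[rows, j]
        hi = rights[rows, j]
        x = lo + rng.random(size) * (hi - lo)
        out[:, k] = x
        # split interval j at x: (lo, x) stays in slot j, (x, hi) goes new
        rights[rows, j] = x
        lefts[:, n + 1 + k] = x
        rights[:, n + 1 + k] = hi
    return out


def npi_b_sample(
    sample: Sample,
    bounds: Bounds | None = None,
    m: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> FutureSample:
    """Draw one NPI-B future sample from ``sample``.

    Parameters
    ----------
    sample : Sample
        The observed group; ties are broken automatically (with a warning).
    bounds : Bounds, optional
        Support endpoints; computed from the sample's max gap by default.
    m : int, optional
        Number of future observations; defaults to ``sample.n`` (a repeat
        experiment of the same size).
    rng : numpy Generator or seed, optional
    """
    sample = _ensure_strict(sample)
    if bounds is None:
        bounds = compute_bounds(sample)
    if m is None:
        m = sample.n
    rng = np.random.default_rng(rng)
    draws = npi_b_sample_matrix(sample.values, bounds, m, 1, rng)
    return FutureSample(draws[0])
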