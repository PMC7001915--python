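"""Occurrence-record sufficiency screening and rarefaction diagnostics.

Point-occurrence archives are uneven: some species carry a handful of
records, others thousands.  A species' latitudinal and thermal range is
estimated from the 1st-99th percentile interval of its records, and a
record count is deemed *sufficient* when resamples of that size reliably
recover the full-sample interval:

* draw ``reps`` subsamples of size ``n`` without replacement;
* a subsample succeeds when its own 1st-99th percentile interval covers
  the species' full-sample interval (shrunk by a small relative tolerance
  so endpoint ties on continuous data do not fail) — i.e. the subsample
  captures the species' range;
* the minimum sufficient ``n`` is the smallest subsample size whose
  success fraction exceeds ``coverage`` (default 0.95, i.e. >950 of 1000).

Species below a global record-count threshold (default 41) are removed.
Rarefaction curves (expected distinct species vs. subsample size) per
latitude bin diagnose residual sampling bias; the analytic hypergeometric
form and a Monte-Carlo estimator are both provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .grids import InvalidInputError
from .synthetic import SpeciesOccurrenceSet

AXES = ("latitudinal", "thermal")


@dataclass
class RangeInterval:
    """A percentile interval along one axis (latitudinal or thermal)."""

    axis: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise InvalidInputError("interval low > high")

    @property
    def width(self) -> float:
        return self.high - self.low

    def widened(self, rel_tol: float) -> "RangeInterval":
        pad = rel_tol * self.width
        return RangeInterval(self.axis, self.low - pad, self.high + pad)

    def shrunk(self, rel_tol: float) -> "RangeInterval":
        pad = rel_tol * self.width
        return RangeInterval(self.axis, self.low + pad, self.high - pad)

    def covered_by(self, low, high) -> np.ndarray:
        """Element-wise: does the interval [low, high] cover this interval?"""
        return (np.asarray(low) <= self.low) & (np.asarray(high) >= self.high)


@dataclass
class ScreeningResult:
    species_id: str
    n_records: int
    passed: bool
    intervals: dict[str, RangeInterval] = field(default_factory=dict)
    min_sufficient: dict[str, int | None] = field(default_factory=dict)


def percentile_interval(values, lo: float = 1.0, hi: float = 99.0, axis: str = "value") -> RangeInterval:
    """1st-99th (by default) percentile interval, linear-interpolation convention."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("percentile_interval: empty input")
    qlo, qhi = np.percentile(values, [lo, hi], method="linear")
    return RangeInterval(axis, float(qlo), float(qhi))


def _resample_intervals(
    values: np.ndarray,
    n: int,
    reps: int,
    rng: np.random.Generator,
    replace: bool = False,
    lo: float = 1.0,
    hi: float = 99.0,
    chunk: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """(lows, highs) of the lo-hi percentile interval of ``reps`` subsamples of size n."""
    N = values.size
    lows = np.empty(reps)
    highs = np.empty(reps)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        if replace:
            idx = rng.integers(0, N, size=(m, n))
            samples = values[idx]
        else:
            # vectorised sampling without replacement: argpartition of random keys
            keys = rng.random((m, N))
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
            samples = values[idx]
        q = np.percentile(samples, [lo, hi], axis=1, method="linear")
        lows[done : done + m] = q[0]
        highs[done : done + m] = q[1]
        done += m
    return lows, highs


def resample_range_widths(
    values,
    n: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
    lo: float = 1.0,
    hi: float = 99.0,
) -> np.ndarray:
    """Widths of the 1st-99th percentile interval over ``reps`` random
    subsamples of size ``n`` drawn without replacement (by default)."""
    values = np.asarray(values, dtype=float)
    if not (1 < n <= values.size):
        raise InvalidInputError(f"need 1 < n <= n_records ({values.size}), got n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lows, highs = _resample_intervals(values, n, reps, rng, replace=replace, lo=lo, hi=hi)
    return highs - lows


def _success_fraction(
    values: np.ndarray,
    n: int,
    reps: int,
    seed: int,
    target: RangeInterval,
    replace: bool,
) -> float:
    # the per-n RNG depends only on (seed, n): any search order over n
    # reproduces identical success fractions
    rng = np.random.default_rng([seed, n])
    lows, highs = _resample_intervals(values, n, reps, rng, replace=replace)
    return float(np.mean(target.covered_by(lows, highs)))


def min_sufficient_records(
    values,
    reps: int = 1000,
    coverage: float = 0.95,
    seed: int = 0,
    rel_tol: float = 0.01,
    replace: bool = False,
    axis: str = "value",
    search: str = "ascending",
) -> int | None:
    """Smallest subsample size that reliably captures the species' range.

    A resample of size n succeeds when its 1st-99th percentile interval
    covers the full-sample interval shrunk by ``rel_tol`` of its width;
    the returned n is the smallest whose success fraction over ``reps``
    resamples exceeds ``coverage``.  Returns None ("undetermined") if no
    n <= n_records qualifies.

    Per-n resamples are seeded by (seed, n), so the result is a
    deterministic function of the success profile, independent of search
    order.  ``search='ascending'`` (default) scans n upward and stops at
    the first acceptable n — the exact minimum.  ``search='binary'`` is a
    faster bracketing search that assumes the success fraction is monotone
    in n (empirically true away from the coverage threshold) and walks
    down over contiguous successes; it can land above an isolated early
    success when the success profile is noisy near the threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("min_sufficient_records needs >= 2 records")
    target = percentile_interval(values, axis=axis).shrunk(rel_tol)

    def success(n: int) -> bool:
        return _success_fraction(values, n, reps, seed, target, replace) > coverage

    if search == "ascending":
        for n in range(2, values.size + 1):
            if success(n):
                return n
        return None
    if search != "binary":
        raise InvalidInputError(f"unknown search {search!r}")
    lo_n, hi_n = 2, values.size
    if not success(hi_n):
        return None
    while lo_n < hi_n:
        mid = (lo_n + hi_n) // 2
        if success(mid):
            hi_n = mid
        else:
            lo_n = mid + 1
    n_min = hi_n
    while n_min > 2 and success(n_min - 1):  # guard: walk down if non-monotone
        n_min -= 1
    return int(n_min)


def screen_species(
    occurrences: SpeciesOccurrenceSet,
    threshold: int = 41,
    compute_sufficiency: bool = False,
    reps: int = 1000,
    coverage: float = 0.95,
    seed: int = 0,
) -> tuple[SpeciesOccurrenceSet, list[ScreeningResult]]:
    """Drop species with fewer than ``threshold`` records.

    Results report record counts and global 1st-99th percentile intervals
    (latitudinal and thermal) for every input species; per-axis minimum
    sufficient record counts are computed when ``compute_sufficiency`` is
    set (it is resampling-heavy).
    """
    counts = occurrences.counts()
    results: list[ScreeningResult] = []
    kept: list[str] = []
    for sp_id, n in counts.sort_index().items():
        res = ScreeningResult(species_id=sp_id, n_records=int(n), passed=bool(n >= threshold))
        for ax in AXES:
            vals = occurrences.species_values(sp_id, ax)
            res.intervals[ax] = percentile_interval(vals, axis=ax)
            if compute_sufficiency and n >= 2:
                res.min_sufficient[ax] = min_sufficient_records(
                    vals, reps=reps, coverage=coverage, seed=seed, axis=ax
                )
        if res.passed:
            kept.append(sp_id)
        results.append(res)
    return occurrences.subset(kept), results


def screening_report(results: list[ScreeningResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"species_id": r.species_id, "n_records": r.n_records, "passed": r.passed}
        for ax, iv in r.intervals.items():
            row[f"{ax}_low"], row[f"{ax}_high"] = iv.low, iv.high
        for ax, m in r.min_sufficient.items():
            row[f"{ax}_min_sufficient"] = np.nan if m is None else m
        rows.append(row)
    return pd.DataFrame(rows)


def median_min_sufficient(
    results: list[ScreeningResult], axis: str
) -> tuple[float, float]:
    """Median and spread (median absolute deviation) of per-species minimum
    sufficient record counts along ``axis``, over determined species."""
    vals = np.array(
        [r.min_sufficient[axis] for r in results if r.min_sufficient.get(axis) is not None],
        dtype=float,
    )
    if vals.size == 0:
        raise InvalidInputError(f"no determined min_sufficient values for axis {axis!r}")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, mad


# ---------------------------------------------------------------------------
# rarefaction


def rarefaction_curve(
    species_of_record,
    sample_sizes,
    method: str = "analytic",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected number of distinct species in uniform subsamples of a pool.

    ``species_of_record`` is one species id per record.  The analytic form
    is the hypergeometric expectation
    ``E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n))``; the Monte-Carlo form
    subsamples records ``reps`` times.
    """
    ids = np.asarray(species_of_record)
    if ids.size == 0:
        raise InvalidInputError("rarefaction_curve: empty pool")
    sizes = np.atleast_1d(np.asarray(sample_sizes, dtype=int))
    N = ids.size
    if np.any(sizes < 1) or np.any(sizes > N):
        raise InvalidInputError(f"sample sizes must lie in [1, {N}]")
    _, counts = np.unique(ids, return_counts=True)

    if method == "analytic":
        expected = [_analytic_rarefaction(counts, N, int(n)) for n in sizes]
    elif method == "monte_carlo":
        rng = np.random.default_rng(seed)
        acc = np.zeros(sizes.size)
        codes = np.unique(ids, return_inverse=True)[1]
        for _ in range(reps):
            perm = rng.permutation(codes)  # nested subsamples share a permutation
            for j, n in enumerate(sizes):
                acc[j] += np.unique(perm[:n]).size
        expected = acc / reps
    else:
        raise InvalidInputError(f"unknown rarefaction method {method!r}")
    return pd.DataFrame({"sample_size": sizes, "expected_species": expected})


def _analytic_rarefaction(counts: np.ndarray, N: int, n: int) -> float:
    # P(species i absent from a size-n subsample) = C(N - N_i, n) / C(N, n)
    with np.errstate(invalid="ignore"):
        M = N - counts
        log_absent = np.where(
            M >= n,
            gammaln(M + 1) - gammaln(M - n + 1) - (gammaln(N + 1) - gammaln(N - n + 1)),
            -np.inf,
        )
    return float(np.sum(1.0 - np.exp(log_absent)))


def latitudinal_rarefaction(
    occurrences: SpeciesOccurrenceSet,
    bin_deg: float = 20.0,
    sample_sizes=None,
    method: str = "analytic",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rarefaction curves per latitude bin.

    Half-open [b, b + bin_deg) bins mirror outward from the equator so the
    northern and southern hemispheres are split (the polemost bin of each
    hemisphere is truncated at 90 when bin_deg does not divide 90).
    Returns a long table (bin_low, bin_high, sample_size, expected_species);
    empty bins appear once with NaN expected_species.
    """
    north = np.arange(0.0, 90.0, bin_deg)
    edges = np.unique(np.concatenate([-north, north, [-90.0, 90.0]]))
    lat = occurrences.table["lat"].to_numpy(dtype=float)
    ids = occurrences.table["species_id"].to_numpy()
    which = np.digitize(lat, edges, right=False) - 1  # [b, b+bin) convention
    which = np.clip(which, 0, edges.size - 2)

    frames = []
    for b in range(edges.size - 1):
        pool = ids[which == b]
        if pool.size == 0:
            frames.append(
                pd.DataFrame(
                    {
                        "bin_low": [edges[b]],
                        "bin_high": [edges[b + 1]],
                        "sample_size": [0],
                        "expected_species": [np.nan],
                    }
                )
            )
            continue
        sizes = (
            np.unique(np.linspace(1, pool.size, min(20, pool.size)).astype(int))
            if sample_sizes is None
            else np.asarray(sample_sizes)[np.asarray(sample_sizes) <= pool.size]
        )
        curve = rarefaction_curve(pool, sizes, method=method, reps=reps, seed=seed + b)
        curve.insert(0, "bin_high", edges[b + 1])
        curve.insert(0, "bin_low", edges[b])
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)
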