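"""Moving-block bootstrap tests for autocorrelated speed series.

Telemetry-derived speed series are serially correlated, so naive
two-sample tests understate the sampling variance and over-reject.
The block bootstrap keeps the short-range dependence structure by
resampling contiguous blocks of length L with replacement and
concatenating them (truncated to the original length) to build each
bootstrap series.  Here the statistic of interest is the difference of
medians between two series; its bootstrap distribution yields a
two-sided p-value and a percentile confidence interval.

Conventions (all switchable where noted):

* moving blocks — a block may start at any admissible index
  (``overlap=False`` restricts starts to a non-overlapping grid);
* the two series are resampled independently (unpaired groups);
* two-sided p = 2 * min(P(D* <= 0), P(D* >= 0)) with a
  +1/(n_boot + 1) continuity correction, so p is never exactly 0;
* a "series" may be a list of arrays (one per animal): blocks are then
  drawn within each array and concatenated, so no block ever spans two
  animals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np

DEFAULT_N_BOOT = 10_000
DEFAULT_BLOCK_LENGTH = 100
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for a block-bootstrap test."""

    n_boot: int = DEFAULT_N_BOOT
    block_length: int = DEFAULT_BLOCK_LENGTH
    alpha: float = DEFAULT_ALPHA
    n_comparisons: int = 1
    seed: int | None = None
    overlap: bool = True  # moving blocks; False = non-overlapping grid

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of one block-bootstrap hypothesis test."""

    statistic_name: str
    observed: float
    p_value: float
    ci_low: float
    ci_high: float
    alpha_effective: float
    settings: BootstrapConfig
    labels: tuple = ()

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha_effective


def _as_segments(series) -> list[np.ndarray]:
    if isinstance(series, (list, tuple)) and len(series) and np.ndim(series[0]) >= 1:
        segs = [np.asarray(s, dtype=float).ravel() for s in series]
    else:
        segs = [np.asarray(series, dtype=float).ravel()]
    if any(len(s) == 0 for s in segs) or not segs:
        raise ValueError("empty series")
    return segs


def block_resample(
    series,
    block_length: int,
    rng: np.random.Generator,
    n_resamples: int = 1,
    overlap: bool = True,
) -> np.ndarray:
    """Block-bootstrap resamples of a series, shape (n_resamples, n).

    Contiguous blocks of exactly ``block_length`` are drawn uniformly
    with replacement and concatenated, then truncated to the original
    length.  ``series`` may be a list of arrays, in which case each
    array is resampled independently (blocks never cross arrays) and
    the results are concatenated.  Raises if any segment is shorter
    than ``block_length``.
    """
    segs = _as_segments(series)
    out_parts = []
    for x in segs:
        n = len(x)
        if n < block_length:
            raise ValueError(
                f"series segment of length {n} shorter than block length {block_length}"
            )
        n_blocks = -(-n // block_length)  # ceil
        if overlap:
            starts = rng.integers(0, n - block_length + 1, size=(n_resamples, n_blocks))
        else:
            grid = np.arange(0, n - block_length + 1, block_length)
            starts = grid[rng.integers(0, len(grid), size=(n_resamples, n_blocks))]
        idx = starts[:, :, None] + np.arange(block_length)[None, None, :]
        out_parts.append(x[idx.reshape(n_resamples, -1)[:, :n]])
    return np.concatenate(out_parts, axis=1)


def test_median_difference(
    series_a,
    series_b,
    config: BootstrapConfig | None = None,
    statistic_name: str = "median difference",
) -> BootstrapResult:
    """Two-sided block-bootstrap test of median(a) - median(b) = 0.

    Both series are independently block-resampled ``n_boot`` times;
    the p-value is 2 * min(tail probabilities) of the bootstrap
    difference distribution around 0, with a +1/(n_boot+1) continuity
    correction, clipped to [0, 1].  The (1 - alpha) percentile CI of
    the bootstrap differences is also returned.
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(config.seed)
    a, b = _as_segments(series_a), _as_segments(series_b)

    obs = float(np.median(np.concatenate(a)) - np.median(np.concatenate(b)))
    boot_a = np.median(
        block_resample(a, config.block_length, rng, config.n_boot, config.overlap), axis=1
    )
    boot_b = np.median(
        block_resample(b, config.block_length, rng, config.n_boot, config.overlap), axis=1
    )
    delta = boot_a - boot_b

    B = config.n_boot
    p_le = (np.count_nonzero(delta <= 0.0) + 1) / (B + 1)
    p_ge = (np.count_nonzero(delta >= 0.0) + 1) / (B + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))

    lo, hi = np.quantile(delta, [config.alpha / 2.0, 1.0 - config.alpha / 2.0])
    alpha_eff = config.alpha / config.n_comparisons
    return BootstrapResult(
        statistic_name=statistic_name,
        observed=obs,
        p_value=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha_effective=float(alpha_eff),
        settings=config,
    )


def pairwise_tests(
    groups: dict,
    config: BootstrapConfig | None = None,
) -> list[BootstrapResult]:
    """All pairwise median-difference tests with Bonferroni correction.

    ``groups`` maps labels (e.g. sex classes F/M/U) to series (or
    per-animal lists of series).  The familywise level ``alpha`` is
    split evenly over the number of testable pairs
    (alpha_effective = alpha / n_pairs).  Pairs involving a group with
    any segment shorter than the block length are skipped with a
    warning (and still count toward the correction, keeping the
    familywise guarantee conservative).
    """
    config = config or BootstrapConfig()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(groups.keys(), 2))
    cfg = replace(config, n_comparisons=len(pairs))
    root = np.random.default_rng(config.seed)
    results = []
    for la, lb in pairs:
        sub_seed = int(root.integers(0, 2**31 - 1))
        try:
            res = test_median_difference(
                groups[la], groups[lb],
                replace(cfg, seed=sub_seed),
                statistic_name=f"median({la}) - median({lb})",
            )
        except ValueError as exc:
            warnings.warn(f"pair ({la}, {lb}) skipped: {exc}")
            continue
        results.append(replace(res, labels=(la, lb)))
    return results
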