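"""ACME-style sliding-window upper-quantile enrichment detection.

Only the upper quantile of the log-ratio distribution of a regulation
array is informative: it is where the enriched probes live.  The window
test asks, for every tiling probe, whether the probes in a window around
it over-sample that upper quantile: with k of the n window probes above
the threshold, against K of N tiling probes genome-wide, a one-sided
chi-square test (1 df, Yates continuity correction) on the 2x2 table
[[k, n-k], [K-k, (N-n)-(K-k)]] yields the per-probe enrichment p-value
(p = 1 when the window is not over-sampling, i.e. k/n <= K/N).  Runs of
significant probes are merged into called regions.

Because only the threshold *rank* matters, the p-values are invariant
under any strictly increasing transform of the log-ratios — which is why
rank-preserving normalizations leave enrichment calls untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .core import ProbeAnnotation, ProbeCategory

__all__ = [
    "EnrichmentParams",
    "EnrichmentResult",
    "enrichment_pvalues",
    "call_regions",
    "count_regions",
]


@dataclass
class EnrichmentParams:
    """Sliding-window test parameters.

    threshold_quantile : quantile of the supplied log-ratio vector that
        defines "above threshold" (default 0.95, i.e. the top 5%).
    window_bp : window width in bp, centered on each probe position.
    alpha : significance cut-off used for region calling.
    """

    threshold_quantile: float = 0.95
    window_bp: int = 1000
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class EnrichmentResult:
    """Per-tiling-probe window test results.

    Arrays align with the tiling probes of the annotation, in (chrom,
    position) order; ``tiling_index`` maps them back to annotation rows.
    """

    pvalues: np.ndarray
    n_in_window: np.ndarray
    k_above: np.ndarray
    threshold: float
    tiling_index: np.ndarray
    chrom: np.ndarray
    position: np.ndarray
    probe_length: np.ndarray
    window_bp: int
    flags: dict = field(default_factory=dict)


def _yates_chi2_one_sided(k: int, n: int, K: int, N: int) -> float:
    """One-sided upper-tail p for over-representation in a 2x2 table.

    Table [[k, n-k], [K-k, (N-n)-(K-k)]]; p = 1 unless k/n > K/N, else
    half the upper tail of the continuity-corrected chi-square (1 df).
    """
    if n == 0 or K == 0 or N == n:
        return 1.0
    if k * N <= K * n:  # k/n <= K/N
        return 1.0
    a, b = k, n - k
    c, d = K - k, (N - n) - (K - k)
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    diff = abs(a * d - b * c) - N / 2.0
    if diff < 0:
        diff = 0.0
    stat = N * diff * diff / (r1 * r2 * c1 * c2)
    return float(chi2.sf(stat, df=1) / 2.0)


def enrichment_pvalues(
    annotation: ProbeAnnotation,
    m_values: np.ndarray,
    params: EnrichmentParams | None = None,
) -> EnrichmentResult:
    """Sliding-window upper-quantile enrichment p-values for tiling probes.

    ``m_values`` is a per-probe log-ratio vector aligned to ``annotation``
    (a single array or a combined vector).  The threshold is the empirical
    ``threshold_quantile`` of the tiling-probe log-ratios — the same
    universe the windows sample, so K/N matches the nominal quantile and
    the 2x2 margins are self-consistent; windows span probes on the same
    chromosome within +/- window_bp/2 of each tiling probe's position.
    Tiling probes must be sorted by (chrom, position).
    """
    if params is None:
        params = EnrichmentParams()
    params.validate()
    m = np.asarray(m_values, dtype=float)
    if len(m) != len(annotation):
        raise ValueError("m_values must align to the annotation")

    tiling_index = np.flatnonzero(annotation.category_mask(ProbeCategory.TILING))
    if tiling_index.size == 0:
        raise ValueError("annotation contains no tiling probes")
    chrom = annotation.chrom[tiling_index]
    pos = annotation.position[tiling_index].astype(np.int64)
    seen: dict[str, int] = {}
    last_chrom = None
    for i in range(len(tiling_index)):
        c = chrom[i]
        if c != last_chrom:
            if c in seen:
                raise ValueError("tiling probes are not sorted by (chrom, position)")
            seen[c] = i
            last_chrom = c
        elif pos[i] < pos[i - 1]:
            raise ValueError("tiling probes are not sorted by (chrom, position)")

    m_tile = m[tiling_index]
    threshold = float(
        np.quantile(m_tile[np.isfinite(m_tile)], params.threshold_quantile)
    )
    above = (m_tile > threshold).astype(np.int64)
    N = int(m_tile.size)
    K = int(above.sum())

    pvals = np.ones(N)
    n_in = np.zeros(N, dtype=np.int64)
    k_in = np.zeros(N, dtype=np.int64)
    half = params.window_bp / 2.0
    single_probe_windows = 0
    start = 0
    while start < N:
        end = start
        while end < N and chrom[end] == chrom[start]:
            end += 1
        cpos = pos[start:end].astype(float)
        cabove = above[start:end]
        csum = np.concatenate([[0], np.cumsum(cabove)])
        lo = np.searchsorted(cpos, cpos - half, side="left")
        hi = np.searchsorted(cpos, cpos + half, side="right")
        for i in range(end - start):
            n = int(hi[i] - lo[i])
            k = int(csum[hi[i]] - csum[lo[i]])
            n_in[start + i] = n
            k_in[start + i] = k
            if n <= 1:
                single_probe_windows += 1
                pvals[start + i] = 1.0
            else:
                pvals[start + i] = _yates_chi2_one_sided(k, n, K, N)
        start = end

    flags = {}
    if single_probe_windows:
        flags["single_probe_windows"] = single_probe_windows
    return EnrichmentResult(
        pvalues=pvals,
        n_in_window=n_in,
        k_above=k_in,
        threshold=threshold,
        tiling_index=tiling_index,
        chrom=chrom,
        position=pos,
        probe_length=annotation.probe_length[tiling_index].astype(np.int64),
        window_bp=params.window_bp,
        flags=flags,
    )


def call_regions(
    result: EnrichmentResult, alpha: float
) -> list[tuple[str, int, int]]:
    """Merge significant tiling probes into enriched regions.

    Maximal runs of consecutive tiling probes with p < alpha are emitted
    as 0-based half-open intervals; adjacent runs on the same chromosome
    separated by less than window_bp/2 are merged.  Regions are sorted and
    non-overlapping.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sig = result.pvalues < alpha
    regions: list[tuple[str, int, int]] = []
    gap = result.window_bp / 2.0
    i, N = 0, len(sig)
    while i < N:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < N and sig[j + 1] and result.chrom[j + 1] == result.chrom[i]:
            j += 1
        start = int(result.position[i])
        end = int(result.position[j] + result.probe_length[j])
        if (
            regions
            and regions[-1][0] == result.chrom[i]
            and start - regions[-1][2] < gap
        ):
            regions[-1] = (regions[-1][0], regions[-1][1], end)
        else:
            regions.append((str(result.chrom[i]), start, end))
        i = j + 1
    return regions


def count_regions(
    result: EnrichmentResult, alphas: Sequence[float] = (0.05, 0.10, 0.20, 0.50)
) -> dict[float, int]:
    """Number of called regions at each p-value cut-off."""
    return {float(a): len(call_regions(result, a)) for a in alphas}
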