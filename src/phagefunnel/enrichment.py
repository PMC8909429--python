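"""Depth normalisation, positive-delta enrichment filtering and
breakpoint-cycle diagnostics.

Counts are normalised within each cycle to counts per million (CPM) so that
clone trajectories are comparable across cycles of unequal sequencing depth.
The first funnel filter keeps only clones whose CPM *increases* between two
cycles (positive delta); a stringent preset instead demands a >= 100-fold
CPM increase between consecutive cycles, the enrichment magnitude typical of
a good binder.

Selection collapses clonal diversity: per-cycle Shannon entropy falls and
the share of reads held by the top-ranking clones rises, until the
sub-library saturates and later cycles add no relative-enrichment
information.  ``find_breakpoint`` formalises that qualitative picture to
pick the earliest informative cycle at which ranking should be read off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import CountsTable

__all__ = [
    "EnrichmentProfile",
    "CycleProfile",
    "normalize_cpm",
    "delta_filter",
    "cycle_entropy",
    "find_breakpoint",
    "diagnostics_frame",
    "STRINGENT_FOLD",
    "PSEUDO_CPM",
]

#: stringent preset: required fold-change between consecutive cycles
STRINGENT_FOLD = 100.0
#: floor applied to the denominator CPM so fold changes stay finite
PSEUDO_CPM = 1.0


@dataclass
class EnrichmentProfile:
    """Per-sequence CPM trajectories and inter-cycle differences.

    ``delta[:, c] = cpm[:, c+1] - cpm[:, c]``;
    ``fold[:, c] = cpm[:, c+1] / max(cpm[:, c], PSEUDO_CPM)``.
    """

    sequences: list[str]
    cpm: np.ndarray
    delta: np.ndarray
    fold: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.cpm.shape[1]


@dataclass
class CycleProfile:
    """Per-cycle diversity diagnostics.

    entropy: Shannon entropy (bits) of the clone frequency distribution;
    top_k_share: fraction of counted reads held by the k most abundant clones.
    """

    entropy: np.ndarray
    top_k_share: np.ndarray
    k: int
    breakpoint_cycle: int | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.entropy)


def normalize_cpm(table: CountsTable) -> EnrichmentProfile:
    """counts-per-million: ``cpm[s, c] = counts[s, c] / cycle_totals[c] * 1e6``.

    Totals are the raw per-cycle depths, so on an unpruned table each cpm
    column sums to 1e6 once N-excluded mass is zero.
    """
    totals = table.cycle_totals.astype(float)
    if (totals <= 0).any():
        bad = int(np.argmin(totals))
        raise ValueError(f"cycle {bad} has zero total reads; cannot normalize")
    cpm = table.counts / totals * 1e6
    delta = np.diff(cpm, axis=1)
    fold = cpm[:, 1:] / np.maximum(cpm[:, :-1], PSEUDO_CPM)
    return EnrichmentProfile(
        sequences=list(table.sequences), cpm=cpm, delta=delta, fold=fold
    )


def delta_filter(
    profile: EnrichmentProfile,
    mode: str = "any_pair",
    pair: tuple[int, int] | None = None,
    threshold: float = 1.0,
    stringent: bool = False,
) -> np.ndarray:
    """Boolean mask of sequences showing positive enrichment.

    mode="any_pair": pass iff cpm[c+1] - cpm[c] > threshold for at least one
    consecutive cycle pair.  mode="specified_pair": evaluate only the given
    ``pair`` (i, j), i < j, as cpm[j] - cpm[i] > threshold.

    stringent=True replaces the additive test with a fold-change requirement
    of >= STRINGENT_FOLD between the cycles, with a pseudo-cpm floor of
    PSEUDO_CPM in the denominator for sequences absent earlier.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("any_pair", "specified_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "specified_pair":
        if pair is None:
            raise ValueError("specified_pair mode requires pair=(i, j)")
        i, j = pair
        if not (0 <= i < j < profile.n_cycles):
            raise ValueError(
                f"pair {pair} out of range for {profile.n_cycles} cycles"
            )
        if stringent:
            return profile.cpm[:, j] / np.maximum(profile.cpm[:, i], PSEUDO_CPM) >= STRINGENT_FOLD
        return profile.cpm[:, j] - profile.cpm[:, i] > threshold
    if stringent:
        return (profile.fold >= STRINGENT_FOLD).any(axis=1)
    return (profile.delta > threshold).any(axis=1)


def cycle_entropy(table: CountsTable, k: int = 100) -> CycleProfile:
    """Shannon entropy (bits) and top-k read share of each cycle's clone
    distribution (over the tabulated sequences)."""
    counts = table.counts
    colsums = counts.sum(axis=0).astype(float)
    n_cycles = counts.shape[1]
    entropy = np.zeros(n_cycles)
    share = np.zeros(n_cycles)
    for c in range(n_cycles):
        col = counts[:, c]
        total = colsums[c]
        if total <= 0:
            continue
        p = col[col > 0] / total
        entropy[c] = float(-(p * np.log2(p)).sum())
        top = np.sort(col)[::-1][:k]
        share[c] = float(top.sum() / total)
    return CycleProfile(entropy=entropy, top_k_share=share, k=k)


def find_breakpoint(cp: CycleProfile, saturation_epsilon: float = 0.1) -> int:
    """Earliest cycle at which enrichment information saturates.

    Returns the earliest cycle ``c >= 1`` whose top-k share gain over the
    previous cycle is below ``saturation_epsilon`` and whose preceding
    entropy drop (into cycle c-1, when defined) was the largest seen so far;
    if no cycle saturates, falls back to the cycle of maximal entropy drop.
    Ties break toward the earlier cycle.
    """
    n = cp.n_cycles
    if n < 2:
        raise ValueError("breakpoint needs at least 2 cycles")
    gains = np.diff(cp.top_k_share)  # gains[c-1] = share[c] - share[c-1]
    drops = -np.diff(cp.entropy)  # drops[c-1] = entropy[c-1] - entropy[c]
    for c in range(1, n):
        if gains[c - 1] < saturation_epsilon:
            if c == 1 or drops[c - 2] >= drops[: c - 1].max():
                cp.breakpoint_cycle = c
                return c
    fallback = int(np.argmax(drops)) + 1
    cp.breakpoint_cycle = fallback
    return fallback


def diagnostics_frame(table: CountsTable, cp: CycleProfile) -> pd.DataFrame:
    """Per-cycle diagnostics table (one row per cycle)."""
    return pd.DataFrame(
        {
            "cycle": np.arange(table.n_cycles),
            "total_reads": table.cycle_totals,
            "distinct_clones": (table.counts > 0).sum(axis=0),
            "entropy_bits": cp.entropy,
            "top_k_share": cp.top_k_share,
        }
    )
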