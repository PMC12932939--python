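"""Sliding-window ΔSNP-index scan, permutation null, and region calling.

The genome-wide significance threshold is the 95th percentile (by default)
of per-iteration maxima of |windowed ΔSNP index| under a no-QTL null.
Three null schemes are provided:

``genetic_null`` (default)
    Parametric null for a RIL pool-seq design: each iteration re-simulates
    near-homozygous RIL haplotypes along the observed marker map (Haldane
    distances, inbred-line recombination R = 2r/(1+2r)) for two bulks of
    ``bulk_size`` lines each, and resamples reads at each locus's observed
    depths. Because lines are exchangeable and the population is redrawn
    every iteration, two disjoint bulks of independently simulated lines
    are distributionally identical to bulks drawn from a larger simulated
    population. This scheme reproduces both the bulk-composition variance
    and the linkage-induced correlation of Δ across loci within a window,
    which per-locus resampling schemes cannot.
``label_swap``
    Per locus, swap the two bulks' depth pairs with probability 1/2
    (equivalently flip the sign of Δ).
``binomial_null``
    Per locus and pool, redraw tracked-allele reads as
    Binomial(observed depth, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMES = ("genetic_null", "label_swap", "binomial_null")


@dataclass
class NullDistribution:
    """Per-iteration genome-wide maxima of |windowed ΔSNP index|."""

    maxima: np.ndarray
    n_iterations: int
    scheme: str
    percentile: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=float)
        if len(self.maxima) != self.n_iterations:
            raise ValueError("maxima length does not match n_iterations")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    peak_delta: float
    n_loci: int
    member_windows: int


def _window_starts(length: int, window_bp: int, step_bp: int) -> np.ndarray:
    return np.arange(1, length + 1, step_bp, dtype=np.int64)


def window_scan(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_markers: int = 3,
) -> pd.DataFrame:
    """Mean ΔSNP index in sliding windows anchored at position 1.

    Windows advance by ``step_bp`` per chromosome; the terminal window is
    truncated at the chromosome end. A window with fewer than
    ``min_markers`` markers reports a missing mean. Returns a frame with
    columns chrom, start, end, mean_delta, n_markers.
    """
    if step_bp <= 0:
        raise ValueError(f"step_bp must be positive, got {step_bp}")
    if window_bp < step_bp:
        raise ValueError(f"window_bp ({window_bp}) must be >= step_bp ({step_bp})")
    frames = []
    for chrom, length in chrom_lengths.items():
        sub = records[records["chrom"] == chrom].sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        delta = sub["delta"].to_numpy(dtype=float)
        starts = _window_starts(length, window_bp, step_bp)
        ends = np.minimum(starts + window_bp - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        # direct slice means (not cumulative-sum differences) so the window
        # mean is bit-identical to averaging the member deltas
        mean = np.full(len(starts), np.nan)
        for w in np.flatnonzero(n >= max(min_markers, 1)):
            mean[w] = delta[lo[w] : hi[w]].mean()
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_delta": mean, "n_markers": n}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class _WindowPlan:
    """Precomputed window membership for repeated scans over fixed positions."""

    lo: np.ndarray
    hi: np.ndarray
    n: np.ndarray
    valid: np.ndarray
    order: np.ndarray  # permutation sorting records by (chrom, pos)

    @classmethod
    def build(cls, records, chrom_lengths, window_bp, step_bp, min_markers):
        order = np.lexsort((records["pos"].to_numpy(), records["chrom"].to_numpy()))
        chrom_sorted = records["chrom"].to_numpy()[order]
        pos_sorted = records["pos"].to_numpy(dtype=np.int64)[order]
        lo_all, hi_all = [], []
        for chrom, length in chrom_lengths.items():
            mask = chrom_sorted == chrom
            base = int(np.flatnonzero(mask)[0]) if mask.any() else 0
            pos = pos_sorted[mask]
            starts = _window_starts(length, window_bp, step_bp)
            ends = np.minimum(starts + window_bp - 1, length)
            lo_all.append(np.searchsorted(pos, starts, side="left") + base)
            hi_all.append(np.searchsorted(pos, ends, side="right") + base)
        lo = np.concatenate(lo_all)
        hi = np.concatenate(hi_all)
        n = hi - lo
        valid = n >= max(min_markers, 1)
        return cls(lo=lo, hi=hi, n=n, valid=valid, order=order)

    def max_abs_mean(self, deltas: np.ndarray) -> np.ndarray:
        """Genome-wide max |window mean| for each row of ``deltas``.

        ``deltas`` has shape (n_iterations, n_records) in the plan's sorted
        record order.
        """
        csum = np.concatenate(
            [np.zeros((deltas.shape[0], 1)), np.cumsum(deltas, axis=1)], axis=1
        )
        lo, hi, n = self.lo[self.valid], self.hi[self.valid], self.n[self.valid]
        means = (csum[:, hi] - csum[:, lo]) / n
        return np.abs(means).max(axis=1)


def _ril_switch_probs(
    chrom: np.ndarray, pos: np.ndarray, cm_per_mb: float
) -> np.ndarray:
    """Per-interval haplotype switch probability for an inbred (RIL) line.

    Adjacent-marker recombination r from the Haldane map function; the
    cumulative RIL recombination fraction after repeated selfing is
    R = 2r/(1+2r). Chromosome boundaries (and the first marker) switch with
    probability 1/2, i.e. an independent start.
    """
    d_morgan = np.diff(pos) * cm_per_mb / 1e6 / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    R = 2.0 * r / (1.0 + 2.0 * r)
    switch = np.concatenate([[0.5], R])
    new_chrom = np.concatenate([[True], chrom[1:] != chrom[:-1]])
    switch[new_chrom] = 0.5
    return switch


def permutation_null(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_iterations: int = 1_000,
    scheme: str = "genetic_null",
    seed: int = 0,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_markers: int = 3,
    bulk_size: int = 15,
    cm_per_mb: float = 3.0,
    error_rate: float = 0.001,
) -> NullDistribution:
    """Null distribution of the genome-wide max |windowed ΔSNP index|.

    Each iteration regenerates per-locus indices under ``scheme``, re-runs
    the window scan with identical parameters, and records the genome-wide
    maximum. Deterministic for a fixed seed. ``bulk_size``, ``cm_per_mb``
    and ``error_rate`` parameterize the ``genetic_null`` design and are
    ignored by the other schemes.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    plan = _WindowPlan.build(records, chrom_lengths, window_bp, step_bp, min_markers)
    if not plan.valid.any():
        raise ValueError("no window has enough markers; cannot build a null distribution")
    order = plan.order
    delta = records["delta"].to_numpy(dtype=float)[order]
    depth_h = records["depth_high"].to_numpy(dtype=np.int64)[order]
    depth_l = records["depth_low"].to_numpy(dtype=np.int64)[order]
    chrom_sorted = records["chrom"].to_numpy()[order]
    pos_sorted = records["pos"].to_numpy(dtype=np.int64)[order]
    m = len(delta)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_iterations)

    if scheme == "label_swap":
        chunk = max(1, min(n_iterations, 200))
        done = 0
        while done < n_iterations:
            k = min(chunk, n_iterations - done)
            signs = rng.integers(0, 2, size=(k, m)) * 2 - 1
            maxima[done : done + k] = plan.max_abs_mean(signs * delta)
            done += k
    elif scheme == "binomial_null":
        chunk = max(1, min(n_iterations, 200))
        done = 0
        while done < n_iterations:
            k = min(chunk, n_iterations - done)
            ih = rng.binomial(depth_h, 0.5, size=(k, m)) / depth_h
            il = rng.binomial(depth_l, 0.5, size=(k, m)) / depth_l
            maxima[done : done + k] = plan.max_abs_mean(ih - il)
            done += k
    else:  # genetic_null
        switch = _ril_switch_probs(chrom_sorted, pos_sorted, cm_per_mb)
        p_read = lambda f: f * (1 - error_rate) + (1 - f) * error_rate
        n_sim = 2 * bulk_size  # two disjoint bulks of iid simulated lines
        # chunk iterations to bound the (iter*lines, loci) haplotype array
        chunk = max(1, int(2e7 // max(n_sim * m, 1)))
        done = 0
        while done < n_iterations:
            k = min(chunk, n_iterations - done)
            flips = rng.random((k * n_sim, m)) < switch
            haps = np.logical_xor.accumulate(flips, axis=1).reshape(k, n_sim, m)
            f_h = haps[:, :bulk_size, :].mean(axis=1)
            f_l = haps[:, bulk_size:, :].mean(axis=1)
            ih = rng.binomial(depth_h, p_read(f_h)) / depth_h
            il = rng.binomial(depth_l, p_read(f_l)) / depth_l
            maxima[done : done + k] = plan.max_abs_mean(ih - il)
            done += k

    return NullDistribution(maxima=maxima, n_iterations=n_iterations, scheme=scheme)


def threshold_from_null(null: NullDistribution, percentile: float = 95.0) -> float:
    """Linear-interpolation percentile of the null maxima.

    Percentile 100 returns the largest maximum; values outside (0, 100]
    are rejected.
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    if len(null.maxima) == 0:
        raise ValueError("empty null distribution")
    threshold = float(np.percentile(null.maxima, percentile, method="linear"))
    null.percentile = percentile
    null.threshold = threshold
    return threshold


def call_regions(
    windows: pd.DataFrame,
    threshold: float,
    records: pd.DataFrame,
) -> list[CandidateRegion]:
    """Merge significant windows (|mean Δ| ≥ threshold) into candidate regions.

    Overlapping or book-ended significant windows merge; region bounds are
    the union extent, peak_delta the extremal windowed mean (sign kept),
    and n_loci the number of filtered markers inside the region.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sig = windows[windows["mean_delta"].abs() >= threshold].dropna(subset=["mean_delta"])
    regions: list[CandidateRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="stable")
        cur = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(row.end))
                cur["windows"] += 1
                if abs(row.mean_delta) > abs(cur["peak"]):
                    cur["peak"] = float(row.mean_delta)
            else:
                if cur is not None:
                    regions.append(_finalize_region(chrom, cur, records))
                cur = {
                    "start": int(row.start),
                    "end": int(row.end),
                    "peak": float(row.mean_delta),
                    "windows": 1,
                }
        if cur is not None:
            regions.append(_finalize_region(chrom, cur, records))
    return regions


def _finalize_region(chrom: str, cur: dict, records: pd.DataFrame) -> CandidateRegion:
    inside = records[
        (records["chrom"] == chrom)
        & (records["pos"] >= cur["start"])
        & (records["pos"] <= cur["end"])
    ]
    return CandidateRegion(
        chrom=chrom,
        start=cur["start"],
        end=cur["end"],
        peak_delta=cur["peak"],
        n_loci=int(len(inside)),
        member_windows=cur["windows"],
    )


def regions_to_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    """0-based half-open BED view of candidate regions."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [f"region_{i + 1}" for i in range(len(regions))],
            "score": [abs(r.peak_delta) for r in regions],
        }
    )
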