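"""Retention-time binning of chromatographic peaks by restarted 1-D k-means.

GC runs drift, so the same fatty acid elutes at slightly different retention
times in different samples. Peaks matched to known standards carry a label;
the remaining peaks are pooled across all samples and grouped into K bins by
Lloyd's k-means on the retention-time axis. Because random initialization can
stick in poor local optima, the clustering is restarted many times with
centroids drawn uniformly over the observed retention-time range, and the run
with the greatest variance explained (SS_between / SS_total) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "KMeansRun",
    "PeakAssignment",
    "DegenerateKError",
    "kmeans_1d",
    "assign_peaks",
    "read_peaks_csv",
    "write_peaks_csv",
]

_MAX_ITER = 300


class DegenerateKError(ValueError):
    """Raised when K exceeds the number of distinct values to cluster."""


@dataclass
class PeakTable:
    """One sample's integrated peaks: retention time (min) and area fraction.

    ``known_labels`` maps peak indices to bin labels for peaks identified
    against standards; those peaks are pinned, not clustered (by default).
    """

    sample_id: str
    retention_times: np.ndarray
    area_fractions: np.ndarray
    known_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rt = np.asarray(self.retention_times, dtype=float)
        af = np.asarray(self.area_fractions, dtype=float)
        if rt.shape != af.shape or rt.ndim != 1:
            raise ValueError("retention_times and area_fractions must be 1-D and equal length")
        if np.any(rt < 0):
            raise ValueError("retention times must be non-negative")
        if af.sum() > 1 + 1e-9 or np.any(af < 0):
            raise ValueError("area fractions must be non-negative and sum to at most 1")
        self.retention_times = rt
        self.area_fractions = af


@dataclass
class KMeansRun:
    """Result of one Lloyd run: centroids in ascending retention-time order."""

    centroids: np.ndarray
    assignment: np.ndarray  # peak -> cluster index
    variance_explained: float
    n_iter: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.variance_explained <= 1 + 1e-12:
            raise ValueError("variance explained must lie in [0, 1]")
        self.variance_explained = float(min(max(self.variance_explained, 0.0), 1.0))


@dataclass
class PeakAssignment:
    """Best-of-restarts clustering plus per-sample area-per-bin vectors."""

    best_run: KMeansRun
    sample_bins: pd.DataFrame  # rows = sample ids, columns = bin labels
    restart_count: int
    peak_bins: list[np.ndarray]  # per table: bin index of each peak (-1 = pinned)


def _assign_to_sorted(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment for ascending centroids.

    Midpoint ties go to the lower-index (lower retention time) centroid.
    """
    boundaries = 0.5 * (centroids[:-1] + centroids[1:])
    return np.searchsorted(boundaries, values, side="left")


def kmeans_1d(
    values: np.ndarray,
    k: int,
    init: np.ndarray,
    max_iter: int = _MAX_ITER,
    allow_empty: bool = False,
) -> KMeansRun:
    """Lloyd's k-means on a 1-D array with explicit initial centroids.

    Clusters are reported in ascending centroid order. Iteration stops when
    the assignment no longer changes or after ``max_iter`` sweeps. A cluster
    that loses all members is re-seeded at the point farthest from its
    nearest centroid, keeping K fixed. Variance explained is
    SS_between / SS_total about the grand mean; if all values coincide
    (SS_total = 0) the clustering is vacuous and VE is defined as 1.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values to cluster")
    if k < 1:
        raise ValueError("k must be at least 1")
    init = np.asarray(init, dtype=float).ravel()
    if init.size != k:
        raise ValueError(f"init has {init.size} centroids, expected k={k}")
    n_distinct = np.unique(values).size
    if k > n_distinct and not allow_empty:
        raise DegenerateKError(
            f"k={k} exceeds the {n_distinct} distinct values; "
            "set allow_empty=True to permit empty clusters"
        )

    order = np.argsort(values, kind="stable")
    sv = values[order]
    sumsq = float(np.sum(sv**2))
    grand = float(sv.mean())
    ss_total = sumsq - sv.size * grand**2

    centroids = np.sort(init)
    assignment = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_assign = _assign_to_sorted(sv, centroids)
        counts = np.bincount(new_assign, minlength=k)
        # re-seed empty clusters at the point farthest from its nearest centroid
        guard = 0
        while np.any(counts == 0) and guard < 4 * k:
            guard += 1
            empty = int(np.flatnonzero(counts == 0)[0])
            dists = np.abs(sv - centroids[new_assign])
            far = int(np.argmax(dists))
            centroids = np.sort(np.concatenate(
                [np.delete(centroids, empty), [sv[far]]]
            ))
            new_assign = _assign_to_sorted(sv, centroids)
            counts = np.bincount(new_assign, minlength=k)
        if assignment is not None and np.array_equal(new_assign, assignment):
            break
        assignment = new_assign
        sums = np.bincount(assignment, weights=sv, minlength=k)
        nonzero = counts > 0
        centroids = centroids.copy()
        centroids[nonzero] = sums[nonzero] / counts[nonzero]
        centroids = np.sort(centroids)

    counts = np.bincount(assignment, minlength=k)
    sums = np.bincount(assignment, weights=sv, minlength=k)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), centroids)
    ss_within = sumsq - float(np.sum(counts * means**2))
    ve = 1.0 if ss_total <= 1e-300 else 1.0 - ss_within / ss_total

    # map assignment back to the original value order
    assignment_orig = np.empty_like(assignment)
    assignment_orig[order] = assignment
    return KMeansRun(
        centroids=means,
        assignment=assignment_orig,
        variance_explained=ve,
        n_iter=n_iter,
    )


def assign_peaks(
    tables: list[PeakTable],
    k: int = 60,
    restarts: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    cluster_all: bool = False,
    allow_empty: bool = False,
) -> PeakAssignment:
    """Bin unknown peaks from all samples jointly by best-of-restarts k-means.

    Retention times are pooled over samples (clustering per sample would lose
    the cross-run correspondence the binning exists to establish). Each
    restart draws K initial centroids uniformly on [min RT, max RT] of the
    pooled unknown peaks; the run with maximal variance explained wins (ties:
    first reached). Cluster indices are reported in ascending centroid
    retention time as ``bin_00`` ... Peaks with known labels are pinned to
    their labels and excluded from clustering unless ``cluster_all``.

    Reproducible bit-for-bit given (seed, restarts); the first n restart
    streams coincide for any two calls sharing a seed, so best-of-n VE is
    non-decreasing in n.
    """
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    pooled = []
    pooled_where: list[tuple[int, int]] = []  # (table index, peak index)
    for ti, t in enumerate(tables):
        for pi, rt in enumerate(t.retention_times):
            if cluster_all or pi not in t.known_labels:
                pooled.append(rt)
                pooled_where.append((ti, pi))
    pooled = np.asarray(pooled, dtype=float)
    if pooled.size == 0:
        raise ValueError("no unknown peaks to cluster")

    lo, hi = float(pooled.min()), float(pooled.max())
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(restarts)
    best: KMeansRun | None = None
    for child in children:
        rng = np.random.default_rng(child)
        init = rng.uniform(lo, hi, size=k)
        run = kmeans_1d(pooled, k, init, allow_empty=allow_empty)
        if best is None or run.variance_explained > best.variance_explained:
            best = run

    bin_labels = [f"bin_{i:02d}" for i in range(k)]
    known_set = sorted(
        {lab for t in tables for lab in t.known_labels.values()}
    )
    columns = known_set + bin_labels
    col_pos = {c: j for j, c in enumerate(columns)}

    peak_bins = [np.full(t.retention_times.size, -1, dtype=int) for t in tables]
    for (ti, pi), cluster in zip(pooled_where, best.assignment):
        peak_bins[ti][pi] = cluster

    areas = np.zeros((len(tables), len(columns)))
    for ti, t in enumerate(tables):
        for pi in range(t.retention_times.size):
            if not cluster_all and pi in t.known_labels:
                areas[ti, col_pos[t.known_labels[pi]]] += t.area_fractions[pi]
            else:
                areas[ti, col_pos[bin_labels[peak_bins[ti][pi]]]] += t.area_fractions[pi]

    sample_bins = pd.DataFrame(
        areas, index=[t.sample_id for t in tables], columns=columns
    )
    return PeakAssignment(
        best_run=best,
        sample_bins=sample_bins,
        restart_count=restarts,
        peak_bins=peak_bins,
    )


def write_peaks_csv(tables: list[PeakTable], path) -> None:
    """Peak CSV: sample_id, retention_time_min, area_fraction, known_label."""
    rows = []
    for t in tables:
        for pi in range(t.retention_times.size):
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "retention_time_min": t.retention_times[pi],
                    "area_fraction": t.area_fractions[pi],
                    "known_label": t.known_labels.get(pi, ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_peaks_csv(path) -> list[PeakTable]:
    df = pd.read_csv(path, dtype={"sample_id": str, "known_label": str})
    required = {"sample_id", "retention_time_min", "area_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV missing columns: {sorted(missing)}")
    tables = []
    for sid, sub in df.groupby("sample_id", sort=False):
        sub = sub.reset_index(drop=True)
        known = {
            i: lab
            for i, lab in enumerate(sub.get("known_label", pd.Series(dtype=str)))
            if isinstance(lab, str) and lab.strip()
        }
        tables.append(
            PeakTable(
                sample_id=str(sid),
                retention_times=sub["retention_time_min"].to_numpy(float),
                area_fractions=sub["area_fraction"].to_numpy(float),
                known_labels=known,
            )
        )
    return tables
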