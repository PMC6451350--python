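"""Threshold-crossing order of per-embryo transcript trajectories.

The RNA-seq side of the analysis: each gene has a smoothed
transcripts-per-embryo trajectory with a 95% confidence band, and genes
are ordered by when the mean curve first reaches a fixed per-embryo count
(by convention 200,000 / 100,000 / 50,000 / 10,000). Genes whose crossing
times fall within a simultaneity window (default 30 min) are grouped as
temporally indistinguishable; band overlap at the crossing times annotates
how confident each adjacent ordering is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTrajectory",
    "CrossingOrder",
    "crossing_time",
    "first_crossing",
    "order_by_crossing",
    "crossing_table",
    "crossing_frame",
    "read_trajectories",
]

DEFAULT_THRESHOLDS = (200_000.0, 100_000.0, 50_000.0, 10_000.0)


@dataclass(frozen=True)
class CountTrajectory:
    """One gene's transcripts-per-embryo curve with a pointwise 95% band."""

    gene_id: str
    hpf: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def __post_init__(self) -> None:
        hpf = np.asarray(self.hpf, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        lo = np.asarray(self.lo95, dtype=float)
        hi = np.asarray(self.hi95, dtype=float)
        if hpf.size == 0:
            raise ValueError("empty trajectory")
        if not (hpf.size == mean.size == lo.size == hi.size):
            raise ValueError("hpf, mean, lo95, hi95 must have equal length")
        if np.any(np.diff(hpf) < 0):
            raise ValueError("time grid must be sorted")
        tol = 1e-9 * np.maximum(1.0, np.abs(mean))
        if np.any(lo > mean + tol) or np.any(mean > hi + tol):
            raise ValueError("band must satisfy lo95 <= mean <= hi95 pointwise")
        object.__setattr__(self, "hpf", hpf)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "lo95", lo)
        object.__setattr__(self, "hi95", hi)

    def band_at(self, t: float) -> tuple[float, float]:
        return (
            float(np.interp(t, self.hpf, self.lo95)),
            float(np.interp(t, self.hpf, self.hi95)),
        )


def crossing_time(times: np.ndarray, values: np.ndarray, threshold: float) -> float | None:
    """Earliest linearly interpolated time ``values`` reaches ``threshold``.

    Returns None if the threshold is never reached on the grid.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty trajectory")
    above = values >= threshold
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    v0, v1 = values[k - 1], values[k]
    if v1 == v0:  # vertical-in-value degenerate; threshold met exactly at k
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))


def first_crossing(traj: CountTrajectory, threshold: float) -> float | None:
    """First time the mean trajectory reaches ``threshold`` (None if never)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return crossing_time(traj.hpf, traj.mean, threshold)


@dataclass(frozen=True)
class CrossingOrder:
    """Genes ranked by first crossing of one threshold.

    ``groups`` partitions the ranked genes into simultaneity groups; genes
    that never reach the threshold form a final group of their own.
    ``ci_overlap`` maps each adjacent ranked pair to whether the two 95%
    bands overlap at both crossing times (None if either gene never crosses).
    """

    threshold: float
    crossing_hpf: dict
    order: tuple
    groups: tuple
    ci_overlap: dict


def _bands_overlap(a: CountTrajectory, b: CountTrajectory, t: float) -> bool:
    lo_a, hi_a = a.band_at(t)
    lo_b, hi_b = b.band_at(t)
    return lo_a <= hi_b and lo_b <= hi_a


def order_by_crossing(
    trajs: Sequence[CountTrajectory],
    threshold: float,
    window_h: float = 0.5,
    linkage: str = "single",
) -> CrossingOrder:
    """Rank genes by first crossing and group near-simultaneous ones.

    Grouping is single-linkage by default: consecutive ranked genes whose
    crossing times differ by at most ``window_h`` chain into one group, so a
    chained group can span more than ``window_h`` end to end.
    ``linkage='complete'`` instead closes a group as soon as its total span
    would exceed the window. Ties in crossing time break by gene_id, so the
    output is independent of input order.
    """
    if len(trajs) < 2:
        raise ValueError("need >= 2 trajectories")
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    by_gene = {t.gene_id: t for t in trajs}
    if len(by_gene) != len(trajs):
        raise ValueError("duplicate gene_id among trajectories")
    crossing = {g: first_crossing(t, threshold) for g, t in by_gene.items()}
    order = sorted(by_gene, key=lambda g: (crossing[g] is None, crossing[g] if crossing[g] is not None else 0.0, g))

    groups: list[list[str]] = []
    anchor: float | None = None
    prev: float | None = None
    for g in order:
        c = crossing[g]
        if c is None:
            if groups and crossing[groups[-1][0]] is None:
                groups[-1].append(g)
            else:
                groups.append([g])
            continue
        ref = prev if linkage == "single" else anchor
        if groups and ref is not None and (c - ref) <= window_h and crossing[groups[-1][0]] is not None:
            groups[-1].append(g)
        else:
            groups.append([g])
            anchor = c
        prev = c

    ci_overlap: dict = {}
    for a, b in zip(order, order[1:]):
        ca, cb = crossing[a], crossing[b]
        if ca is None or cb is None:
            ci_overlap[(a, b)] = None
        else:
            ci_overlap[(a, b)] = bool(
                _bands_overlap(by_gene[a], by_gene[b], ca)
                and _bands_overlap(by_gene[a], by_gene[b], cb)
            )
    return CrossingOrder(
        threshold=float(threshold),
        crossing_hpf=crossing,
        order=tuple(order),
        groups=tuple(tuple(g) for g in groups),
        ci_overlap=ci_overlap,
    )


def crossing_table(
    trajs: Sequence[CountTrajectory],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    window_h: float = 0.5,
    linkage: str = "single",
) -> dict[float, CrossingOrder]:
    """One CrossingOrder per threshold (conventionally sorted descending)."""
    return {
        float(th): order_by_crossing(trajs, th, window_h=window_h, linkage=linkage)
        for th in thresholds
    }


def crossing_frame(table: dict[float, CrossingOrder]) -> pd.DataFrame:
    """Tidy report: one row per (threshold, rank) with crossing time and group."""
    rows = []
    for th, co in table.items():
        group_of = {g: gi for gi, grp in enumerate(co.groups, start=1) for g in grp}
        for rank, g in enumerate(co.order, start=1):
            rows.append(
                {
                    "threshold": th,
                    "rank": rank,
                    "gene_id": g,
                    "crossing_hpf": co.crossing_hpf[g],
                    "group": group_of[g],
                }
            )
    return pd.DataFrame(rows)


def read_trajectories(path: str | Path) -> list[CountTrajectory]:
    """Read a trajectory CSV (gene_id, hpf, mean, lo95, hi95)."""
    df = pd.read_csv(path)
    out = []
    for gene, grp in df.groupby("gene_id", sort=True):
        grp = grp.sort_values("hpf")
        out.append(
            CountTrajectory(
                gene_id=str(gene),
                hpf=grp["hpf"].to_numpy(float),
                mean=grp["mean"].to_numpy(float),
                lo95=grp["lo95"].to_numpy(float),
                hi95=grp["hi95"].to_numpy(float),
            )
        )
    return out
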