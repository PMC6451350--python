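"""Onset-of-transcription estimators.

Three estimators, all driven by the qPCR statistics:

* **qpcr_detection** — the earliest sampled time at which RT+ copy numbers
  significantly exceed the RT- background.
* **extrapolated** — find the earliest significant rise in background-
  subtracted de novo copy numbers between two sampling points, draw the
  line through those two points and take its x-axis intercept; the onset of
  active transcription can thus fall before the first time point of the
  rise.
* **midpoint** — the midpoint of the same rise interval, on the reasoning
  that activation lies after the last time without a significant increase
  and before the time at which one is seen.

The rise interval normally joins two consecutive sampling points. When no
adjacent pair within the earliest rise is itself significant but a wider
pair is (a gradual riser), the wider pair is used ("bridged"): the
extrapolation then fits an ordinary least-squares line through all points
of the span, and the midpoint uses the span's endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .qpcr import DetectionCall, TukeyKramerResult, background_subtract, detection_calls, tukey_kramer

__all__ = [
    "OnsetEstimate",
    "RiseInterval",
    "onset_by_detection",
    "find_rise_interval",
    "onset_extrapolated",
    "onset_midpoint",
    "estimate_onsets",
    "METHODS",
]

METHODS = ("qpcr_detection", "extrapolated", "midpoint")
MBT_HPF = 4.0


@dataclass(frozen=True)
class OnsetEstimate:
    """One gene's onset under one method.

    ``onset_hpf`` is None when the method finds no onset (flag ``no_onset``).
    ``t_lo``/``t_hi`` bracket the supporting sampling interval. Flags:
    ``pre_mbt`` (onset before the midblastula transition), ``clamped``
    (negative extrapolation clamped to 0), ``bridged`` (non-adjacent rise
    interval), ``boundary`` (detection at the first sampled time),
    ``early_extrapolation`` (intercept before the sample preceding the rise).
    """

    method: str
    onset_hpf: float | None
    t_lo: float | None = None
    t_hi: float | None = None
    gene_id: str | None = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.onset_hpf is not None and self.onset_hpf < 0:
            raise ValueError("onset_hpf must be >= 0")


class RiseInterval(NamedTuple):
    """Indices (into the usable time points) of the earliest significant rise."""

    i: int
    j: int
    bridged: bool


def onset_by_detection(
    calls: Sequence[DetectionCall],
    mbt_hpf: float = MBT_HPF,
    gene_id: str | None = None,
) -> OnsetEstimate:
    """Earliest sampled time with a significant RT+ vs RT- difference."""
    calls = sorted((c for c in calls if c.hpf is not None), key=lambda c: c.hpf)
    if not calls:
        raise ValueError("no detection calls given")
    flags = set()
    hits = [c for c in calls if c.significant]
    if not hits:
        return OnsetEstimate(
            method="qpcr_detection", onset_hpf=None, gene_id=gene_id, flags=frozenset({"no_onset"})
        )
    onset = float(hits[0].hpf)
    times = [c.hpf for c in calls]
    k = times.index(hits[0].hpf)
    if onset < mbt_hpf:
        flags.add("pre_mbt")
    if k == 0:
        flags.add("boundary")
    t_lo = times[k - 1] if k > 0 else onset
    return OnsetEstimate(
        method="qpcr_detection", onset_hpf=onset, t_lo=float(t_lo), t_hi=onset,
        gene_id=gene_id, flags=frozenset(flags),
    )


def find_rise_interval(
    pairwise: TukeyKramerResult,
    times: Sequence[float] | None = None,
) -> RiseInterval | None:
    """Locate the earliest significant increase in de novo copy numbers.

    Among all significant pairs (i, j) with a mean increase, the earliest
    rise is the one ending soonest (smallest j): the first time the
    transcript number is demonstrably above an earlier level. If the
    adjacent pair (j-1, j) is itself significant the interval is that
    consecutive pair; otherwise the interval bridges from the latest
    earlier point i that is significantly below j (the last time still at
    the pre-rise level), flagged ``bridged``. Returns None when no
    significant increase exists.
    """
    if times is None:
        times = [float(lbl) for lbl in pairwise.labels]
    times = np.asarray(times, dtype=float)
    if times.size != len(pairwise.labels):
        raise ValueError("times must match the Tukey-Kramer group labels")
    means = pairwise.means
    k = times.size
    rising = [
        (i, j)
        for j in range(1, k)
        for i in range(j)
        if pairwise.significant[i, j] and means[j] > means[i]
    ]
    if not rising:
        return None
    j_star = min(j for _, j in rising)
    if (j_star - 1, j_star) in rising:
        return RiseInterval(j_star - 1, j_star, bridged=False)
    i_star = max(i for i, j in rising if j == j_star)
    return RiseInterval(i_star, j_star, bridged=True)


def onset_extrapolated(
    times: Sequence[float],
    means: Sequence[float],
    interval: RiseInterval,
    gene_id: str | None = None,
) -> OnsetEstimate:
    """X-axis intercept of the line through the rise interval.

    Consecutive interval: the line joining the two points. Bridged
    interval: an OLS regression line through all points of the span.
    Intercepts before 0 hpf clamp to 0 (flag ``clamped``); intercepts
    before the sampling point preceding the interval are reported raw with
    an ``early_extrapolation`` flag and a warning.
    """
    times = np.asarray(times, dtype=float)
    means = np.asarray(means, dtype=float)
    i, j = interval.i, interval.j
    if not means[j] > means[i]:
        raise ValueError("rise interval is invalid: mean does not increase")
    flags = set()
    if interval.bridged:
        flags.add("bridged")
        span_t = times[i : j + 1]
        span_y = means[i : j + 1]
        slope, intercept_y = np.polyfit(span_t, span_y, 1)
        if slope <= 0:
            raise ValueError("bridged rise interval has non-positive OLS slope")
        onset = -intercept_y / slope
    else:
        slope = (means[j] - means[i]) / (times[j] - times[i])
        onset = times[i] - means[i] / slope
    if onset < 0:
        onset = 0.0
        flags.add("clamped")
    if i > 0 and onset < times[i - 1]:
        warnings.warn(
            f"extrapolated onset {onset:.2f} hpf precedes the sampling point "
            f"before the rise interval ({times[i - 1]:g} hpf)"
        )
        flags.add("early_extrapolation")
    return OnsetEstimate(
        method="extrapolated", onset_hpf=float(onset),
        t_lo=float(times[i]), t_hi=float(times[j]),
        gene_id=gene_id, flags=frozenset(flags),
    )


def onset_midpoint(
    t_lo: float,
    t_hi: float,
    bridged: bool = False,
    gene_id: str | None = None,
) -> OnsetEstimate:
    """Midpoint of the rise interval; bridged intervals use their endpoints."""
    if not t_lo < t_hi:
        raise ValueError("interval must satisfy t_lo < t_hi")
    flags = frozenset({"bridged"}) if bridged else frozenset()
    return OnsetEstimate(
        method="midpoint", onset_hpf=(t_lo + t_hi) / 2.0,
        t_lo=float(t_lo), t_hi=float(t_hi), gene_id=gene_id, flags=flags,
    )


def _no_onset(method: str, gene_id: str | None) -> OnsetEstimate:
    return OnsetEstimate(method=method, onset_hpf=None, gene_id=gene_id, flags=frozenset({"no_onset"}))


def estimate_onsets(
    copies: pd.DataFrame,
    alpha: float = 0.05,
    mbt_hpf: float = MBT_HPF,
    alternative: str = "greater",
    methods: Sequence[str] = METHODS,
    compute_pvalues: bool = False,
) -> pd.DataFrame:
    """Run the requested onset estimators for every gene in a copy table.

    ``copies`` is a quantified plate (see ``qpcr.plate_to_copies``). Returns
    a tidy table (gene_id, method, onset_hpf, t_lo, t_hi, flags) mirroring
    the three-estimates-per-gene summary layout.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    estimates: list[OnsetEstimate] = []
    for gene, gene_copies in copies.groupby("gene_id", sort=True):
        if "qpcr_detection" in methods:
            calls = detection_calls(gene_copies, alpha=alpha, alternative=alternative)
            estimates.append(onset_by_detection(calls, mbt_hpf=mbt_hpf, gene_id=gene))
        if "extrapolated" in methods or "midpoint" in methods:
            denovo = background_subtract(gene_copies)
            groups = {
                float(h): grp["denovo"].to_numpy(float)
                for h, grp in denovo.groupby("hpf", sort=True)
            }
            usable = {h: v for h, v in groups.items() if v.size >= 2}
            interval = None
            if len(usable) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tk = tukey_kramer(usable, alpha=alpha, compute_pvalues=compute_pvalues)
                interval = find_rise_interval(tk)
            if interval is None:
                for m in ("extrapolated", "midpoint"):
                    if m in methods:
                        estimates.append(_no_onset(m, gene))
            else:
                t = np.array([float(lbl) for lbl in tk.labels])
                if "extrapolated" in methods:
                    estimates.append(onset_extrapolated(t, tk.means, interval, gene_id=gene))
                if "midpoint" in methods:
                    estimates.append(
                        onset_midpoint(
                            t[interval.i], t[interval.j], bridged=interval.bridged, gene_id=gene
                        )
                    )
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "method": e.method,
                "onset_hpf": e.onset_hpf,
                "t_lo": e.t_lo,
                "t_hi": e.t_hi,
                "flags": ";".join(sorted(e.flags)),
            }
            for e in estimates
        ]
    )
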