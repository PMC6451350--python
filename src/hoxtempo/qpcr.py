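"""Absolute qPCR quantitation and RT+/RT- de novo detection.

Cq values are converted to copies per reaction through a log-linear
standard curve fitted to a dilution series, and a gene is called "de novo
detected" at a time point when its RT+ copy numbers exceed the RT-
(no-reverse-transcriptase) background: an F-test first decides whether the
pooled or the Welch t-test applies, then a one-sided t-test (RT+ > RT-)
is run at alpha. Copy values are trusted only inside the calibrated
dilution range; a censored reaction (no amplification by the cycle limit)
counts as zero copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CopyEstimate",
    "DetectionCall",
    "TukeyKramerResult",
    "fit_standard_curve",
    "quantify_copies",
    "plate_to_copies",
    "compare_rt",
    "detection_calls",
    "background_subtract",
    "tukey_kramer",
]


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear Cq-vs-copies calibration.

    Cq = intercept + slope * log10(copies); slope is negative (more template,
    fewer cycles). The validity range [copies_min, copies_max] is the span of
    template amounts actually used for the dilution series — quantities
    outside it are never extrapolated.
    """

    slope: float
    intercept: float
    r_squared: float
    copies_min: float
    copies_max: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative (Cq falls as copies rise)")
        if not self.copies_min < self.copies_max:
            raise ValueError("copies_min must be < copies_max")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10**(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq_of(self, copies: float) -> float:
        return self.intercept + self.slope * np.log10(copies)


class CopyEstimate(NamedTuple):
    """A single back-calculated copy number with its validity status."""

    copies: float
    status: str  # 'ok' | 'censored' | 'below_range' | 'above_range'

    @property
    def usable(self) -> bool:
        """Whether the value enters downstream statistics (in-range or zero-by-censoring)."""
        return self.status in ("ok", "censored")


@dataclass(frozen=True)
class DetectionCall:
    """Outcome of one RT+ vs RT- comparison."""

    significant: bool
    p_value: float
    test_used: str  # 'pooled_t' | 'welch_t' | 'degenerate' | 'none'
    gene_id: str | None = None
    hpf: float | None = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def fit_standard_curve(dilutions) -> StandardCurve:
    """Ordinary least squares of Cq on log10(known copies).

    ``dilutions`` is a DataFrame with columns ``copies`` and ``cq`` or a
    sequence of (copies, cq) pairs. At least three distinct dilution levels
    spanning at least two orders of magnitude are required; a positive
    fitted slope signals swapped axes and is rejected.
    """
    if isinstance(dilutions, pd.DataFrame):
        copies = np.asarray(dilutions["copies"], dtype=float)
        cq = np.asarray(dilutions["cq"], dtype=float)
    else:
        arr = np.asarray(list(dilutions), dtype=float)
        copies, cq = arr[:, 0], arr[:, 1]
    if np.any(copies <= 0):
        raise ValueError("template amounts must be positive")
    levels = np.unique(copies)
    if levels.size < 3:
        raise ValueError(f"need >= 3 distinct dilution levels, got {levels.size}")
    if np.log10(levels.max() / levels.min()) < 2.0:
        raise ValueError("dilution series must span >= 2 orders of magnitude")
    fit = stats.linregress(np.log10(copies), cq)
    if fit.slope >= 0:
        raise ValueError("fitted slope is positive; check for swapped copies/Cq columns")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        copies_min=float(levels.min()),
        copies_max=float(levels.max()),
    )


def quantify_copies(cq: float, curve: StandardCurve, censored: bool = False) -> CopyEstimate:
    """Back-calculate copies/reaction from one Cq value.

    Out-of-range values are returned with a marker, not an error: the range
    rule ("only data that fit the dilution curve") is applied downstream by
    excluding them. A censored Cq maps to zero copies.
    """
    if censored or (cq is None) or np.isnan(cq):
        return CopyEstimate(0.0, "censored")
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    if copies < curve.copies_min:
        return CopyEstimate(copies, "below_range")
    if copies > curve.copies_max:
        return CopyEstimate(copies, "above_range")
    return CopyEstimate(copies, "ok")


def plate_to_copies(plate: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Convert a plate of replicate Cq values to copy numbers.

    Input columns: gene_id, hpf, rt, replicate, cq, censored (stage is
    carried through if present). Output adds ``copies`` and ``status``.
    """
    est = [
        quantify_copies(row.cq, curve, censored=bool(row.censored))
        for row in plate.itertuples()
    ]
    out = plate.copy()
    out["copies"] = [e.copies for e in est]
    out["status"] = [e.status for e in est]
    return out


def _usable(values: pd.DataFrame) -> np.ndarray:
    """Replicate copy values entering statistics: in-range plus censored-as-zero."""
    keep = values["status"].isin(["ok", "censored"])
    return np.asarray(values.loc[keep, "copies"], dtype=float)


def compare_rt(
    plus: Sequence[float],
    minus: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "greater",
    f_alpha: float | None = None,
    gene_id: str | None = None,
    hpf: float | None = None,
) -> DetectionCall:
    """Test whether RT+ copy numbers exceed the RT- background.

    A two-sided F-test of variance equality (at ``f_alpha``, default =
    ``alpha``) chooses between the pooled and the Welch two-sample t-test;
    the t-test is one-sided (RT+ > RT-) by default, since contamination
    cannot make RT+ fall below RT- in expectation. Pass
    ``alternative='two-sided'`` for the symmetric variant.
    """
    plus = np.asarray(plus, dtype=float)
    minus = np.asarray(minus, dtype=float)
    f_alpha = alpha if f_alpha is None else f_alpha
    flags = set()
    if plus.size < 2 or minus.size < 2:
        return DetectionCall(
            significant=False, p_value=np.nan, test_used="none",
            gene_id=gene_id, hpf=hpf, flags=frozenset({"insufficient_replicates"}),
        )
    if np.all(plus == 0):
        flags.add("rt_plus_all_censored")
        return DetectionCall(
            significant=False, p_value=np.nan, test_used="none",
            gene_id=gene_id, hpf=hpf, flags=frozenset(flags),
        )
    v_plus, v_minus = plus.var(ddof=1), minus.var(ddof=1)
    if v_plus == 0 and v_minus == 0:
        # no dispersion on either side: a strict mean difference is all there is
        diff = plus.mean() > minus.mean() if alternative == "greater" else plus.mean() != minus.mean()
        return DetectionCall(
            significant=bool(diff), p_value=0.0 if diff else 1.0, test_used="degenerate",
            gene_id=gene_id, hpf=hpf, flags=frozenset(flags | {"zero_variance"}),
        )
    if v_plus > 0 and v_minus > 0:
        f_stat = v_plus / v_minus
        p_f = 2.0 * min(
            stats.f.sf(f_stat, plus.size - 1, minus.size - 1),
            stats.f.cdf(f_stat, plus.size - 1, minus.size - 1),
        )
        equal_var = p_f > f_alpha
    else:
        equal_var = False  # one side degenerate: Welch is the safe branch
        flags.add("zero_variance")
    res = stats.ttest_ind(plus, minus, equal_var=equal_var, alternative=alternative)
    p = float(res.pvalue)
    return DetectionCall(
        significant=bool(p < alpha),
        p_value=p,
        test_used="pooled_t" if equal_var else "welch_t",
        gene_id=gene_id,
        hpf=hpf,
        flags=frozenset(flags),
    )


def detection_calls(
    copies: pd.DataFrame,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> list[DetectionCall]:
    """Per (gene, hpf) RT+ vs RT- detection calls from a copy-number table."""
    calls = []
    for (gene, hpf), cell in copies.groupby(["gene_id", "hpf"], sort=True):
        plus = _usable(cell[cell["rt"] == "plus"])
        minus = _usable(cell[cell["rt"] == "minus"])
        calls.append(
            compare_rt(plus, minus, alpha=alpha, alternative=alternative, gene_id=gene, hpf=float(hpf))
        )
    return calls


def background_subtract(copies: pd.DataFrame) -> pd.DataFrame:
    """Per-time de novo copy estimates: each RT+ replicate minus the RT- mean.

    The RT- mean is a plate-level background estimate (replicates are not
    paired), so subtracting it preserves RT+ replicate dispersion. Negative
    differences are clamped to zero and flagged. A time point with RT+ data
    but no RT- cell is an error naming the gene and time.
    """
    rows = []
    for (gene, hpf), cell in copies.groupby(["gene_id", "hpf"], sort=True):
        plus_cell = cell[cell["rt"] == "plus"]
        minus_cell = cell[cell["rt"] == "minus"]
        if plus_cell.empty:
            continue
        if minus_cell.empty:
            raise ValueError(f"no RT- measurements for gene {gene!r} at {hpf} hpf")
        minus_vals = _usable(minus_cell)
        background = float(minus_vals.mean()) if minus_vals.size else 0.0
        plus_keep = plus_cell[plus_cell["status"].isin(["ok", "censored"])]
        for row in plus_keep.itertuples():
            denovo = row.copies - background
            rows.append(
                {
                    "gene_id": gene,
                    "hpf": float(hpf),
                    "replicate": row.replicate,
                    "denovo": max(denovo, 0.0),
                    "clamped": denovo < 0,
                }
            )
    return pd.DataFrame(rows)


@lru_cache(maxsize=128)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


@dataclass(frozen=True)
class TukeyKramerResult:
    """All-pairs comparison of per-time-point groups."""

    labels: tuple  # group labels (e.g. hpf values), in input order
    means: np.ndarray
    n: np.ndarray
    significant: np.ndarray  # symmetric boolean matrix
    q_critical: float
    alpha: float
    p_values: np.ndarray | None = None  # symmetric, None if not computed

    def pair(self, a, b) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.significant[i, j])


def tukey_kramer(
    groups: Mapping | Sequence[Sequence[float]],
    alpha: float = 0.05,
    compute_pvalues: bool = True,
) -> TukeyKramerResult:
    """Tukey-Kramer all-pairs comparison with unequal group sizes.

    The studentized-range statistic for pair (i, j) is
    |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) with the pooled
    within-group MSE; significance compares it against the 1-alpha
    studentized-range quantile for k groups and N-k error df. Groups with
    fewer than two replicates are excluded with a warning.
    """
    if isinstance(groups, Mapping):
        items = list(groups.items())
    else:
        items = list(enumerate(groups))
    kept = []
    for label, vals in items:
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {label!r} has < 2 replicates; excluded from Tukey-Kramer")
            continue
        kept.append((label, vals))
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates")
    labels = tuple(lbl for lbl, _ in kept)
    means = np.array([v.mean() for _, v in kept])
    n = np.array([v.size for _, v in kept])
    k = len(kept)
    df = int(n.sum() - k)
    sse = sum(((v - v.mean()) ** 2).sum() for _, v in kept)
    mse = sse / df

    diff = np.abs(means[:, None] - means[None, :])
    se = np.sqrt(mse / 2.0 * (1.0 / n[:, None] + 1.0 / n[None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q_obs = np.where(diff == 0, 0.0, np.where(se > 0, diff / se, np.inf))
    q_crit = _q_crit(alpha, k, df)
    significant = q_obs > q_crit
    np.fill_diagonal(significant, False)
    p = None
    if compute_pvalues:
        p = np.ones((k, k))
        finite = np.isfinite(q_obs) & (q_obs > 0)
        if finite.any():
            p[finite] = stats.studentized_range.sf(q_obs[finite], k, df)
        p[np.isinf(q_obs)] = 0.0
        np.fill_diagonal(p, 1.0)
    return TukeyKramerResult(
        labels=labels, means=means, n=n, significant=significant,
        q_critical=q_crit, alpha=alpha, p_values=p,
    )
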