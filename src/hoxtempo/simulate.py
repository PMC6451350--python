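"""Synthetic embryo time courses, qPCR plates and transcript trajectories.

The generator emulates the data-generating process the downstream analysis
assumes for a Xenopus tropicalis whole-embryo time course:

* maternal mRNA deposited at fertilization decays exponentially;
* zygotic transcription of a gene starts at its onset time, but never
  before the midblastula transition (MBT, ~4 hpf at 23 C), and then
  synthesizes pre-mRNA at a constant per-embryo rate;
* pre-mRNA is converted to mature mRNA by first-order splicing, so the
  nascent pool is a small, early-saturating fraction of the mature pool;
* qPCR measures copies per reaction through a log-linear standard curve
  with Gaussian replicate noise on Cq, Poisson genomic-DNA contamination
  (the RT- background), and censoring at the cycle limit.

All stochastic operations take explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import SAMPLING_HPF, StageTimeTable, default_stage_table
from .qpcr import StandardCurve
from .trajectories import CountTrajectory, crossing_time

__all__ = [
    "TranscriptionParams",
    "QpcrNoiseModel",
    "TissueMixture",
    "Timecourse",
    "simulate_timecourse",
    "simulate_qpcr_plate",
    "simulate_trajectory",
    "simulate_whole_embryo",
    "default_standard_curve",
    "simulate_dilution_series",
    "make_collinear_panel",
    "make_demo_dataset",
    "EMBRYO_FRACTION_PER_REACTION",
]

#: Fraction of one embryo's transcripts present in a single qPCR reaction.
#: Ten embryos yield the RNA pool, of which one reaction uses 5 ng out of
#: the 2 ug reverse transcribed: 10 * 5/2000 = 1/40 embryo per reaction.
EMBRYO_FRACTION_PER_REACTION = 0.025


@dataclass(frozen=True)
class TranscriptionParams:
    """Kinetic parameters for one gene in one tissue.

    Defaults describe a housekeeping-like gene: a large maternal pool that
    decays slowly, zygotic synthesis from the MBT onward, and splicing slow
    enough that the nascent pool keeps rising over the sampled window while
    remaining far below the mature pool.

    Attributes
    ----------
    onset_hpf : float
        True activation time (hours post fertilization). Transcription
        never starts before ``mbt_hpf``; the effective onset is
        ``max(onset_hpf, mbt_hpf)``.
    rate : float
        Pre-mRNA synthesis, copies/embryo/hour after onset.
    splicing_rate : float
        First-order conversion of pre-mRNA to mature mRNA, per hour.
    maternal_copies0 : float
        Mature copies per embryo at fertilization.
    maternal_decay : float
        First-order decay of the maternal pool, per hour.
    mbt_hpf : float
        Midblastula transition time.
    leaky_rate : float
        Optional low-level synthesis active from 0 hpf ("leaky" pre-MBT
        expression); off by default.
    """

    onset_hpf: float = 4.0
    rate: float = 2000.0
    splicing_rate: float = 0.2
    maternal_copies0: float = 5.0e5
    maternal_decay: float = 0.05
    mbt_hpf: float = 4.0
    leaky_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rate", "splicing_rate", "maternal_copies0", "maternal_decay", "leaky_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.onset_hpf < 0:
            raise ValueError("onset_hpf must be >= 0")

    @property
    def effective_onset(self) -> float:
        return max(self.onset_hpf, self.mbt_hpf)


@dataclass(frozen=True)
class QpcrNoiseModel:
    """Replicate-level measurement noise for simulated qPCR plates."""

    cq_sd: float = 0.2
    rtminus_contamination_copies: float = 0.05
    max_cycles: int = 40
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.cq_sd < 0:
            raise ValueError("cq_sd must be >= 0")
        if self.rtminus_contamination_copies < 0:
            raise ValueError("rtminus_contamination_copies must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")


@dataclass(frozen=True)
class TissueMixture:
    """A whole embryo as a weighted mixture of tissues (germ layers).

    ``tissues`` maps each tissue to its per-gene kinetic parameters; all
    tissues must cover the same gene set. ``fractions`` are the tissue
    proportions of the embryo and must sum to one.
    """

    fractions: tuple
    tissues: tuple  # tuple of Mapping[str, TranscriptionParams]
    detection_limit: float = 1.0

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.tissues):
            raise ValueError("fractions and tissues must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"tissue fractions must sum to 1, got {sum(self.fractions)!r}")
        if any(f < 0 for f in self.fractions):
            raise ValueError("tissue fractions must be >= 0")
        genes = set(self.tissues[0])
        for t in self.tissues[1:]:
            if set(t) != genes:
                raise ValueError("all tissues must parameterize the same genes")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be > 0")


class Timecourse(NamedTuple):
    """Deterministic per-embryo copy numbers on a time grid."""

    hpf: np.ndarray
    premrna: np.ndarray
    mature: np.ndarray


def _synthesis_pools(rate: float, splicing: float, t_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pre-mRNA and mature pools from constant synthesis started at t_rel=0.

    With synthesis r and first-order splicing s the nascent pool is
    (r/s)(1 - exp(-s t)) and everything synthesized but no longer nascent
    is mature, so mature = r t - pre. s = 0 degenerates to pre = r t.
    """
    t = np.clip(t_rel, 0.0, None)
    active = t > 0
    pre = np.zeros_like(t)
    if splicing > 0:
        pre[active] = rate / splicing * -np.expm1(-splicing * t[active])
    else:
        pre[active] = rate * t[active]
    mature = rate * t - pre
    return pre, mature


def simulate_timecourse(params: TranscriptionParams, times: Sequence[float]) -> Timecourse:
    """Closed-form pre-mRNA and mature copies per embryo at the given times.

    Raises if ``times`` is not sorted ascending.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    pre, zyg_mature = _synthesis_pools(params.rate, params.splicing_rate, t - params.effective_onset)
    if params.leaky_rate > 0:
        pre_l, mat_l = _synthesis_pools(params.leaky_rate, params.splicing_rate, t)
        pre = pre + pre_l
        zyg_mature = zyg_mature + mat_l
    mature = params.maternal_copies0 * np.exp(-params.maternal_decay * t) + zyg_mature
    return Timecourse(hpf=t, premrna=pre, mature=mature)


def default_standard_curve() -> StandardCurve:
    """A perfect-efficiency calibration: one Cq per doubling, Cq 37 at 1 copy."""
    return StandardCurve(
        slope=-1.0 / np.log10(2.0),  # -3.3219...: efficiency exactly 1
        intercept=37.0,
        r_squared=1.0,
        copies_min=1.0,
        copies_max=1.0e7,
    )


def simulate_qpcr_plate(
    copies: pd.DataFrame,
    noise: QpcrNoiseModel,
    curve: StandardCurve,
    seed: int,
    stage_table: StageTimeTable | None = None,
) -> pd.DataFrame:
    """Simulate replicate Cq values for RT+ and RT- reactions.

    Parameters
    ----------
    copies : DataFrame
        Columns ``gene_id``, ``hpf``, ``copies`` — true template copies per
        reaction for the RT+ sample (the RT- template is contamination only).
    noise : QpcrNoiseModel
    curve : StandardCurve
        The calibration through which Cq values are generated.
    seed : int
        Seeds a private generator; identical seeds give identical plates.

    Returns
    -------
    DataFrame with columns gene_id, hpf, stage, rt, replicate, cq, censored.
    A reaction with zero template, or whose Cq falls beyond ``max_cycles``,
    is censored (no amplification; cq = NaN).
    """
    required = {"gene_id", "hpf", "copies"}
    if not required.issubset(copies.columns):
        raise ValueError(f"copies table needs columns {sorted(required)}")
    if (copies["copies"] < 0).any():
        raise ValueError("negative copies are not meaningful")
    if stage_table is None:
        stage_table = default_stage_table()
    rng = np.random.default_rng(seed)
    stage_lookup = {float(h): s for h, s in zip(stage_table.hpf, stage_table.stage)}

    rows = []
    for _, rec in copies.iterrows():
        hpf = float(rec["hpf"])
        # nearest-sample stage label, for reporting only
        stage = stage_lookup.get(hpf)
        if stage is None:
            idx = int(np.argmin(np.abs(np.asarray(stage_table.hpf) - hpf)))
            stage = stage_table.stage[idx]
        for rt, true_copies in (("plus", float(rec["copies"])), ("minus", 0.0)):
            for rep in range(1, noise.replicates + 1):
                template = true_copies + rng.poisson(noise.rtminus_contamination_copies)
                if template <= 0:
                    cq, censored = np.nan, True
                else:
                    cq = (
                        curve.intercept
                        + curve.slope * np.log10(template)
                        + rng.normal(0.0, noise.cq_sd)
                    )
                    censored = cq > noise.max_cycles
                    if censored:
                        cq = np.nan
                rows.append(
                    {
                        "gene_id": rec["gene_id"],
                        "hpf": hpf,
                        "stage": stage,
                        "rt": rt,
                        "replicate": rep,
                        "cq": cq,
                        "censored": censored,
                    }
                )
    return pd.DataFrame(rows)


def simulate_trajectory(
    params: TranscriptionParams,
    noise_sd: float,
    n_draws: int,
    seed: int,
    times: Sequence[float] | None = None,
    gene_id: str = "gene",
) -> CountTrajectory:
    """An RNA-seq-style per-embryo mature-transcript trajectory with a 95% band.

    Replicate draws multiply the closed-form mature curve by lognormal noise
    exp(N(0, noise_sd)); the band is the pointwise 2.5/97.5 percentile across
    draws. This stands in for the Gaussian-process fits of the profile
    database: only the band-overlap semantics are consumed downstream.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times is None:
        times = np.arange(0.0, 20.01, 0.5)
    tc = simulate_timecourse(params, times)
    rng = np.random.default_rng(seed)
    draws = tc.mature[None, :] * np.exp(rng.normal(0.0, noise_sd, size=(n_draws, tc.hpf.size)))
    return CountTrajectory(
        gene_id=gene_id,
        hpf=tc.hpf,
        mean=draws.mean(axis=0),
        lo95=np.percentile(draws, 2.5, axis=0),
        hi95=np.percentile(draws, 97.5, axis=0),
    )


@dataclass(frozen=True)
class WholeEmbryoResult:
    """Mixture-weighted nascent-transcript curves and detection times."""

    hpf: np.ndarray
    premrna: dict  # gene -> np.ndarray, copies/embryo
    detection_hpf: dict  # gene -> float or None (first crossing of the limit)


def simulate_whole_embryo(mix: TissueMixture, times: Sequence[float]) -> WholeEmbryoResult:
    """Whole-embryo pre-mRNA as the tissue-fraction-weighted sum.

    Records, per gene, the first (linearly interpolated) time the mixture
    curve exceeds ``mix.detection_limit``.
    """
    t = np.asarray(times, dtype=float)
    genes = sorted(mix.tissues[0])
    pre = {g: np.zeros_like(t) for g in genes}
    for frac, tissue in zip(mix.fractions, mix.tissues):
        if frac == 0:
            continue
        for g in genes:
            pre[g] = pre[g] + frac * simulate_timecourse(tissue[g], t).premrna
    detection = {g: crossing_time(t, pre[g], mix.detection_limit) for g in genes}
    return WholeEmbryoResult(hpf=t, premrna=pre, detection_hpf=detection)


# ---------------------------------------------------------------------------
# fixture builders


def simulate_dilution_series(
    curve: StandardCurve,
    levels: Sequence[float] = (10.0, 100.0, 1e3, 1e4, 1e5, 1e6),
    cq_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """A standard-curve dilution table (known copies, Cq) generated from ``curve``."""
    rng = np.random.default_rng(seed)
    rows = []
    for copies in levels:
        for _ in range(replicates):
            cq = curve.intercept + curve.slope * np.log10(copies) + rng.normal(0.0, cq_sd)
            rows.append({"copies": copies, "cq": cq})
    return pd.DataFrame(rows)


#: Onsets used by the collinear demo panel: each falls just after a grid
#: point, inside a distinct sampling interval of the 14-point series, so
#: the first post-onset sample already carries most of an interval's worth
#: of signal and every downstream method resolves the order.
COLLINEAR_ONSETS = (4.6, 6.6, 7.6, 8.6, 9.6, 10.6, 11.6, 12.6, 13.6, 14.6, 16.6)


def make_collinear_panel(
    gene_ids: Sequence[str],
    onsets: Sequence[float] | None = None,
    anti: bool = False,
    rate: float = 2000.0,
    splicing_rate: float = 0.2,
) -> dict[str, TranscriptionParams]:
    """Hox-like kinetics (no maternal pool) with onsets in genomic order.

    With ``anti=True`` the onset order is reversed, giving a perfectly
    anti-collinear panel.
    """
    if onsets is None:
        onsets = COLLINEAR_ONSETS[: len(gene_ids)]
    if len(onsets) != len(gene_ids):
        raise ValueError("need one onset per gene")
    ordered = list(reversed(onsets)) if anti else list(onsets)
    return {
        g: TranscriptionParams(
            onset_hpf=o,
            rate=rate,
            splicing_rate=splicing_rate,
            maternal_copies0=0.0,
            maternal_decay=0.0,
        )
        for g, o in zip(gene_ids, ordered)
    }


#: Measurement settings for the collinear demonstration dataset: clean
#: technical replicates and a contamination-free RT- control, so ordering
#: failures can only come from the estimators, not the plate.
DEMO_NOISE = QpcrNoiseModel(cq_sd=0.05, rtminus_contamination_copies=0.0)
DEMO_RATE = 3000.0


def collinear_qpcr_plate(
    gene_ids: Sequence[str],
    seed: int,
    anti: bool = False,
    noise: QpcrNoiseModel = DEMO_NOISE,
    curve: StandardCurve | None = None,
) -> pd.DataFrame:
    """Simulated plate for a perfectly (anti-)collinear panel of genes."""
    curve = curve or default_standard_curve()
    panel = make_collinear_panel(gene_ids, anti=anti, rate=DEMO_RATE)
    return simulate_qpcr_plate(panel_reaction_copies(panel), noise, curve, seed=seed)


def panel_reaction_copies(
    panel: Mapping[str, TranscriptionParams],
    times: Sequence[float] = SAMPLING_HPF,
    embryo_fraction: float = EMBRYO_FRACTION_PER_REACTION,
) -> pd.DataFrame:
    """True nascent copies per qPCR reaction for each gene and sampling time."""
    rows = []
    for gene, params in panel.items():
        tc = simulate_timecourse(params, times)
        for h, pre in zip(tc.hpf, tc.premrna):
            rows.append({"gene_id": gene, "hpf": h, "copies": pre * embryo_fraction})
    return pd.DataFrame(rows)


#: De novo copies/reaction over the sampling grid for a gradual riser:
#: nothing through 10.5 hpf, a sub-significant step at 11.5, a clear rise
#: by 12.5, then a plateau. With ~14% replicate CV the Tukey-Kramer
#: critical difference lands between the one-step and the two-step rise,
#: so no adjacent pair within 10.5-12.5 hpf is significant but the
#: bridging pair (10.5, 12.5) is — the pattern that forces the bridged
#: rise interval.
GRADUAL_RISE_COPIES = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 175.0, 360.0, 800.0, 1000.0, 1100.0, 1150.0, 1180.0)


def make_gradual_rise_plate(
    gene_id: str = "gradual",
    cq_spread: float = 0.2,
    curve: StandardCurve | None = None,
    copies: Sequence[float] = GRADUAL_RISE_COPIES,
    times: Sequence[float] = SAMPLING_HPF,
) -> pd.DataFrame:
    """A deterministic plate for a gene with a gradual two-step rise.

    Each positive time point carries three replicates at Cq offsets
    (-cq_spread, 0, +cq_spread) around the curve's Cq for the design copy
    number (a ~14% copy-level CV for the default spread); zero-copy points
    and all RT- reactions are censored. Deterministic on purpose: the
    significance pattern it produces is a designed property, not a draw.
    """
    curve = curve or default_standard_curve()
    stage_table = default_stage_table()
    stage = {float(h): s for h, s in zip(stage_table.hpf, stage_table.stage)}
    rows = []
    for h, m in zip(times, copies):
        for rt in ("plus", "minus"):
            for rep, off in enumerate((-cq_spread, 0.0, cq_spread), start=1):
                if rt == "minus" or m <= 0:
                    cq, censored = np.nan, True
                else:
                    cq, censored = curve.cq_of(m) + off, False
                rows.append(
                    {
                        "gene_id": gene_id, "hpf": float(h), "stage": stage[float(h)],
                        "rt": rt, "replicate": rep, "cq": cq, "censored": censored,
                    }
                )
    return pd.DataFrame(rows)


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    noise: QpcrNoiseModel | None = None,
    anti: bool = False,
) -> dict[str, Path]:
    """Write a complete demo dataset for the 11 HoxA genes.

    Emits ``plate.csv`` (replicate Cq values), ``dilutions.csv`` (standard
    curve), ``trajectories.csv`` (per-embryo mature-count trajectories with
    95% bands) and ``annotation.csv``. Returns the paths.
    """
    from .annotation import annotation_frame, default_annotation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = noise or DEMO_NOISE
    curve = default_standard_curve()
    ann = [a for a in default_annotation() if a.cluster == "A"]
    genes = [a.gene_id for a in sorted(ann, key=lambda a: a.position_index)]
    panel = make_collinear_panel(genes, anti=anti, rate=DEMO_RATE)

    plate = simulate_qpcr_plate(panel_reaction_copies(panel), noise, curve, seed=seed)
    dilutions = simulate_dilution_series(curve, cq_sd=0.02, seed=seed + 1)
    trajs = []
    for k, g in enumerate(genes):
        params = replace(panel[g], rate=60_000.0, splicing_rate=1.0)
        t = simulate_trajectory(params, noise_sd=0.1, n_draws=50, seed=seed + 10 + k, gene_id=g)
        trajs.append(pd.DataFrame({"gene_id": g, "hpf": t.hpf, "mean": t.mean, "lo95": t.lo95, "hi95": t.hi95}))

    paths = {
        "plate": outdir / "plate.csv",
        "dilutions": outdir / "dilutions.csv",
        "trajectories": outdir / "trajectories.csv",
        "annotation": outdir / "annotation.csv",
    }
    plate.to_csv(paths["plate"], index=False)
    dilutions.to_csv(paths["dilutions"], index=False)
    pd.concat(trajs, ignore_index=True).to_csv(paths["trajectories"], index=False)
    annotation_frame(ann).to_csv(paths["annotation"], index=False)
    return paths
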