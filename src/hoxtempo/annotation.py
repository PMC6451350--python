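"""Hox gene positions within clusters and the embryo sampling-stage table.

Genomic order inside a cluster is what "collinear" is measured against.
Genes are identified by paralogous group (PG 1-13, numbered 3'->5'), but
because Xenopus tropicalis clusters are gappy (e.g. HoxA has no PG8 or
PG12), ordering comparisons use a dense ``position_index`` (1 = most
3'/anterior gene actually present in that cluster) rather than the PG
number itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "StageTimeTable",
    "load_annotation",
    "default_annotation",
    "default_stage_table",
    "stage_for_time",
    "SAMPLING_HPF",
]

VALID_CLUSTERS = frozenset("ABCD")

#: The 14 whole-embryo sampling times (hours post fertilization at 23 C)
#: used throughout: 3 hpf (stage 7) through 19.5 hpf (stage 24).
SAMPLING_HPF = (3.0, 4.5, 6.5, 7.5, 8.5, 9.5, 10.5, 11.5, 12.5, 13.5, 14.5, 16.5, 18.5, 19.5)


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """Position of one hox gene inside its cluster.

    Attributes
    ----------
    gene_id : str
        e.g. ``"hoxa3"``.
    cluster : str
        Cluster letter, one of A-D.
    paralogous_group : int
        PG number 1-13, counted from the 3' end of the cluster.
    position_index : int
        Dense rank of the gene within its cluster (1 = most 3').
    """

    cluster: str
    position_index: int
    paralogous_group: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.cluster not in VALID_CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r} for {self.gene_id!r}")
        if not 1 <= self.paralogous_group <= 13:
            raise ValueError(
                f"paralogous_group must be in 1..13, got {self.paralogous_group} for {self.gene_id!r}"
            )
        if self.position_index < 1:
            raise ValueError("position_index must be >= 1")


@dataclass(frozen=True)
class StageTimeTable:
    """Lookup between hours post fertilization and Nieuwkoop-Faber stage labels.

    Stage strings are opaque reporting metadata ("10~10.5" is allowed);
    nothing is ever computed on them.
    """

    hpf: tuple
    stage: tuple

    def __post_init__(self) -> None:
        if len(self.hpf) != len(self.stage):
            raise ValueError("hpf and stage must have equal length")
        if len(self.hpf) == 0:
            raise ValueError("stage/time table is empty")
        if not np.all(np.diff(self.hpf) > 0):
            raise ValueError("hpf must be strictly increasing")

    def __len__(self) -> int:
        return len(self.hpf)


def _annotate(df: pd.DataFrame) -> list[GeneAnnotation]:
    required = {"gene_id", "cluster", "paralogous_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id entries: {dups}")
    out: list[GeneAnnotation] = []
    for cluster, grp in df.groupby("cluster", sort=True):
        grp = grp.sort_values("paralogous_group")
        if grp["paralogous_group"].duplicated().any():
            raise ValueError(f"duplicate paralogous_group within cluster {cluster}")
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            out.append(
                GeneAnnotation(
                    gene_id=str(row["gene_id"]),
                    cluster=str(cluster),
                    paralogous_group=int(row["paralogous_group"]),
                    position_index=rank,
                )
            )
    return out


def load_annotation(path: Union[str, Path, pd.DataFrame]) -> list[GeneAnnotation]:
    """Load a gene annotation table (CSV with gene_id, cluster, paralogous_group).

    ``position_index`` is assigned by sorting paralogous_group within each
    cluster, so it is a gap-free rank regardless of which PGs a cluster has.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    return _annotate(df)


def default_annotation() -> list[GeneAnnotation]:
    """All 38 X. tropicalis hox genes (clusters A-D)."""
    with resources.files("hoxtempo.data").joinpath("hox_annotation.csv").open() as fh:
        return _annotate(pd.read_csv(fh))


def default_stage_table() -> StageTimeTable:
    """The 14-point sampling series, 3 hpf (stage 7) to 19.5 hpf (stage 24)."""
    with resources.files("hoxtempo.data").joinpath("stage_table.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"stage": str})
    return StageTimeTable(hpf=tuple(float(h) for h in df["hpf"]), stage=tuple(df["stage"]))


def stage_for_time(hpf: float, table: StageTimeTable | None = None) -> str:
    """Stage label of the tabulated sampling time nearest to ``hpf``.

    Ties between two equidistant sampling times break toward the earlier one.
    """
    if table is None:
        table = default_stage_table()
    times = np.asarray(table.hpf, dtype=float)
    idx = int(np.argmin(np.abs(times - float(hpf))))  # argmin is first-wins -> earlier time
    return table.stage[idx]


def annotation_frame(annotations: Iterable[GeneAnnotation]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of annotations."""
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "cluster": a.cluster,
                "paralogous_group": a.paralogous_group,
                "position_index": a.position_index,
            }
            for a in annotations
        ]
    )


def position_map(annotations: Iterable[GeneAnnotation]) -> dict[str, int]:
    """gene_id -> position_index."""
    return {a.gene_id: a.position_index for a in annotations}
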