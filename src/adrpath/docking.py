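"""Docking-score post-processing.

Raw virtual-screening scores are engine- and receptor-specific, so they are
(1) collapsed to the better of the two pocket attempts per drug–target pair,
(2) oriented so that larger always means stronger predicted binding and
z-score normalized along a chosen axis (per receptor by default, since
score scales differ mostly between receptors), (3) thresholded per drug —
only targets scoring more than one standard deviation above that drug's
mean are called interactions — and (4) summed over pathway membership to
give the continuous drug×pathway feature matrix used by the inference
stage.  All standard deviations are population (n-denominator).
"""

from __future__ import annotations

import enum
import logging

import numpy as np
import pandas as pd

from .io import Direction, DockingScoreMatrix

logger = logging.getLogger(__name__)


class Axis(enum.Enum):
    PER_RECEPTOR = "receptor"
    PER_DRUG = "drug"

    @classmethod
    def coerce(cls, value: "Axis | str") -> "Axis":
        return value if isinstance(value, cls) else cls(str(value).lower())


def merge_pockets(matrix: DockingScoreMatrix) -> pd.DataFrame:
    """Best raw score per (drug, protein) across pocket attempts.

    Under LOWER-better orientation the best score is the minimum; under
    HIGHER-better the maximum.  Pairs docked in a single pocket pass
    through unchanged.
    """
    agg = "min" if matrix.better_direction is Direction.LOWER else "max"
    best = (
        matrix.entries.groupby(["drug_id", "protein_id"], sort=False)["raw_score"]
        .agg(agg)
        .reset_index()
    )
    return best


def normalize_scores(
    best: pd.DataFrame,
    direction: Direction | str,
    axis: Axis | str = Axis.PER_RECEPTOR,
) -> pd.DataFrame:
    """Orient scores (larger = better) and z-normalize along ``axis``.

    z = (s − mean)/sd with population sd, computed within each receptor
    (or drug).  Groups with zero variance — including singletons — map to
    z = 0 with a logged warning, since no ranking information exists there.
    """
    direction = Direction.coerce(direction)
    axis = Axis.coerce(axis)
    df = best.copy()
    s = df.raw_score.to_numpy(dtype=float)
    if direction is Direction.LOWER:
        s = -s
    df["oriented"] = s
    group_col = "protein_id" if axis is Axis.PER_RECEPTOR else "drug_id"
    grp = df.groupby(group_col)["oriented"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=0))
    n_degenerate = int((sd.to_numpy() == 0).sum())
    if n_degenerate:
        logger.warning(
            "normalize_scores: %d observations in zero-variance %s groups -> z = 0",
            n_degenerate, group_col,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd.to_numpy() > 0, (df.oriented - mean) / sd, 0.0)
    out = df[["drug_id", "protein_id"]].copy()
    out["z"] = z
    return out


def call_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Flag, per drug, the targets scoring better than one sd above the mean.

    The mean and sd are over that drug's normalized scores; the threshold
    is strict (a score exactly at mean + sd is not retained).  Drugs with a
    single docked target carry no ranking information and retain nothing.
    """
    out = table.copy()
    grp = out.groupby("drug_id")["z"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=0))
    count = grp.transform("size")
    out["retained"] = (out.z > mean + sd) & (count >= 2)
    lonely = out.loc[count < 2, "drug_id"].unique()
    if len(lonely):
        logger.warning("call_interactions: %d drugs with <2 docked proteins retain nothing", len(lonely))
    return out


def build_pathway_features(
    table: pd.DataFrame,
    pathway_map: pd.DataFrame,
    drugs: list[str] | None = None,
    pathways: list[str] | None = None,
) -> pd.DataFrame:
    """Drug×pathway matrix X: sum of retained z over each pathway's members.

    A protein annotated to k pathways contributes its score to all k
    columns; a drug with no retained interaction in a pathway scores 0
    there.  Retained proteins absent from the map contribute nowhere (one
    logged notice).
    """
    retained = table[table.retained] if "retained" in table.columns else table
    drugs = list(drugs) if drugs is not None else sorted(table.drug_id.unique())
    pathways = list(pathways) if pathways is not None else sorted(pathway_map.pathway_id.unique())
    unmapped = set(retained.protein_id) - set(pathway_map.protein_id)
    if unmapped:
        logger.warning(
            "build_pathway_features: %d retained proteins lack pathway annotation", len(unmapped)
        )
    joined = retained.merge(pathway_map[["protein_id", "pathway_id"]], on="protein_id", how="inner")
    sums = joined.groupby(["drug_id", "pathway_id"])["z"].sum()
    X = pd.DataFrame(0.0, index=pd.Index(drugs, name="drug_id"), columns=pathways)
    for (d, p), v in sums.items():
        if d in X.index and p in X.columns:
            X.loc[d, p] = v
    return X
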