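"""Drug and protein-structure eligibility filters.

Ligands are kept when they are dockable small molecules: molecular weight
within a closed 100–800 Da window and fewer than 10 rotatable bonds.
Protein structures are kept when they are well-determined human enzymes with
pathway annotation; near-identical structures (>90% identity over >90% of
the sequence) are collapsed to a single representative per single-linkage
cluster.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

XRAY = "XRAY"
NMR = "NMR"


def filter_ligands(
    drugs: pd.DataFrame,
    mw_min: float = 100.0,
    mw_max: float = 800.0,
    max_rot: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Keep drugs with mw_min <= MW <= mw_max and rotatable_bonds < max_rot.

    Returns (retained drug ids in input order, drop log with per-drug
    reasons).  Drugs missing either property cannot be assessed and are
    dropped with a logged reason.
    """
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for row in drugs.itertuples(index=False):
        mw = row.molecular_weight
        rot = row.rotatable_bonds
        if pd.isna(mw) or pd.isna(rot):
            dropped.append((row.drug_id, "missing molecular_weight or rotatable_bonds"))
        elif not (mw_min <= mw <= mw_max):
            dropped.append((row.drug_id, f"molecular weight {mw} outside [{mw_min}, {mw_max}] Da"))
        elif rot >= max_rot:
            dropped.append((row.drug_id, f"{int(rot)} rotatable bonds >= {max_rot}"))
        else:
            kept.append(row.drug_id)
    if dropped:
        logger.info("filter_ligands: dropped %d of %d drugs", len(dropped), len(drugs))
    log = pd.DataFrame(dropped, columns=["drug_id", "reason"])
    return kept, log


def filter_targets(
    proteins: pd.DataFrame,
    max_res: float = 3.0,
    min_len: int = 50,
    organism: str = "human",
) -> tuple[list[str], pd.DataFrame]:
    """Apply the six structure-eligibility criteria.

    Kept when: solved by X-ray or NMR; if X-ray, resolution strictly better
    than ``max_res`` Å; length strictly greater than ``min_len`` residues;
    source organism matches; carries an EC number; and has a pathway
    annotation.
    """
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for row in proteins.itertuples(index=False):
        reason = None
        if row.method not in (XRAY, NMR):
            reason = f"method {row.method} not X-ray or NMR"
        elif row.method == XRAY and (pd.isna(row.resolution) or row.resolution >= max_res):
            reason = f"X-ray resolution {row.resolution} not better than {max_res} A"
        elif row.length <= min_len:
            reason = f"length {row.length} aa not more than {min_len}"
        elif str(row.organism).lower() != organism.lower():
            reason = f"organism {row.organism!r} is not {organism!r}"
        elif not row.has_ec:
            reason = "no EC number"
        elif not row.pathway_annotated:
            reason = "no pathway annotation"
        if reason is None:
            kept.append(row.protein_id)
        else:
            dropped.append((row.protein_id, reason))
    log = pd.DataFrame(dropped, columns=["protein_id", "reason"])
    return kept, log


def cluster_redundant(
    protein_ids: Sequence[str],
    pairs: pd.DataFrame,
    id_thresh: float = 90.0,
    cov_thresh: float = 90.0,
    quality: Mapping[str, tuple] | Callable[[str], tuple] | None = None,
) -> tuple[list[str], list[frozenset[str]]]:
    """Collapse redundant structures to one representative per cluster.

    Edges connect pairs with identity > ``id_thresh`` AND coverage >
    ``cov_thresh`` (both strict); clusters are connected components
    (single linkage), so absent pairs count as below-threshold.  The
    representative minimizes the ``quality`` sort key (default:
    lexicographic id; callers typically pass (resolution, -length, id)).

    Returns (representatives sorted, clusters covering every input id).
    """
    ids = list(dict.fromkeys(protein_ids))
    id_set = set(ids)
    unknown = (set(pairs.protein_a) | set(pairs.protein_b)) - id_set
    if unknown:
        raise ValueError(f"similarity pairs reference unknown protein ids: {sorted(unknown)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    strong = pairs[(pairs.identity > id_thresh) & (pairs.coverage > cov_thresh)]
    g.add_edges_from(zip(strong.protein_a, strong.protein_b))

    if quality is None:
        key: Callable[[str], tuple] = lambda p: (p,)
    elif callable(quality):
        key = quality
    else:
        key = lambda p: quality[p]

    reps: list[str] = []
    clusters: list[frozenset[str]] = []
    for comp in nx.connected_components(g):
        clusters.append(frozenset(comp))
        reps.append(min(comp, key=lambda p: (key(p), p)))
    return sorted(reps), sorted(clusters, key=min)


def protein_quality_key(proteins: pd.DataFrame) -> dict[str, tuple]:
    """Default representative preference: best (lowest) resolution, then
    longest sequence, then lexicographic id.  NMR structures carry no
    resolution and sort after any resolved X-ray structure."""
    out: dict[str, tuple] = {}
    for row in proteins.itertuples(index=False):
        res = float(row.resolution) if not pd.isna(row.resolution) else float("inf")
        out[row.protein_id] = (res, -int(row.length), row.protein_id)
    return out
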