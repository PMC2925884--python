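"""Permutation null control and literature-count filtering.

Shuffling which drug owns which docking profile severs the X→Y pairing
while preserving every marginal statistic of both matrices; re-running the
inference on shuffled data yields the distribution of association counts
expected from unstructured docking data.  The literature filter keeps only
associations whose (pathway term, ADR term) pair reaches a minimum
co-mention count in an offline hit-count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .inference import infer_associations

logger = logging.getLogger(__name__)


def shuffle_drug_mapping(
    X: pd.DataFrame, Y: pd.DataFrame, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reassign docking-profile rows to drugs by a uniform permutation.

    Y is untouched; shuffling X against Y is equivalent to shuffling the
    drug→ADR mapping.  Row and column value multisets of X are preserved.
    """
    if not X.index.equals(Y.index):
        raise ValueError("X and Y must share the same drug ordering")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    Xp = pd.DataFrame(X.to_numpy()[perm], index=X.index, columns=X.columns)
    return Xp, Y


@dataclass
class NullDistribution:
    trial_counts: list[int]
    observed: int
    n_trials: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)
    empirical_p: float = field(init=False)
    normal_p: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.trial_counts, dtype=float)
        self.n_trials = len(counts)
        self.mean = float(counts.mean())
        self.sd = float(counts.std(ddof=0))
        # add-one estimator: never exactly zero, honest at small trial counts
        self.empirical_p = (1 + int((counts >= self.observed).sum())) / (self.n_trials + 1)
        self.normal_p = (
            float(norm.sf((self.observed - self.mean) / self.sd)) if self.sd > 0 else float("nan")
        )


def null_distribution(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_trials: int = 100,
    seed: int = 0,
    **infer_kwargs,
) -> NullDistribution:
    """Distribution of significant-association counts under shuffled pairing.

    Runs the full two-phase inference on the observed data and on
    ``n_trials`` independently permuted datasets, recording the number of
    significant associations each time.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    observed = int(infer_associations(X, Y, **infer_kwargs).significant.sum())
    rng = np.random.default_rng(seed)
    counts = []
    for t in range(n_trials):
        Xp, Yp = shuffle_drug_mapping(X, Y, rng)
        counts.append(int(infer_associations(Xp, Yp, **infer_kwargs).significant.sum()))
        logger.debug("null trial %d/%d: %d significant", t + 1, n_trials, counts[-1])
    return NullDistribution(trial_counts=counts, observed=observed)


def literature_filter(
    associations: pd.DataFrame,
    hits: pd.DataFrame,
    min_hits: int = 5,
    pathway_terms: dict[str, str] | None = None,
    adr_terms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Keep associations with >= ``min_hits`` literature co-mentions.

    ``hits`` maps (pathway_term, adr_term) to a count; pairs absent from
    the table count 0.  Optional term maps translate pathway/ADR ids to
    the vocabulary of the hit table.
    """
    counts = {
        (row.pathway_term, row.adr_term): int(row.hit_count)
        for row in hits.itertuples(index=False)
    }

    def n_hits(row) -> int:
        pt = (pathway_terms or {}).get(row.pathway_id, row.pathway_id)
        at = (adr_terms or {}).get(row.adr_group, row.adr_group)
        return counts.get((pt, at), 0)

    if len(associations) == 0:
        return associations.copy()
    mask = associations.apply(n_hits, axis=1) >= min_hits
    return associations[mask].reset_index(drop=True)
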