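"""Synthetic data with planted pathway→ADR effects.

The generator embodies the modelling assumption under test — drugs that
modulate the same pathway tend to share ADRs — while keeping the two noise
sources (docking-score noise and label noise) independently controllable:

* proteins are assigned to one or more pathways (overlap via a clipped
  binomial), so the multi-membership summation path is exercised;
* each drug modulates a random subset of pathways; docking scores are
  Gaussian noise plus a positive shift on modulated pathways' proteins,
  reported in two pockets with higher = better;
* ADR labels are drawn from a logistic model on the *true* modulation
  indicators (not the noisy scores) with planted per-(pathway, ADR)
  log-odds effects;
* drug properties are drawn inside the eligibility ranges so the cohort
  filters pass everything through by construction.

A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import Direction, DockingScoreMatrix


@dataclass(frozen=True)
class SyntheticParams:
    n_drugs: int = 200
    n_proteins: int = 120
    n_pathways: int = 20
    n_adrs: int = 12
    n_planted: int = 4
    effect_size: float = 2.0        # log-odds per modulated planted pathway
    binder_fraction: float = 0.15   # P(a drug modulates a given pathway)
    noise_sd: float = 1.0           # docking-score noise, engine units
    binder_shift: float = 3.0       # score shift on modulated proteins (units of noise_sd)
    overlap_p: float = 0.25         # extra-membership probability (Binomial(3, p), clipped >= 1)
    max_memberships: int = 3
    adr_base_logit: float = -1.1    # baseline ADR log-odds (~25% prevalence)

    def validate(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.n_pathways, self.n_adrs) < 1:
            raise ValueError("all entity counts must be >= 1")
        if not 0 < self.binder_fraction < 1:
            raise ValueError("binder_fraction must be in (0, 1)")
        if self.n_planted > self.n_pathways * self.n_adrs:
            raise ValueError("more planted pairs than (pathway, ADR) combinations")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    planted: set[tuple[str, str]]                 # (pathway_id, adr_id)
    effect_sizes: dict[tuple[str, str], float]
    modulated: pd.DataFrame                       # drugs × pathways binary indicators
    generator_params: dict = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    docking: DockingScoreMatrix
    pathway_map: pd.DataFrame
    adr_entries: pd.DataFrame
    drugs: pd.DataFrame
    truth: SyntheticTruth

    def adr_matrix(self) -> pd.DataFrame:
        """Binary drug×ADR matrix straight from the generated entries
        (no retention filtering applied)."""
        occ = pd.DataFrame(
            0,
            index=pd.Index(list(self.drugs.drug_id), name="drug_id"),
            columns=sorted(self.adr_entries.adr_phrase.unique()),
            dtype=int,
        )
        for row in self.adr_entries.itertuples(index=False):
            occ.loc[row.drug_id, row.adr_phrase] = 1
        return occ


def generate_synthetic(params: SyntheticParams | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a complete input bundle with known ground truth."""
    p = params or SyntheticParams()
    p.validate()
    rng = np.random.default_rng(seed)

    drug_ids = [f"drug_{i:04d}" for i in range(p.n_drugs)]
    protein_ids = [f"prot_{i:04d}" for i in range(p.n_proteins)]
    pathway_ids = [f"path_{i:03d}" for i in range(p.n_pathways)]
    # the doubled index keeps any two ADR phrases at edit distance >= 2, so
    # downstream edit-distance harmonization leaves them as singleton groups
    adr_ids = [f"adr_{i:03d}_{i:03d}" for i in range(p.n_adrs)]

    # protein -> pathway map; every pathway gets a seed member first
    pairs: set[tuple[str, str]] = set()
    for i, prot in enumerate(protein_ids):
        memberships = {pathway_ids[i % p.n_pathways]} if i < p.n_pathways else set()
        extra = max(1, rng.binomial(p.max_memberships, p.overlap_p)) - len(memberships)
        if extra > 0:
            memberships |= set(rng.choice(pathway_ids, size=extra, replace=False))
        pairs.update((prot, pw) for pw in memberships)
    pathway_map = pd.DataFrame(sorted(pairs), columns=["protein_id", "pathway_id"])
    members: dict[str, list[str]] = {
        pw: list(g.protein_id) for pw, g in pathway_map.groupby("pathway_id")
    }

    # per-drug modulated pathways
    modulated = pd.DataFrame(
        rng.random((p.n_drugs, p.n_pathways)) < p.binder_fraction,
        index=pd.Index(drug_ids, name="drug_id"), columns=pathway_ids,
    ).astype(int)

    # docking scores: two pockets, higher = better, shift on modulated members
    shift = p.binder_shift * p.noise_sd
    prot_index = {pr: j for j, pr in enumerate(protein_ids)}
    prot_shift = np.zeros((p.n_drugs, p.n_proteins))
    for pw in pathway_ids:
        idx = [prot_index[pr] for pr in members.get(pw, [])]
        if idx:
            prot_shift[:, idx] += np.outer(modulated[pw].to_numpy(), np.ones(len(idx)))
    prot_shift = np.minimum(prot_shift, 1.0) * shift   # membership in >1 modulated pathway is not additive
    rows = []
    for pocket in (1, 2):
        noise = rng.normal(0.0, p.noise_sd, size=(p.n_drugs, p.n_proteins))
        scores = prot_shift + noise
        for d, drug in enumerate(drug_ids):
            for j, prot in enumerate(protein_ids):
                rows.append((drug, prot, pocket, scores[d, j]))
    docking_df = pd.DataFrame(rows, columns=["drug_id", "protein_id", "pocket_id", "raw_score"])
    docking = DockingScoreMatrix(docking_df, Direction.HIGHER)

    # planted (pathway, ADR) effects, spread over distinct ADRs first
    adr_order = [adr_ids[i] for i in rng.permutation(p.n_adrs)]
    planted: list[tuple[str, str]] = []
    i = 0
    while len(planted) < p.n_planted:
        adr = adr_order[i % p.n_adrs]
        available = [pw for pw in pathway_ids if (pw, adr) not in planted]
        planted.append((str(rng.choice(available)), adr))
        i += 1
    effects = {pair: p.effect_size for pair in planted}

    # ADR labels from the true modulation indicators
    logit = np.full((p.n_drugs, p.n_adrs), p.adr_base_logit)
    adr_index = {a: j for j, a in enumerate(adr_ids)}
    for (pw, adr), eff in effects.items():
        logit[:, adr_index[adr]] += eff * modulated[pw].to_numpy()
    labels = rng.random((p.n_drugs, p.n_adrs)) < expit(logit)
    adr_rows = [
        {"drug_id": drug_ids[d], "adr_phrase": adr_ids[a], "frequency": None,
         "placebo_frequency": None, "post_marketing": False}
        for d in range(p.n_drugs) for a in range(p.n_adrs) if labels[d, a]
    ]
    adr_entries = pd.DataFrame(
        adr_rows, columns=["drug_id", "adr_phrase", "frequency", "placebo_frequency", "post_marketing"]
    )
    adr_entries["frequency"] = adr_entries["frequency"].astype("Float64")
    adr_entries["placebo_frequency"] = adr_entries["placebo_frequency"].astype("Float64")
    adr_entries["post_marketing"] = adr_entries["post_marketing"].astype(bool)

    # drug properties inside the eligibility ranges
    drugs = pd.DataFrame({
        "drug_id": drug_ids,
        "name": [f"compound {i}" for i in range(p.n_drugs)],
        "molecular_weight": np.round(rng.uniform(100.0, 800.0, size=p.n_drugs), 1),
        "rotatable_bonds": rng.integers(0, 10, size=p.n_drugs),
    })
    drugs["rotatable_bonds"] = drugs["rotatable_bonds"].astype("Int64")
    drugs["molecular_weight"] = drugs["molecular_weight"].astype("Float64")

    truth = SyntheticTruth(
        planted=set(planted),
        effect_sizes=effects,
        modulated=modulated,
        generator_params={**asdict(p), "seed": seed},
    )
    return SyntheticBundle(docking=docking, pathway_map=pathway_map,
                           adr_entries=adr_entries, drugs=drugs, truth=truth)


def recovery_metrics(results: pd.DataFrame, truth: SyntheticTruth) -> tuple[float, float]:
    """Precision and recall of the significant set against the planted pairs.

    Pairs are (pathway_id, adr_id).  An empty significant set has precision
    1 by convention and recall 0.
    """
    sig = {
        (row.pathway_id, row.adr_group)
        for row in results.itertuples(index=False)
        if row.significant
    }
    tp = len(sig & truth.planted)
    precision = tp / len(sig) if sig else 1.0
    recall = tp / len(truth.planted) if truth.planted else 1.0
    return precision, recall
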