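"""ADR vocabulary harmonization.

Side-effect phrases arrive as free text in which the same reaction appears
under slightly different names ("headache" / "headaches").  Harmonization
proceeds in three steps: token-wise suffix stemming, single-linkage grouping
of phrases whose Levenshtein distance is below two, and application of the
per-drug / per-column retention rules that yield the binary drug×ADR-group
occurrence matrix used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stemming

# Ordered suffix-strip rules (first match wins).  Deliberately light: the
# goal is to collapse inflectional variants deterministically, not to be a
# full Porter stemmer.  Each rule is (suffix, replacement); a rule applies
# only if the stripped stem keeps >= _MIN_STEM characters.
_RULES: tuple[tuple[str, str], ...] = (
    ("sses", "ss"),
    ("ies", "i"),
    ("ness", ""),
    ("ment", ""),
    ("ing", ""),
    ("es", ""),
    ("ed", ""),
    ("s", ""),
)
_MIN_STEM = 3


def _strip_once(token: str) -> str:
    for suffix, repl in _RULES:
        if token.endswith(suffix):
            stem = token[: len(token) - len(suffix)] + repl
            if len(stem) >= _MIN_STEM:
                # "ss" endings stay intact: the bare-"s" rule must not turn
                # "glass" into "glas"
                if suffix == "s" and stem.endswith("s"):
                    return token
                return stem
            return token
    return token


def _stem_token(token: str) -> str:
    # iterate to a fixed point so stemming is idempotent even when one
    # stripped suffix exposes another ("pressings" -> "pressing" -> "press")
    while True:
        nxt = _strip_once(token)
        if nxt == token:
            return token
        token = nxt


def suffix_stemmer(phrase: str) -> str:
    """Lowercase and strip common inflectional suffixes per token."""
    return " ".join(_stem_token(t) for t in phrase.lower().split())


def identity_stemmer(phrase: str) -> str:
    """No-op normalizer apart from case folding and whitespace collapse."""
    return " ".join(phrase.lower().split())


STEMMERS: dict[str, Callable[[str], str]] = {
    "suffix": suffix_stemmer,
    "none": identity_stemmer,
}


def stem_phrase(phrase: str, stemmer: str | Callable[[str], str] = "suffix") -> str:
    """Normalize one ADR phrase with a pluggable stemmer.

    Idempotent: ``stem_phrase(stem_phrase(x)) == stem_phrase(x)``.
    """
    if not phrase or not phrase.strip():
        raise ValueError("empty ADR phrase")
    fn = STEMMERS[stemmer] if isinstance(stemmer, str) else stemmer
    return fn(phrase)


# ---------------------------------------------------------------------------
# Edit distance

def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character edits transforming ``a`` into ``b``."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = np.arange(len(b) + 1)
    cur = np.empty(len(b) + 1, dtype=prev.dtype)
    bb = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
    for i, ca in enumerate(a, 1):
        cur[0] = i
        sub = prev[:-1] + (bb != ord(ca))
        # cur[j] = min(prev[j] + 1, prev[j-1] + (a[i]!=b[j]), cur[j-1] + 1)
        np.minimum(prev[1:] + 1, sub, out=cur[1:])
        for j in range(1, len(b) + 1):   # left-to-right dependency
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev, cur = cur, prev
    return int(prev[-1])


# ---------------------------------------------------------------------------
# Grouping

@dataclass(frozen=True)
class ADRGroup:
    group_id: str
    members: frozenset[str]
    representative: str


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_adr_terms(phrases: Iterable[str], max_distance: int = 1) -> list[ADRGroup]:
    """Partition phrases into groups connected by edits of <= ``max_distance``.

    Grouping is by transitive closure (single linkage): a chain a–b–c with
    each link within distance merges all three even if the endpoints are
    farther apart.  The representative is the lexicographically smallest
    member; group ids are stable across runs.
    """
    items = sorted(set(phrases))
    uf = _UnionFind(items)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if abs(len(a) - len(b)) <= max_distance and levenshtein(a, b) <= max_distance:
                uf.union(a, b)
    clusters: dict[str, list[str]] = {}
    for x in items:
        clusters.setdefault(uf.find(x), []).append(x)
    groups = []
    for members in sorted(clusters.values(), key=min):
        rep = min(members)
        groups.append(ADRGroup(group_id=rep, members=frozenset(members), representative=rep))
    return groups


# ---------------------------------------------------------------------------
# Retention rules and the binary matrix

@dataclass
class ADRMatrix:
    """Binary drug×ADR-group occurrence matrix after harmonization/filtering."""

    occurrence: pd.DataFrame          # index = drug ids, columns = group ids, values in {0,1}
    groups: list[ADRGroup]

    @property
    def drugs(self) -> list[str]:
        return list(self.occurrence.index)

    @property
    def adr_groups(self) -> list[str]:
        return list(self.occurrence.columns)


def max_support_cap(n_drugs: int, max_frac: float = 0.05) -> int:
    """Largest admissible per-column drug support: floor(max_frac · n)."""
    return math.floor(max_frac * n_drugs)


def filter_adrs(
    entries: pd.DataFrame,
    drugs: Sequence[str],
    groups: list[ADRGroup] | None = None,
    *,
    min_freq: float = 1.0,
    min_drugs: int = 3,
    max_frac: float = 0.05,
    stemmer: str | Callable[[str], str] = "suffix",
    group_on_stemmed: bool = True,
) -> ADRMatrix:
    """Apply the per-instance and per-column ADR retention rules.

    Per drug–ADR instance, drop when (i) the report is post-marketing only,
    or (ii) the frequency net of placebo is below ``min_freq`` percent —
    applied only when the frequency is known, and placebo subtracted only
    when available.  Then drop ADR-group columns supported by fewer than
    ``min_drugs`` drugs or by more than floor(``max_frac``·n) drugs ("more
    than" exclusive: a column at exactly the cap is kept).  Remaining
    occurrences are binary; frequency information is discarded.
    """
    keep_drugs = list(dict.fromkeys(drugs))
    drug_set = set(keep_drugs)
    unknown = set(entries.drug_id) - drug_set
    if unknown:
        logger.warning("filter_adrs: skipping %d entries for non-retained drugs", len(unknown))
    ent = entries[entries.drug_id.isin(drug_set)].copy()

    ent = ent[~ent.post_marketing.astype(bool)]
    freq = ent.frequency.astype("Float64")
    placebo = ent.placebo_frequency.astype("Float64").fillna(0.0)
    net = freq - placebo
    ent = ent[freq.isna().to_numpy() | (net >= min_freq).fillna(False).to_numpy()]

    stem_fn = STEMMERS[stemmer] if isinstance(stemmer, str) else stemmer
    stemmed = ent.adr_phrase.map(lambda p: stem_phrase(p, stem_fn))
    if groups is None:
        basis = stemmed if group_on_stemmed else ent.adr_phrase.map(identity_stemmer)
        groups = group_adr_terms(basis)
    phrase_to_group: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            phrase_to_group[m] = g.group_id
    lookup_key = stemmed if group_on_stemmed else ent.adr_phrase.map(identity_stemmer)
    missing = set(lookup_key) - set(phrase_to_group)
    if missing:
        raise ValueError(f"groups do not cover phrases: {sorted(missing)[:5]}")
    gid = lookup_key.map(phrase_to_group)

    occ = pd.DataFrame(0, index=pd.Index(keep_drugs, name="drug_id"),
                       columns=sorted(set(phrase_to_group.values())), dtype=int)
    for d, g in zip(ent.drug_id, gid):
        occ.loc[d, g] = 1

    support = occ.sum(axis=0)
    cap = max_support_cap(len(keep_drugs), max_frac)
    keep_cols = support[(support >= min_drugs) & (support <= cap)].index
    occ = occ[sorted(keep_cols)]
    kept_groups = [g for g in groups if g.group_id in set(occ.columns)]
    return ADRMatrix(occurrence=occ, groups=kept_groups)
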