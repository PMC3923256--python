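"""Training-set construction: drug-likeness filtering and similarity-stratified pair selection.

The procedure mirrors how a calibration set for expert similarity assessment
is assembled from a drug database: keep molecules satisfying rule-of-five
style bounds (and at least one carbon), score every distinct pair under a
reference fingerprint, then pick pairs so that the full Tanimoto range is
covered as evenly as possible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fingerprints import (
    REFERENCE_SCHEME,
    MoleculeRecord,
    SimilarityProfile,
    pair_similarity_table,
)


@dataclass(frozen=True)
class FilterRule:
    """Drug-likeness bounds; comparisons are inclusive."""

    max_hba: int = 10
    max_hbd: int = 5
    max_mw: float = 500.0
    max_logp: float = 5.0
    min_carbon: int = 1


def filter_druglike(mols: list[MoleculeRecord], rule: FilterRule = FilterRule()) -> list[MoleculeRecord]:
    """Retain exactly the records satisfying every bound, in stable order."""
    return [
        m
        for m in mols
        if m.n_hba <= rule.max_hba
        and m.n_hbd <= rule.max_hbd
        and m.mol_weight <= rule.max_mw
        and m.logp <= rule.max_logp
        and m.n_carbon >= rule.min_carbon
    ]


def all_pair_profiles(
    mols: list[MoleculeRecord], schemes=(REFERENCE_SCHEME,)
) -> list[SimilarityProfile]:
    """Similarity profiles for every distinct (unordered) molecule pair."""
    pairs = list(itertools.combinations(mols, 2))
    return pair_similarity_table(pairs, schemes=schemes)


def select_stratified_pairs(
    profiles: list[SimilarityProfile],
    n_pairs: int,
    n_bins: int = 10,
    seed: int = 0,
    scheme: str = REFERENCE_SCHEME,
) -> list[SimilarityProfile]:
    """Select ``n_pairs`` profiles spread as evenly as possible over the similarity range.

    The observed range [min, max] on ``scheme`` is split into ``n_bins``
    equal-width bins; each bin contributes its share of the selection,
    sampled without replacement.  When a bin holds fewer candidates than its
    quota, the shortfall is redistributed to the nearest bins that still have
    spare candidates, which preserves the spread as far as the data allow.
    Deterministic for a fixed seed; no unordered molecule pair is repeated.
    """
    if n_bins < 1 or n_pairs < n_bins:
        raise ValueError("need n_pairs >= n_bins >= 1")
    # drop duplicated unordered pairs, keeping first occurrence
    seen: set[frozenset[str]] = set()
    candidates: list[SimilarityProfile] = []
    for p in profiles:
        key = frozenset((p.molecule_a_id, p.molecule_b_id))
        if key not in seen:
            seen.add(key)
            candidates.append(p)
    if not candidates:
        raise ValueError("no candidate pairs")
    if len(candidates) < n_pairs:
        raise ValueError(
            f"insufficient candidate pairs: need {n_pairs}, have {len(candidates)} "
            f"(deficit {n_pairs - len(candidates)})"
        )
    sims = np.array([p.similarities[scheme] for p in candidates])
    lo, hi = float(sims.min()), float(sims.max())
    if math.isclose(lo, hi):
        edges = np.array([lo, hi])
        bin_of = np.zeros(len(sims), dtype=int)
        n_eff = 1
        warnings.warn("all candidate similarities fall in a single bin", stacklevel=2)
    else:
        n_eff = n_bins
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_of = np.clip(np.digitize(sims, edges[1:-1]), 0, n_bins - 1)
        occupied = np.unique(bin_of)
        if occupied.size == 1:
            warnings.warn("all candidate similarities fall in a single bin", stacklevel=2)

    members = [np.flatnonzero(bin_of == b) for b in range(n_eff)]
    avail = np.array([len(m) for m in members])
    # base quota: n_pairs // n_bins everywhere, remainder spread from the low end
    quota = np.full(n_eff, n_pairs // n_eff)
    quota[: n_pairs % n_eff] += 1
    take = np.minimum(quota, avail)
    # redistribute each unit of shortfall to the nearest bin with spare candidates
    deficits = quota - take
    for src in range(n_eff):
        for _ in range(int(deficits[src])):
            spare = np.flatnonzero(avail > take)
            dest = spare[np.argmin(np.abs(spare - src))]
            take[dest] += 1

    rng = np.random.default_rng(seed)
    selected_idx: list[int] = []
    for b in range(n_eff):
        if take[b] > 0:
            selected_idx.extend(rng.choice(members[b], size=take[b], replace=False))
    selected_idx.sort()
    return [candidates[i] for i in selected_idx]
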