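"""Consensus fusion of per-fingerprint similarity classifications.

Each fingerprint scheme classifies a molecule pair as similar when its
Tanimoto similarity meets that scheme's threshold (t_LR or t_ROC); the
consensus verdict is "similar" when at least ``min_votes`` schemes agree
(default: three or more).  Pairs missing a similarity for any configured
scheme are excluded from the consensus with a warning rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .calibration import label_majority
from .fingerprints import SimilarityProfile

__all__ = ["ConsensusConfig", "classify_pair", "consensus_vote", "count_correct"]

CONSENSUS_ROW = "Consensus"


@dataclass
class ConsensusConfig:
    schemes: list[str]
    thresholds: dict[str, tuple[float, float]]  # scheme -> (t_lr, t_roc)
    min_votes: int = 3
    threshold_kind: str = "lr"  # "lr" or "roc"

    def __post_init__(self) -> None:
        if not 1 <= self.min_votes <= len(self.schemes):
            raise ValueError("min_votes must lie in [1, number of schemes]")
        if self.threshold_kind not in ("lr", "roc"):
            raise ValueError("threshold_kind must be 'lr' or 'roc'")
        missing = [s for s in self.schemes if s not in self.thresholds]
        if missing:
            raise ValueError(f"no thresholds for schemes: {missing}")

    def threshold_for(self, scheme: str, kind: str | None = None) -> float:
        t_lr, t_roc = self.thresholds[scheme]
        return t_lr if (kind or self.threshold_kind) == "lr" else t_roc


def classify_pair(profile: SimilarityProfile, scheme: str, threshold: float) -> bool:
    """Similar iff the pair's similarity under ``scheme`` is >= threshold."""
    if scheme not in profile.similarities:
        raise ValueError(f"pair {profile.pair_id!r} carries no similarity for scheme {scheme!r}")
    return profile.similarities[scheme] >= threshold


def consensus_vote(labels: list[bool], min_votes: int) -> bool:
    """Similar iff at least ``min_votes`` of the individual labels are similar."""
    if not labels:
        raise ValueError("empty label list")
    return sum(bool(v) for v in labels) >= min_votes


def _reference_label(profile: SimilarityProfile) -> bool:
    if profile.majority_label is not None:
        return profile.majority_label
    if profile.yes_fraction is not None:
        return label_majority(profile.yes_fraction)
    raise ValueError(f"pair {profile.pair_id!r} is unlabeled")


def count_correct(profiles: list[SimilarityProfile], config: ConsensusConfig) -> pd.DataFrame:
    """Correct-prediction counts per scheme and for the consensus, under both thresholds.

    Returns a frame indexed by scheme (plus a final ``Consensus`` row) with
    columns ``t_LR`` and ``t_ROC``.  Per-scheme counts use every pair that
    carries that scheme's similarity; the consensus row uses only pairs that
    carry all configured schemes.
    """
    if not profiles:
        raise ValueError("no profiles to evaluate")
    truth = {p.pair_id: _reference_label(p) for p in profiles}
    counts: dict[str, dict[str, int]] = {}
    for kind, col in (("lr", "t_LR"), ("roc", "t_ROC")):
        for scheme in config.schemes:
            correct = sum(
                classify_pair(p, scheme, config.threshold_for(scheme, kind)) == truth[p.pair_id]
                for p in profiles
                if scheme in p.similarities
            )
            counts.setdefault(scheme, {})[col] = correct
        consensus_correct = 0
        skipped = []
        for p in profiles:
            missing = [s for s in config.schemes if s not in p.similarities]
            if missing:
                skipped.append(p.pair_id)
                continue
            votes = [classify_pair(p, s, config.threshold_for(s, kind)) for s in config.schemes]
            if consensus_vote(votes, config.min_votes) == truth[p.pair_id]:
                consensus_correct += 1
        counts.setdefault(CONSENSUS_ROW, {})[col] = consensus_correct
        if skipped and kind == "lr":
            warnings.warn(
                f"{len(skipped)} pair(s) excluded from consensus for missing scheme "
                f"similarities: {skipped[:5]}",
                stacklevel=2,
            )
    index = list(config.schemes) + [CONSENSUS_ROW]
    return pd.DataFrame(counts).T.loc[index][["t_LR", "t_ROC"]]
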