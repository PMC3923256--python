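"""Synthetic molecule-pair sets and heterogeneous expert-panel votes.

The generator emulates the statistical structure the calibration pipeline
assumes: ~100 molecule pairs spanning the Tanimoto range ≈0.12–1.00, judged
by a ~143-member panel whose members differ in their propensity to call a
pair similar.  Panel heterogeneity enters through per-expert random
intercept offsets on the population logit

    logit p_j(s) = beta0_true + delta_j + beta1_true * 10 * s,
    delta_j ~ Normal(0, expert_sd^2),

with each expert casting an independent Bernoulli vote per pair.  With the
default heterogeneity the distribution of per-pair Yes-fractions is bimodal:
most pairs draw near-unanimous verdicts at either end, with a thin band of
genuine disagreement in between.

Two similarity sources are available.  ``abstract-grid`` places pair
similarities on an even grid over [0.116, 1.0] with jitter, split around the
population threshold so that a target fraction of pairs is
majority-similar.  ``analog-series`` computes real fingerprint Tanimoto
values over enumerated substituent variants of a handful of drug-like
scaffolds (benzodiazepine-, beta-blocker-, sulfonamide- and salicylate-like
cores), so every fingerprint scheme sees chemically coherent structure with
no external data dependency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import dataset
from .calibration import label_majority
from .fingerprints import (
    ALL_SCHEMES,
    REFERENCE_SCHEME,
    SimilarityProfile,
    pair_similarity_table,
    parse_molecule,
)

__all__ = [
    "PanelSimConfig",
    "simulate_similarities",
    "simulate_votes",
    "simulate_trainset",
    "simulate_testset",
    "ANALOG_SERIES",
]

#: synthetic analog series: hard-coded scaffold variants, one list per family
ANALOG_SERIES: dict[str, list[str]] = {
    "bzd": [  # benzodiazepine-like
        "O=C1CN=C(c2ccccc2)c2ccccc2N1",
        "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
        "O=C1CN=C(c2ccccc2)c2cc(F)ccc2N1",
        "O=C1CN=C(c2ccccc2)c2cc([N+](=O)[O-])ccc2N1",
        "CN1C(=O)CN=C(c2ccccc2F)c2cc(Cl)ccc21",
    ],
    "bblk": [  # beta-blocker-like aryloxypropanolamines
        "CC(C)NCC(O)COc1ccccc1",
        "CC(C)NCC(O)COc1ccc(O)cc1",
        "CC(C)(C)NCC(O)COc1ccccc1",
        "CCC(C)NCC(O)COc1ccccc1",
        "CC(C)NCC(O)COc1ccccc1C",
        "CC(C)NCC(O)COc1ccc(C)cc1",
    ],
    "sulfa": [  # sulfonamide-like
        "NS(=O)(=O)c1ccc(N)cc1",
        "CNS(=O)(=O)c1ccc(N)cc1",
        "NS(=O)(=O)c1ccc(Cl)cc1",
        "NS(=O)(=O)c1ccccc1",
    ],
    "sal": [  # salicylate-like
        "CC(=O)Oc1ccccc1C(=O)O",
        "Oc1ccccc1C(=O)O",
        "COc1ccccc1C(=O)O",
        "CC(=O)Oc1ccc(C)cc1C(=O)O",
    ],
}

ABSTRACT_GRID = "abstract-grid"
ANALOG = "analog-series"

#: similarity range the abstract grid covers
_SIM_LO, _SIM_HI = 0.116, 1.0


@dataclass
class PanelSimConfig:
    """Generator parameters for one simulated study."""

    n_pairs: int = 100
    n_experts: int = 143
    beta0_true: float = -12.75  # population log-odds intercept (0.1-similarity scale)
    beta1_true: float = 2.5  # population log-odds slope per 0.1 similarity
    expert_sd: float = 2.0  # SD of per-expert intercept offsets
    similarity_source: str = ABSTRACT_GRID
    prevalence_target: float = 0.49  # fraction of majority-similar pairs (test mode: 0.11)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if self.expert_sd < 0:
            raise ValueError("expert_sd must be >= 0")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must lie in (0, 1)")
        if self.similarity_source not in (ABSTRACT_GRID, ANALOG):
            raise ValueError(f"unknown similarity_source {self.similarity_source!r}")

    @property
    def t_true(self) -> float:
        """Similarity at which the population model crosses probability 0.5 (nan if flat)."""
        if self.beta1_true <= 0:
            return float("nan")
        return -self.beta0_true / (10.0 * self.beta1_true)


def _rng(config: PanelSimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _grid_similarities(config: PanelSimConfig) -> np.ndarray:
    """Even coverage of [0.116, 1.0] with jitter, split around t_true.

    The grid is laid out as two sub-grids on either side of the population
    threshold, sized so that a ``prevalence_target`` fraction of pairs falls
    on the similar side; jitter stays within each point's grid cell, so the
    intended class split survives.
    """
    rng = _rng(config, 0)
    n = config.n_pairs
    if not np.isfinite(config.t_true):  # flat population model: plain even grid
        pts = np.linspace(_SIM_LO, _SIM_HI, n)
        half = 0.45 * (_SIM_HI - _SIM_LO) / max(n - 1, 1)
        return np.sort(np.clip(pts + rng.uniform(-half, half, n), _SIM_LO, _SIM_HI))
    t = float(np.clip(config.t_true, _SIM_LO + 0.05, _SIM_HI - 0.05))
    # keep grid points just off the threshold; large margins would hollow out
    # the genuine-disagreement band the panel model is meant to produce
    margin = 0.005
    n_hi = int(round(config.prevalence_target * n))
    n_lo = n - n_hi
    segments = []
    for count, lo, hi in ((n_lo, _SIM_LO, t - margin), (n_hi, t + margin, _SIM_HI)):
        if count == 0:
            continue
        pts = np.linspace(lo, hi, count)
        half = 0.45 * (hi - lo) / max(count - 1, 1)
        pts = np.clip(pts + rng.uniform(-half, half, count), lo, hi)
        segments.append(pts)
    return np.sort(np.concatenate(segments))


def _analog_profiles(config: PanelSimConfig, schemes) -> list[SimilarityProfile]:
    mols = [
        parse_molecule(smi, f"{family}-{i}")
        for family, smis in ANALOG_SERIES.items()
        for i, smi in enumerate(smis)
    ]
    pairs = list(itertools.combinations(mols, 2))
    pairs += [(m, m) for m in mols[:4]]  # a few self-pairs anchor similarity 1.0
    profiles = pair_similarity_table(pairs, schemes=schemes)
    if config.n_pairs > len(profiles):
        raise ValueError(
            f"analog series enumerates only {len(profiles)} pairs; "
            f"requested {config.n_pairs}"
        )
    return dataset.select_stratified_pairs(
        profiles, n_pairs=config.n_pairs, n_bins=10, seed=config.seed, scheme=REFERENCE_SCHEME
    )


def simulate_similarities(config: PanelSimConfig) -> np.ndarray:
    """Pair similarity values under the configured source; deterministic per seed."""
    if config.similarity_source == ABSTRACT_GRID:
        return _grid_similarities(config)
    profiles = _analog_profiles(config, (REFERENCE_SCHEME,))
    return np.array([p.similarities[REFERENCE_SCHEME] for p in profiles])


def simulate_votes(
    similarities, config: PanelSimConfig, stream: int = 1
) -> np.ndarray:
    """Per-pair Yes-fractions from a heterogeneous panel of independent voters."""
    s = np.asarray(similarities, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("similarities must lie in [0, 1]")
    rng = _rng(config, stream)
    delta = rng.normal(0.0, config.expert_sd, config.n_experts)
    p = expit(config.beta0_true + delta[:, None] + config.beta1_true * 10.0 * s[None, :])
    votes = rng.random(p.shape) < p
    return votes.mean(axis=0)


def _attach_scheme_similarities(
    base: np.ndarray, schemes, config: PanelSimConfig, stream: int
) -> list[dict[str, float]]:
    """Per-scheme similarities as the base value plus small correlated jitter.

    Emulates the high but imperfect agreement between fingerprint schemes;
    the reference scheme carries the base value exactly.
    """
    rng = _rng(config, stream)
    out: list[dict[str, float]] = [{} for _ in base]
    for scheme in schemes:
        if scheme == REFERENCE_SCHEME:
            vals = base
        else:
            vals = np.clip(base + rng.normal(0.0, 0.02, base.size), 0.0, 1.0)
        for d, v in zip(out, vals):
            d[scheme] = float(v)
    return out


def simulate_trainset(
    config: PanelSimConfig, schemes=(REFERENCE_SCHEME,)
) -> list[SimilarityProfile]:
    """A labelled training set: similarity profiles with panel Yes-fractions."""
    if config.similarity_source == ANALOG:
        profiles = _analog_profiles(config, schemes)
        base = np.array([p.similarities[REFERENCE_SCHEME] for p in profiles])
    else:
        base = simulate_similarities(config)
        sims = _attach_scheme_similarities(base, schemes, config, stream=3)
        profiles = [
            SimilarityProfile(
                pair_id=f"train-{i:03d}",
                molecule_a_id=f"mol-{i:03d}a",
                molecule_b_id=f"mol-{i:03d}b",
                similarities=sims[i],
            )
            for i in range(base.size)
        ]
    fractions = simulate_votes(base, config, stream=1)
    for prof, frac in zip(profiles, fractions):
        prof.yes_fraction = float(frac)
        prof.majority_label = label_majority(float(frac))
    return profiles


def simulate_testset(
    config: PanelSimConfig, schemes=(REFERENCE_SCHEME,)
) -> list[SimilarityProfile]:
    """An imbalanced labelled test set, labels drawn from the same vote model.

    Pair similarities are sampled uniformly on either side of the population
    threshold (with a small guard margin), with the similar side drawn with
    probability ``prevalence_target`` — mimicking an external evaluation set
    dominated by non-similar pairs.
    """
    rng = _rng(config, 2)
    t = float(np.clip(config.t_true, 0.15, 0.85))
    margin = 0.07
    hi_side = rng.random(config.n_pairs) < config.prevalence_target
    base = np.where(
        hi_side,
        rng.uniform(t + margin, 1.0, config.n_pairs),
        rng.uniform(0.03, t - margin, config.n_pairs),
    )
    sims = _attach_scheme_similarities(base, schemes, config, stream=5)
    fractions = simulate_votes(base, config, stream=4)
    profiles = []
    for i in range(config.n_pairs):
        frac = float(fractions[i])
        profiles.append(
            SimilarityProfile(
                pair_id=f"test-{i:03d}",
                molecule_a_id=f"tmol-{i:03d}a",
                molecule_b_id=f"tmol-{i:03d}b",
                similarities=sims[i],
                yes_fraction=frac,
                majority_label=label_majority(frac),
            )
        )
    return profiles
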