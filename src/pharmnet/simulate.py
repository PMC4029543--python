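"""Synthetic drug-target interaction data with planted associations.

The generator emulates the statistical structure the method assumes, at a
desk scale: sparse binary side-effect and domain profiles, an interaction
label for every (drug, protein) pair drawn from a logistic model over a small
set of planted (side effect, domain) associations,

    Pr(y_ij = +1) = 1 / (1 + exp(-(sum_planted beta * d_i p_j + b))),

with labels then flipped at a small noise rate, and chemical fingerprints
organised into lead series: each series has one random base pattern and each
member flips every bit independently at a small rate, producing the
within-series Tanimoto redundancy that the benchmark-construction clustering
is designed to remove.

Every random component draws from its own sub-stream of the master seed, so
adding a component never perturbs earlier draws and two runs with the same
seed are identical field for field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import InteractionDataset, ProfileMatrix

__all__ = ["SimConfig", "SimTruth", "SimData", "generate", "recovery_score"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 80 drugs x 60 proteins, 30 side effects, 20 domains, 64
    fingerprint bits, 5 planted associations of effect size 4 and an
    intercept calibrated so about 5% of pairs interact — a scaled-down
    likeness of a curated gold standard (hundreds of drugs/proteins,
    profile dimensions in the hundreds-to-thousands, <1% positive pairs).
    Profile densities put a handful of on-bits in each entity's profile,
    mirroring the sparsity of real side-effect and domain annotations.
    """

    n_drugs: int = 80
    n_proteins: int = 60
    n_side_effects: int = 30
    n_domains: int = 20
    n_fp_bits: int = 64
    se_density: float = 0.15
    domain_density: float = 0.10
    fp_base_density: float = 0.30
    n_planted: int = 5
    effect_size: float = 4.0
    intercept: float | None = None  # None: calibrate to target_positive_rate
    target_positive_rate: float = 0.05
    label_noise: float = 0.01
    n_lead_series: int = 8
    fp_flip_rate: float = 0.05
    planted_pairs: tuple[tuple[int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.n_side_effects, self.n_domains) < 1:
            raise ValueError("entity and feature counts must be positive")
        if self.n_planted > self.n_side_effects * self.n_domains:
            raise ValueError("n_planted exceeds the number of (se, domain) pairs")
        for name in ("se_density", "domain_density", "fp_base_density",
                     "label_noise", "fp_flip_rate", "target_positive_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.n_lead_series < 1 or self.n_lead_series > self.n_drugs:
            raise ValueError("n_lead_series must be in [1, n_drugs]")
        if self.planted_pairs is not None and len(self.planted_pairs) != self.n_planted:
            raise ValueError("planted_pairs length must equal n_planted")


@dataclass
class SimTruth:
    """Everything needed to score recovery against the generator's ground truth."""

    planted: list[tuple[str, str, float]]  # (side effect, domain, beta)
    intercept: float
    interaction_probs: np.ndarray = field(repr=False)  # drugs x proteins
    lead_series: dict[str, int] = field(default_factory=dict)

    @property
    def planted_identities(self) -> set[tuple[str, str]]:
        return {(se, dom) for se, dom, _ in self.planted}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "planted": self.planted,
                    "intercept": self.intercept,
                    "interaction_probs": self.interaction_probs.tolist(),
                    "lead_series": self.lead_series,
                }
            )
            + "\n"
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            [tuple(p) for p in d["planted"]],
            d["intercept"],
            np.asarray(d["interaction_probs"]),
            d["lead_series"],
        )


@dataclass
class SimData:
    """One generated dataset: profiles, interactions and the ground truth."""

    side_effects: ProfileMatrix  # drugs x side effects
    fingerprints: ProfileMatrix  # drugs x fingerprint bits
    domains: ProfileMatrix  # proteins x domains
    interactions: InteractionDataset
    truth: SimTruth
    config: SimConfig

    def write(self, out_dir: str | Path) -> None:
        """Write the TSV formats the readers consume, plus the truth JSON."""
        from .data import write_interactions, write_profile_matrix

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_profile_matrix(self.side_effects, out / "side_effects.tsv")
        write_profile_matrix(self.fingerprints, out / "fingerprints.tsv")
        write_profile_matrix(self.domains, out / "domains.tsv")
        write_interactions(self.interactions, out / "interactions.tsv")
        self.truth.save_json(out / "truth.json")
        (out / "sim_config.json").write_text(
            json.dumps(asdict(self.config), default=list) + "\n"
        )


def _bernoulli(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    return (rng.random(shape) < rate).astype(np.int8)


def generate(config: SimConfig) -> SimData:
    """Draw one dataset under the configured study conditions."""
    ss = np.random.SeedSequence(config.seed)
    s_se, s_dom, s_plant, s_label, s_noise, s_fp = ss.spawn(6)

    drug_ids = [f"D{i+1:04d}" for i in range(config.n_drugs)]
    protein_ids = [f"P{j+1:04d}" for j in range(config.n_proteins)]
    se_names = [f"se_{k+1:03d}" for k in range(config.n_side_effects)]
    dom_names = [f"dom_{k+1:03d}" for k in range(config.n_domains)]
    fp_names = [f"fp_{k+1:03d}" for k in range(config.n_fp_bits)]

    D = _bernoulli(np.random.default_rng(s_se), (config.n_drugs, config.n_side_effects),
                   config.se_density)
    P = _bernoulli(np.random.default_rng(s_dom), (config.n_proteins, config.n_domains),
                   config.domain_density)

    if config.planted_pairs is not None:
        planted_idx = list(config.planted_pairs)
    else:
        rng_p = np.random.default_rng(s_plant)
        flat = rng_p.choice(
            config.n_side_effects * config.n_domains, size=config.n_planted, replace=False
        )
        planted_idx = [(int(k) // config.n_domains, int(k) % config.n_domains) for k in flat]

    # linear predictor over all pairs from the planted associations
    B = np.zeros((config.n_side_effects, config.n_domains))
    for i, j in planted_idx:
        B[i, j] = config.effect_size
    scores = D.astype(float) @ B @ P.astype(float).T  # drugs x proteins

    if config.intercept is None:
        b = _calibrate_intercept(scores, config.target_positive_rate)
    else:
        b = float(config.intercept)
    probs = expit(scores + b)

    rng_y = np.random.default_rng(s_label)
    y = rng_y.random(probs.shape) < probs
    noise_mask = np.random.default_rng(s_noise).random(probs.shape) < config.label_noise
    y = np.logical_xor(y, noise_mask)

    positive_pairs = {
        (drug_ids[i], protein_ids[j]) for i, j in zip(*np.nonzero(y))
    }

    rng_fp = np.random.default_rng(s_fp)
    bases = _bernoulli(rng_fp, (config.n_lead_series, config.n_fp_bits),
                       config.fp_base_density)
    series_of = {drug_ids[i]: i % config.n_lead_series for i in range(config.n_drugs)}
    flips = _bernoulli(rng_fp, (config.n_drugs, config.n_fp_bits), config.fp_flip_rate)
    FP = np.array(
        [np.logical_xor(bases[series_of[d]], flips[i]) for i, d in enumerate(drug_ids)],
        dtype=np.int8,
    )

    truth = SimTruth(
        planted=[(se_names[i], dom_names[j], float(config.effect_size))
                 for i, j in planted_idx],
        intercept=b,
        interaction_probs=probs,
        lead_series=series_of,
    )
    return SimData(
        side_effects=ProfileMatrix.from_dense(drug_ids, se_names, D),
        fingerprints=ProfileMatrix.from_dense(drug_ids, fp_names, FP),
        domains=ProfileMatrix.from_dense(protein_ids, dom_names, P),
        interactions=InteractionDataset.build(drug_ids, protein_ids, positive_pairs),
        truth=truth,
        config=config,
    )


def _calibrate_intercept(scores: np.ndarray, target_rate: float) -> float:
    """Solve mean(sigmoid(scores + b)) = target_rate for b (monotone in b)."""

    def gap(b):
        return float(expit(scores + b).mean() - target_rate)

    return float(brentq(gap, -60.0, 60.0, xtol=1e-10))


def recovery_score(extracted: Sequence, truth: SimTruth, top_n: int) -> float:
    """Fraction of planted (se, domain) pairs among the top_n extracted features.

    ``extracted`` is a weight-sorted feature list as produced by
    ``extract_features``; monotone non-decreasing in ``top_n``.
    """
    if top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    planted = truth.planted_identities
    if not planted:
        raise ValueError("truth contains no planted pairs")
    top = {(f.side_effect, f.domain) for f in list(extracted)[:top_n]}
    return len(top & planted) / len(planted)
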