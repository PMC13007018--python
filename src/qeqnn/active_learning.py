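"""Query-by-committee active learning.

The first batch is seeded by greedy farthest-point selection on per-element
averaged (scaled) descriptor vectors; every later round scores the entire
remaining candidate pool by the committee force disagreement sigma_F
(aggregated per configuration, maximum over atoms by default), labels the
top ``configs_per_round`` with the oracle, and retrains all members from
their current weights with the quick-train epoch budget.  No configuration
is ever selected twice.

A one-sided harmonic bias in the aggregated disagreement,
E_bias = k (sigma_max - sigma_0)^2 for sigma_max > sigma_0, can be added to
sampling dynamics to keep trajectories out of regions the committee cannot
yet describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_types import AtomicConfiguration, LabeledConfiguration
from .descriptors import fit_scaling
from .model import (
    ConfigRecord,
    FourthGenCommittee,
    TrainingConfig,
)

__all__ = [
    "ALConfig",
    "BiasParameters",
    "CandidatePool",
    "farthest_point_select",
    "config_disagreement",
    "al_round",
    "run_active_learning",
    "bias_energy_forces",
    "BiasedPotential",
    "generation_protocol",
]


@dataclass
class BiasParameters:
    sigma0: float = 0.5  # eV/A disagreement threshold
    strength: float = 5.0  # eV per (eV/A)^2
    neighborhood: float = 4.0  # A around the worst atom for FD forces
    fd_step: float = 1e-3  # A

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")


@dataclass
class ALConfig:
    configs_per_round: int = 20
    rounds: int = 5
    committee_size: int = 4
    quick_epochs: int = 15
    aggregation: str = "max"  # or "mean"
    bias: BiasParameters = field(default_factory=BiasParameters)
    seed: int = 0

    def __post_init__(self):
        if self.configs_per_round < 1:
            raise ValueError("configs_per_round must be >= 1")


class CandidatePool:
    """Unlabeled candidates with selection bookkeeping and cached records."""

    def __init__(
        self,
        configurations: Sequence[AtomicConfiguration],
        provenance: Optional[Sequence[str]] = None,
    ):
        self.configurations = list(configurations)
        self.provenance = list(provenance) if provenance else [""] * len(self.configurations)
        self.selected: List[int] = []
        self.scores = np.full(len(self.configurations), np.nan)
        self._records: Dict[int, ConfigRecord] = {}

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def remaining(self) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        mask[self.selected] = False
        return np.where(mask)[0]

    def record(self, i: int, committee: FourthGenCommittee) -> ConfigRecord:
        if i not in self._records:
            self._records[i] = ConfigRecord(
                self.configurations[i], committee.sf_set, committee.qeq_params
            )
        return self._records[i]

    def mark_selected(self, indices: Sequence[int]) -> None:
        for i in indices:
            if i in self.selected:
                raise ValueError(f"configuration {i} was already selected")
            self.selected.append(int(i))


def farthest_point_select(
    features: np.ndarray, k: int, start: Optional[int] = None
) -> List[int]:
    """Greedy max-min selection of k rows; deterministic, ties -> lowest index.

    The first pick is the point farthest from the feature centroid (or
    ``start``); each later pick maximizes its minimum distance to the
    already-picked set.
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"cannot select {k} items from a pool of {n}")
    if k == 0:
        return []
    if start is None:
        d0 = np.linalg.norm(X - X.mean(axis=0), axis=1)
        start = int(np.argmax(np.round(d0, 12)))
    picked = [start]
    dmin = np.linalg.norm(X - X[start], axis=1)
    while len(picked) < k:
        nxt = int(np.argmax(np.round(dmin, 12)))
        picked.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(X - X[nxt], axis=1))
    return picked


def pool_features(
    pool: CandidatePool, committee: FourthGenCommittee
) -> np.ndarray:
    """Per-config feature: concatenated per-element mean descriptor vectors."""
    sf = committee.sf_set
    if not sf.scaled:
        fit_scaling(pool.configurations, sf)
    rows = []
    for i in range(len(pool)):
        rec = pool.record(i, committee)
        gs = rec.scaled_descriptors(sf)
        parts = [
            gs[e].mean(axis=0) if e in gs else np.zeros(sf.n_functions(e))
            for e in sf.elements
        ]
        rows.append(np.concatenate(parts))
    return np.array(rows)


def config_disagreement(
    committee: FourthGenCommittee,
    config,
    aggregation: str = "max",
) -> float:
    """One disagreement score per configuration from per-atom sigma_F."""
    if committee.n < 2:
        raise ValueError("disagreement is undefined for a single-member committee")
    pred = committee.predict(config)
    if aggregation == "max":
        return float(pred.sigma_f.max())
    if aggregation == "mean":
        return float(pred.sigma_f.mean())
    raise ValueError(f"unknown aggregation {aggregation!r}")


def al_round(
    pool: CandidatePool,
    committee: FourthGenCommittee,
    oracle: Callable[[AtomicConfiguration], LabeledConfiguration],
    al_config: ALConfig,
    dataset: List[LabeledConfiguration],
    training: Optional[TrainingConfig] = None,
) -> Dict:
    """One QbC round: score remaining pool, label top picks, quick-retrain."""
    remaining = pool.remaining
    if len(remaining) == 0:
        import warnings

        warnings.warn("candidate pool exhausted; nothing to select")
        return {"selected": [], "scores": []}
    scores = np.array(
        [
            config_disagreement(
                committee, pool.record(i, committee), al_config.aggregation
            )
            for i in remaining
        ]
    )
    pool.scores[remaining] = scores
    n_take = min(al_config.configs_per_round, len(remaining))
    if n_take < al_config.configs_per_round:
        import warnings

        warnings.warn("pool smaller than configs_per_round; taking what remains")
    # stable sort => ties broken by pool index
    order = np.argsort(-np.round(scores, 12), kind="stable")[:n_take]
    chosen = [int(remaining[j]) for j in order]
    pool.mark_selected(chosen)
    for i in chosen:
        dataset.append(oracle(pool.configurations[i]))
    tc = training or TrainingConfig(
        epochs_elec=al_config.quick_epochs, epochs_short=al_config.quick_epochs
    )
    committee.train(dataset, tc, warm_start=True)
    return {
        "selected": chosen,
        "scores": [float(pool.scores[i]) for i in chosen],
        "train_size": len(dataset),
    }


def run_active_learning(
    pool: CandidatePool,
    oracle: Callable[[AtomicConfiguration], LabeledConfiguration],
    committee: FourthGenCommittee,
    al_config: ALConfig,
    training: Optional[TrainingConfig] = None,
) -> Tuple[FourthGenCommittee, List[LabeledConfiguration], List[Dict]]:
    """Farthest-point seeding followed by ``rounds`` disagreement rounds."""
    feats = pool_features(pool, committee)
    first = farthest_point_select(feats, min(al_config.configs_per_round, len(pool)))
    pool.mark_selected(first)
    dataset = [oracle(pool.configurations[i]) for i in first]
    tc = training or TrainingConfig(
        epochs_elec=al_config.quick_epochs, epochs_short=al_config.quick_epochs
    )
    committee.train(dataset, tc, warm_start=False)
    records = [{"selected": list(first), "scores": None, "train_size": len(dataset)}]
    for _ in range(al_config.rounds):
        rec = al_round(pool, committee, oracle, al_config, dataset, training=tc)
        records.append(rec)
        if not rec["selected"]:
            break
    return committee, dataset, records


# ---------------------------------------------------------------------------
# disagreement bias potential
# ---------------------------------------------------------------------------


def _bias_energy(committee, config, params: BiasParameters, aggregation="max"):
    pred = committee.predict(config)
    smax = float(pred.sigma_f.max()) if aggregation == "max" else float(pred.sigma_f.mean())
    worst = int(np.argmax(pred.sigma_f))
    if smax <= params.sigma0:
        return 0.0, smax, worst
    return params.strength * (smax - params.sigma0) ** 2, smax, worst


def bias_energy_forces(
    committee: FourthGenCommittee,
    config: AtomicConfiguration,
    params: BiasParameters,
) -> Tuple[float, np.ndarray]:
    """One-sided harmonic disagreement bias and its finite-difference forces.

    Zero (with zero slope, C^1) at and below sigma_0.  Forces are central
    finite differences restricted to atoms within ``neighborhood`` of the
    highest-disagreement atom -- the bias only needs to push that local
    environment back toward configurations the committee agrees on.
    """
    if committee.n < 2:
        raise ValueError("bias requires a committee of at least two members")
    e0, smax, worst = _bias_energy(committee, config, params)
    forces = np.zeros((config.n_atoms, 3))
    if e0 == 0.0:
        return 0.0, forces
    ref = config.positions[worst]
    dist = np.linalg.norm(config.positions - ref, axis=1)
    active = np.where(dist <= params.neighborhood)[0]
    h = params.fd_step
    for a in active:
        for c in range(3):
            for sgn in (1.0, -1.0):
                pos = config.positions.copy()
                pos[a, c] += sgn * h
                e, _, _ = _bias_energy(committee, config.with_positions(pos), params)
                forces[a, c] -= sgn * e / (2.0 * h)
    return e0, forces


class BiasedPotential:
    """Committee potential plus the disagreement bias (for sampling runs)."""

    def __init__(self, committee: FourthGenCommittee, params: BiasParameters):
        self.committee = committee
        self.params = params

    def energy_forces(self, config: AtomicConfiguration):
        pred = self.committee.predict(config)
        smax = float(pred.sigma_f.max())
        if smax <= self.params.sigma0:
            return pred.energy, pred.forces
        e_b, f_b = bias_energy_forces(self.committee, config, self.params)
        return pred.energy + e_b, pred.forces + f_b

    def charges(self, config: AtomicConfiguration):
        return self.committee.predict(config).charges


# ---------------------------------------------------------------------------
# multi-generation protocol
# ---------------------------------------------------------------------------


def generation_protocol(
    stages: Sequence[Dict],
    oracle: Callable[[AtomicConfiguration], LabeledConfiguration],
    committee: FourthGenCommittee,
    final_training: Optional[TrainingConfig] = None,
) -> Tuple[FourthGenCommittee, List[Dict]]:
    """Staged training: sample -> pool -> QbC rounds -> final long training.

    Each stage dict provides ``pool`` (a sequence of configurations or a
    callable committee -> configurations, so later generations can sample
    with the current models and more beads) and optionally ``al`` (an
    ALConfig).  The training set accumulates across generations.
    """
    final_training = final_training or TrainingConfig(epochs_elec=50, epochs_short=100)
    dataset: List[LabeledConfiguration] = []
    history: List[Dict] = []
    for g, stage in enumerate(stages):
        source = stage["pool"]
        configs = source(committee) if callable(source) else list(source)
        if len(configs) == 0:
            raise ValueError(f"generation {g}: sampler produced an empty pool")
        pool = CandidatePool(configs, provenance=[f"gen{g}"] * len(configs))
        al_config = stage.get("al", ALConfig())
        feats = pool_features(pool, committee)
        first = farthest_point_select(
            feats, min(al_config.configs_per_round, len(pool))
        )
        pool.mark_selected(first)
        dataset.extend(oracle(pool.configurations[i]) for i in first)
        quick = TrainingConfig(
            epochs_elec=al_config.quick_epochs, epochs_short=al_config.quick_epochs
        )
        committee.train(dataset, quick, warm_start=g > 0)
        stage_records = []
        for _ in range(al_config.rounds):
            rec = al_round(pool, committee, oracle, al_config, dataset, training=quick)
            stage_records.append(rec)
            if not rec["selected"]:
                break
        # final long training for this generation, from scratch
        committee.train(dataset, final_training, warm_start=False)
        history.append(
            {
                "generation": g,
                "train_size": len(dataset),
                "rounds": stage_records,
            }
        )
    return committee, history
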