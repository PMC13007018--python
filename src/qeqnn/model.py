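"""Fourth-generation neural-network potential: networks, training, committees.

A :class:`FourthGenModel` couples two per-element network families sharing
one symmetry-function set:

* electronegativity networks chi_i = NN_chi(G_i), whose outputs feed the
  global charge equilibration (:mod:`qeqnn.electrostatics`), and
* short-range atomic-energy networks E_i = NN_E(G_i ++ Q_i), taking the
  equilibrated atomic charge as an extra input feature.

The total energy is E_elec(R, Q(R)) + sum_i E_i, and analytic forces carry
chain-rule terms through the descriptors and through the implicit charge
response dQ/dR (one adjoint solve per configuration).

Training is two-stage: the electronegativity networks are fit so that
equilibrated charges match reference charges (gradients propagated through
the constrained linear solve); then the electrostatic energy (and, by
default, its forces) is subtracted from the reference labels and the
short-range networks are fit to the residual with an energy + force loss.
Reference charges are used as the charge input feature during training
(teacher forcing); predicted charges are used at inference.

A committee is n such models differing only in their initialization seeds;
its force disagreement sigma_F(alpha) = sqrt(1/n sum_i |F_i,alpha -
Fbar_alpha|^2) drives query-by-committee selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from .core_types import AtomicConfiguration, LabeledConfiguration
from .descriptors import SymmetryFunctionSet, compute_descriptors, fit_scaling
from .electrostatics import ChargeSolution, EwaldSystem, QeqParameters
from .nn import MLP

__all__ = [
    "TrainingConfig",
    "ConfigRecord",
    "FourthGenModel",
    "FourthGenCommittee",
    "CommitteePrediction",
    "predict_charges",
    "predict_energy_forces",
    "train_electrostatic",
    "train_short_range",
    "committee_predict",
    "second_gen_mode",
    "save_committee",
    "load_committee",
]


@dataclass
class TrainingConfig:
    """Optimization protocol knobs.

    ``epochs_*`` follow the 15-epoch quick-train / 50+100-epoch final-train
    convention of the committee workflow; since the optimizer here is
    full-batch L-BFGS rather than a per-pattern filter, one epoch is mapped
    to ``iters_per_epoch`` quasi-Newton iterations.
    """

    epochs_elec: int = 50
    epochs_short: int = 100
    force_weight: float = 10.0
    subtract_elec_forces: bool = True
    iters_per_epoch: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs_elec < 1 or self.epochs_short < 1:
            raise ValueError("epochs must be >= 1")
        if self.force_weight < 0:
            raise ValueError("force weight must be >= 0")


class ConfigRecord:
    """Geometry-dependent quantities cached once per configuration.

    Descriptors, their gradients, the Ewald/Coulomb matrices and the
    factored augmented Qeq system depend only on positions, so they are
    shared by all committee members and all training iterations.
    """

    def __init__(
        self,
        config: AtomicConfiguration,
        sf_set: SymmetryFunctionSet,
        qeq_params: QeqParameters,
        gradients: bool = True,
    ):
        self.config = config
        self.desc = compute_descriptors(config, sf_set, gradients=gradients)
        self.ewald = EwaldSystem(config, qeq_params, gradients=gradients)
        self.elem_atoms = {
            e: np.where(config.species == e)[0] for e in sf_set.elements
        }
        self.n_functions = {e: sf_set.n_functions(e) for e in sf_set.elements}
        n = config.n_atoms
        if gradients:
            ng = self.desc.values.shape[1]
            self.D2 = self.desc.gradients.reshape(n * ng, n * 3)
        else:
            self.D2 = None

    @property
    def n_atoms(self) -> int:
        return self.config.n_atoms

    def scaled_descriptors(self, sf_set: SymmetryFunctionSet) -> Dict[str, np.ndarray]:
        out = {}
        for e, idx in self.elem_atoms.items():
            if len(idx):
                out[e] = sf_set.scale(e, self.desc.values[idx, : self.n_functions[e]])
        return out

    def contract_forces(self, W: np.ndarray) -> np.ndarray:
        """-sum_ig W[i,g] dG[i,g,a,c]; W padded to (N, n_max)."""
        n = self.n_atoms
        return -(W.ravel() @ self.D2).reshape(n, 3)

    def force_cotangent(self, dLdF: np.ndarray, n_max: int) -> np.ndarray:
        """d(sum dLdF*F_model)/dW for F_model = contract_forces(W)."""
        n = self.n_atoms
        return -(self.D2 @ dLdF.ravel()).reshape(n, n_max)


def as_record(
    item: Union[AtomicConfiguration, ConfigRecord],
    sf_set: SymmetryFunctionSet,
    qeq_params: QeqParameters,
    gradients: bool = True,
) -> ConfigRecord:
    if isinstance(item, ConfigRecord):
        return item
    return ConfigRecord(item, sf_set, qeq_params, gradients=gradients)


@dataclass
class FourthGenModel:
    """One committee member: per-element chi and short-range networks."""

    sf_set: SymmetryFunctionSet
    qeq_params: QeqParameters
    chi_nets: Dict[str, MLP]
    short_nets: Dict[str, MLP]
    e_baseline: Dict[str, float] = field(default_factory=dict)
    q_min: float = -1.0
    q_max: float = 1.0
    fourth_gen: bool = True  # False -> 2G mode (no electrostatics, no Q input)
    fixed_charges: Optional[Dict[str, float]] = None  # 2G dipole charges
    stage1_trained: bool = False
    stage2_trained: bool = False

    @property
    def elements(self) -> List[str]:
        return list(self.sf_set.elements)

    @classmethod
    def create(
        cls,
        sf_set: SymmetryFunctionSet,
        qeq_params: QeqParameters,
        seed: int = 0,
        hidden: Tuple[int, int] = (15, 15),
        fourth_gen: bool = True,
        fixed_charges: Optional[Dict[str, float]] = None,
    ) -> "FourthGenModel":
        chi_nets, short_nets = {}, {}
        for k, e in enumerate(sf_set.elements):
            nf = sf_set.n_functions(e)
            chi_nets[e] = MLP(nf, hidden, seed=seed * 1009 + 2 * k)
            extra = 1 if fourth_gen else 0
            short_nets[e] = MLP(nf + extra, hidden, seed=seed * 1009 + 2 * k + 1)
        return cls(
            sf_set=sf_set,
            qeq_params=qeq_params,
            chi_nets=chi_nets,
            short_nets=short_nets,
            fourth_gen=fourth_gen,
            fixed_charges=fixed_charges,
        )

    # -- charge feature scaling -------------------------------------------
    def scale_charge(self, q: np.ndarray) -> np.ndarray:
        span = self.q_max - self.q_min
        if span <= 0:
            return np.zeros_like(q)
        return 2.0 * (q - self.q_min) / span - 1.0

    @property
    def charge_scale_factor(self) -> float:
        span = self.q_max - self.q_min
        return 2.0 / span if span > 0 else 0.0

    # -- evaluation ---------------------------------------------------------
    def chi(self, record: ConfigRecord, with_grad: bool = False):
        """Per-atom electronegativities (and d chi/d scaled descriptors)."""
        n = record.n_atoms
        chi = np.zeros(n)
        dchi = {} if with_grad else None
        gs = record.scaled_descriptors(self.sf_set)
        for e, idx in record.elem_atoms.items():
            if not len(idx):
                continue
            if e not in self.chi_nets:
                raise KeyError(f"element {e!r} missing from the model")
            if with_grad:
                y, g = self.chi_nets[e].forward_with_input_grad(gs[e])
                dchi[e] = g
            else:
                y = self.chi_nets[e].forward(gs[e])
            chi[idx] = y
        return (chi, gs, dchi) if with_grad else (chi, gs)

    def predict_charges(
        self, item: Union[AtomicConfiguration, ConfigRecord]
    ) -> ChargeSolution:
        record = as_record(item, self.sf_set, self.qeq_params, gradients=False)
        if not self.fourth_gen:
            if self.fixed_charges is None:
                q = np.zeros(record.n_atoms)
            else:
                q = np.array([self.fixed_charges[s] for s in record.config.species])
            return ChargeSolution(charges=q, multiplier=0.0, e_elec=0.0, e_qeq=0.0)
        chi, _ = self.chi(record)
        return record.ewald.solve(chi, record.config.total_charge)

    def predict_energy_forces(
        self, item: Union[AtomicConfiguration, ConfigRecord]
    ) -> Tuple[float, np.ndarray, ChargeSolution]:
        record = as_record(item, self.sf_set, self.qeq_params, gradients=True)
        n = record.n_atoms
        n_max = self.sf_set.n_max
        gs = None
        if self.fourth_gen:
            chi, gs, dchi = self.chi(record, with_grad=True)
            sol = record.ewald.solve(chi, record.config.total_charge)
            qs = self.scale_charge(sol.charges)
        else:
            sol = self.predict_charges(record)
        if gs is None:
            gs = record.scaled_descriptors(self.sf_set)

        e_short = 0.0
        W = np.zeros((n, n_max))  # cotangent on raw descriptors
        dE_dq = np.zeros(n)
        for e, idx in record.elem_atoms.items():
            if not len(idx):
                continue
            nf = record.n_functions[e]
            s = self.sf_set.scale_factors(e)
            if self.fourth_gen:
                X = np.hstack([gs[e], qs[idx, None]])
            else:
                X = gs[e]
            y, gin = self.short_nets[e].forward_with_input_grad(X)
            e_short += y.sum() + self.e_baseline.get(e, 0.0) * len(idx)
            W[idx, :nf] = gin[:, :nf] * s
            if self.fourth_gen:
                dE_dq[idx] = gin[:, nf] * self.charge_scale_factor

        if self.fourth_gen:
            # adjoint for the implicit charge response of E_elec + E_short
            g_vec = record.ewald.A_prime @ sol.charges + dE_dq
            u = record.ewald.adjoint(g_vec)
            for e, idx in record.elem_atoms.items():
                if not len(idx):
                    continue
                nf = record.n_functions[e]
                s = self.sf_set.scale_factors(e)
                W[idx, :nf] -= u[idx, None] * dchi[e] * s
            grad_elec = 0.5 * record.ewald.pair_grad(
                sol.charges, sol.charges
            ) - record.ewald.pair_grad(u, sol.charges)
            energy = sol.e_elec + e_short
            forces = record.contract_forces(W) - grad_elec
        else:
            energy = e_short
            forces = record.contract_forces(W)
        return energy, forces, sol


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _concat_params(nets: Dict[str, MLP], elements: Sequence[str]) -> np.ndarray:
    return np.concatenate([nets[e].get_params() for e in elements])


def _set_params(nets: Dict[str, MLP], elements: Sequence[str], theta: np.ndarray):
    ofs = 0
    for e in elements:
        k = nets[e].n_params
        nets[e].set_params(theta[ofs : ofs + k])
        ofs += k


def _prepare_records(
    dataset: Sequence[LabeledConfiguration],
    sf_set: SymmetryFunctionSet,
    qeq_params: QeqParameters,
    gradients: bool = True,
) -> List[ConfigRecord]:
    return [
        ConfigRecord(lab.configuration, sf_set, qeq_params, gradients=gradients)
        for lab in dataset
    ]


def train_electrostatic(
    model: FourthGenModel,
    dataset: Sequence[LabeledConfiguration],
    config: TrainingConfig,
    records: Optional[Sequence[ConfigRecord]] = None,
    test_set: Optional[Sequence[LabeledConfiguration]] = None,
) -> Dict:
    """Stage 1: fit chi networks so equilibrated charges match the labels.

    The loss is the per-atom MSE of Q_predicted vs Q_reference; its gradient
    is propagated through the constrained linear solve by one adjoint solve
    per configuration and iteration.
    """
    if not model.fourth_gen:
        raise RuntimeError("2G models have no electrostatic stage")
    for lab in dataset:
        if lab.charges is None:
            raise ValueError("dataset lacks per-atom charge labels")
    if not model.sf_set.scaled:
        fit_scaling(dataset, model.sf_set)
    if records is None:
        records = _prepare_records(dataset, model.sf_set, model.qeq_params, False)
    elements = model.elements
    n_total = sum(r.n_atoms for r in records)
    # fixed inputs: scaled descriptors per element, with scatter indices
    gs_all = {e: [] for e in elements}
    for r in records:
        gs = r.scaled_descriptors(model.sf_set)
        for e in elements:
            if e in gs:
                gs_all[e].append(gs[e])
    X_all = {e: np.vstack(v) for e, v in gs_all.items() if v}

    def objective(theta):
        _set_params(model.chi_nets, elements, theta)
        chi_flat = {e: model.chi_nets[e].forward(X_all[e]) for e in X_all}
        loss = 0.0
        cot = {e: np.zeros(len(X_all[e])) for e in X_all}
        ofs = {e: 0 for e in X_all}
        for r, lab in zip(records, dataset):
            chi = np.zeros(r.n_atoms)
            for e, idx in r.elem_atoms.items():
                if len(idx):
                    chi[idx] = chi_flat[e][ofs[e] : ofs[e] + len(idx)]
            sol = r.ewald.solve(chi, r.config.total_charge)
            dq = sol.charges - lab.charges
            loss += dq @ dq / n_total
            u = r.ewald.adjoint(2.0 * dq / n_total)
            for e, idx in r.elem_atoms.items():
                if len(idx):
                    cot[e][ofs[e] : ofs[e] + len(idx)] = -u[idx]
                    ofs[e] += len(idx)
        grad = np.concatenate(
            [
                model.chi_nets[e].vjp(X_all[e], vy=cot[e])
                if e in X_all
                else np.zeros(model.chi_nets[e].n_params)
                for e in elements
            ]
        )
        return loss, grad

    theta0 = _concat_params(model.chi_nets, elements)
    maxiter = config.epochs_elec * config.iters_per_epoch
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 3 * maxiter, "maxls": 40,
                 "ftol": 1e-14, "gtol": 1e-12},
    )
    _set_params(model.chi_nets, elements, res.x)
    model.stage1_trained = True
    report = {
        "loss": float(res.fun),
        "iterations": int(res.nit),
        "train_charge_rmse_me": charge_rmse(model, dataset, records) * 1000,
    }
    if test_set is not None:
        report["test_charge_rmse_me"] = charge_rmse(model, test_set) * 1000
    return report


def charge_rmse(
    model: FourthGenModel,
    dataset: Sequence[LabeledConfiguration],
    records: Optional[Sequence[ConfigRecord]] = None,
) -> float:
    """RMSE of predicted vs reference atomic charges [e]."""
    if records is None:
        records = _prepare_records(dataset, model.sf_set, model.qeq_params, False)
    sq, n = 0.0, 0
    for r, lab in zip(records, dataset):
        dq = model.predict_charges(r).charges - lab.charges
        sq += dq @ dq
        n += r.n_atoms
    return float(np.sqrt(sq / n))


def train_short_range(
    model: FourthGenModel,
    dataset: Sequence[LabeledConfiguration],
    config: TrainingConfig,
    records: Optional[Sequence[ConfigRecord]] = None,
    test_set: Optional[Sequence[LabeledConfiguration]] = None,
) -> Dict:
    """Stage 2: fit short-range networks to the electrostatics-subtracted labels.

    Energy targets are E_ref - E_elec(Q_predicted) minus a per-element
    composition baseline; force targets subtract the full analytic
    electrostatic force (including dQ/dR) when
    ``config.subtract_elec_forces`` is set.  The loss is the per-atom energy
    MSE plus ``force_weight`` times the force-component MSE.
    """
    if model.fourth_gen and not model.stage1_trained:
        raise RuntimeError("electrostatic stage must be trained first")
    if not model.sf_set.scaled:
        fit_scaling(dataset, model.sf_set)
    if records is None:
        records = _prepare_records(dataset, model.sf_set, model.qeq_params, True)
    elements = model.elements
    n_max = model.sf_set.n_max
    n_cfg = len(records)
    n_total = sum(r.n_atoms for r in records)

    # targets
    e_targets = np.zeros(n_cfg)
    f_targets = []
    for k, (r, lab) in enumerate(zip(records, dataset)):
        if model.fourth_gen:
            chi, _, dchi = model.chi(r, with_grad=True)
            sol = r.ewald.solve(chi, r.config.total_charge)
            e_targets[k] = lab.energy - sol.e_elec
            if config.subtract_elec_forces:
                g = r.ewald.A_prime @ sol.charges
                u = r.ewald.adjoint(g)
                W = np.zeros((r.n_atoms, n_max))
                for e, idx in r.elem_atoms.items():
                    if len(idx):
                        nf = r.n_functions[e]
                        W[idx, :nf] = -u[idx, None] * dchi[e] * model.sf_set.scale_factors(e)
                grad_elec = 0.5 * r.ewald.pair_grad(
                    sol.charges, sol.charges
                ) - r.ewald.pair_grad(u, sol.charges)
                f_elec = r.contract_forces(W) - grad_elec
                f_targets.append(lab.forces - f_elec)
            else:
                f_targets.append(lab.forces.copy())
        else:
            e_targets[k] = lab.energy
            f_targets.append(lab.forces.copy())

    # per-element composition baseline (linear least squares)
    counts = np.array(
        [[np.sum(lab.configuration.species == e) for e in elements] for lab in dataset],
        dtype=float,
    )
    coef, *_ = np.linalg.lstsq(counts, e_targets, rcond=None)
    model.e_baseline = {e: float(c) for e, c in zip(elements, coef)}
    e_targets = e_targets - counts @ coef

    # charge feature: reference charges (teacher forcing)
    if model.fourth_gen:
        all_q = np.concatenate([lab.charges for lab in dataset])
        model.q_min, model.q_max = float(all_q.min()), float(all_q.max())

    # fixed network inputs
    X_rows = {e: [] for e in elements}
    for r, lab in zip(records, dataset):
        gs = r.scaled_descriptors(model.sf_set)
        for e, idx in r.elem_atoms.items():
            if not len(idx):
                continue
            if model.fourth_gen:
                qs = model.scale_charge(lab.charges[idx])
                X_rows[e].append(np.hstack([gs[e], qs[:, None]]))
            else:
                X_rows[e].append(gs[e])
    X_all = {e: np.vstack(v) for e, v in X_rows.items() if v}
    natoms = np.array([r.n_atoms for r in records], dtype=float)
    w_f = config.force_weight

    def objective(theta):
        _set_params(model.short_nets, elements, theta)
        fw = {e: model.short_nets[e].forward_with_input_grad(X_all[e]) for e in X_all}
        loss = 0.0
        vy = {e: np.zeros(len(X_all[e])) for e in X_all}
        Vg = {e: np.zeros_like(X_all[e]) for e in X_all}
        ofs = {e: 0 for e in X_all}
        for k, r in enumerate(records):
            n = r.n_atoms
            e_model = 0.0
            W = np.zeros((n, n_max))
            slots = {}
            for e, idx in r.elem_atoms.items():
                if not len(idx):
                    continue
                nf = r.n_functions[e]
                y, gin = fw[e]
                sl = slice(ofs[e], ofs[e] + len(idx))
                slots[e] = sl
                e_model += y[sl].sum()
                W[idx, :nf] = gin[sl, :nf] * model.sf_set.scale_factors(e)
                ofs[e] += len(idx)
            de = e_model - e_targets[k]
            loss += (de / natoms[k]) ** 2 / n_cfg
            dLdy = 2.0 * de / (natoms[k] ** 2 * n_cfg)
            dLdF = None
            if w_f > 0:
                f_model = r.contract_forces(W)
                df = f_model - f_targets[k]
                loss += w_f * np.sum(df * df) / (3.0 * n_total)
                dLdF = 2.0 * w_f * df / (3.0 * n_total)
                cotW = r.force_cotangent(dLdF, n_max)
            for e, idx in r.elem_atoms.items():
                if not len(idx):
                    continue
                nf = r.n_functions[e]
                sl = slots[e]
                vy[e][sl] = dLdy
                if w_f > 0:
                    Vg[e][sl, :nf] = cotW[idx, :nf] * model.sf_set.scale_factors(e)
        grad = np.concatenate(
            [
                model.short_nets[e].vjp(X_all[e], vy=vy[e], Vg=Vg[e])
                if e in X_all
                else np.zeros(model.short_nets[e].n_params)
                for e in elements
            ]
        )
        return loss, grad

    theta0 = _concat_params(model.short_nets, elements)
    maxiter = config.epochs_short * config.iters_per_epoch
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 3 * maxiter, "maxls": 40,
                 "ftol": 1e-14, "gtol": 1e-12},
    )
    _set_params(model.short_nets, elements, res.x)
    model.stage2_trained = True
    report = {"loss": float(res.fun), "iterations": int(res.nit)}
    report.update(validation_report(model, dataset, records, prefix="train_"))
    if test_set is not None:
        report.update(validation_report(model, test_set, prefix="test_"))
    return report


def validation_report(
    model: FourthGenModel,
    dataset: Sequence[LabeledConfiguration],
    records: Optional[Sequence[ConfigRecord]] = None,
    prefix: str = "",
) -> Dict[str, float]:
    """Energy [meV/atom], force [eV/A] and charge [me] RMS errors."""
    if records is None:
        records = _prepare_records(dataset, model.sf_set, model.qeq_params, True)
    se, sf, sq, n_at, n_cfg = 0.0, 0.0, 0.0, 0, 0
    for r, lab in zip(records, dataset):
        E, F, sol = model.predict_energy_forces(r)
        se += ((E - lab.energy) / r.n_atoms) ** 2
        sf += np.sum((F - lab.forces) ** 2)
        sq += np.sum((sol.charges - lab.charges) ** 2)
        n_at += r.n_atoms
        n_cfg += 1
    out = {
        prefix + "energy_rmse_mev_per_atom": float(np.sqrt(se / n_cfg)) * 1000,
        prefix + "force_rmse_ev_per_a": float(np.sqrt(sf / (3 * n_at))),
    }
    if model.fourth_gen:
        out[prefix + "charge_rmse_me"] = float(np.sqrt(sq / n_at)) * 1000
    return out


# ---------------------------------------------------------------------------
# committees
# ---------------------------------------------------------------------------


@dataclass
class CommitteePrediction:
    energy: float  # ensemble mean [eV]
    forces: np.ndarray  # ensemble mean [eV/A]
    charges: np.ndarray  # ensemble mean [e]
    sigma_f: np.ndarray  # per-atom force disagreement [eV/A]
    member_energies: np.ndarray
    member_forces: np.ndarray  # (n_members, N, 3)


@dataclass
class FourthGenCommittee:
    """n models sharing one symmetry-function set, differing in seed."""

    members: List[FourthGenModel]

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("committee needs at least one member")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def sf_set(self) -> SymmetryFunctionSet:
        return self.members[0].sf_set

    @property
    def qeq_params(self) -> QeqParameters:
        return self.members[0].qeq_params

    @classmethod
    def create(
        cls,
        sf_set: SymmetryFunctionSet,
        qeq_params: Optional[QeqParameters] = None,
        n: int = 4,
        seed: int = 0,
        hidden: Tuple[int, int] = (15, 15),
        fourth_gen: bool = True,
        fixed_charges: Optional[Dict[str, float]] = None,
    ) -> "FourthGenCommittee":
        qeq_params = qeq_params or QeqParameters()
        members = [
            FourthGenModel.create(
                sf_set,
                qeq_params,
                seed=seed + 17 * (i + 1),
                hidden=hidden,
                fourth_gen=fourth_gen,
                fixed_charges=fixed_charges,
            )
            for i in range(n)
        ]
        return cls(members=members)

    def reinitialize(self) -> None:
        """Fresh random weights with each member's original seed."""
        for m in self.members:
            for nets in (m.chi_nets, m.short_nets):
                for e, net in nets.items():
                    nets[e] = MLP(net.n_input, net.hidden, seed=net.seed)
            m.stage1_trained = m.stage2_trained = False

    def train(
        self,
        dataset: Sequence[LabeledConfiguration],
        config: Optional[TrainingConfig] = None,
        test_set: Optional[Sequence[LabeledConfiguration]] = None,
        warm_start: bool = False,
        records: Optional[Sequence[ConfigRecord]] = None,
    ) -> List[Dict]:
        """Two-stage training of every member on the same dataset."""
        config = config or TrainingConfig()
        if not self.sf_set.scaled:
            fit_scaling(dataset, self.sf_set)
        if not warm_start:
            self.reinitialize()
        if records is None:
            records = _prepare_records(dataset, self.sf_set, self.qeq_params, True)
        reports = []
        for m in self.members:
            rep = {}
            if m.fourth_gen:
                rep["electrostatic"] = train_electrostatic(
                    m, dataset, config, records=records
                )
            rep["short_range"] = train_short_range(
                m, dataset, config, records=records, test_set=test_set
            )
            reports.append(rep)
        return reports

    def predict(
        self, item: Union[AtomicConfiguration, ConfigRecord]
    ) -> CommitteePrediction:
        record = as_record(item, self.sf_set, self.qeq_params, gradients=True)
        energies, forces, charges = [], [], []
        for m in self.members:
            E, F, sol = m.predict_energy_forces(record)
            energies.append(E)
            forces.append(F)
            charges.append(sol.charges)
        energies = np.array(energies)
        forces = np.array(forces)
        charges = np.array(charges)
        fbar = forces.mean(axis=0)
        dev = forces - fbar
        sigma_f = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
        return CommitteePrediction(
            energy=float(energies.mean()),
            forces=fbar,
            charges=charges.mean(axis=0),
            sigma_f=sigma_f,
            member_energies=energies,
            member_forces=forces,
        )


def predict_charges(
    model: FourthGenModel, config: Union[AtomicConfiguration, ConfigRecord]
) -> ChargeSolution:
    return model.predict_charges(config)


def predict_energy_forces(
    model: FourthGenModel, config: Union[AtomicConfiguration, ConfigRecord]
):
    return model.predict_energy_forces(config)


def committee_predict(
    committee: FourthGenCommittee, config: Union[AtomicConfiguration, ConfigRecord]
) -> CommitteePrediction:
    """Ensemble mean energy/forces/charges and per-atom force disagreement.

    sigma_F(alpha) is the root mean square over members of |F_i,alpha -
    Fbar_alpha|; it vanishes for a single-member committee.
    """
    return committee.predict(config)


def second_gen_mode(
    committee_2g: FourthGenCommittee,
    fixed_charge_table: Dict[str, float],
    config: Union[AtomicConfiguration, ConfigRecord],
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Short-range-only (2G) prediction with fixed per-element charges.

    Energies and forces come from the charge-free short-range networks; the
    returned charges are taken verbatim from the table (for dipole analysis
    only -- they exert no forces).
    """
    for m in committee_2g.members:
        if m.fourth_gen:
            raise ValueError("second_gen_mode requires a 2G committee")
    record = as_record(
        config, committee_2g.sf_set, committee_2g.qeq_params, gradients=True
    )
    for s in record.config.species:
        if s not in fixed_charge_table:
            raise KeyError(f"no fixed charge for element {s!r}")
    pred = committee_2g.predict(record)
    charges = np.array([fixed_charge_table[s] for s in record.config.species])
    return pred.energy, pred.forces, charges


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------


def _save_member(model: FourthGenModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    model.sf_set.to_text(path / "symmetry_functions.txt")
    arrays = {}
    for role, nets in (("chi", model.chi_nets), ("short", model.short_nets)):
        for e, net in nets.items():
            arrays[f"{role}_{e}"] = net.get_params()
            arrays[f"{role}_{e}_meta"] = np.array(
                [net.n_input, *net.hidden, net.seed], dtype=float
            )
    for e in model.sf_set.elements:
        if model.sf_set.scaled:
            arrays[f"gmin_{e}"] = model.sf_set.g_min[e]
            arrays[f"gmax_{e}"] = model.sf_set.g_max[e]
    np.savez(path / "weights.npz", **arrays)
    manifest = {
        "format": "qeqnn-model-1",
        "fourth_gen": model.fourth_gen,
        "elements": model.elements,
        "e_baseline": model.e_baseline,
        "q_min": model.q_min,
        "q_max": model.q_max,
        "fixed_charges": model.fixed_charges,
        "stage1_trained": model.stage1_trained,
        "stage2_trained": model.stage2_trained,
        "qeq": {
            "hardness": model.qeq_params.hardness,
            "sigma": model.qeq_params.sigma,
            "ewald_eta": model.qeq_params.ewald_eta,
            "r_cut_real": model.qeq_params.r_cut_real,
            "kspace_cutoff": model.qeq_params.kspace_cutoff,
            "tolerance": model.qeq_params.tolerance,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_member(path: Path) -> FourthGenModel:
    manifest = json.loads((path / "manifest.json").read_text())
    sf_set = SymmetryFunctionSet.from_text(path / "symmetry_functions.txt")
    data = np.load(path / "weights.npz")
    qeq = QeqParameters(**manifest["qeq"])
    chi_nets, short_nets = {}, {}
    for e in manifest["elements"]:
        if sf_set.scaled or f"gmin_{e}" in data:
            sf_set.g_min[e] = data[f"gmin_{e}"]
            sf_set.g_max[e] = data[f"gmax_{e}"]
        for role, target in (("chi", chi_nets), ("short", short_nets)):
            meta = data[f"{role}_{e}_meta"]
            net = MLP(int(meta[0]), (int(meta[1]), int(meta[2])), seed=int(meta[3]))
            net.set_params(data[f"{role}_{e}"])
            target[e] = net
    model = FourthGenModel(
        sf_set=sf_set,
        qeq_params=qeq,
        chi_nets=chi_nets,
        short_nets=short_nets,
        e_baseline=manifest["e_baseline"],
        q_min=manifest["q_min"],
        q_max=manifest["q_max"],
        fourth_gen=manifest["fourth_gen"],
        fixed_charges=manifest["fixed_charges"],
        stage1_trained=manifest["stage1_trained"],
        stage2_trained=manifest["stage2_trained"],
    )
    return model


def save_committee(committee: FourthGenCommittee, path: Union[str, Path]) -> None:
    """Versioned model archive: one subdirectory per member."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "committee.json").write_text(
        json.dumps({"format": "qeqnn-committee-1", "n": committee.n})
    )
    for i, m in enumerate(committee.members):
        _save_member(m, path / f"member_{i:02d}")


def load_committee(path: Union[str, Path]) -> FourthGenCommittee:
    path = Path(path)
    meta = json.loads((path / "committee.json").read_text())
    members = [_load_member(path / f"member_{i:02d}") for i in range(meta["n"])]
    # members share one symmetry-function set object
    for m in members[1:]:
        m.sf_set = members[0].sf_set
        m.qeq_params = members[0].qeq_params
    return FourthGenCommittee(members=members)
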