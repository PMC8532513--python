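"""Enzyme-constrained models and flux control analysis.

An enzyme-constrained model extends a stoichiometric species model with one
usage variable e_i (mmol gDW-1) per enzyme.  Each catalysed irreversible
reaction j is coupled to its enzymes through

    v_j <= sum_i kcat_ij * e_i          (isozymes additive),

and total enzyme mass is bounded by a shared protein pool P (g gDW-1):

    sum_i MW_i * e_i <= P.

Flux control coefficients are measured by perturbing all kcats of one enzyme
by a small relative amount (0.1% by default) and scaling the induced relative
change of the target flux:

    FCC_i = ((v_j* - v_j) / v_j) / 0.001.

The same machinery supports kcat fold-change scans used to probe overflow
metabolism (Crabtree-style aerobic fermentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from ._solver import solve_lp
from .fba import FLUX_DECIMALS, FluxResult, MediaSpec, apply_media
from .ssmodel import SpeciesModel

__all__ = ["EcModel", "build_ec_model", "ec_fba", "ec_pfba", "compute_fcc", "kcat_scan"]

DEFAULT_PERTURBATION = 0.001  # 0.1% relative kcat perturbation for FCCs


@dataclass
class EcModel:
    base: SpeciesModel
    kcat: Dict[Tuple[str, str], float]  # (enzyme id, base reaction id) -> h-1
    mw: Dict[str, float]  # enzyme id -> g mmol-1
    pool: float  # g gDW-1; non-finite disables the pool constraint

    @property
    def enzymes(self) -> List[str]:
        return sorted({e for e, _ in self.kcat})

    def scaled(self, factors: Mapping[str, float]) -> "EcModel":
        """Copy with each listed enzyme's kcats multiplied by its factor."""
        kcat = {
            (e, r): k * factors.get(e, 1.0) for (e, r), k in self.kcat.items()
        }
        return EcModel(self.base, kcat, dict(self.mw), self.pool)


def build_ec_model(
    model: SpeciesModel,
    kcat: Mapping[Tuple[str, str], float],
    mw: Mapping[str, float],
    pool: float,
) -> EcModel:
    """Validate tables and assemble an enzyme-constrained model.

    Every kcat must be positive and every enzyme carrying a kcat must have a
    molecular weight.  A model without any kcats reduces exactly to the base
    model.
    """
    rxn_ids = set(model.reaction_ids)
    bad_kcat = [(e, r) for (e, r), k in kcat.items() if k <= 0]
    if bad_kcat:
        raise ValueError(f"non-positive kcat for {sorted(bad_kcat)}")
    unknown = [(e, r) for (e, r) in kcat if r not in rxn_ids]
    if unknown:
        raise ValueError(f"kcat references unknown reactions: {sorted(unknown)}")
    missing_mw = sorted({e for (e, _) in kcat} - set(mw))
    if missing_mw:
        raise ValueError(f"missing molecular weight for enzymes: {missing_mw}")
    bad_mw = sorted(e for e, m in mw.items() if m <= 0)
    if bad_mw:
        raise ValueError(f"non-positive molecular weight for enzymes: {bad_mw}")
    return EcModel(model, dict(kcat), dict(mw), float(pool))


# ---------------------------------------------------------------------------
# LP assembly: irreversible split + enzyme usage variables
# ---------------------------------------------------------------------------

@dataclass
class _EcProblem:
    var_names: List[str]
    n_flux: int
    fwd_of: Dict[str, int]  # base reaction id -> fwd variable index
    rev_of: Dict[str, int]
    enzyme_idx: Dict[str, int]
    a_eq: sparse.csr_matrix
    a_ub: sparse.csr_matrix
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    pool_cost: np.ndarray  # MW vector over all variables (0 for fluxes)


def _assemble(ec: EcModel, media: Optional[MediaSpec]) -> _EcProblem:
    model = ec.base
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    base_lb, base_ub = apply_media(model, media)

    var_names: List[str] = []
    fwd_of: Dict[str, int] = {}
    rev_of: Dict[str, int] = {}
    rows, cols, vals = [], [], []
    lb_list: List[float] = []
    ub_list: List[float] = []

    def add_flux(name, stoich, sign, lo, hi):
        j = len(var_names)
        var_names.append(name)
        for met, coef in stoich.items():
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(sign * float(coef))
        lb_list.append(lo)
        ub_list.append(hi)
        return j

    for rxn, lo, hi in zip(model.reactions, base_lb, base_ub):
        if lo < 0 and hi > 0:
            fwd_of[rxn.id] = add_flux(rxn.id, rxn.stoichiometry, 1.0, 0.0, hi)
            rev_of[rxn.id] = add_flux(
                rxn.id + "__rev", rxn.stoichiometry, -1.0, 0.0, -lo
            )
        elif hi <= 0:
            rev_of[rxn.id] = add_flux(
                rxn.id + "__rev", rxn.stoichiometry, -1.0, max(0.0, -hi), -lo
            )
        else:
            fwd_of[rxn.id] = add_flux(rxn.id, rxn.stoichiometry, 1.0, max(0.0, lo), hi)

    n_flux = len(var_names)
    enzyme_idx = {e: n_flux + k for k, e in enumerate(ec.enzymes)}
    for e in ec.enzymes:
        var_names.append(f"enzyme::{e}")
        lb_list.append(0.0)
        ub_list.append(np.inf)
    n = len(var_names)
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), n))

    # usage constraints: v_j - sum_i kcat_ij e_i <= 0 per catalysed direction
    by_rxn: Dict[str, List[Tuple[str, float]]] = {}
    for (e, r), k in ec.kcat.items():
        by_rxn.setdefault(r, []).append((e, k))
    u_rows, u_cols, u_vals = [], [], []
    r_idx = 0
    for rid in sorted(by_rxn):
        for j in (fwd_of.get(rid), rev_of.get(rid)):
            if j is None:
                continue
            u_rows.append(r_idx)
            u_cols.append(j)
            u_vals.append(1.0)
            for e, k in sorted(by_rxn[rid]):
                u_rows.append(r_idx)
                u_cols.append(enzyme_idx[e])
                u_vals.append(-k)
            r_idx += 1
    pool_cost = np.zeros(n)
    for e, j in enzyme_idx.items():
        pool_cost[j] = ec.mw[e]
    if np.isfinite(ec.pool) and enzyme_idx:
        for j, cost in enumerate(pool_cost):
            if cost:
                u_rows.append(r_idx)
                u_cols.append(j)
                u_vals.append(cost)
        b_extra = [ec.pool]
        r_idx += 1
    else:
        b_extra = []
    a_ub = sparse.csr_matrix((u_vals, (u_rows, u_cols)), shape=(r_idx, n))
    b_ub = np.concatenate([np.zeros(r_idx - len(b_extra)), np.array(b_extra)])
    return _EcProblem(
        var_names=var_names,
        n_flux=n_flux,
        fwd_of=fwd_of,
        rev_of=rev_of,
        enzyme_idx=enzyme_idx,
        a_eq=a_eq,
        a_ub=a_ub,
        b_ub=b_ub,
        lb=np.array(lb_list),
        ub=np.array(ub_list),
        pool_cost=pool_cost,
    )


def _net_fluxes(prob: _EcProblem, x: np.ndarray) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for rid in set(prob.fwd_of) | set(prob.rev_of):
        v = 0.0
        if rid in prob.fwd_of:
            v += x[prob.fwd_of[rid]]
        if rid in prob.rev_of:
            v -= x[prob.rev_of[rid]]
        out[rid] = round(float(v), FLUX_DECIMALS)
    return out


def ec_fba(
    ec: EcModel,
    media: Optional[MediaSpec] = None,
    objective_reaction: Optional[str] = None,
) -> FluxResult:
    """FBA under enzyme-usage and protein-pool constraints."""
    objective_reaction = objective_reaction or ec.base.biomass_id
    prob = _assemble(ec, media)
    c = np.zeros(len(prob.var_names))
    if objective_reaction in prob.fwd_of:
        c[prob.fwd_of[objective_reaction]] = 1.0
    if objective_reaction in prob.rev_of:
        c[prob.rev_of[objective_reaction]] = -1.0
    if not c.any():
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    sol = solve_lp(
        c,
        prob.a_eq,
        np.zeros(prob.a_eq.shape[0]),
        prob.lb,
        prob.ub,
        maximize=True,
        a_ub=prob.a_ub,
        b_ub=prob.b_ub,
    )
    if sol.status != "optimal":
        return FluxResult(sol.status, None)
    return FluxResult("optimal", float(sol.objective), _net_fluxes(prob, sol.x))


def ec_pfba(
    ec: EcModel,
    media: Optional[MediaSpec] = None,
    objective_reaction: Optional[str] = None,
) -> FluxResult:
    """ec-pFBA: maximize the objective, then minimize total protein-pool
    usage (sum of MW_i e_i) at the fixed optimum; falls back to total flux
    minimization when no enzyme is constrained."""
    objective_reaction = objective_reaction or ec.base.biomass_id
    first = ec_fba(ec, media, objective_reaction)
    if not first.optimal:
        return first
    prob = _assemble(ec, media)
    j_obj = prob.fwd_of.get(objective_reaction)
    opt = first.objective
    if j_obj is not None:
        prob.lb[j_obj] = opt
    if prob.pool_cost.any():
        c = prob.pool_cost.copy()
    else:
        c = np.ones(len(prob.var_names))
    sol = solve_lp(
        c,
        prob.a_eq,
        np.zeros(prob.a_eq.shape[0]),
        prob.lb,
        prob.ub,
        maximize=False,
        a_ub=prob.a_ub,
        b_ub=prob.b_ub,
    )
    if sol.status != "optimal":
        return FluxResult(sol.status, None)
    fluxes = _net_fluxes(prob, sol.x)
    return FluxResult("optimal", float(fluxes[objective_reaction]), fluxes)


# ---------------------------------------------------------------------------
# flux control coefficients and kcat scans
# ---------------------------------------------------------------------------

def compute_fcc(
    ec: EcModel,
    enzyme_id: str,
    target_reaction: Optional[str] = None,
    media: Optional[MediaSpec] = None,
    relative_perturbation: float = DEFAULT_PERTURBATION,
    denominator: str = "reference",
) -> float:
    """Flux control coefficient of one enzyme over a target flux.

    All kcats of the enzyme are multiplied by (1 + relative_perturbation)
    and the scaled finite difference of the target flux is returned.  The
    reference flux normalizes the difference by default; pass
    ``denominator="perturbed"`` for the alternative reading.
    """
    if not any(e == enzyme_id for e, _ in ec.kcat):
        raise KeyError(f"enzyme {enzyme_id!r} has no kcat in the model")
    target_reaction = target_reaction or ec.base.biomass_id
    ref = ec_fba(ec, media, target_reaction)
    if not ref.optimal:
        raise RuntimeError("reference ec-model solve failed")
    v_ref = ref.objective
    if v_ref == 0:
        raise ValueError("control coefficient undefined at zero reference flux")
    perturbed = ec.scaled({enzyme_id: 1.0 + relative_perturbation})
    per = ec_fba(perturbed, media, target_reaction)
    if not per.optimal:
        raise RuntimeError("perturbed ec-model solve failed")
    v_per = per.objective
    if v_per == v_ref:
        return 0.0
    denom = v_per if denominator == "perturbed" else v_ref
    return ((v_per - v_ref) / denom) / relative_perturbation


def kcat_scan(
    ec: EcModel,
    enzyme_ids: Sequence[str],
    folds: Sequence[float],
    report_reactions: Sequence[str],
    media: Optional[MediaSpec] = None,
    carbon_exchange_id: Optional[str] = None,
    carbon_mw: float = 0.180,
) -> pd.DataFrame:
    """Scan kcat fold-changes and report per-fold fluxes and yields.

    For each fold the targeted enzymes' kcats are multiplied and ec-pFBA is
    run (biomass maximization, then protein-pool minimization).  Reported
    fluxes are also normalized per gram of consumed carbon substrate when
    ``carbon_exchange_id`` is given (``carbon_mw`` in g mmol-1; the default
    corresponds to a hexose).
    """
    folds = list(folds)
    if any(f <= 0 for f in folds):
        raise ValueError("folds must be positive")
    if folds != sorted(folds) or folds[0] != 1:
        raise ValueError("fold grid must be ascending and start at 1")
    records = []
    for fold in folds:
        scaled = ec.scaled({e: fold for e in enzyme_ids})
        res = ec_pfba(scaled, media)
        row: Dict[str, float] = {"fold": fold, "biomass": res.objective}
        consumed = None
        if carbon_exchange_id is not None and res.optimal:
            consumed = -res.fluxes.get(carbon_exchange_id, 0.0)  # mmol gDW-1 h-1
        for rid in report_reactions:
            flux = res.fluxes.get(rid, np.nan) if res.optimal else np.nan
            row[rid] = flux
            if consumed is not None and consumed > 0:
                row[f"{rid}_per_g_substrate"] = flux / (consumed * carbon_mw)
        if consumed is not None and consumed > 0 and res.objective is not None:
            row["biomass_yield_per_g_substrate"] = res.objective / (
                consumed * carbon_mw
            )
        records.append(row)
    return pd.DataFrame.from_records(records)
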