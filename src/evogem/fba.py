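"""Flux balance analysis core.

Implements FBA and parsimonious FBA on stoichiometric models, substrate
utilization tests at the standard uptake rate of 10 mmol gDW-1 h-1 with a
growth threshold of 1e-6 h-1 (a simulated maximal growth rate below the
threshold is classified as no growth), single-gene-deletion essentiality via
GPR re-evaluation, and the confusion-matrix metric family used to score
predictions against experimental trait tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from ._solver import LpSolution, solve_lp
from .gpr import evaluate_gpr

logger = logging.getLogger(__name__)

GROWTH_THRESHOLD = 1e-6  # h-1; growth at or above the threshold counts
DEFAULT_UPTAKE = 10.0  # mmol gDW-1 h-1
FLUX_DECIMALS = 10  # reported fluxes rounded to suppress solver noise

__all__ = [
    "MediaSpec",
    "FluxResult",
    "ConfusionCounts",
    "Metrics",
    "build_stoichiometry",
    "solve_fba",
    "pfba",
    "test_substrate_utilization",
    "single_gene_deletions",
    "confusion_metrics",
    "GROWTH_THRESHOLD",
    "DEFAULT_UPTAKE",
]


@dataclass(frozen=True)
class MediaSpec:
    """Exchange-reaction bounds defining a growth medium.

    Uptake is encoded as a negative lower bound.  Exchanges not listed are
    closed for uptake (lb 0) but left open for secretion when the medium is
    applied, so a medium fully determines the nutrient environment.
    """

    bounds: Mapping[str, Tuple[float, float]]
    name: str = "custom"

    def __post_init__(self):
        for ex, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(f"media entry {ex}: lb {lb} > ub {ub}")

    def with_exchange(self, exchange_id: str, lb: float, ub: float) -> "MediaSpec":
        new = dict(self.bounds)
        new[exchange_id] = (lb, ub)
        return MediaSpec(new, self.name)

    def without_exchange(self, exchange_id: str) -> "MediaSpec":
        new = dict(self.bounds)
        new.pop(exchange_id, None)
        return MediaSpec(new, self.name)

    def replace_source(
        self, old_exchange: str, new_exchange: str, uptake_rate: float = DEFAULT_UPTAKE
    ) -> "MediaSpec":
        """Close one nutrient exchange and open another for uptake."""
        new = dict(self.bounds)
        new.pop(old_exchange, None)
        new[new_exchange] = (-abs(uptake_rate), 1000.0)
        return MediaSpec(new, self.name)

    def to_tsv(self, path) -> None:
        rows = [
            {"exchange": ex, "lb": lb, "ub": ub}
            for ex, (lb, ub) in sorted(self.bounds.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str = "custom") -> "MediaSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {row.exchange: (float(row.lb), float(row.ub)) for row in df.itertuples()},
            name,
        )


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    fpr: float


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def build_stoichiometry(model) -> Tuple[list, list, sparse.csr_matrix]:
    """Return (reaction ids, metabolite ids, S matrix) for a model."""
    rxn_ids = [r.id for r in model.reactions]
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            rows.append(met_pos[met])
            cols.append(j)
            vals.append(float(coef))
    s = sparse.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return rxn_ids, met_ids, s


def apply_media(model, media: Optional[MediaSpec]) -> Tuple[np.ndarray, np.ndarray]:
    """Bounds vectors for the model under a medium.

    Exchanges listed in the medium take its bounds; unlisted exchanges are
    closed for uptake (lb 0); non-exchange reactions keep their own bounds.
    """
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if media is None:
        return lb, ub
    for j, rxn in enumerate(model.reactions):
        if not rxn.is_exchange:
            continue
        if rxn.id in media.bounds:
            lb[j], ub[j] = media.bounds[rxn.id]
        else:
            lb[j] = max(lb[j], 0.0)
            ub[j] = max(ub[j], lb[j])
    return lb, ub


def _finish(rxn_ids, sol: LpSolution) -> FluxResult:
    if sol.status != "optimal":
        return FluxResult(sol.status, None)
    fluxes = {
        rid: round(float(v), FLUX_DECIMALS) for rid, v in zip(rxn_ids, sol.x)
    }
    return FluxResult("optimal", float(sol.objective), fluxes)


def solve_fba(
    model,
    media: Optional[MediaSpec] = None,
    objective_reaction: Optional[str] = None,
    bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> FluxResult:
    """Maximize flux through the objective reaction at steady state.

    The objective defaults to the model's biomass reaction.  Only the
    objective value is contract-bound; the flux vector may be degenerate.
    """
    objective_reaction = objective_reaction or model.biomass_id
    rxn_ids, _, s = build_stoichiometry(model)
    if objective_reaction not in rxn_ids:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    lb, ub = apply_media(model, media)
    if bound_overrides:
        pos = {rid: j for j, rid in enumerate(rxn_ids)}
        for rid, (lo, hi) in bound_overrides.items():
            lb[pos[rid]], ub[pos[rid]] = lo, hi
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_reaction)] = 1.0
    sol = solve_lp(c, s, np.zeros(s.shape[0]), lb, ub, maximize=True)
    return _finish(rxn_ids, sol)


def pfba(
    model,
    media: Optional[MediaSpec] = None,
    objective_reaction: Optional[str] = None,
) -> FluxResult:
    """Parsimonious FBA: fix the objective at its optimum, minimize total
    absolute flux via splitting into non-negative forward/reverse parts."""
    objective_reaction = objective_reaction or model.biomass_id
    first = solve_fba(model, media, objective_reaction)
    if not first.optimal:
        return first
    rxn_ids, _, s = build_stoichiometry(model)
    lb, ub = apply_media(model, media)
    j_obj = rxn_ids.index(objective_reaction)
    opt = first.objective
    # pin the objective exactly at its optimum
    lb[j_obj] = opt
    ub[j_obj] = opt
    n = len(rxn_ids)
    # v = f - r with f, r >= 0
    s_split = sparse.hstack([s, -s], format="csr")
    lb2 = np.zeros(2 * n)
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    # forward part must still honour positive lower bounds (and reverse
    # part negative upper bounds)
    lb2[:n] = np.maximum(lb, 0.0)
    lb2[n:] = np.maximum(-ub, 0.0)
    c = np.ones(2 * n)
    sol = solve_lp(c, s_split, np.zeros(s.shape[0]), lb2, ub2, maximize=False)
    if sol.status != "optimal":
        return FluxResult(sol.status, None)
    v = sol.x[:n] - sol.x[n:]
    fluxes = {rid: round(float(x), FLUX_DECIMALS) for rid, x in zip(rxn_ids, v)}
    return FluxResult("optimal", float(fluxes[objective_reaction]), fluxes)


# ---------------------------------------------------------------------------
# substrate utilization and essentiality
# ---------------------------------------------------------------------------

def test_substrate_utilization(
    model,
    substrate_exchange_id: str,
    media: MediaSpec,
    replace_exchange_id: str,
    uptake_rate: float = DEFAULT_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> bool:
    """Can the species grow with the test substrate as sole carbon
    (or nitrogen) source?

    The default source's exchange (``replace_exchange_id``) is closed and
    the test substrate's exchange opened at ``-uptake_rate``; growth at or
    above the threshold counts as utilization.  A species lacking the
    substrate's exchange reaction is a non-utilizer.
    """
    rxn_ids = {r.id for r in model.reactions}
    if substrate_exchange_id not in rxn_ids:
        logger.info(
            "exchange %s absent from model; scored as non-utilizer",
            substrate_exchange_id,
        )
        return False
    test_media = media.replace_source(
        replace_exchange_id, substrate_exchange_id, uptake_rate
    )
    result = solve_fba(model, test_media)
    return result.optimal and result.objective >= growth_threshold


def single_gene_deletions(
    model,
    media: MediaSpec,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> Dict[str, str]:
    """Classify each gene as essential / non_essential by simulated knockout.

    For every gene the model's GPRs are re-evaluated with the gene removed;
    reactions whose rule becomes inactive are disabled (bounds 0) and growth
    re-maximized.  Maximal growth below the threshold marks the gene
    essential.
    """
    base = solve_fba(model, media)
    if not (base.optimal and base.objective >= growth_threshold):
        raise ValueError("model does not grow on the given media")
    genes = set()
    for rxn in model.reactions:
        genes |= rxn.genes
    out: Dict[str, str] = {}
    for gene in sorted(genes):
        present = genes - {gene}
        overrides = {}
        for rxn in model.reactions:
            if rxn.gpr is None:
                continue
            active, _ = evaluate_gpr(rxn.gpr, present)
            if not active:
                overrides[rxn.id] = (0.0, 0.0)
        if overrides:
            result = solve_fba(model, media, bound_overrides=overrides)
            growing = result.optimal and result.objective >= growth_threshold
        else:
            growing = True
        out[gene] = "non_essential" if growing else "essential"
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, precision, F1 and FPR.

    Ratios with a zero denominator are returned as NaN, never as 0.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    accuracy = (tp + tn) / counts.total
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    fpr = 1 - specificity if not math.isnan(specificity) else math.nan
    return Metrics(accuracy, sensitivity, specificity, precision, f1, fpr)


def score_predictions(
    predicted: Iterable[int], observed: Iterable[object]
) -> ConfusionCounts:
    """Confusion counts of binary predictions against 1/0/NA observations;
    NA observations are skipped."""
    tp = tn = fp = fn = 0
    for p, o in zip(predicted, observed):
        if o is None or (isinstance(o, float) and math.isnan(o)):
            continue
        o = int(o)
        p = int(p)
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and o:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)
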