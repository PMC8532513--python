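"""Species-specific model derivation and gap-filling.

A species model is a copy of the pan-model restricted to the reactions whose
GPR rule is satisfied by the species' ortholog content (rules without a GPR
— exchange and spontaneous reactions — are always kept, as is the biomass
pseudo-reaction).  When a derived model cannot grow on the given medium, a
minimum-cardinality set of pan-model reactions restoring growth is found by
mixed-integer programming, mirroring gap-filling against a universal
reaction database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from ._solver import solve_lp, solve_milp_min_count
from .fba import GROWTH_THRESHOLD, MediaSpec, apply_media, build_stoichiometry, solve_fba
from .gpr import evaluate_gpr
from .panmodel import PanModel, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesModel",
    "UnfillableError",
    "derive_species_model",
    "check_producibility",
    "gap_fill",
    "apply_gap_fill",
    "read_species_model",
    "write_species_model",
]


class UnfillableError(RuntimeError):
    """No subset of pan-model reactions restores growth (auxotrophy is
    handled by media augmentation, not gap-filling)."""


@dataclass
class SpeciesModel:
    species_id: str
    metabolites: list
    reactions: List[Reaction]
    biomass_id: str
    provenance: Dict[str, str] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> set:
        out = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)


def write_species_model(model: SpeciesModel, path) -> None:
    """Serialize a species model to JSON (pan-model schema plus species_id
    and per-reaction provenance)."""
    import json
    from pathlib import Path

    from .panmodel import _model_to_dict

    data = _model_to_dict(
        PanModel(model.metabolites, model.reactions, model.biomass_id)
    )
    data["species_id"] = model.species_id
    data["provenance"] = dict(sorted(model.provenance.items()))
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def read_species_model(path) -> SpeciesModel:
    import json
    from pathlib import Path

    from .panmodel import read_pan_model

    data = json.loads(Path(path).read_text())
    pan = read_pan_model(path)
    return SpeciesModel(
        species_id=data.get("species_id", "species"),
        metabolites=pan.metabolites,
        reactions=pan.reactions,
        biomass_id=pan.biomass_id,
        provenance=data.get("provenance", {}),
    )


def derive_species_model(
    pan: PanModel, existence_row: Mapping[str, int], species_id: str = "species"
) -> SpeciesModel:
    """Derive a species model from the pan-model and one existence row.

    A reaction is retained iff its GPR evaluates active under the species'
    gene set (complexes need a strict majority of subunits; isozymes need one
    member), or it has no GPR; retained reactions carry pruned GPRs.  The
    biomass reaction is always retained.  Genes missing from the row are
    treated as absent.
    """
    missing = pan.gene_ids - set(existence_row)
    if missing:
        logger.info(
            "%s: %d pan genes missing from existence row, treated as absent",
            species_id,
            len(missing),
        )
    present = {g for g in pan.gene_ids if existence_row.get(g, 0) == 1}
    reactions: List[Reaction] = []
    provenance: Dict[str, str] = {}
    for rxn in pan.reactions:
        if rxn.gpr is None:
            reactions.append(rxn)
            provenance[rxn.id] = "no_gpr_kept"
            continue
        active, pruned = evaluate_gpr(rxn.gpr, present)
        if active or rxn.id == pan.biomass_id:
            reactions.append(replace(rxn, gpr=pruned))
            provenance[rxn.id] = "derived"
    return SpeciesModel(
        species_id=species_id,
        metabolites=list(pan.metabolites),
        reactions=reactions,
        biomass_id=pan.biomass_id,
        provenance=provenance,
    )


def check_producibility(
    model: SpeciesModel,
    metabolite_id: str,
    media: MediaSpec,
    threshold: float = GROWTH_THRESHOLD,
) -> bool:
    """Can the model produce the metabolite under the medium?

    Maximizes flux through a temporary demand reaction draining the
    metabolite; true iff the optimum exceeds the threshold.
    """
    met_ids = {m.id for m in model.metabolites}
    if metabolite_id not in met_ids:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    demand = Reaction(
        id="__demand__", stoichiometry={metabolite_id: -1.0}, lower_bound=0.0
    )
    probe = SpeciesModel(
        species_id=model.species_id,
        metabolites=model.metabolites,
        reactions=model.reactions + [demand],
        biomass_id=model.biomass_id,
    )
    result = solve_fba(probe, media, objective_reaction="__demand__")
    return result.optimal and result.objective > threshold


def _growth(model_reactions, metabolites, biomass_id, media) -> float:
    probe = SpeciesModel("probe", metabolites, list(model_reactions), biomass_id)
    res = solve_fba(probe, media)
    return res.objective if res.optimal else 0.0


def gap_fill(
    model: SpeciesModel,
    pan: PanModel,
    media: MediaSpec,
    growth_threshold: float = GROWTH_THRESHOLD,
    preferred_candidates: Optional[Sequence[str]] = None,
) -> List[str]:
    """Minimum-cardinality reaction set from the pan-model restoring growth.

    Solved as a MILP with one binary indicator per candidate reaction
    coupling its bounds, objective = indicator sum.  Among equal-cardinality
    optima the lexicographically smallest reaction-id set is returned.  A
    user-supplied ``preferred_candidates`` pool is tried first and the full
    pan-minus-model pool only as fallback.  Raises :class:`UnfillableError`
    when no subset restores growth.
    """
    if _growth(model.reactions, model.metabolites, model.biomass_id, media) >= growth_threshold:
        return []
    have = set(model.reaction_ids)
    full_pool = sorted(r.id for r in pan.reactions if r.id not in have)
    pools = []
    if preferred_candidates:
        pools.append(sorted(set(preferred_candidates) & set(full_pool)))
    pools.append(full_pool)
    for pool in pools:
        result = _gap_fill_pool(model, pan, media, growth_threshold, pool)
        if result is not None:
            return result
    raise UnfillableError(
        f"{model.species_id}: no pan-model reaction subset restores growth "
        f">= {growth_threshold} on media {media.name!r}"
    )


def _gap_fill_pool(
    model: SpeciesModel,
    pan: PanModel,
    media: MediaSpec,
    growth_threshold: float,
    pool: List[str],
) -> Optional[List[str]]:
    if not pool:
        return None
    candidates = [pan.reaction(rid) for rid in pool]
    combined = SpeciesModel(
        species_id=model.species_id,
        metabolites=list(pan.metabolites),
        reactions=list(model.reactions) + candidates,
        biomass_id=model.biomass_id,
    )
    rxn_ids, _, s = build_stoichiometry(combined)
    lb, ub = apply_media(combined, media)
    n = len(rxn_ids)
    cand_idx = [rxn_ids.index(rid) for rid in pool]
    growth_row = np.zeros(n)
    growth_row[rxn_ids.index(model.biomass_id)] = 1.0

    def solve(forced_on=(), forced_off=(), cardinality=None):
        return solve_milp_min_count(
            n_cont=n,
            candidate_idx=cand_idx,
            a_eq=s,
            b_eq=np.zeros(s.shape[0]),
            lb=lb,
            ub=ub,
            extra_lb_row=growth_row,
            extra_lb_value=growth_threshold,
            forced_on=forced_on,
            forced_off=forced_off,
            cardinality=cardinality,
        )

    indicators = solve()
    if indicators is None:
        return None
    k_star = int(indicators.sum())
    if k_star == 0:
        return []
    # lexicographically smallest id set among size-k* optima
    forced_on: List[int] = []
    for pos in range(len(pool)):
        if len(forced_on) == k_star:
            break
        trial = solve(forced_on=forced_on + [pos], cardinality=k_star)
        if trial is not None:
            forced_on.append(pos)
    chosen = [pool[pos] for pos in forced_on]
    # post-check: adding the set restores growth
    filled = apply_gap_fill(model, pan, chosen)
    if _growth(filled.reactions, filled.metabolites, filled.biomass_id, media) < growth_threshold:
        raise RuntimeError("gap-fill post-check failed: growth not restored")
    return chosen


def apply_gap_fill(
    model: SpeciesModel, pan: PanModel, reaction_ids: Sequence[str]
) -> SpeciesModel:
    """Return a copy of the model with the reactions added, tagged
    ``gap_filled``."""
    have = set(model.reaction_ids)
    added = [pan.reaction(rid) for rid in reaction_ids if rid not in have]
    provenance = dict(model.provenance)
    for rxn in added:
        provenance[rxn.id] = "gap_filled"
    return SpeciesModel(
        species_id=model.species_id,
        metabolites=list(pan.metabolites),
        reactions=list(model.reactions) + added,
        biomass_id=model.biomass_id,
        provenance=provenance,
    )
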