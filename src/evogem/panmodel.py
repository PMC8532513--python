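"""Pan metabolic network data model and model-set comparisons.

The pan-model is the union metabolic network over a set of species: every
reaction any species can carry, with boolean gene-reaction (GPR) rules keyed
by ortholog-group identifiers.  Species-specific models are derived from it
by :mod:`evogem.ssmodel`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .gpr import GprTree, format_gpr, gene_leaves, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "PanModel",
    "ExistenceMatrix",
    "classify_core_accessory",
    "reaction_hamming",
    "read_pan_model",
    "write_pan_model",
]


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.compartment:
            raise ValueError(f"metabolite {self.id}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol gDW-1 h-1.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed).  ``gpr`` is None for spontaneous and exchange
    reactions, which are always retained in derived species models.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GprTree] = None
    subsystem: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> Set[str]:
        return gene_leaves(self.gpr) if self.gpr is not None else set()


@dataclass
class PanModel:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_id: str
    gene_ids: Set[str] = field(default_factory=set)

    def __post_init__(self):
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        if self.biomass_id not in set(rxn_ids):
            raise ValueError(f"biomass reaction {self.biomass_id!r} not in model")
        declared = set(met_ids)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - declared
            if unknown:
                raise ValueError(
                    f"reaction {rxn.id} references undeclared metabolites {sorted(unknown)}"
                )
        gpr_genes: Set[str] = set()
        for rxn in self.reactions:
            gpr_genes |= rxn.genes
        if not self.gene_ids:
            self.gene_ids = gpr_genes
        elif not gpr_genes <= self.gene_ids:
            raise ValueError(
                f"GPR genes not declared: {sorted(gpr_genes - self.gene_ids)}"
            )

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(met_id)

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_ids(self) -> List[str]:
        return [r.id for r in self.reactions if r.is_exchange]


@dataclass
class ExistenceMatrix:
    """Species x ortholog-group binary presence table."""

    table: pd.DataFrame  # index = species ids, columns = gene ids, cells 0/1

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise ValueError("duplicate species ids")
        if self.table.columns.has_duplicates:
            raise ValueError("duplicate gene ids")
        values = self.table.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("existence matrix cells must be 0 or 1")
        self.table = self.table.astype(int)

    @property
    def species(self) -> List[str]:
        return list(self.table.index)

    @property
    def genes(self) -> List[str]:
        return list(self.table.columns)

    def row(self, species_id: str) -> Dict[str, int]:
        return self.table.loc[species_id].to_dict()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "ExistenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="species"))


# ---------------------------------------------------------------------------
# model-set comparisons
# ---------------------------------------------------------------------------

def classify_core_accessory(
    models: Sequence[Iterable[str]],
) -> Tuple[Set[str], Set[str]]:
    """Split reaction ids into core (present in every model) and accessory.

    ``models`` is a sequence of per-species reaction-id collections.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    sets = [set(m) for m in models]
    core = set.intersection(*sets)
    union = set.union(*sets)
    return core, union - core


def reaction_hamming(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Hamming distances between binary reaction-existence rows.

    Returns a symmetric species x species integer table with zero diagonal.
    """
    values = matrix.to_numpy()
    bad = np.argwhere(~np.isin(values, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-binary cell at species {matrix.index[i]!r}, "
            f"reaction {matrix.columns[j]!r}: {values[i, j]!r}"
        )
    values = values.astype(int)
    dist = (values[:, None, :] != values[None, :, :]).sum(axis=2)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _model_to_dict(model: PanModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": format_gpr(r.gpr),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "biomass_id": model.biomass_id,
    }


def write_pan_model(model: PanModel, path) -> None:
    Path(path).write_text(
        json.dumps(_model_to_dict(model), indent=1, sort_keys=True) + "\n"
    )


def read_pan_model(path) -> PanModel:
    data = json.loads(Path(path).read_text())
    metabolites = [
        Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
        for m in data["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lb"]),
            upper_bound=float(r["ub"]),
            gpr=parse_gpr(r["gpr"]) if r.get("gpr") else None,
            subsystem=r.get("subsystem", ""),
        )
        for r in data["reactions"]
    ]
    return PanModel(metabolites, reactions, data["biomass_id"])
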