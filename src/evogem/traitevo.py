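"""Connecting reaction content to metabolic traits.

Covers: scoring how well a reaction's presence/absence across species
predicts a trait (accuracy and sensitivity of the implied confusion table),
selecting highly correlated reactions at the published thresholds
(accuracy > 0.83, sensitivity > 0.92), classifying per-species trait changes
against the ancestral state posterior (present >= 0.85, absent < 0.15),
mechanistic attribution of trait losses — including the "downstream pathway"
case where the direct utilization pathway is intact but a distantly related
reaction is missing — and tallying gain mechanisms (HGT, gene family
expansion, enzyme promiscuity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .fba import ConfusionCounts, MediaSpec, confusion_metrics, test_substrate_utilization
from .panmodel import PanModel
from .ssmodel import SpeciesModel, gap_fill

ACCURACY_THRESHOLD = 0.83
SENSITIVITY_THRESHOLD = 0.92
PRESENT_CUTOFF = 0.85
ABSENT_CUTOFF = 0.15

__all__ = [
    "TraitTable",
    "reaction_trait_metrics",
    "find_correlated_reactions",
    "classify_trait_changes",
    "attribute_loss_mechanism",
    "gain_mechanism_tally",
]


@dataclass
class TraitTable:
    """Species x trait observations; cells are 1, 0 or NaN (not assayed)."""

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.columns.has_duplicates:
            raise ValueError("duplicate trait ids")
        values = self.table.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0))
        if not ok.all():
            raise ValueError("trait cells must be 1, 0 or NA")
        for trait in self.table.columns:
            if self.table[trait].isna().all():
                raise ValueError(f"trait {trait!r} has no non-NA observation")
        self.table = self.table.astype(float)

    @property
    def species(self):
        return list(self.table.index)

    @property
    def traits(self):
        return list(self.table.columns)

    def to_tsv(self, path) -> None:
        self.table.replace({1.0: "1", 0.0: "0"}).fillna("NA").to_csv(
            path, sep="\t", index_label="species"
        )

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        df = pd.read_csv(path, sep="\t", index_col="species", na_values=["NA"])
        return cls(df)


def reaction_trait_metrics(
    presence: Sequence[int], trait: Sequence[float]
) -> Tuple[float, float]:
    """Accuracy and sensitivity of reaction presence as a trait predictor.

    Species with NA trait values are excluded.  TP = present & trait 1,
    FP = present & trait 0, FN = absent & trait 1, TN = absent & trait 0.
    """
    presence = np.asarray(presence, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if presence.shape != trait.shape:
        raise ValueError("presence and trait vectors differ in length")
    mask = ~np.isnan(trait)
    if not mask.any():
        raise ValueError("all trait observations are NA")
    p = presence[mask].astype(int)
    t = trait[mask].astype(int)
    counts = ConfusionCounts(
        TP=int(((p == 1) & (t == 1)).sum()),
        FP=int(((p == 1) & (t == 0)).sum()),
        FN=int(((p == 0) & (t == 1)).sum()),
        TN=int(((p == 0) & (t == 0)).sum()),
    )
    m = confusion_metrics(counts)
    return m.accuracy, m.sensitivity


def find_correlated_reactions(
    existence: pd.DataFrame,
    trait: Sequence[float],
    accuracy_threshold: float = ACCURACY_THRESHOLD,
    sensitivity_threshold: float = SENSITIVITY_THRESHOLD,
) -> list:
    """Reactions whose presence predicts the trait with accuracy and
    sensitivity strictly above the thresholds.

    ``existence`` is a species x reaction binary table aligned with the
    trait vector.  Returned ids are sorted for determinism.
    """
    hits = []
    trait = np.asarray(trait, dtype=float)
    for rxn in existence.columns:
        acc, sens = reaction_trait_metrics(existence[rxn].to_numpy(), trait)
        if math.isnan(sens):
            continue
        if acc > accuracy_threshold and sens > sensitivity_threshold:
            hits.append(rxn)
    return sorted(hits)


def classify_trait_changes(
    traits: TraitTable,
    ancestor: Mapping[str, float],
    present_cutoff: float = PRESENT_CUTOFF,
    absent_cutoff: float = ABSENT_CUTOFF,
) -> pd.DataFrame:
    """Label each species x trait cell against the ancestral state.

    Ancestor present (posterior >= present_cutoff) and species 0 -> loss;
    ancestor absent (posterior < absent_cutoff) and species 1 -> gain;
    matching states -> retained_present / retained_absent; intermediate
    posterior or NA observation -> undetermined.
    """
    if not absent_cutoff < present_cutoff:
        raise ValueError("absent_cutoff must be below present_cutoff")
    bad = [t for t, p in ancestor.items() if not 0.0 <= p <= 1.0]
    if bad:
        raise ValueError(f"posterior out of [0,1] for traits {bad}")
    out = pd.DataFrame(
        "undetermined", index=traits.table.index, columns=traits.table.columns
    )
    for trait in traits.traits:
        p = ancestor.get(trait)
        if p is None:
            continue
        if p >= present_cutoff:
            anc = 1
        elif p < absent_cutoff:
            anc = 0
        else:
            continue  # ambiguous ancestral state -> undetermined
        col = traits.table[trait]
        for sp, value in col.items():
            if math.isnan(value):
                continue
            value = int(value)
            if anc == 1 and value == 0:
                out.loc[sp, trait] = "loss"
            elif anc == 0 and value == 1:
                out.loc[sp, trait] = "gain"
            elif value == 1:
                out.loc[sp, trait] = "retained_present"
            else:
                out.loc[sp, trait] = "retained_absent"
    return out


def attribute_loss_mechanism(
    species_model: SpeciesModel,
    pan: PanModel,
    trait_id: str,
    direct_pathway_reactions: Set[str],
    correlated: Set[str],
    media: MediaSpec,
    substrate_exchange_id: str,
    replace_exchange_id: str,
) -> str:
    """Explain why a species lost a substrate-utilization trait.

    Returns one of ``correlated_reaction_loss`` (a trait-correlated reaction
    is missing), ``noncorrelated_pathway_loss`` (a direct-pathway reaction is
    missing but none of the correlated ones), ``downstream_pathway_gap`` (the
    whole direct pathway is present and gap-filling to restore utilization
    adds only reactions outside it), or ``unexplained``.
    """
    if test_substrate_utilization(
        species_model, substrate_exchange_id, media, replace_exchange_id
    ):
        raise ValueError(
            f"{species_model.species_id} utilizes {trait_id}: no loss to attribute"
        )
    have = set(species_model.reaction_ids)
    if correlated - have:
        return "correlated_reaction_loss"
    if direct_pathway_reactions - have:
        return "noncorrelated_pathway_loss"
    substrate_media = media.replace_source(replace_exchange_id, substrate_exchange_id)
    try:
        fill = gap_fill(species_model, pan, substrate_media)
    except Exception:
        return "unexplained"
    if fill and not (set(fill) & direct_pathway_reactions):
        return "downstream_pathway_gap"
    return "unexplained"


def gain_mechanism_tally(
    gains: Mapping[str, Iterable[str]],
    pathway_genes: Mapping[str, Set[str]],
    hgt_genes: Set[str],
    expanded_family_genes: Set[str],
    promiscuous_genes: Set[str],
) -> pd.DataFrame:
    """Count candidate mechanisms behind each species' trait gains.

    ``gains`` maps species id -> gained trait ids; ``pathway_genes`` maps
    trait id -> direct-pathway gene set.  A gain is counted under a
    mechanism when its pathway genes intersect that mechanism's gene set;
    categories are not mutually exclusive and are reported separately.
    """
    records = []
    for species, traits in sorted(gains.items()):
        row = {"species": species, "hgt": 0, "expanded_family": 0, "promiscuity": 0}
        for trait in traits:
            if trait not in pathway_genes:
                raise KeyError(f"no pathway genes recorded for trait {trait!r}")
            genes = pathway_genes[trait]
            if genes & hgt_genes:
                row["hgt"] += 1
            if genes & expanded_family_genes:
                row["expanded_family"] += 1
            if genes & promiscuous_genes:
                row["promiscuity"] += 1
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("species")
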