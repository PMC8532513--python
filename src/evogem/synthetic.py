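"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with seeded
randomness and a recorded answer key, so each downstream stage has a known
expected result:

* a growth-capable toy pan-network (complexes, isozymes, a promiscuous
  ortholog, a "downstream pathway" reaction required by lower-entry
  substrates but on no catabolic branch) plus an existence matrix whose
  ortholog losses are placed on branches of a random species tree;
* trait tables simulated by FBA with optional observation noise;
* homology hit tables with planted distant- and close-donor HGT genes;
* two-class nucleotide sequences with class-dependent trinucleotide
  composition and evolution features;
* a helix backbone with a planted spatial cluster of fast-evolving sites.

The pan-network topology: every substrate has an exchange, a transporter and
a catabolic reaction feeding one of two hub metabolites (upper U or lower
L).  Biomass needs precursors from both hubs; U -> L runs through a
respiratory complex (or a fermentative bypass), while L -> U requires the
single gluconeogenesis-like "downstream" reaction.  Substrates entering at L
therefore silently depend on that reaction even though their own catabolic
branch is complete — the planted downstream-pathway-gap case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .ecmodel import EcModel, build_ec_model
from .essml import EvolutionFeatures
from .fba import DEFAULT_UPTAKE, MediaSpec, test_substrate_utilization
from .gpr import parse_gpr
from .panmodel import ExistenceMatrix, Metabolite, PanModel, Reaction
from .siteevo import AMINO_ACIDS, AlignmentBlock, StructureModel
from .ssmodel import SpeciesModel, derive_species_model
from .traitevo import TraitTable

__all__ = [
    "SyntheticWorld",
    "generate_pan_network",
    "generate_trait_table",
    "generate_hit_table",
    "generate_sequences",
    "generate_structure_alignment",
    "generate_ec_world",
]

_NT = "ACGT"


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class _TreeNode:
    name: Optional[str]
    children: List["_TreeNode"]
    tips: FrozenSet[str]


def _random_tree(names: Sequence[str], rng: np.random.Generator) -> _TreeNode:
    """Random bifurcating tree by uniform coalescent-style joins."""
    nodes = [_TreeNode(n, [], frozenset([n])) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(_TreeNode(None, [a, b], a.tips | b.tips))
    return nodes[0]


def _newick(node: _TreeNode) -> str:
    if not node.children:
        return node.name
    return "(" + ",".join(_newick(c) for c in node.children) + ")"


def _clades(root: _TreeNode) -> List[FrozenSet[str]]:
    """Tip sets of all proper subtrees (branches), including terminal ones."""
    out: List[FrozenSet[str]] = []

    def walk(node: _TreeNode, is_root: bool):
        if not is_root:
            out.append(node.tips)
        for child in node.children:
            walk(child, False)

    walk(root, True)
    return out


# ---------------------------------------------------------------------------
# the synthetic world
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    pan_model: PanModel
    existence: ExistenceMatrix
    species_tree: str  # newick
    media: MediaSpec  # minimal medium with the default carbon source open
    truth: dict
    default_carbon_exchange: str = "EX_s0"

    @property
    def species(self) -> List[str]:
        return self.existence.species

    def species_model(self, species_id: str) -> SpeciesModel:
        return derive_species_model(
            self.pan_model, self.existence.row(species_id), species_id
        )

    def simulate_traits(self) -> TraitTable:
        """Noiseless FBA-simulated substrate utilization per species."""
        exchanges = self.truth["substrate_exchanges"]
        data = {}
        for sp in self.species:
            model = self.species_model(sp)
            data[sp] = {
                trait: float(
                    test_substrate_utilization(
                        model, ex, self.media, self.default_carbon_exchange
                    )
                )
                for trait, ex in exchanges.items()
            }
        table = pd.DataFrame.from_dict(data, orient="index")
        table = table.loc[self.species, list(exchanges)]
        return TraitTable(table)

    def reaction_existence(self) -> pd.DataFrame:
        """Species x reaction binary table from derived models."""
        all_rxns = self.pan_model.reaction_ids
        rows = {}
        for sp in self.species:
            have = set(self.species_model(sp).reaction_ids)
            rows[sp] = {r: int(r in have) for r in all_rxns}
        return pd.DataFrame.from_dict(rows, orient="index").loc[self.species, all_rxns]

    def write(self, outdir) -> None:
        from .panmodel import write_pan_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pan_model(self.pan_model, outdir / "pan.json")
        self.existence.to_tsv(outdir / "existence.tsv")
        (outdir / "tree.nwk").write_text(self.species_tree + ";\n")
        self.media.to_tsv(outdir / "media.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True, default=_jsonable) + "\n"
        )


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def generate_pan_network(
    n_substrates: int = 4,
    n_species: int = 16,
    complex_fraction: float = 0.3,
    isozyme_fraction: float = 0.3,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate the toy pan-network, species tree and existence matrix.

    Substrate 0 is the default carbon source (upper-hub entry, never lost);
    at least two further substrates enter at the lower hub and depend on the
    downstream reaction ``R_LU``.  When ``n_substrates >= 4`` the last
    substrate is a gain trait whose transporter ortholog (``OG_hgt``) is
    present only in one clade (plus the complete species).  Loss events are
    placed on tree branches: per loss trait one clade loses the catabolic
    ortholog(s) and — when ``n_species >= 12`` — one terminal branch loses
    the transporter; one terminal branch loses ``OG_down`` (the downstream
    reaction), planting the downstream-pathway-gap case.
    """
    if n_substrates < 3:
        raise ValueError("need at least 3 substrates")
    if n_species < 4:
        raise ValueError("need at least 4 species")
    for name, frac in (("complex_fraction", complex_fraction), ("isozyme_fraction", isozyme_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if complex_fraction + isozyme_fraction > 1.0:
        raise ValueError("complex_fraction + isozyme_fraction must be <= 1")
    rng = np.random.default_rng(seed)

    has_gain = n_substrates >= 4
    gain_sub = n_substrates - 1 if has_gain else None
    loss_subs = [i for i in range(1, n_substrates) if i != gain_sub]
    # entries: substrate 0 and the gain trait enter at the upper hub; at
    # least two loss substrates enter at the lower hub
    entry: Dict[int, str] = {0: "U"}
    if gain_sub is not None:
        entry[gain_sub] = "U"
    for k, i in enumerate(loss_subs):
        entry[i] = "L" if k < 2 or k % 2 == 0 else "U"

    mets = [
        Metabolite("u_c"), Metabolite("l_c"),
        Metabolite("pu_c"), Metabolite("pl_c"), Metabolite("pn_c"),
        Metabolite("nh4_e", compartment="e"), Metabolite("nh4_c"),
        Metabolite("pi_e", compartment="e"), Metabolite("pi_c"),
        Metabolite("so4_e", compartment="e"), Metabolite("so4_c"),
        Metabolite("o2_e", compartment="e"), Metabolite("o2_c"),
        Metabolite("eth_c"), Metabolite("eth_e", compartment="e"),
        Metabolite("biomass_c"),
    ]
    for i in range(n_substrates):
        mets += [Metabolite(f"s{i}_e", compartment="e"), Metabolite(f"s{i}_c")]

    def rxn(rid, stoich, gpr=None, lb=0.0, ub=1000.0, subsystem=""):
        return Reaction(rid, stoich, lb, ub, parse_gpr(gpr) if gpr else None, subsystem)

    reactions: List[Reaction] = []
    substrate_exchanges: Dict[str, str] = {}
    direct_pathways: Dict[str, Set[str]] = {}
    pathway_genes: Dict[str, Set[str]] = {}
    gpr_text: Dict[str, str] = {}

    for i in range(n_substrates):
        trait = f"trait_s{i}"
        hub = "u_c" if entry[i] == "U" else "l_c"
        t_gene = "OG_hgt" if i == gain_sub else f"OG_t{i}"
        if i == 0:
            c_gpr = "OG_c0 or OG_prom"
        elif i == gain_sub:
            c_gpr = "OG_cg or OG_prom"
        else:
            c_gpr = f"OG_c{i}"
        reactions.append(rxn(f"EX_s{i}", {f"s{i}_e": -1.0}, subsystem="exchange"))
        reactions.append(
            rxn(f"T_s{i}", {f"s{i}_e": -1.0, f"s{i}_c": 1.0}, t_gene, subsystem="transport")
        )
        reactions.append(
            rxn(f"CAT_s{i}", {f"s{i}_c": -1.0, hub: 1.0}, c_gpr, subsystem="catabolism")
        )
        gpr_text[f"T_s{i}"] = t_gene
        gpr_text[f"CAT_s{i}"] = c_gpr
        substrate_exchanges[trait] = f"EX_s{i}"
        direct_pathways[trait] = {f"EX_s{i}", f"T_s{i}", f"CAT_s{i}"}

    for nut, gene in (("nh4", "OG_tn"), ("pi", "OG_tp"), ("so4", "OG_ts")):
        reactions.append(rxn(f"EX_{nut}", {f"{nut}_e": -1.0}, subsystem="exchange"))
        reactions.append(
            rxn(f"T_{nut}", {f"{nut}_e": -1.0, f"{nut}_c": 1.0}, gene, subsystem="transport")
        )
        gpr_text[f"T_{nut}"] = gene
    reactions.append(rxn("EX_o2", {"o2_e": -1.0}, subsystem="exchange"))
    reactions.append(rxn("T_o2", {"o2_e": -1.0, "o2_c": 1.0}, subsystem="transport"))
    reactions.append(rxn("EX_eth", {"eth_e": -1.0}, subsystem="exchange"))
    reactions.append(rxn("T_eth", {"eth_c": -1.0, "eth_e": 1.0}, subsystem="transport"))

    reactions.append(
        rxn("R_UL", {"u_c": -1.0, "o2_c": -1.0, "l_c": 1.0},
            "OG_ul1 and OG_ul2 and OG_ul3", subsystem="central")
    )
    gpr_text["R_UL"] = "OG_ul1 and OG_ul2 and OG_ul3"
    reactions.append(
        rxn("R_UL_ferm", {"u_c": -1.0, "l_c": 0.5, "eth_c": 0.5}, "OG_ferm",
            subsystem="central")
    )
    gpr_text["R_UL_ferm"] = "OG_ferm"
    reactions.append(
        rxn("R_LU", {"l_c": -1.0, "u_c": 1.0}, "OG_down", subsystem="downstream")
    )
    gpr_text["R_LU"] = "OG_down"
    for rid, stoich, gene in (
        ("PU", {"u_c": -1.0, "o2_c": -1.0, "pu_c": 1.0}, "OG_pu"),
        ("PL", {"l_c": -1.0, "pl_c": 1.0}, "OG_pl"),
        ("PN", {"l_c": -1.0, "nh4_c": -1.0, "pn_c": 1.0}, "OG_pn"),
    ):
        reactions.append(rxn(rid, stoich, gene, subsystem="central"))
        gpr_text[rid] = gene
    reactions.append(
        rxn(
            "r_biomass",
            {"pu_c": -1.0, "pl_c": -1.0, "pn_c": -1.0, "pi_c": -1.0,
             "so4_c": -1.0, "biomass_c": 1.0},
            subsystem="biomass",
        )
    )
    reactions.append(rxn("EX_biomass", {"biomass_c": -1.0}, subsystem="exchange"))

    # random complex/isozyme decoration of single-gene rules
    protected = {f"T_s{gain_sub}" if gain_sub is not None else "", "CAT_s0",
                 f"CAT_s{gain_sub}" if gain_sub is not None else "", "R_UL"}
    decorated: List[Reaction] = []
    for r in reactions:
        text = gpr_text.get(r.id)
        if text is None or r.id in protected or " " in text:
            decorated.append(r)
            continue
        u = rng.random()
        if u < complex_fraction:
            new = f"{text}_su1 and {text}_su2 and {text}_su3"
        elif u < complex_fraction + isozyme_fraction:
            new = f"{text} or {text}_iso"
        else:
            decorated.append(r)
            continue
        gpr_text[r.id] = new
        decorated.append(
            Reaction(r.id, r.stoichiometry, r.lower_bound, r.upper_bound,
                     parse_gpr(new), r.subsystem)
        )
    reactions = decorated

    pan = PanModel(mets, reactions, "r_biomass")
    for trait in substrate_exchanges:
        pathway_genes[trait] = set().union(
            *(pan.reaction(rid).genes for rid in direct_pathways[trait])
        )

    media = MediaSpec(
        {
            "EX_s0": (-DEFAULT_UPTAKE, 1000.0),
            "EX_o2": (-1000.0, 1000.0),
            "EX_nh4": (-1000.0, 1000.0),
            "EX_pi": (-1000.0, 1000.0),
            "EX_so4": (-1000.0, 1000.0),
        },
        name="minimal",
    )

    # ------------------------------------------------------------------
    # species tree and existence matrix with planted events
    # ------------------------------------------------------------------
    species = [f"sp{i:02d}" for i in range(n_species)]
    complete = species[0]
    # the catabolic-loss clade must push the transporter's accuracy to or
    # below 0.83, while the transporter/downstream singletons must leave the
    # catabolic reaction's accuracy strictly above it
    a_size_min = math.ceil(0.17 * n_species + 1e-9)
    a_size_max = max(a_size_min, math.floor(0.3 * n_species))
    plant_transporter_losses = n_species >= 12

    for attempt in range(200):
        tree = _random_tree(species, rng)
        clades = [c for c in _clades(tree) if complete not in c]
        singles = [c for c in clades if len(c) == 1]
        mids = [c for c in clades if a_size_min <= len(c) <= a_size_max]
        gains = [c for c in clades if 2 <= len(c) <= max(2, math.floor(0.3 * n_species))]
        plan = _plan_events(
            rng, loss_subs, entry, singles, mids, gains,
            has_gain, plant_transporter_losses,
        )
        if plan is not None:
            break
    else:
        raise RuntimeError("could not place planted events on a random tree")
    cat_loss, t_loss, downstream_clade, gain_clade = plan

    table = pd.DataFrame(
        1, index=species, columns=sorted(pan.gene_ids), dtype=int
    )
    if has_gain:
        table.loc[:, "OG_hgt"] = 0
        for sp in gain_clade | {complete}:
            table.loc[sp, "OG_hgt"] = 1
    for i, clade in cat_loss.items():
        for g in pan.reaction(f"CAT_s{i}").genes:
            table.loc[sorted(clade), g] = 0
    for i, clade in t_loss.items():
        for g in pan.reaction(f"T_s{i}").genes:
            table.loc[sorted(clade), g] = 0
    for g in pan.reaction("R_LU").genes:
        table.loc[sorted(downstream_clade), g] = 0
    # harmless decorations: drop isozyme partners / the fermentative bypass
    # on random clades so losses look phylogenetically clustered
    droppable = [g for g in sorted(pan.gene_ids) if g.endswith("_iso")]
    if "OG_ferm" in pan.gene_ids:
        droppable.append("OG_ferm")
    for g in droppable:
        if rng.random() < 0.4:
            clade = clades[int(rng.integers(len(clades)))]
            table.loc[sorted(clade), g] = 0
    table.loc[complete, :] = 1  # the complete species keeps everything
    existence = ExistenceMatrix(table)

    # ------------------------------------------------------------------
    # answer key
    # ------------------------------------------------------------------
    l_entry_loss = [i for i in loss_subs if entry[i] == "L"]
    loss_labels: Dict[str, Dict[str, str]] = {}
    for i in loss_subs:
        trait = f"trait_s{i}"
        labels: Dict[str, str] = {}
        for sp in sorted(cat_loss[i]):
            labels[sp] = "correlated_reaction_loss"
        for sp in sorted(t_loss.get(i, frozenset())):
            labels[sp] = "noncorrelated_pathway_loss"
        if entry[i] == "L":
            for sp in sorted(downstream_clade - cat_loss[i] - t_loss.get(i, frozenset())):
                labels[sp] = "downstream_pathway_gap"
        loss_labels[trait] = labels

    ancestral = {f"trait_s{i}": 0.95 for i in range(n_substrates)}
    if has_gain:
        ancestral[f"trait_s{gain_sub}"] = 0.05

    truth = {
        "substrate_exchanges": substrate_exchanges,
        "trait_causal_reactions": {
            f"trait_s{i}": [f"CAT_s{i}"] for i in loss_subs
        },
        "direct_pathway_reactions": {t: sorted(v) for t, v in direct_pathways.items()},
        "pathway_genes": {t: sorted(v) for t, v in pathway_genes.items()},
        "downstream_reaction": "R_LU",
        "downstream_dependent_traits": [f"trait_s{i}" for i in l_entry_loss],
        "loss_labels": loss_labels,
        "loss_traits": [f"trait_s{i}" for i in loss_subs],
        "gain_traits": [f"trait_s{gain_sub}"] if has_gain else [],
        "gain_species": sorted(gain_clade | {complete}) if has_gain else [],
        "ancestral_posterior": ancestral,
        "hgt_genes": ["OG_hgt"] if has_gain else [],
        "promiscuous_genes": ["OG_prom"],
        "expanded_family_genes": ["OG_prom"],
        "complete_species": complete,
        "entry_hub": {f"trait_s{i}": entry[i] for i in range(n_substrates)},
    }
    return SyntheticWorld(
        pan_model=pan,
        existence=existence,
        species_tree=_newick(tree),
        media=media,
        truth=truth,
    )


def _plan_events(
    rng: np.random.Generator,
    loss_subs: Sequence[int],
    entry: Mapping[int, str],
    singles: List[FrozenSet[str]],
    mids: List[FrozenSet[str]],
    gains: List[FrozenSet[str]],
    has_gain: bool,
    plant_transporter_losses: bool,
):
    """Assign clades to planted events.

    The downstream clade must be disjoint from each lower-entry trait's
    other loss clades, and each trait's own clades must be disjoint, so that
    per-trait loss groups do not overlap and the accuracy arithmetic at the
    0.83 threshold is exact.  Overlap across different traits is allowed.
    """
    if not singles or not mids or (has_gain and not gains):
        return None
    # all loss-event clades are kept mutually disjoint: identical or nested
    # catabolic-loss clades for two traits would make each trait's catabolic
    # reaction correlate with the other trait as well
    used: FrozenSet[str] = frozenset()
    order = rng.permutation(len(singles))
    downstream_clade = singles[int(order[0])]
    used |= downstream_clade
    cat_loss: Dict[int, FrozenSet[str]] = {}
    t_loss: Dict[int, FrozenSet[str]] = {}
    for i in loss_subs:
        mid_ok = [c for c in mids if not (c & used)]
        if not mid_ok:
            return None
        cat = mid_ok[int(rng.integers(len(mid_ok)))]
        cat_loss[i] = cat
        used |= cat
        if plant_transporter_losses:
            single_ok = [c for c in singles if not (c & used)]
            if not single_ok:
                return None
            t_loss[i] = single_ok[int(rng.integers(len(single_ok)))]
            used |= t_loss[i]
    gain_clade = gains[int(rng.integers(len(gains)))] if has_gain else frozenset()
    return cat_loss, t_loss, downstream_clade, gain_clade


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def generate_trait_table(
    world: SyntheticWorld,
    flip_rate: float = 0.0,
    na_fraction: float = 0.0,
    seed: int = 0,
) -> TraitTable:
    """Observed trait table: FBA-simulated utilization with each value
    independently flipped with probability ``flip_rate`` and a fraction
    masked to NA."""
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    if not 0.0 <= na_fraction <= 1.0:
        raise ValueError("na_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    table = world.simulate_traits().table.copy()
    values = table.to_numpy()
    flips = rng.random(values.shape) < flip_rate
    values = np.where(flips, 1.0 - values, values)
    mask = rng.random(values.shape) < na_fraction
    values = np.where(mask, np.nan, values)
    return TraitTable(pd.DataFrame(values, index=table.index, columns=table.columns))


# ---------------------------------------------------------------------------
# HGT hit tables
# ---------------------------------------------------------------------------

def generate_hit_table(
    n_genes: int,
    n_hgt_distant: int,
    n_hgt_close: int,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Hit table with planted HGT genes; returns (table, truth).

    Distant-HGT genes get outside-group best hits at least e^45 stronger
    than any group-lineage hit and >= 90% outside-group hit rows; close-HGT
    genes get group-lineage best hits with bitscore >= 100, >= 90%
    group-lineage rows and an HGT index >= 0.5.  Ordinary genes fail all
    screens.  "No hit" in a lineage is an absent row.
    """
    if n_hgt_distant + n_hgt_close > n_genes:
        raise ValueError("planted HGT genes exceed n_genes")
    rng = np.random.default_rng(seed)
    rows = []
    distant = [f"g{k:04d}" for k in range(n_hgt_distant)]
    close = [f"g{k:04d}" for k in range(n_hgt_distant, n_hgt_distant + n_hgt_close)]
    normal = [f"g{k:04d}" for k in range(n_hgt_distant + n_hgt_close, n_genes)]

    def log_uniform(lo_exp, hi_exp):
        return 10.0 ** rng.uniform(lo_exp, hi_exp)

    def add(gene, cls, evalue, bitscore, sp):
        rows.append(
            {"gene_id": gene, "taxonomy_class": cls, "evalue": evalue,
             "bitscore": bitscore, "species": sp}
        )

    for gene in normal:
        best = log_uniform(-180, -20)
        add(gene, "recipient_subphylum", best, rng.uniform(200, 500), f"{gene}_rec0")
        for k in range(8):  # group hits, weak bitscores: fail the close screen
            add(gene, "group_lineage", best * 10 ** rng.uniform(1, 20),
                rng.uniform(30, 90), f"{gene}_grp{k}")
        # out-group hit no stronger than the group best: AI <= 0
        add(gene, "outside_group", best * 10 ** rng.uniform(21, 40),
            rng.uniform(20, 60), f"{gene}_out0")

    for gene in distant:
        bbh_o = log_uniform(-150, -60)
        add(gene, "recipient_subphylum", log_uniform(-170, -100),
            rng.uniform(200, 500), f"{gene}_rec0")
        n_out = 10
        for k in range(n_out):
            ev = bbh_o if k == 0 else bbh_o * 10 ** rng.uniform(0, 10)
            add(gene, "outside_group", ev, rng.uniform(150, 400), f"{gene}_out{k}")
        if rng.random() < 0.5:  # at most one weak in-group hit (<=10% of rows)
            bbh_g = bbh_o * math.exp(rng.uniform(50, 120))
            add(gene, "group_lineage", min(bbh_g, 0.9), rng.uniform(30, 80),
                f"{gene}_grp0")

    for gene in close:
        rec_score = rng.uniform(170, 300)
        add(gene, "recipient_subphylum", log_uniform(-150, -60), rec_score,
            f"{gene}_rec0")
        best_group = rec_score * rng.uniform(0.6, 0.9)  # >= 102 and ratio >= 0.5
        for k in range(10):
            score = best_group if k == 0 else best_group * rng.uniform(0.5, 0.99)
            add(gene, "group_lineage", log_uniform(-120, -40), score,
                f"{gene}_grp{k}")
        if rng.random() < 0.5:  # rare weak out-group hit
            add(gene, "outside_group", log_uniform(-20, -5),
                best_group * rng.uniform(0.1, 0.4), f"{gene}_out0")

    table = pd.DataFrame.from_records(rows)
    truth = {"distant": distant, "close": close, "none": normal}
    return table, truth


# ---------------------------------------------------------------------------
# labelled sequences for essential-gene prediction
# ---------------------------------------------------------------------------

def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def generate_sequences(
    n_per_class: int,
    length: int = 300,
    shift: float = 0.2,
    seed: int = 0,
) -> Tuple[Dict[str, str], Dict[str, int], Dict[str, EvolutionFeatures], dict]:
    """Two-class nucleotide records with class-dependent composition.

    Sequences are drawn from an order-2 Markov chain; the essential class's
    conditional trinucleotide profile is displaced from the non-essential
    one in log-space by ``shift``.  Evolution features (conservation, dN/dS,
    occurrence, paralog number) are drawn from class-conditional
    distributions whose separation also scales with ``shift``, so
    ``shift=0`` carries no signal at all.  Returns (sequences, labels,
    evolution features, truth).
    """
    if length < 30:
        raise ValueError("length must be >= 30")
    if not 0.0 <= shift <= 0.3:
        raise ValueError("shift must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    base_logits = rng.normal(0.0, 0.5, size=(16, 4))
    delta = rng.normal(0.0, 1.0, size=(16, 4))
    profiles = {
        0: _softmax(base_logits),
        1: _softmax(base_logits + 0.6 * shift * delta),
    }

    def draw_sequence(label: int) -> str:
        p = profiles[label]
        seq = [int(rng.integers(4)), int(rng.integers(4))]
        for _ in range(length - 2):
            ctx = seq[-2] * 4 + seq[-1]
            seq.append(int(rng.choice(4, p=p[ctx])))
        return "".join(_NT[i] for i in seq)

    sequences: Dict[str, str] = {}
    labels: Dict[str, int] = {}
    evo: Dict[str, EvolutionFeatures] = {}
    for label, prefix in ((1, "ess"), (0, "non")):
        for k in range(n_per_class):
            gene = f"{prefix}{k:04d}"
            sequences[gene] = draw_sequence(label)
            labels[gene] = label
            cons_mu = 0.6 + (0.9 * shift if label == 1 else 0.0)
            cons = float(np.clip(rng.normal(cons_mu, 0.08), 0.0, 1.0))
            dnds = float(rng.lognormal(math.log(0.25) - (7.0 * shift if label else 0.0), 0.35))
            occ_mu = 150 + (500 * shift if label == 1 else 0.0)
            occ = int(np.clip(round(rng.normal(occ_mu, 50)), 1, 332))
            par_scale = max(0.05, 0.3 - (1.0 * shift if label == 1 else 0.0))
            n_unique = occ
            n_seq = n_unique + int(rng.poisson(par_scale * n_unique))
            evo[gene] = EvolutionFeatures(
                conservation_score=cons,
                dn_ds=dnds,
                occurrence_count=occ,
                avg_paralog_number=n_seq / n_unique,
            )
    truth = {
        "shift": shift,
        "length": length,
        "n_per_class": n_per_class,
        "labels": dict(labels),
    }
    return sequences, labels, evo, truth


# ---------------------------------------------------------------------------
# structures and alignments with a planted spatial cluster
# ---------------------------------------------------------------------------

def generate_structure_alignment(
    n_species: int = 20,
    length: int = 80,
    n_cluster_sites: int = 4,
    seed: int = 0,
) -> Tuple[AlignmentBlock, StructureModel, dict]:
    """Helix backbone + alignment with planted fast-evolving cluster.

    The backbone is an ideal helix (1.5 A rise, 100 degree turn, 2.3 A
    radius); on it, spatial adjacency below 6 A is only possible at small
    sequence offsets, so the planted cluster uses offsets of 1, 3 and 4
    residues: consecutive cluster sites are < 6 A apart while the cluster as
    a whole spans several turns.  Invariant "functional" columns are placed
    at least 10 A (>= 7 residues along the helix axis) from every cluster
    site; cluster columns are hyper-variable across species.
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    if n_cluster_sites < 3:
        raise ValueError("need at least 3 cluster sites")
    if n_cluster_sites > length / 4:
        raise ValueError("n_cluster_sites must be <= length/4")
    rng = np.random.default_rng(seed)

    k = np.arange(length)
    theta = np.deg2rad(100.0 * k)
    coords = {
        int(i + 1): np.array([2.3 * math.cos(t), 2.3 * math.sin(t), 1.5 * i])
        for i, t in zip(k, theta)
    }

    start = max(1, length // 4)
    offsets = [0]
    step = [3, 1, 3]  # alternating small offsets keep consecutive pairs < 6 A
    while len(offsets) < n_cluster_sites:
        offsets.append(offsets[-1] + step[(len(offsets) - 1) % len(step)])
    cluster_sites = [start + o for o in offsets]
    if cluster_sites[-1] > length:
        raise ValueError("cluster does not fit in the structure")

    # functional sites at the far end, >= 10 A from every cluster site
    n_functional = max(3, length // 20)
    functional: List[int] = []
    pos = length
    cluster_xyz = np.array([coords[s] for s in cluster_sites])
    while len(functional) < n_functional and pos > 0:
        d = np.sqrt(((cluster_xyz - coords[pos]) ** 2).sum(axis=1)).min()
        if d >= 10.0 and pos not in cluster_sites:
            functional.append(pos)
            pos -= 3
        else:
            pos -= 1
    if len(functional) < n_functional:
        raise ValueError("could not place functional sites >= 10 A away")

    aa = np.array(list(AMINO_ACIDS))
    ref_seq = aa[rng.integers(len(aa), size=length)]
    species = [f"sp{i:02d}" for i in range(n_species)]
    records: List[Tuple[str, str]] = []
    cluster_set = set(cluster_sites)
    functional_set = set(functional)
    for si, sp in enumerate(species):
        if si == 0:
            records.append((sp, "".join(ref_seq)))
            continue
        chars = []
        for p in range(1, length + 1):
            if p in functional_set:
                chars.append(ref_seq[p - 1])  # invariant column
            elif p in cluster_set:
                chars.append(str(aa[rng.integers(len(aa))]))  # fast-evolving
            elif rng.random() < 0.05:
                chars.append("-")
            elif rng.random() < 0.15:
                chars.append(str(aa[rng.integers(len(aa))]))
            else:
                chars.append(ref_seq[p - 1])
        records.append((sp, "".join(chars)))
    block = AlignmentBlock(records, reference_id=species[0])

    half = len(functional) // 2 or 1
    structure = StructureModel(
        coords,
        annotations={
            "active_site": set(functional[:half]),
            "binding_site": set(functional[half:]),
        },
    )
    site_dnds = {s: float(rng.uniform(1.2, 3.0)) for s in cluster_sites}
    site_dnds.update(
        {p: float(rng.uniform(0.05, 0.6)) for p in functional}
    )
    truth = {
        "cluster_sites": cluster_sites,
        "functional_sites": sorted(functional),
        "site_dnds": site_dnds,
    }
    return block, structure, truth


# ---------------------------------------------------------------------------
# enzyme-constrained toy with a fermentation/respiration branch
# ---------------------------------------------------------------------------

def generate_ec_world(pool: float = 0.05) -> Tuple[EcModel, MediaSpec, dict]:
    """Small enzyme-constrained model exhibiting overflow metabolism.

    Glucose uptake is catalysed by an uptake enzyme; the intermediate can be
    respired (high biomass yield, enzyme-expensive) or fermented (low yield,
    enzyme-cheap, secreting an ethanol analogue).  Under a tight protein
    pool the optimum mixes both branches and raising the uptake enzyme's
    kcat pushes flux into fermentation — the Crabtree-style response probed
    by kcat scans.  Returns (model, media, truth) with the pool-limiting
    enzyme recorded.
    """
    mets = [
        Metabolite("glc_e", compartment="e"), Metabolite("glc_c"),
        Metabolite("pyr_c"), Metabolite("pre_c"),
        Metabolite("eth_c"), Metabolite("eth_e", compartment="e"),
        Metabolite("o2_e", compartment="e"), Metabolite("o2_c"),
        Metabolite("biomass_c"),
    ]

    def rxn(rid, stoich, gpr=None, lb=0.0, ub=1000.0):
        return Reaction(rid, stoich, lb, ub, parse_gpr(gpr) if gpr else None)

    reactions = [
        rxn("EX_glc", {"glc_e": -1.0}),
        rxn("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, "E_upt"),
        rxn("GLY", {"glc_c": -1.0, "pyr_c": 1.0}, "E_gly"),
        rxn("RESP", {"pyr_c": -1.0, "o2_c": -1.0, "pre_c": 2.0}, "E_resp"),
        rxn("FERM", {"pyr_c": -1.0, "pre_c": 1.0, "eth_c": 1.0}, "E_ferm"),
        rxn("T_eth", {"eth_c": -1.0, "eth_e": 1.0}),
        rxn("EX_eth", {"eth_e": -1.0}),
        rxn("EX_o2", {"o2_e": -1.0}),
        rxn("T_o2", {"o2_e": -1.0, "o2_c": 1.0}),
        rxn("r_biomass", {"pre_c": -1.0, "biomass_c": 1.0}),
        rxn("EX_biomass", {"biomass_c": -1.0}),
    ]
    model = SpeciesModel(
        "ec_toy", mets, reactions, "r_biomass",
        provenance={r.id: "derived" for r in reactions},
    )
    kcat = {
        ("E_upt", "T_glc"): 100.0,
        ("E_gly", "GLY"): 200.0,
        ("E_resp", "RESP"): 20.0,
        ("E_ferm", "FERM"): 400.0,
    }
    mw = {"E_upt": 1.0, "E_gly": 0.5, "E_resp": 5.0, "E_ferm": 0.4}
    ec = build_ec_model(model, kcat, mw, pool)
    media = MediaSpec(
        {"EX_glc": (-DEFAULT_UPTAKE, 1000.0), "EX_o2": (-1000.0, 1000.0)},
        name="glucose_minimal",
    )
    truth = {
        "limiting_enzyme": "E_upt",
        "fermentation_exchange": "EX_eth",
        "carbon_exchange": "EX_glc",
    }
    return ec, media, truth
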