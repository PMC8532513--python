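"""End-to-end pipeline on a seeded synthetic world.

Runs every stage — world generation, species-model derivation, trait
simulation, correlated-reaction detection, gain/loss classification and
attribution, HGT screening, site-level analyses, and essential-gene
features/classification — and writes all outputs as deterministic text
files, so two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import essml, hgt, siteevo
from .ecmodel import compute_fcc, kcat_scan
from .fba import MediaSpec, single_gene_deletions
from .panmodel import classify_core_accessory, reaction_hamming
from .synthetic import (
    SyntheticWorld,
    generate_ec_world,
    generate_hit_table,
    generate_pan_network,
    generate_sequences,
    generate_structure_alignment,
    generate_trait_table,
)
from .traitevo import (
    attribute_loss_mechanism,
    classify_trait_changes,
    find_correlated_reactions,
    gain_mechanism_tally,
)

__all__ = ["run_pipeline"]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default) + "\n")


def _default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(type(obj))


def run_pipeline(
    seed: int = 0,
    outdir: str = "pipeline_out",
    n_substrates: int = 4,
    n_species: int = 16,
    n_sequences_per_class: int = 150,
    n_permutations: int = 2000,
) -> Dict[str, float]:
    """Run all stages on one synthetic world; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, float] = {}

    # -- world, models, traits ------------------------------------------
    world = generate_pan_network(n_substrates, n_species, 0.3, 0.3, seed=seed)
    world.write(out / "world")
    rxn_matrix = world.reaction_existence()
    rxn_matrix.to_csv(out / "reaction_existence.tsv", sep="\t", index_label="species")
    reaction_hamming(rxn_matrix).to_csv(out / "hamming.tsv", sep="\t", index_label="species")
    core, accessory = classify_core_accessory(
        [set(rxn_matrix.columns[rxn_matrix.loc[sp] == 1]) for sp in rxn_matrix.index]
    )
    _dump_json({"core": core, "accessory": accessory}, out / "core_accessory.json")
    summary["n_core_reactions"] = len(core)
    summary["n_accessory_reactions"] = len(accessory)

    traits = generate_trait_table(world, flip_rate=0.0, seed=seed + 1)
    traits.to_tsv(out / "traits.tsv")

    essential = single_gene_deletions(
        world.species_model(world.truth["complete_species"]), world.media
    )
    pd.Series(essential, name="call").to_csv(
        out / "essentiality.tsv", sep="\t", index_label="gene"
    )
    summary["n_essential_genes"] = sum(v == "essential" for v in essential.values())

    # -- trait evolution ------------------------------------------------
    changes = classify_trait_changes(traits, world.truth["ancestral_posterior"])
    changes.to_csv(out / "trait_changes.tsv", sep="\t", index_label="species")

    correlated: Dict[str, list] = {}
    attribution_rows = []
    n_attributed = n_losses = 0
    for trait in world.truth["loss_traits"]:
        corr = find_correlated_reactions(rxn_matrix, traits.table[trait].to_numpy())
        correlated[trait] = corr
        ex = world.truth["substrate_exchanges"][trait]
        direct = set(world.truth["direct_pathway_reactions"][trait])
        for sp, expected in world.truth["loss_labels"][trait].items():
            label = attribute_loss_mechanism(
                world.species_model(sp), world.pan_model, trait, direct,
                set(corr), world.media, ex, world.default_carbon_exchange,
            )
            attribution_rows.append(
                {"trait": trait, "species": sp, "label": label, "expected": expected}
            )
            n_losses += 1
            n_attributed += int(label == expected)
    _dump_json(correlated, out / "correlated_reactions.json")
    pd.DataFrame(attribution_rows).to_csv(out / "loss_attribution.tsv", sep="\t", index=False)
    summary["loss_attribution_agreement"] = (
        n_attributed / n_losses if n_losses else float("nan")
    )

    gains = {
        sp: [t for t in changes.columns if changes.loc[sp, t] == "gain"]
        for sp in changes.index
    }
    tally = gain_mechanism_tally(
        gains,
        {t: set(g) for t, g in world.truth["pathway_genes"].items()},
        set(world.truth["hgt_genes"]),
        set(world.truth["expanded_family_genes"]),
        set(world.truth["promiscuous_genes"]),
    )
    tally.to_csv(out / "gain_mechanisms.tsv", sep="\t", index_label="species")

    # -- HGT screening --------------------------------------------------
    hits, hit_truth = generate_hit_table(60, 5, 5, seed=seed + 2)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    distant = hgt.screen_distant(hits)
    close = hgt.screen_close(hits)
    hgt.calls_to_frame(distant + close).to_csv(out / "hgt_calls.tsv", sep="\t", index=False)
    summary["hgt_distant_recovered"] = int(
        sorted(c.gene_id for c in distant) == sorted(hit_truth["distant"])
    )
    summary["hgt_close_recovered"] = int(
        sorted(c.gene_id for c in close) == sorted(hit_truth["close"])
    )

    # -- site-level analyses --------------------------------------------
    block, structure, site_truth = generate_structure_alignment(
        n_species=20, length=80, n_cluster_sites=4, seed=seed + 3
    )
    block.to_fasta(out / "alignment.fasta")
    siteevo.write_ca_structure(structure, out / "structure.pdb")
    cons = siteevo.jsd_conservation(block)
    cons.to_csv(out / "conservation.tsv", sep="\t", index=False)
    dists = siteevo.distance_to_functional_sites(
        site_truth["cluster_sites"], structure
    )
    dists.to_csv(out / "site_distances.tsv", sep="\t", index=False)
    score, p_value = siteevo.clumps_test(
        site_truth["cluster_sites"], structure, n_permutations=n_permutations,
        seed=seed + 4,
    )
    summary["clumps_score"] = score
    summary["clumps_p_value"] = p_value

    # -- essential-gene machine learning --------------------------------
    sequences, labels, evo, _ = generate_sequences(
        n_sequences_per_class, length=300, shift=0.2, seed=seed + 5
    )
    features_full = essml.feature_table(sequences, evo)
    features_seq = essml.feature_table(sequences)
    features_full.to_csv(out / "features.tsv", sep="\t", index_label="gene")
    y = [labels[g] for g in features_full.index]
    auc_seq = essml.cross_validated_auc(features_seq, y, kind="rf", seed=seed + 6)
    auc_full = essml.cross_validated_auc(features_full, y, kind="rf", seed=seed + 6)
    summary["auc_sequence_only"] = auc_seq
    summary["auc_with_evolution_features"] = auc_full
    ranking = essml.feature_importance_chi2(features_full, y)
    ranking.to_csv(out / "feature_ranking.tsv", sep="\t", index=False)

    # -- enzyme-constrained analysis ------------------------------------
    ec, ec_media, ec_truth = generate_ec_world()
    fcc = {
        enzyme: compute_fcc(ec, enzyme, media=ec_media) for enzyme in ec.enzymes
    }
    _dump_json(fcc, out / "fcc.json")
    summary["fcc_sum"] = float(sum(fcc.values()))
    free_media = ec_media.with_exchange(ec_truth["carbon_exchange"], -1000.0, 1000.0)
    scan = kcat_scan(
        ec, [ec_truth["limiting_enzyme"]], [1, 2, 4, 6, 8, 10],
        [ec_truth["fermentation_exchange"]], media=free_media,
        carbon_exchange_id=ec_truth["carbon_exchange"],
    )
    scan.to_csv(out / "kcat_scan.tsv", sep="\t", index=False)

    _dump_json(summary, out / "summary.json")
    return summary
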