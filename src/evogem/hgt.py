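"""Horizontal gene transfer screening from tabulated homology-search hits.

Two screens mirror the standard practice for yeast:

* **distant** (donor outside the fungal lineage): Alien Index

      AI = ln(bbhG + 1e-200) - ln(bbhO + 1e-200),

  where bbhG is the E-value of the best hit inside the group lineage (fungi
  outside the recipient subphylum) and bbhO the best hit outside it; a gene
  is a candidate when AI >= 45 and the fraction of hit species outside the
  group lineage (out_pct) is >= 90%.

* **close** (donor among other fungi): three sequential filters — best
  non-recipient hit lies in the group lineage with bitscore >= 100; >= 90%
  of non-recipient hits come from the group lineage; HGT index (best
  group-lineage bitscore over best recipient bitscore) >= 0.5.

Taxonomy classes are inputs (``recipient_subphylum``, ``group_lineage``,
``outside_group``); running the homology search and resolving taxonomy are
upstream of this module.  A lineage with no hit at all enters the Alien
Index with the conventional "no significant hit" E-value of 1.0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSEUDO_COUNT = 1e-200
NO_HIT_EVALUE = 1.0  # conventional ceiling when a lineage has no hit
AI_THRESHOLD = 45.0
OUT_PCT_THRESHOLD = 0.90
BITSCORE_THRESHOLD = 100.0
CLOSE_PCT_THRESHOLD = 0.90
HGT_INDEX_THRESHOLD = 0.50

TAXONOMY_CLASSES = ("recipient_subphylum", "group_lineage", "outside_group")

__all__ = [
    "HgtCall",
    "alien_index",
    "out_group_percentage",
    "screen_distant",
    "screen_close",
    "read_hit_table",
]


@dataclass(frozen=True)
class HgtCall:
    gene_id: str
    ai: float
    out_pct: float
    hgt_index: Optional[float]
    screen: str  # distant | close | none


def read_hit_table(path) -> pd.DataFrame:
    """Read a hit table TSV (gene_id, taxonomy_class, evalue, bitscore,
    optional species) and validate it."""
    df = pd.read_csv(path, sep="\t")
    return validate_hit_table(df)


def validate_hit_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "taxonomy_class", "evalue", "bitscore"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns {sorted(missing)}")
    bad = set(df["taxonomy_class"]) - set(TAXONOMY_CLASSES)
    if bad:
        raise ValueError(f"unknown taxonomy classes {sorted(bad)}")
    if (df["evalue"] <= 0).any():
        raise ValueError("E-values must be positive")
    if (df["bitscore"] < 0).any():
        raise ValueError("bitscores must be non-negative")
    return df


def alien_index(bbh_group_evalue: float, bbh_outside_evalue: float) -> float:
    """Alien Index from the two best E-values; positive when the out-group
    hit is stronger (smaller E-value)."""
    if bbh_group_evalue < 0 or bbh_outside_evalue < 0:
        raise ValueError("E-values must be non-negative")
    return math.log(bbh_group_evalue + PSEUDO_COUNT) - math.log(
        bbh_outside_evalue + PSEUDO_COUNT
    )


def _dedup(hits: pd.DataFrame) -> pd.DataFrame:
    """Count unique species when a species column is present, else records."""
    if "species" in hits.columns and hits["species"].notna().all():
        return hits.drop_duplicates(subset=["species"])
    return hits


def out_group_percentage(hits: pd.DataFrame, denominator: str = "non_recipient") -> float:
    """Fraction of hit species with class ``outside_group``.

    ``denominator`` is ``non_recipient`` (group lineage + outside, the
    distant-screen convention) or ``all`` (every hit species).
    """
    if hits.empty:
        raise ValueError("empty hit list")
    deduped = _dedup(hits)
    if denominator == "non_recipient":
        pool = deduped[deduped["taxonomy_class"] != "recipient_subphylum"]
    elif denominator == "all":
        pool = deduped
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if pool.empty:
        return 0.0
    return float((pool["taxonomy_class"] == "outside_group").mean())


def _best_evalue(hits: pd.DataFrame, taxonomy_class: str) -> float:
    sub = hits[hits["taxonomy_class"] == taxonomy_class]
    if sub.empty:
        return NO_HIT_EVALUE
    return float(sub["evalue"].min())


def screen_distant(
    table: pd.DataFrame,
    ai_threshold: float = AI_THRESHOLD,
    out_pct_threshold: float = OUT_PCT_THRESHOLD,
) -> List[HgtCall]:
    """Screen for transfers from outside the group lineage.

    Per gene: AI from the best group-lineage and outside-group E-values,
    out_pct over non-recipient hit species; candidates satisfy both
    thresholds inclusively.
    """
    validate_hit_table(table)
    calls: List[HgtCall] = []
    for gene_id, hits in table.groupby("gene_id", sort=True):
        bbh_g = _best_evalue(hits, "group_lineage")
        bbh_o = _best_evalue(hits, "outside_group")
        if bbh_g == NO_HIT_EVALUE or bbh_o == NO_HIT_EVALUE:
            logger.info("%s: missing best hit in a lineage; AI uses E-value 1.0", gene_id)
        ai = alien_index(bbh_g, bbh_o)
        pct = out_group_percentage(hits, denominator="non_recipient")
        if ai >= ai_threshold and pct >= out_pct_threshold:
            calls.append(HgtCall(str(gene_id), ai, pct, None, "distant"))
    return calls


def screen_close(
    table: pd.DataFrame,
    bitscore_threshold: float = BITSCORE_THRESHOLD,
    pct_threshold: float = CLOSE_PCT_THRESHOLD,
    index_threshold: float = HGT_INDEX_THRESHOLD,
) -> List[HgtCall]:
    """Screen for transfers from closely related (group-lineage) donors.

    Three sequential filters: (1) the best non-recipient hit is in the group
    lineage with bitscore >= 100; (2) the fraction of non-recipient hit
    species in the group lineage is >= 90%; (3) the HGT index — best
    group-lineage bitscore divided by best recipient bitscore — is >= 0.5.
    Genes without a recipient hit are skipped (index undefined).
    """
    validate_hit_table(table)
    calls: List[HgtCall] = []
    for gene_id, hits in table.groupby("gene_id", sort=True):
        non_recipient = hits[hits["taxonomy_class"] != "recipient_subphylum"]
        if non_recipient.empty:
            continue
        best = non_recipient.loc[non_recipient["bitscore"].idxmax()]
        if best["taxonomy_class"] != "group_lineage" or best["bitscore"] < bitscore_threshold:
            continue
        deduped = _dedup(non_recipient)
        pct = float((deduped["taxonomy_class"] == "group_lineage").mean())
        if pct < pct_threshold:
            continue
        recipient = hits[hits["taxonomy_class"] == "recipient_subphylum"]
        if recipient.empty:
            logger.warning("%s: no recipient hit; HGT index undefined, skipped", gene_id)
            continue
        index = float(best["bitscore"]) / float(recipient["bitscore"].max())
        if index >= index_threshold:
            out_pct = out_group_percentage(hits, denominator="non_recipient")
            calls.append(HgtCall(str(gene_id), math.nan, out_pct, index, "close"))
    return calls


def calls_to_frame(calls: List[HgtCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene_id,
                "AI": c.ai,
                "out_pct": c.out_pct,
                "hgt_index": c.hgt_index,
                "screen": c.screen,
            }
            for c in calls
        ],
        columns=["gene", "AI", "out_pct", "hgt_index", "screen"],
    )
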