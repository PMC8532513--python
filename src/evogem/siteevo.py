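"""Residue-level evolution analysis on alignments and 3D structures.

* Column conservation scored as the Jensen-Shannon divergence (base 2,
  lambda = 0.5) between the observed residue distribution and a background,
  linearly penalized by the column's gap fraction; columns with gap fraction
  above 0.3 are flagged low-confidence but still scored.
* Unique-mutation detection for a binary phenotype split (e.g. heat
  tolerance): residues present in > 80% of tolerant species and absent from
  the reference residue set (> 20% of non-tolerant species).
* Euclidean C-alpha distances from candidate sites to annotated functional
  residues, with adjacency at 10 A.
* CLUMPS-style spatial clustering: a Gaussian pair-potential score over the
  flagged sites, tested against a null of uniformly re-placed residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

GAP_CHARS = set("-.")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CUTOFF = 0.3
ADJACENCY_DISTANCE = 10.0  # Angstrom
CLUMPS_BANDWIDTH = 6.0  # Angstrom

__all__ = [
    "AlignmentBlock",
    "StructureModel",
    "jsd_conservation",
    "unique_mutations",
    "distance_to_functional_sites",
    "clumps_test",
    "read_ca_structure",
    "write_ca_structure",
]


@dataclass
class AlignmentBlock:
    """An aligned protein block with a designated ungapped reference."""

    records: List[Tuple[str, str]]  # (species id, aligned residues)
    reference_id: str

    def __post_init__(self):
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences differ in length")
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids in alignment")
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def species(self) -> List[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, species_id: str) -> str:
        for sid, seq in self.records:
            if sid == species_id:
                return seq
        raise KeyError(species_id)

    def reference_positions(self) -> List[Optional[int]]:
        """Per column: 1-based ungapped reference position, or None at
        reference gaps."""
        ref = self.sequence(self.reference_id)
        out: List[Optional[int]] = []
        pos = 0
        for ch in ref:
            if ch in GAP_CHARS:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    @classmethod
    def from_fasta(cls, path, reference_id: str) -> "AlignmentBlock":
        from Bio import SeqIO

        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records, reference_id)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        SeqIO.write(
            [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in self.records],
            str(path),
            "fasta",
        )


@dataclass
class StructureModel:
    """C-alpha coordinates (1-based residue index) plus functional-site
    annotations by category (active_site, binding_site, metal_binding, site,
    ...)."""

    coordinates: Dict[int, np.ndarray]
    annotations: Dict[str, Set[int]] = field(default_factory=dict)

    def __post_init__(self):
        for idx, xyz in self.coordinates.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.isfinite(xyz).all():
                raise ValueError(f"residue {idx}: bad coordinate {xyz!r}")
            self.coordinates[idx] = xyz
        known = set(self.coordinates)
        for cat, sites in self.annotations.items():
            missing = set(sites) - known
            if missing:
                raise ValueError(
                    f"annotation {cat!r} references unknown residues {sorted(missing)}"
                )

    @property
    def positions(self) -> List[int]:
        return sorted(self.coordinates)

    def coordinate_array(self, positions: Optional[Sequence[int]] = None) -> np.ndarray:
        positions = self.positions if positions is None else list(positions)
        return np.array([self.coordinates[p] for p in positions])

    def distance_matrix(self) -> Tuple[List[int], np.ndarray]:
        pos = self.positions
        xyz = self.coordinate_array(pos)
        diff = xyz[:, None, :] - xyz[None, :, :]
        return pos, np.sqrt((diff**2).sum(axis=2))


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def jsd_conservation(
    block: AlignmentBlock,
    background: Optional[np.ndarray] = None,
    gap_cutoff: float = GAP_CUTOFF,
) -> pd.DataFrame:
    """Per-column conservation scores in [0, 1].

    Each column's residue distribution (gaps excluded) is compared to the
    background by Jensen-Shannon divergence (base 2) and multiplied by
    (1 - gap fraction).  Columns with gap fraction above ``gap_cutoff`` are
    flagged low-confidence; all-gap columns score 0.
    Returns a frame with columns: column (1-based), score, gap_fraction,
    low_confidence.
    """
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    background = np.asarray(background, dtype=float)
    if background.shape != (len(AMINO_ACIDS),) or not np.isclose(background.sum(), 1.0):
        raise ValueError("background must be a distribution over the 20 residues")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_seq = len(block.records)
    rows = []
    for col in range(block.length):
        chars = [seq[col] for _, seq in block.records]
        gap_fraction = sum(c in GAP_CHARS for c in chars) / n_seq
        counts = np.zeros(len(AMINO_ACIDS))
        for c in chars:
            if c in aa_index:
                counts[aa_index[c]] += 1
        total = counts.sum()
        if total == 0:
            score = 0.0
        else:
            p = counts / total
            jsd = jensenshannon(p, background, base=2) ** 2
            score = float(jsd * (1.0 - gap_fraction))
        rows.append(
            {
                "column": col + 1,
                "score": score,
                "gap_fraction": gap_fraction,
                "low_confidence": gap_fraction > gap_cutoff,
            }
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# unique mutations
# ---------------------------------------------------------------------------

def unique_mutations(
    block: AlignmentBlock,
    tolerant_species: Set[str],
    non_tolerant_species: Set[str],
    conserved_threshold: float = 0.80,
    reference_threshold: float = 0.20,
    count_gaps_in_denominator: bool = False,
) -> List[Tuple[int, str]]:
    """Residues conserved in the tolerant group but outside the reference set.

    Per reference position, a residue is reported iff its frequency among
    tolerant species exceeds ``conserved_threshold`` and it is absent from
    the reference set (residues exceeding ``reference_threshold`` among
    non-tolerant species).  Frequencies are over species with a non-gap
    character at the column unless ``count_gaps_in_denominator``.  Only
    columns mappable to the reference are reported.
    """
    if tolerant_species & non_tolerant_species:
        raise ValueError("tolerant and non-tolerant species sets overlap")
    if not tolerant_species or not non_tolerant_species:
        raise ValueError("both species sets must be non-empty")
    missing = (tolerant_species | non_tolerant_species) - set(block.species)
    if missing:
        raise ValueError(f"species not in alignment: {sorted(missing)}")

    seqs = dict(block.records)
    ref_positions = block.reference_positions()

    def freq(group: Set[str], col: int) -> Dict[str, float]:
        chars = [seqs[s][col] for s in sorted(group)]
        residues = [c for c in chars if c not in GAP_CHARS]
        denom = len(chars) if count_gaps_in_denominator else len(residues)
        if denom == 0:
            return {}
        out: Dict[str, float] = {}
        for c in residues:
            out[c] = out.get(c, 0.0) + 1.0 / denom
        return out

    hits: List[Tuple[int, str]] = []
    for col, ref_pos in enumerate(ref_positions):
        if ref_pos is None:
            continue
        tol = freq(tolerant_species, col)
        ref_set = {
            r for r, f in freq(non_tolerant_species, col).items() if f > reference_threshold
        }
        for residue, f in sorted(tol.items()):
            if f > conserved_threshold and residue not in ref_set:
                hits.append((ref_pos, residue))
    return hits


# ---------------------------------------------------------------------------
# structure-based analyses
# ---------------------------------------------------------------------------

def distance_to_functional_sites(
    sites: Sequence[int],
    structure: StructureModel,
    categories: Optional[Sequence[str]] = None,
    adjacency: float = ADJACENCY_DISTANCE,
) -> pd.DataFrame:
    """Minimum C-alpha distance from each site to any annotated functional
    residue in the selected categories; adjacent iff distance <= 10 A."""
    categories = list(categories) if categories else sorted(structure.annotations)
    annotated: Set[int] = set()
    for cat in categories:
        annotated |= structure.annotations.get(cat, set())
    if not annotated:
        raise ValueError(f"no annotated residues in categories {categories}")
    missing = set(sites) - set(structure.coordinates)
    if missing:
        raise KeyError(f"sites not in structure: {sorted(missing)}")
    ann_xyz = structure.coordinate_array(sorted(annotated))
    rows = []
    for site in sites:
        d = np.sqrt(((ann_xyz - structure.coordinates[site]) ** 2).sum(axis=1))
        dmin = float(d.min())
        rows.append({"site": site, "min_distance": dmin, "adjacent": dmin <= adjacency})
    return pd.DataFrame.from_records(rows)


def _pair_score(xyz: np.ndarray, bandwidth: float) -> float:
    diff = xyz[:, None, :] - xyz[None, :, :]
    d2 = (diff**2).sum(axis=2)
    weights = np.exp(-d2 / (2.0 * bandwidth**2))
    iu = np.triu_indices(len(xyz), k=1)
    return float(weights[iu].sum())


def clumps_test(
    sites: Sequence[int],
    structure: StructureModel,
    n_permutations: int = 10_000,
    seed: int = 0,
    bandwidth: float = CLUMPS_BANDWIDTH,
) -> Tuple[float, float]:
    """Spatial clustering of flagged sites on a structure.

    Score = sum over site pairs of exp(-d_ij^2 / (2 t^2)) with t the
    bandwidth.  The null re-places the same number of residues uniformly
    without replacement ``n_permutations`` times; the p-value uses add-one
    smoothing, so it lies in (0, 1].
    """
    sites = list(sites)
    if len(sites) < 2:
        raise ValueError("cluster undefined for fewer than 2 sites")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    missing = set(sites) - set(structure.coordinates)
    if missing:
        raise KeyError(f"sites not in structure: {sorted(missing)}")
    positions = structure.positions
    xyz_all = structure.coordinate_array(positions)
    pos_index = {p: i for i, p in enumerate(positions)}
    observed = _pair_score(structure.coordinate_array(sites), bandwidth)

    rng = np.random.default_rng(seed)
    k = len(sites)
    n = len(positions)
    # draw k distinct positions per permutation via partial argsort of noise
    noise = rng.random((n_permutations, n))
    draws = np.argpartition(noise, k - 1, axis=1)[:, :k]
    coords = xyz_all[draws]  # (n_permutations, k, 3)
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    d2 = (diff**2).sum(axis=3)
    weights = np.exp(-d2 / (2.0 * bandwidth**2))
    iu = np.triu_indices(k, k=1)
    null_scores = weights[:, iu[0], iu[1]].sum(axis=1)
    p_value = (1 + int((null_scores >= observed).sum())) / (1 + n_permutations)
    return observed, float(p_value)


# ---------------------------------------------------------------------------
# minimal PDB I/O (C-alpha traces)
# ---------------------------------------------------------------------------

def write_ca_structure(structure: StructureModel, path) -> None:
    """Write a C-alpha-only PDB file (poly-alanine trace)."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as pdbio

    positions = structure.positions
    arr = struc.AtomArray(len(positions))
    arr.coord = structure.coordinate_array(positions)
    arr.chain_id[:] = "A"
    arr.res_id = np.array(positions)
    arr.res_name[:] = "ALA"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.hetero[:] = False
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def read_ca_structure(path, chain: Optional[str] = None) -> StructureModel:
    """Read C-alpha coordinates from a PDB file (ATOM records only)."""
    from biotite.structure.io import pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1)
    mask = arr.atom_name == "CA"
    if chain is not None:
        mask &= arr.chain_id == chain
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ValueError(f"no C-alpha atoms found in {path}")
    coords = {
        int(res_id): coord for res_id, coord in zip(arr.res_id, arr.coord)
    }
    return StructureModel(coords)
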