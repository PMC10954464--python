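"""Residue prioritization for transposase engineering from docking ensembles.

Given an ensemble of protein-DNA docking models, this module ranks models by
the composite docking score (weighted sum of van der Waals, electrostatic,
desolvation and restraint energies), clusters poses by Kabsch RMSD with
greedy best-first leader clustering, identifies protein residues at the DNA
interface (buried-surface-area change or a simple distance rule), keeps
residues that are interfacial in more than two-thirds of the ensemble, and
proposes substitutions by three rules: hydrophobic -> hydrophilic, acidic ->
basic, and naturally occurring variants from a homolog alignment column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("pletools")

__all__ = [
    "Atom",
    "StructureModel",
    "DockingEnsemble",
    "MutationProposal",
    "composite_score",
    "kabsch_rmsd",
    "cluster_models",
    "interface_residues",
    "consensus_targets",
    "propose_mutations",
    "conserved_mask_from_alignment",
    "HYDROPHOBIC",
    "HYDROPHILIC",
    "ACIDIC",
    "BASIC_PLUS_H",
]

DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DN", "A", "C", "G", "T", "U"}

# van der Waals radii (Angstrom) for the Shrake-Rupley surface
_VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
_DEFAULT_RADIUS = 1.7
_PROBE = 1.4
_N_SPHERE_POINTS = 256

HYDROPHOBIC = set("AVLIMFWC")
HYDROPHILIC = set("STNQKREDH")
ACIDIC = set("DE")
BASIC_PLUS_H = set("KRH")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Atom:
    chain: str
    res_index: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def element(self) -> str:
        name = self.atom_name.strip()
        return name[0] if name else "C"

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_dna(self) -> bool:
        return self.res_name in DNA_RESIDUES


@dataclass
class StructureModel:
    """One docking pose: atoms plus the four component energies."""

    model_id: str
    atoms: list[Atom]
    Evdw: float = 0.0
    Elec: float = 0.0
    Edesol: float = 0.0
    Eair: float = 0.0

    def __post_init__(self) -> None:
        coords = np.array([[a.x, a.y, a.z] for a in self.atoms]) if self.atoms else np.zeros((0, 3))
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")

    @property
    def score(self) -> float:
        return composite_score(self.Evdw, self.Elec, self.Edesol, self.Eair)

    def selection_coords(self) -> np.ndarray:
        """Default clustering selection: protein CA plus nucleic-acid P atoms."""
        picked = [
            a.coord for a in self.atoms
            if (not a.is_dna and a.atom_name == "CA") or (a.is_dna and a.atom_name == "P")
        ]
        if not picked:
            raise ValueError(f"model {self.model_id}: no CA/P atoms to cluster on")
        return np.array(picked)

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_dna]

    def dna_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_dna]


@dataclass
class DockingEnsemble:
    """Models plus clustering results (id groups) and per-cluster selections."""

    models: list[StructureModel]
    clusters: list[list[str]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def model_by_id(self, model_id: str) -> StructureModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


@dataclass(frozen=True)
class MutationProposal:
    """Proposed substitutions at one residue, tagged by the rule that fired."""

    residue: int
    wild_type: str
    proposals: dict[str, tuple[str, ...]]  # aa -> rule tags
    support: float

    def __post_init__(self) -> None:
        if self.wild_type in self.proposals:
            raise ValueError("wild type cannot be proposed")


def composite_score(Evdw: float, Elec: float, Edesol: float, Eair: float) -> float:
    """Composite docking score 1.0*Evdw + 0.2*Elec + 1.0*Edesol + 0.1*Eair."""
    for v in (Evdw, Elec, Edesol, Eair):
        if not np.isfinite(v):
            raise ValueError("energy terms must be finite")
    return 1.0 * Evdw + 0.2 * Elec + 1.0 * Edesol + 0.1 * Eair


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets under proper rigid motion.

    Centers both sets, finds the optimal rotation by SVD (determinant +1
    enforced, so reflections are not allowed), and returns the residual RMSD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    if A.shape[0] < 3:
        raise ValueError("need >= 3 atoms for superposition")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Ac @ R.T - Bc
    return float(np.sqrt((diff ** 2).sum() / A.shape[0]))


def cluster_models(
    ensemble: DockingEnsemble,
    cutoff: float = 5.0,
    top_n: int = 4,
) -> DockingEnsemble:
    """Greedy best-first leader clustering of docking poses by RMSD.

    Models are walked in composite-score order (best = most negative first,
    ties by model id); each model joins the first existing cluster whose
    leader is within ``cutoff`` RMSD (inclusive), else founds a new cluster.
    The best ``top_n`` by score in each cluster are marked selected.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    order = sorted(ensemble.models, key=lambda m: (m.score, m.model_id))
    coords = {m.model_id: m.selection_coords() for m in order}
    clusters: list[list[StructureModel]] = []
    for model in order:
        placed = False
        for cluster in clusters:
            leader = cluster[0]
            if kabsch_rmsd(coords[leader.model_id], coords[model.model_id]) <= cutoff:
                cluster.append(model)
                placed = True
                break
        if not placed:
            clusters.append([model])
    selected: list[str] = []
    for cluster in clusters:
        selected.extend(m.model_id for m in cluster[:top_n])
    return DockingEnsemble(
        models=ensemble.models,
        clusters=[[m.model_id for m in c] for c in clusters],
        selected=selected,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic spiral (golden-angle) point set on the unit sphere."""
    idx = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + 5 ** 0.5) * idx
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def _shrake_rupley(atoms: list[Atom]) -> dict[tuple[str, int], float]:
    """Accessible surface area per residue (probe 1.4 A, 256 points/atom)."""
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([_VDW_RADII.get(a.element, _DEFAULT_RADIUS) + _PROBE for a in atoms])
    tree = cKDTree(coords)
    unit = _sphere_points(_N_SPHERE_POINTS)
    asa: dict[tuple[str, int], float] = {}
    max_r = radii.max()
    for i, atom in enumerate(atoms):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[neighbors]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_radii ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = _N_SPHERE_POINTS
        area = 4.0 * np.pi * radii[i] ** 2 * accessible / _N_SPHERE_POINTS
        key = (atom.chain, atom.res_index)
        asa[key] = asa.get(key, 0.0) + area
    return asa


def interface_residues(
    model: StructureModel,
    mode: str = "dasa",
    cutoff: float | None = None,
) -> set[int]:
    """Protein residues at the DNA interface of one docking pose.

    ``dasa`` mode (default, cutoff 1.0 A^2): a residue is interfacial iff its
    solvent-accessible surface area drops by more than the cutoff when the
    DNA is present (Shrake-Rupley, probe 1.4 A, deterministic spiral, 256
    points per atom). ``contact`` mode (default cutoff 5.0 A): any protein
    heavy atom within the cutoff of any DNA atom.
    """
    protein = model.protein_atoms()
    dna = model.dna_atoms()
    if not dna:
        raise ValueError(f"model {model.model_id}: no DNA chain")
    if not protein:
        raise ValueError(f"model {model.model_id}: no protein chain")

    if mode == "contact":
        cut = 5.0 if cutoff is None else cutoff
        p_coords = np.array([[a.x, a.y, a.z] for a in protein])
        d_tree = cKDTree(np.array([[a.x, a.y, a.z] for a in dna]))
        hits = d_tree.query_ball_point(p_coords, cut)
        return {
            protein[i].res_index
            for i, near in enumerate(hits)
            if near and protein[i].element != "H"
        }
    if mode == "dasa":
        cut = 1.0 if cutoff is None else cutoff
        alone = _shrake_rupley(protein)
        complexed = _shrake_rupley(protein + dna)
        out = set()
        for key, area in alone.items():
            delta = area - complexed.get(key, 0.0)
            if delta > cut:
                out.add(key[1])
        return out
    raise ValueError(f"unknown interface mode {mode!r}")


def consensus_targets(
    ensemble: DockingEnsemble,
    interfaces: dict[str, set[int]],
    conserved_mask: set[int] | None = None,
    threshold: float = 2.0 / 3.0,
) -> list[tuple[int, float]]:
    """Residues interfacial in strictly more than ``threshold`` of the models.

    ``interfaces`` maps model id to its interface residue set (typically over
    the selected models of a clustered ensemble). Residues in
    ``conserved_mask`` are excluded. Returns (residue, support) sorted by
    support descending then residue index.
    """
    if not interfaces:
        raise ValueError("empty ensemble")
    conserved_mask = conserved_mask or set()
    n = len(interfaces)
    counts: dict[int, int] = {}
    for resset in interfaces.values():
        for r in resset:
            counts[r] = counts.get(r, 0) + 1
    out = [
        (r, c / n)
        for r, c in counts.items()
        if c / n > threshold and r not in conserved_mask
    ]
    out.sort(key=lambda rs: (-rs[1], rs[0]))
    return out


def propose_mutations(
    residue: int,
    wt_aa: str,
    variant_column: str = "",
    support: float = 1.0,
) -> MutationProposal:
    """Substitution proposals at one residue under the three mutation rules.

    (i) hydrophobic wild type -> every hydrophilic residue; (ii) acidic wild
    type -> basic residues (K, R, H); (iii) every non-wild-type residue
    observed at this position among homologs. Proposals carry the tags of all
    rules that produced them.
    """
    if wt_aa not in STANDARD_AA:
        raise ValueError(f"nonstandard wild-type residue {wt_aa!r}")
    rules: dict[str, list[str]] = {}

    def add(aa: str, tag: str) -> None:
        if aa == wt_aa:
            return
        rules.setdefault(aa, [])
        if tag not in rules[aa]:
            rules[aa].append(tag)

    if wt_aa in HYDROPHOBIC:
        for aa in sorted(HYDROPHILIC):
            add(aa, "hydrophobic_to_hydrophilic")
    if wt_aa in ACIDIC:
        for aa in sorted(BASIC_PLUS_H):
            add(aa, "acidic_to_basic")
    for aa in variant_column:
        if aa in STANDARD_AA:
            add(aa, "natural_variant")

    return MutationProposal(
        residue=residue,
        wild_type=wt_aa,
        proposals={aa: tuple(tags) for aa, tags in sorted(rules.items())},
        support=support,
    )


def conserved_mask_from_alignment(
    rows: list[str],
    target_row: int = 0,
    min_identity: float = 0.9,
) -> set[int]:
    """Residue indices of the target sequence in >= ``min_identity`` conserved columns.

    Helper for the consensus step: alignment columns whose modal residue
    frequency (gaps excluded) reaches the threshold are marked conserved, and
    the corresponding 1-based residue indices of the target row returned.
    """
    if not rows:
        return set()
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows must have equal length")
    conserved: set[int] = set()
    res_idx = 0
    target = rows[target_row]
    for col in range(length):
        if target[col] == "-":
            continue
        res_idx += 1
        column = [r[col] for r in rows if r[col] != "-"]
        if not column:
            continue
        top = max(column.count(a) for a in set(column))
        if top / len(column) >= min_identity:
            conserved.add(res_idx)
    return conserved


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as PDB text with REMARK energy lines."""
    with open(path, "w") as fh:
        for name in ("Evdw", "Elec", "Edesol", "Eair"):
            fh.write(f"REMARK energy {name} {getattr(model, name):.3f}\n")
        for serial, a in enumerate(model.atoms, start=1):
            record = "ATOM"
            fh.write(
                f"{record:<6}{serial:>5} {a.atom_name:<4}{a.res_name:>4}"
                f" {a.chain}{a.res_index:>4}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}\n"
            )
        fh.write("END\n")
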