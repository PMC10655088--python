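"""Read protein structures and extract sp2 planar groups.

The planar groups of interest are the side-chain pi systems of the nine
residue types Arg, His, Asp, Glu, Asn, Gln, Phe, Tyr and Trp, plus the
peptide-backbone amide (the -HN-C=O unit spanning two consecutive
residues).  Each residue type belongs to one of three side-chain classes
-- aromatic (Phe, Trp, Tyr, His), hydrophilic (Asn, Gln) and charged
(Arg, Asp, Glu) -- with the backbone amide forming a fourth class of its
own.  The atom sets defining each plane are data-driven (see
:data:`DEFAULT_REGISTRY`) and can be overridden from a YAML file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

BACKBONE = "BACKBONE"

#: Alternate histidine protonation-state names all map to HIS.
_HIS_ALIASES = {"HID", "HIE", "HIP", "HSD", "HSE", "HSP"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a parsed structure, coordinates in angstrom."""

    name: str
    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_index: int
    chain_id: str

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    def key(self) -> tuple[str, int, str]:
        """Identity of the atom within its structure."""
        return (self.chain_id, self.residue_index, self.name)


@dataclass(frozen=True)
class PlanarGroupSpec:
    """Definition of an sp2 plane for one residue type (or the backbone)."""

    residue_name: str
    plane_atom_names: tuple[str, ...]
    residue_class: str  # aromatic | hydrophilic | charged | backbone
    formal_charge: int = 0
    optional_atom_names: tuple[str, ...] = ()
    min_atoms: int = 3

    def __post_init__(self) -> None:
        if len(self.plane_atom_names) < 3:
            raise ValueError(
                f"{self.residue_name}: a plane needs >= 3 atoms, "
                f"got {len(self.plane_atom_names)}"
            )


@dataclass
class PlanarGroup:
    """An extracted planar group with its atoms and provenance."""

    group_id: str
    spec: PlanarGroupSpec
    atoms: list[AtomRecord]
    source: tuple  # (chain, res_index) or (chain, res_i, res_i_plus_1)
    metadata: dict = field(default_factory=dict)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_class(self) -> str:
        return self.spec.residue_class

    @property
    def is_backbone(self) -> bool:
        return self.spec.residue_class == "backbone"

    def atom_keys(self) -> set[tuple[str, int, str]]:
        return {a.key() for a in self.atoms}


def _spec(resname, atoms, klass, charge=0, optional=()):
    return PlanarGroupSpec(resname, tuple(atoms), klass, charge, tuple(optional))


#: Maximal conjugated heavy-atom set of each sp2 group.  The amide
#: hydrogen is optional because X-ray structures routinely omit it.
DEFAULT_REGISTRY: dict[str, PlanarGroupSpec] = {
    BACKBONE: _spec(BACKBONE, ("C", "O", "N"), "backbone", 0, optional=("H",)),
    "ARG": _spec("ARG", ("CZ", "NE", "NH1", "NH2"), "charged", +1),
    "HIS": _spec("HIS", ("CG", "ND1", "CD2", "CE1", "NE2"), "aromatic", 0),
    "PHE": _spec("PHE", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic", 0),
    "TYR": _spec("TYR", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic", 0),
    "TRP": _spec(
        "TRP",
        ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
        "aromatic",
        0,
    ),
    "ASP": _spec("ASP", ("CG", "OD1", "OD2"), "charged", -1),
    "GLU": _spec("GLU", ("CD", "OE1", "OE2"), "charged", -1),
    "ASN": _spec("ASN", ("CG", "OD1", "ND2"), "hydrophilic", 0),
    "GLN": _spec("GLN", ("CD", "OE1", "NE2"), "hydrophilic", 0),
}

RESIDUE_CLASSES = ("aromatic", "hydrophilic", "charged", "backbone")


def load_registry(path: str | Path) -> dict[str, PlanarGroupSpec]:
    """Load a plane registry from YAML.

    Expected layout::

        PHE:
          plane_atoms: [CG, CD1, CD2, CE1, CE2, CZ]
          class: aromatic
          charge: 0
          optional_atoms: []   # optional
    """
    raw = yaml.safe_load(Path(path).read_text())
    registry = {}
    for resname, entry in raw.items():
        registry[resname] = PlanarGroupSpec(
            residue_name=resname,
            plane_atom_names=tuple(entry["plane_atoms"]),
            residue_class=entry["class"],
            formal_charge=int(entry.get("charge", 0)),
            optional_atom_names=tuple(entry.get("optional_atoms", ())),
        )
    return registry


def canonical_residue_name(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in _HIS_ALIASES:
        return "HIS"
    return resname


def read_structure(path: str | Path, model_index: int = 1) -> list[AtomRecord]:
    """Read all atoms of one model of a PDB file.

    ``model_index`` is 1-based, matching PDB MODEL numbering.  Alternate
    locations other than '' or 'A' are dropped; occupancy is ignored.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse PDB file {path}: {exc}") from exc
    n_models = len(structure)
    if n_models == 0:
        raise IOError(f"no models found in {path}")
    if not 1 <= model_index <= n_models:
        raise ValueError(
            f"model_index {model_index} out of range: {path} has "
            f"{n_models} model(s)"
        )
    model = structure[model_index - 1]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise IOError(
                        f"non-finite coordinates for {atom.name} in {path}"
                    )
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=atom.element.name,
                        coords=(pos.x, pos.y, pos.z),
                        residue_name=residue.name,
                        residue_index=residue.seqid.num,
                        chain_id=chain.name,
                    )
                )
    return atoms


def _group_by_residue(
    atoms: Iterable[AtomRecord],
) -> dict[tuple[str, int], dict[str, AtomRecord]]:
    residues: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for atom in atoms:
        residues.setdefault((atom.chain_id, atom.residue_index), {})[atom.name] = atom
    return residues


def extract_planar_groups(
    atoms: Sequence[AtomRecord],
    registry: Mapping[str, PlanarGroupSpec] | None = None,
) -> list[PlanarGroup]:
    """Extract every complete planar group defined by the registry.

    Side-chain groups require all their plane atoms; backbone amides
    require C and O of residue i and N of residue i+1, with the amide H
    included when present.  Incomplete groups are skipped with a warning
    and never fabricated.  Output order is deterministic (chain, then
    residue index) and independent of the input atom order.
    """
    if registry is None:
        registry = DEFAULT_REGISTRY
    residues = _group_by_residue(atoms)
    resnames: dict[tuple[str, int], str] = {}
    for atom in atoms:
        resnames[(atom.chain_id, atom.residue_index)] = atom.residue_name

    groups: list[PlanarGroup] = []

    # Side-chain planes.
    for (chain, idx) in sorted(residues, key=lambda k: (k[0], k[1])):
        resname = canonical_residue_name(resnames[(chain, idx)])
        spec = registry.get(resname)
        if spec is None or spec.residue_class == "backbone":
            continue
        atom_map = residues[(chain, idx)]
        missing = [n for n in spec.plane_atom_names if n not in atom_map]
        if missing:
            logger.warning(
                "skipping %s %s%d side-chain plane: missing %s",
                resname, chain, idx, ",".join(missing),
            )
            continue
        members = [atom_map[n] for n in spec.plane_atom_names]
        members += [atom_map[n] for n in spec.optional_atom_names if n in atom_map]
        groups.append(
            PlanarGroup(
                group_id=f"{chain}:{idx}:{resname}:SC",
                spec=spec,
                atoms=members,
                source=(chain, idx),
            )
        )

    # Backbone amide planes spanning residues i -> i+1.
    bb_spec = registry.get(BACKBONE)
    if bb_spec is not None:
        by_chain: dict[str, list[int]] = {}
        for (chain, idx) in residues:
            by_chain.setdefault(chain, []).append(idx)
        for chain in sorted(by_chain):
            for idx in sorted(by_chain[chain]):
                nxt = idx + 1
                if (chain, nxt) not in residues:
                    continue
                res_i = residues[(chain, idx)]
                res_j = residues[(chain, nxt)]
                present = ("C" in res_i) + ("O" in res_i) + ("N" in res_j)
                if present < 3:
                    if present > 0:
                        logger.warning(
                            "skipping backbone amide %s%d-%d: incomplete C/O/N",
                            chain, idx, nxt,
                        )
                    continue
                members = [res_i["C"], res_i["O"], res_j["N"]]
                if "H" in res_j:
                    members.append(res_j["H"])
                groups.append(
                    PlanarGroup(
                        group_id=f"{chain}:{idx}-{nxt}:BB",
                        spec=bb_spec,
                        atoms=members,
                        source=(chain, idx, nxt),
                    )
                )

    groups.sort(key=lambda g: (g.source[0], g.source[1], g.group_id))
    return groups
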