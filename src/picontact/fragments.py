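"""Carve interacting residue pairs into capped dimer fragments.

Side chains are cut at the C-beta/C-alpha bond and terminated at C-beta
with a hydrogen (Phe becomes toluene, Asp becomes acetate, and so on).
Backbone amides become N-methylacetamide: the two flanking C-alpha
atoms are kept at their crystallographic positions and converted to
methyl carbons.  Caps never move input atoms; added hydrogens are the
only new coordinates (C-H 1.09 A, N-H 1.01 A, methyl hydrogens placed
tetrahedrally and staggered relative to the amide plane).

Protonation follows the residue-class assignments at physiological pH:
Asp/Glu deprotonated (-1), Arg protonated (+1), His neutral.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import AtomRecord, PlanarGroup

CH_BOND = 1.09  # A
NH_BOND = 1.01  # A
_TET_COS = -1.0 / 3.0  # cos(109.47 deg)


class FragmentError(ValueError):
    """A residue cannot be capped into a chemically complete fragment."""


#: Heavy side-chain atoms retained from C-beta outward, per residue type.
SIDE_CHAIN_HEAVY: dict[str, tuple[str, ...]] = {
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

#: Net charge of each capped side-chain fragment.
FRAGMENT_CHARGE = {
    "PHE": 0, "TYR": 0, "TRP": 0, "HIS": 0,
    "ASN": 0, "GLN": 0, "ASP": -1, "GLU": -1, "ARG": +1,
}

#: Hydrogen names bonded to the backbone, never to the side chain.
_BACKBONE_H = {"H", "HA", "HA2", "HA3", "H1", "H2", "H3", "HN", "HXT"}


@dataclass
class MonomerFragment:
    """A capped monomer: element list, coordinates, and provenance."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) A
    net_charge: int
    source: str  # group_id
    added_atoms: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) != len(self.coords):
            raise ValueError("element and coordinate lists differ in length")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def formula(self) -> str:
        """Hill-order molecular formula, e.g. ``C7H8`` or ``C3H7NO``."""
        counts = Counter(self.elements)
        parts = []
        for el in ("C", "H"):
            n = counts.pop(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(counts):
            n = counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


@dataclass
class DimerFragment:
    monomer_a: MonomerFragment
    monomer_b: MonomerFragment
    pair_type: str
    subclass: str

    @property
    def total_charge(self) -> int:
        return self.monomer_a.net_charge + self.monomer_b.net_charge


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise FragmentError("zero-length bond vector")
    return v / n


def _residue_atoms(
    all_atoms: Sequence[AtomRecord], chain: str, index: int
) -> dict[str, AtomRecord]:
    return {
        a.name: a
        for a in all_atoms
        if a.chain_id == chain and a.residue_index == index
    }


def _methyl_fill(
    center: np.ndarray,
    bonded_heavy: np.ndarray,
    existing_h: list[np.ndarray],
    plane_normal: np.ndarray,
) -> list[np.ndarray]:
    """Positions completing a methyl carbon to three hydrogens.

    The three H directions make the tetrahedral angle with the retained
    heavy-atom bond and sit 120 degrees apart in azimuth.  When no
    hydrogen exists the azimuth is anchored to the amide-plane normal
    (staggered conformation); otherwise the existing hydrogens fix it.
    """
    axis = _unit(bonded_heavy - center)
    ref = plane_normal - np.dot(plane_normal, axis) * axis
    if np.linalg.norm(ref) < 1e-6:
        ref = np.array([1.0, 0.0, 0.0])
        ref -= np.dot(ref, axis) * axis
        if np.linalg.norm(ref) < 1e-6:
            ref = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
    u = _unit(ref)
    v = np.cross(axis, u)

    def direction(theta: float) -> np.ndarray:
        s = np.sqrt(1.0 - _TET_COS**2)
        return _TET_COS * axis + s * (np.cos(theta) * u + np.sin(theta) * v)

    def azimuth(pos: np.ndarray) -> float:
        d = _unit(pos - center)
        return float(np.arctan2(np.dot(d, v), np.dot(d, u)))

    theta0 = azimuth(existing_h[0]) if existing_h else 0.0
    slots = [theta0 + k * 2.0 * np.pi / 3.0 for k in range(3)]
    taken = [azimuth(p) for p in existing_h]
    new = []
    for theta in slots:
        if any(
            abs((theta - t + np.pi) % (2 * np.pi) - np.pi) < np.pi / 6 for t in taken
        ):
            continue
        new.append(center + CH_BOND * direction(theta))
        if len(existing_h) + len(new) == 3:
            break
    return new


def cap_side_chain(
    group: PlanarGroup, all_atoms: Sequence[AtomRecord]
) -> MonomerFragment:
    """Cap a side chain at C-beta with a hydrogen along the old CA bond.

    The fragment keeps every side-chain atom from C-beta outward,
    including any hydrogens present in the input, and adds exactly one
    hydrogen 1.09 A from C-beta in the direction of the removed
    C-alpha.
    """
    chain, index = group.source[0], group.source[1]
    resname = group.spec.residue_name
    heavy = SIDE_CHAIN_HEAVY.get(resname)
    if heavy is None:
        raise FragmentError(f"no side-chain definition for {resname}")
    atom_map = _residue_atoms(all_atoms, chain, index)
    missing = [n for n in heavy if n not in atom_map]
    if missing:
        raise FragmentError(
            f"{resname} {chain}{index}: missing side-chain atom(s) "
            + ",".join(missing)
        )
    if "CA" not in atom_map:
        raise FragmentError(f"{resname} {chain}{index}: missing CA for capping")

    elements, coords = [], []
    for name in heavy:
        a = atom_map[name]
        elements.append(a.element)
        coords.append(a.xyz)
    # Keep existing side-chain hydrogens (MD-derived structures have them).
    for name in sorted(atom_map):
        a = atom_map[name]
        if a.element == "H" and name not in _BACKBONE_H:
            elements.append("H")
            coords.append(a.xyz)

    cb = atom_map["CB"].xyz
    ca = atom_map["CA"].xyz
    cap = cb + CH_BOND * _unit(ca - cb)
    elements.append("H")
    coords.append(cap)
    return MonomerFragment(
        elements=elements,
        coords=np.array(coords),
        net_charge=FRAGMENT_CHARGE[resname],
        source=group.group_id,
        added_atoms=[len(elements) - 1],
    )


def cap_backbone(
    group: PlanarGroup, all_atoms: Sequence[AtomRecord]
) -> MonomerFragment:
    """Cap a peptide amide into N-methylacetamide (CH3-CO-NH-CH3).

    The flanking C-alpha atoms are retained verbatim and completed to
    methyl groups (existing alpha hydrogens are reused); the amide
    hydrogen is reused when present, otherwise placed along the
    idealized sp2 bisector.  Formula C3H7NO, 12 atoms, neutral.
    """
    chain, i, j = group.source
    res_i = _residue_atoms(all_atoms, chain, i)
    res_j = _residue_atoms(all_atoms, chain, j)
    for name, res, which in (("C", res_i, i), ("O", res_i, i), ("N", res_j, j)):
        if name not in res:
            raise FragmentError(f"backbone {chain}{i}-{j}: missing {name} of {which}")
    if "CA" not in res_i or "CA" not in res_j:
        raise FragmentError(f"backbone {chain}{i}-{j}: missing flanking CA")

    c, o = res_i["C"].xyz, res_i["O"].xyz
    n = res_j["N"].xyz
    ca_i, ca_j = res_i["CA"].xyz, res_j["CA"].xyz
    plane_normal = _unit(np.cross(o - c, n - c))

    elements = ["C", "C", "O", "N", "C"]
    coords = [ca_i, c, o, n, ca_j]
    added: list[int] = []

    # Amide hydrogen: reuse, never duplicate.
    if "H" in res_j:
        elements.append("H")
        coords.append(res_j["H"].xyz)
    else:
        h_dir = -(_unit(ca_j - n) + _unit(c - n))
        elements.append("H")
        coords.append(n + NH_BOND * _unit(h_dir))
        added.append(len(elements) - 1)

    # Complete each flanking C-alpha to a methyl carbon.
    for res, ca, heavy in ((res_i, ca_i, c), (res_j, ca_j, n)):
        existing = [
            res[nm].xyz
            for nm in ("HA", "HA2", "HA3")
            if nm in res and res[nm].element == "H"
        ]
        for pos in existing:
            elements.append("H")
            coords.append(pos)
        for pos in _methyl_fill(ca, heavy, existing, plane_normal):
            elements.append("H")
            coords.append(pos)
            added.append(len(elements) - 1)

    return MonomerFragment(
        elements=elements,
        coords=np.array(coords),
        net_charge=0,
        source=group.group_id,
        added_atoms=added,
    )


def build_dimer(
    group_a: PlanarGroup,
    group_b: PlanarGroup,
    all_atoms: Sequence[AtomRecord],
    pair_type: str,
    subclass: str,
) -> DimerFragment:
    """Cap both groups of a contact into a dimer fragment."""

    def cap(group: PlanarGroup) -> MonomerFragment:
        if group.is_backbone:
            return cap_backbone(group, all_atoms)
        return cap_side_chain(group, all_atoms)

    return DimerFragment(
        monomer_a=cap(group_a),
        monomer_b=cap(group_b),
        pair_type=pair_type,
        subclass=subclass,
    )


def write_fragments(
    dimer: DimerFragment, path: str | Path, format: str = "xyz"
) -> None:
    """Write a dimer as XYZ or PDB; monomer membership stays recoverable.

    XYZ: monomer a first, with a comment line recording net charges,
    subclass and the monomer split.  PDB: monomer a is chain A, monomer
    b chain B.  A JSON sidecar (same stem, ``.json``) carries charges,
    subclass and source residue identifiers.
    """
    path = Path(path)
    fmt = format.lower()
    a, b = dimer.monomer_a, dimer.monomer_b
    if fmt == "xyz":
        lines = [str(a.n_atoms + b.n_atoms)]
        lines.append(
            f"charge_a={a.net_charge} charge_b={b.net_charge} "
            f"subclass={dimer.subclass} pair_type={dimer.pair_type} "
            f"natoms_a={a.n_atoms}"
        )
        for mono in (a, b):
            for el, xyz in zip(mono.elements, mono.coords):
                lines.append(f"{el:<2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        lines = []
        serial = 0
        for mono, chain_id, resname in ((a, "A", "MOA"), (b, "B", "MOB")):
            elem_counts: Counter = Counter()
            for el, xyz in zip(mono.elements, mono.coords):
                serial += 1
                elem_counts[el] += 1
                name = f"{el}{elem_counts[el]}"
                lines.append(
                    f"HETATM{serial:5d} {name:<4s} {resname:<3s} {chain_id}{1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
                )
            lines.append(f"TER   {serial + 1:5d}      {resname:<3s} {chain_id}{1:4d}")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown fragment format: {format}")

    sidecar = {
        "pair_type": dimer.pair_type,
        "subclass": dimer.subclass,
        "charge_a": a.net_charge,
        "charge_b": b.net_charge,
        "total_charge": dimer.total_charge,
        "source_a": a.source,
        "source_b": b.source,
        "format": fmt,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_fragment(path: str | Path, format: str | None = None) -> DimerFragment:
    """Read back a dimer written by :func:`write_fragments`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    def monomer(elements, coords, charge, source):
        return MonomerFragment(
            elements=list(elements),
            coords=np.array(coords, dtype=float),
            net_charge=int(charge),
            source=str(source),
        )

    if fmt == "xyz":
        lines = path.read_text().splitlines()
        n_total = int(lines[0].split()[0])
        comment = dict(
            tok.split("=", 1) for tok in lines[1].split() if "=" in tok
        )
        n_a = int(comment["natoms_a"])
        elements, coords = [], []
        for line in lines[2 : 2 + n_total]:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return DimerFragment(
            monomer_a=monomer(
                elements[:n_a], coords[:n_a], comment.get("charge_a", 0),
                sidecar.get("source_a", ""),
            ),
            monomer_b=monomer(
                elements[n_a:], coords[n_a:], comment.get("charge_b", 0),
                sidecar.get("source_b", ""),
            ),
            pair_type=comment.get("pair_type", sidecar.get("pair_type", "")),
            subclass=comment.get("subclass", sidecar.get("subclass", "")),
        )
    if fmt == "pdb":
        chains: dict[str, tuple[list, list]] = {"A": ([], []), "B": ([], [])}
        for line in path.read_text().splitlines():
            if not line.startswith(("ATOM", "HETATM")):
                continue
            chain_id = line[21]
            el = line[76:78].strip() or line[12:14].strip().rstrip("0123456789")
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            chains[chain_id][0].append(el)
            chains[chain_id][1].append(xyz)
        return DimerFragment(
            monomer_a=monomer(
                *chains["A"], sidecar.get("charge_a", 0), sidecar.get("source_a", "")
            ),
            monomer_b=monomer(
                *chains["B"], sidecar.get("charge_b", 0), sidecar.get("source_b", "")
            ),
            pair_type=sidecar.get("pair_type", ""),
            subclass=sidecar.get("subclass", ""),
        )
    raise ValueError(f"unknown fragment format: {fmt}")
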