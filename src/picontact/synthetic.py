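"""Synthetic geometries, structures and decomposition records.

Everything the pipeline consumes can be generated here, deterministic
in its seed: idealized ring dimers at controlled separation, offset and
tilt; whole benchmark frames with planted stacked pairs among random
decoys; hydrogen-complete idealized residues and short peptides for
fragment capping; and decomposition-component records whose
class-conditional structure mirrors what protein fragment dimers show
-- dispersion-dominant neutral stacks, electrostatics-dominant ion
pairs, orbital/dispersion-balanced ion-pi pairs, and dielectric
screening of electrostatics and polarization.

The numeric envelopes of the record generator (total-energy ranges per
class) follow the published per-subset ranges; within those envelopes
the component draws are truncated-uniform, which reproduces the
dominance orderings the classifier relies on without pretending to the
full empirical spread.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .eda import EDAComponents, EDARecord, solvate
from .structure_io import AtomRecord, PlanarGroup, PlanarGroupSpec

MOTIFS = ("cofacial_stack", "parallel_displaced", "t_shaped", "tilted", "random")

#: Synthetic ring residues are labelled with this spec (benzene-like).
RING_SPEC = PlanarGroupSpec(
    residue_name="RNG",
    plane_atom_names=("C1", "C2", "C3"),
    residue_class="aromatic",
    formal_charge=0,
)
AMIDE_SPEC = PlanarGroupSpec(
    residue_name="AMD",
    plane_atom_names=("C1", "O1", "N1"),
    residue_class="backbone",
    formal_charge=0,
)


@dataclass(frozen=True)
class GeometrySpec:
    """An idealized two-ring arrangement."""

    motif: str = "cofacial_stack"
    separation: float = 3.4  # A, along the first ring's normal
    lateral_offset: float = 0.0  # A, in-plane displacement of ring b
    tilt_deg: float = 0.0  # rotation of ring b about an in-plane axis
    ring_size: int = 6
    ring_radius: float = 1.39  # A (benzene-like C-C bond for a hexagon)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if not 0 <= self.tilt_deg <= 90:
            raise ValueError("tilt_deg must lie in [0, 90]")


@dataclass(frozen=True)
class EDAGenSpec:
    """A batch of class-conditioned decomposition records."""

    class_label: str = "neutral_aromatic"
    environment: str = "gas"  # "gas" or "pcm" (pcm adds screened components)
    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.class_label not in CLASS_TRUE_LABEL:
            raise ValueError(f"unknown class {self.class_label!r}")


def ring_coords(n: int = 6, radius: float = 1.39) -> np.ndarray:
    """Vertices of a regular n-gon in the z = 0 plane, centred at origin."""
    angles = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )


def _ring_group(
    coords: np.ndarray,
    group_id: str,
    residue_index: int,
    normal: np.ndarray,
    spec: PlanarGroupSpec = RING_SPEC,
    chain: str = "S",
) -> PlanarGroup:
    atoms = [
        AtomRecord(
            name=f"C{i + 1}",
            element="C",
            coords=tuple(float(x) for x in xyz),
            residue_name=spec.residue_name,
            residue_index=residue_index,
            chain_id=chain,
        )
        for i, xyz in enumerate(coords)
    ]
    return PlanarGroup(
        group_id=group_id,
        spec=spec,
        atoms=atoms,
        source=(chain, residue_index),
        metadata={"analytic_normal": np.asarray(normal, dtype=float)},
    )


def make_dimer_geometry(spec: GeometrySpec) -> tuple[PlanarGroup, PlanarGroup]:
    """Build two planar ring groups in the requested arrangement.

    Ring a sits in the z = 0 plane at the origin; ring b is placed
    ``separation`` along +z, offset laterally along +x, and (for the
    tilted and t-shaped motifs) rotated about the x axis through its
    own centroid.  The ``random`` motif applies a seeded random
    rotation and random centroid offset to ring b.  Both groups carry
    their exact analytic normals in ``metadata`` for oracle use.
    """
    base = ring_coords(spec.ring_size, spec.ring_radius)
    normal_a = np.array([0.0, 0.0, 1.0])
    coords_a = base.copy()

    rng = np.random.default_rng(spec.seed)
    if spec.motif == "random":
        rot = Rotation.random(random_state=np.random.RandomState(spec.seed))
        offset = rng.uniform(-1.0, 1.0, size=3)
        offset = offset / max(np.linalg.norm(offset), 1e-9)
        centre = offset * spec.separation
        coords_b = rot.apply(base) + centre
        normal_b = rot.apply(normal_a)
    else:
        tilt = {
            "cofacial_stack": 0.0,
            "parallel_displaced": 0.0,
            "tilted": spec.tilt_deg,
            "t_shaped": 90.0,
        }[spec.motif]
        offset = spec.lateral_offset
        if spec.motif == "parallel_displaced" and offset == 0.0:
            offset = 1.5
        rot = Rotation.from_euler("x", tilt, degrees=True)
        centre = np.array([offset, 0.0, spec.separation])
        coords_b = rot.apply(base) + centre
        normal_b = rot.apply(normal_a)

    group_a = _ring_group(coords_a, "synthetic:a", 1, normal_a)
    group_b = _ring_group(coords_b, "synthetic:b", 2, normal_b)
    return group_a, group_b


# ---------------------------------------------------------------------------
# Benchmark frames: planted stacked pairs among random decoys.

def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )

#: Ring atom names that make a planted frame readable as PHE side chains.
_PHE_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def make_benchmark_frame(
    n_groups: int,
    n_engineered_contacts: int,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """A PDB frame of hexagonal rings with planted stacked pairs.

    Rings are written as PHE side-chain planes (one residue each, chain
    A) so the standard extraction applies.  Planted pairs are cofacial
    at 3.5 A; all other rings sit on a coarse grid with >= 20 A spacing
    and random orientation, so no accidental contact can occur.
    Returns the PDB text and the ground-truth list of contacting
    residue-index pairs; byte-identical for a fixed seed.
    """
    if n_engineered_contacts > n_groups // 2:
        raise ValueError("cannot plant more contacts than group pairs available")
    rng = np.random.default_rng(seed)
    base = ring_coords(6, 1.39)
    sites_needed = n_groups - n_engineered_contacts
    placements: list[np.ndarray] = []  # ring coordinate blocks

    site = 0
    for k in range(n_engineered_contacts):
        origin = np.array([30.0 * site, 0.0, 0.0])
        rot = Rotation.random(random_state=np.random.RandomState(seed * 7919 + k))
        normal = rot.apply([0.0, 0.0, 1.0])
        a = rot.apply(base) + origin
        b = rot.apply(base) + origin + 3.5 * normal
        placements.append(a)
        placements.append(b)
        site += 1
    for k in range(sites_needed - n_engineered_contacts):
        origin = np.array([30.0 * site, 0.0, 0.0])
        rot = Rotation.random(
            random_state=np.random.RandomState(seed * 104729 + 1000 + k)
        )
        placements.append(rot.apply(base) + origin)
        site += 1

    truth = [(2 * k + 1, 2 * k + 2) for k in range(n_engineered_contacts)]
    lines = ["REMARK synthetic benchmark frame"]
    serial = 0
    for res_idx, block in enumerate(placements, start=1):
        # CB/CA stubs radially outward from CG keep the residues cappable.
        centre = block.mean(axis=0)
        out = block[0] - centre
        out = out / np.linalg.norm(out)
        stubs = (("CB", block[0] + 1.5 * out), ("CA", block[0] + 2.6 * out))
        for name, xyz in stubs:
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "PHE", "A", res_idx, xyz, "C"))
        for name, xyz in zip(_PHE_RING_NAMES, block):
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "PHE", "A", res_idx, xyz, "C"))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text, truth


# ---------------------------------------------------------------------------
# Class-conditioned decomposition records.

CLASS_TRUE_LABEL = {
    "neutral_aromatic": "vdw_cfh",
    "neutral_hydrophilic": "vdw_cfh",
    "hs_type": "hunter_sanders",
    "ion_pi": "ion_pi",
    "ion_ion": "ion_ion",
}

_CLASS_SUBCLASS = {
    "neutral_aromatic": "aromatic-aromatic",
    "neutral_hydrophilic": "hydrophilic-hydrophilic",
    "hs_type": "aromatic-hydrophilic",
    "ion_pi": "aromatic-charged",
    "ion_ion": "charged-charged",
}

#: Published per-subset gas-phase total-energy envelopes, kJ/mol.
CLASS_TOTAL_RANGE = {
    "neutral_aromatic": (-23.0, -2.0),
    "neutral_hydrophilic": (-41.0, 5.0),
    "hs_type": (-24.0, 13.0),
    "ion_pi": (-75.0, 5.0),
    "ion_ion": (-463.0, 298.0),
}


def _gas_components(class_label: str, rng: np.random.Generator) -> tuple[EDAComponents, tuple[int, int]]:
    lo, hi = CLASS_TOTAL_RANGE[class_label]
    if class_label in ("neutral_aromatic", "neutral_hydrophilic"):
        # Dispersion-dominant stack: mildly attractive electrostatics,
        # Pauli repulsion that outweighs it, small orbital terms.
        elec = rng.uniform(-25.0, -5.0)
        pauli = -elec * rng.uniform(1.2, 2.0)
        pol = rng.uniform(-4.0, -1.0)
        ct = rng.uniform(-4.0, -1.0)
        partial = elec + pauli + pol + ct
        # Target total below the partial sum keeps dispersion attractive.
        total = rng.uniform(lo, min(hi, -2.0, partial - 2.0))
        disp = total - partial
        charges = (0, 0)
    elif class_label == "hs_type":
        # Repulsive permanent electrostatics with dominant dispersion.
        elec = rng.uniform(2.0, 10.0)
        pauli = rng.uniform(5.0, 20.0)
        pol = rng.uniform(-3.0, -1.0)
        ct = rng.uniform(-3.0, -1.0)
        total = rng.uniform(max(lo, -20.0), -2.0)
        disp = total - (elec + pauli + pol + ct)
        charges = (0, 0)
    elif class_label == "ion_pi":
        # Orbital and dispersion balanced, significant electrostatics;
        # the frozen term stays modest next to dispersion so the
        # composition is genuinely three-way.
        pauli = rng.uniform(15.0, 30.0)
        elec = -pauli - rng.uniform(4.0, 18.0)
        pol = rng.uniform(-20.0, -12.0)
        ct = rng.uniform(-5.0, -2.0)
        disp = rng.uniform(-22.0, -14.0)
        charges = (int(rng.choice([-1, 1])), 0)
    elif class_label == "ion_ion":
        # Monopole electrostatics of either sign dominates everything.
        qa, qb = int(rng.choice([-1, 1])), int(rng.choice([-1, 1]))
        magnitude = rng.uniform(120.0, 430.0)
        elec = -magnitude if qa * qb < 0 else magnitude * rng.uniform(0.5, 0.63)
        pauli = rng.uniform(2.0, 25.0)
        pol = rng.uniform(-12.0, -2.0)
        ct = rng.uniform(-8.0, -1.0)
        disp = rng.uniform(-12.0, -3.0)
        charges = (qa, qb)
    else:  # pragma: no cover - guarded by EDAGenSpec
        raise ValueError(class_label)
    comp = EDAComponents(elec=elec, pauli=pauli, disp=disp, pol=pol, ct=ct)
    return comp, charges


def pcm_screen(
    gas: EDAComponents, rng: np.random.Generator, epsilon: float = 78.39
) -> EDAComponents:
    """Apply the dielectric-screening transform to gas-phase components.

    Electrostatics and polarization are strongly screened toward zero,
    charge transfer slightly reduced, Pauli repulsion and dispersion
    untouched.  The solvation correction is a small stabilizing term on
    the electrostatic side.
    """
    elec_s = gas.elec * rng.uniform(0.12, 0.30)
    pol_s = gas.pol * rng.uniform(0.08, 0.25)
    ct_s = gas.ct * rng.uniform(0.60, 0.80)
    solv = -abs(gas.elec) * rng.uniform(0.01, 0.05)
    return solvate(
        gas,
        elec_s=elec_s,
        pauli_s=gas.pauli,
        pol_s=pol_s,
        ct_s=ct_s,
        solv_correction=solv,
        epsilon=epsilon,
    )


def sample_eda(spec: EDAGenSpec) -> list[EDARecord]:
    """Draw class-conditioned decomposition records.

    Every record stores its generator ground-truth label in
    ``extra["true_label"]``; PCM components are attached when the spec
    asks for the dielectric environment.  Pure function of the seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n):
        comp, charges = _gas_components(spec.class_label, rng)
        pcm = pcm_screen(comp, rng) if spec.environment == "pcm" else None
        is_pi = True
        if spec.class_label == "ion_ion":
            is_pi = bool(rng.uniform() < 0.5)
        records.append(
            EDARecord(
                dimer_id=f"{spec.class_label}-{spec.seed}-{i:04d}",
                pair_type="SCSC",
                subclass=_CLASS_SUBCLASS[spec.class_label],
                charges=charges,
                components_gas=comp,
                components_pcm=pcm,
                is_pi_contact=is_pi,
                extra={"true_label": CLASS_TRUE_LABEL[spec.class_label]},
            )
        )
    return records


def sample_mixed_suite(
    n_per_class: int = 100, seed: int = 0, environment: str = "pcm"
) -> list[EDARecord]:
    """A balanced suite covering all five generator classes."""
    records = []
    for k, class_label in enumerate(sorted(CLASS_TRUE_LABEL)):
        records.extend(
            sample_eda(
                EDAGenSpec(
                    class_label=class_label,
                    environment=environment,
                    n=n_per_class,
                    seed=seed * 31 + k,
                )
            )
        )
    return records


# ---------------------------------------------------------------------------
# Idealized hydrogen-complete residues and peptides (fixture builders).

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180-degree flip about any axis orthogonal to a.
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _tetra_dirs(axis: np.ndarray, ref: np.ndarray) -> list[np.ndarray]:
    """Three unit directions tetrahedral to ``axis`` (pointing away)."""
    axis = axis / np.linalg.norm(axis)
    u = ref - np.dot(ref, axis) * axis
    if np.linalg.norm(u) < 1e-6:
        u = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    cos_t = -1.0 / 3.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    return [
        cos_t * axis + sin_t * (np.cos(th) * u + np.sin(th) * v)
        for th in (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
    ]


def make_residue(resname: str, chain: str = "A", index: int = 1) -> list[AtomRecord]:
    """An idealized, hydrogen-complete residue for fixture use.

    Geometry is constructed, not taken from any database: rings are
    regular polygons with standard bond lengths, sp3 centres are
    tetrahedral, ring hydrogens point radially outward.  The backbone
    (N, CA, C, O, HA) is attached in a plausible orientation.  Suitable
    for exercising plane extraction and fragment capping, not for
    energetics.
    """
    resname = resname.upper()
    atoms: dict[str, tuple[str, np.ndarray]] = {}

    def put(name: str, element: str, xyz) -> None:
        atoms[name] = (element, np.asarray(xyz, dtype=float))

    cb = np.array([0.0, 0.0, 0.0])
    # The CB->CG bond direction used by the side-chain templates.
    cg_dir = np.array([0.0, 1.0, 0.0])

    if resname in ("PHE", "TYR"):
        centre = np.array([0.0, 1.5 + 1.39, 0.0])
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring = ring_coords(6, 1.39)
        # Vertex 0 of the polygon points toward CB.
        rot = _rotation_between(np.array([1.0, 0.0, 0.0]), cb - centre)
        ring = ring @ rot.T + centre
        for name, xyz in zip(names, ring):
            put(name, "C", xyz)
        for name in names[1:]:
            if resname == "TYR" and name == "CZ":
                continue
            out = atoms[name][1] - centre
            out /= np.linalg.norm(out)
            put("H" + name[1:], "H", atoms[name][1] + 1.09 * out)
        if resname == "TYR":
            out = atoms["CZ"][1] - centre
            out /= np.linalg.norm(out)
            oh = atoms["CZ"][1] + 1.36 * out
            put("OH", "O", oh)
            put("HH", "H", oh + 0.96 * out)
    elif resname == "TRP":
        # Indole: pyrrole fused to a benzene ring on the CD2-CE2 edge.
        cg = cb + 1.5 * cg_dir
        r5 = 1.37 / (2.0 * np.sin(np.pi / 5.0))
        centre5 = cg + r5 * cg_dir
        pent_names = ("CG", "CD1", "NE1", "CE2", "CD2")
        pent = ring_coords(5, r5)
        rot5 = _rotation_between(np.array([1.0, 0.0, 0.0]), (cg - centre5) / r5)
        pent = pent @ rot5.T + centre5
        for name, xyz in zip(pent_names, pent):
            put(name, "N" if name.startswith("N") else "C", xyz)
        cd2, ce2 = atoms["CD2"][1], atoms["CE2"][1]
        mid = 0.5 * (cd2 + ce2)
        away = mid - centre5
        away /= np.linalg.norm(away)
        edge_len = np.linalg.norm(ce2 - cd2)
        centre6 = mid + away * edge_len * np.sqrt(3.0) / 2.0
        hex_r = edge_len
        hexv = ring_coords(6, hex_r)
        rot6 = _rotation_between(
            np.array([1.0, 0.0, 0.0]), (cd2 - centre6) / np.linalg.norm(cd2 - centre6)
        )
        hexv = hexv @ rot6.T + centre6
        remaining = [
            xyz
            for xyz in hexv
            if np.linalg.norm(xyz - cd2) > 0.35 and np.linalg.norm(xyz - ce2) > 0.35
        ]
        # CE3 neighbours CD2, CZ2 neighbours CE2; CZ3/CH2 complete the ring.
        ce3 = min(remaining, key=lambda p: np.linalg.norm(p - cd2))
        cz2 = min(remaining, key=lambda p: np.linalg.norm(p - ce2))
        cz3 = min(
            (p for p in remaining if np.linalg.norm(p - ce3) > 1e-6
             and np.linalg.norm(p - cz2) > 1e-6),
            key=lambda p: np.linalg.norm(p - ce3),
        )
        ch2 = next(
            p for p in remaining
            if min(np.linalg.norm(p - q) for q in (ce3, cz2, cz3)) > 1e-6
        )
        for name, xyz in zip(("CE3", "CZ2", "CZ3", "CH2"), (ce3, cz2, cz3, ch2)):
            put(name, "C", xyz)
        put("HD1", "H", atoms["CD1"][1] + 1.09 * _radial(atoms["CD1"][1], centre5))
        put("HE1", "H", atoms["NE1"][1] + 1.01 * _radial(atoms["NE1"][1], centre5))
        for name in ("CE3", "CZ2", "CZ3", "CH2"):
            put(
                "H" + name[1:],
                "H",
                atoms[name][1] + 1.09 * _radial(atoms[name][1], centre6),
            )
    elif resname == "HIS":
        cg = cb + 1.5 * cg_dir
        r5 = 1.37 / (2.0 * np.sin(np.pi / 5.0))
        centre = cg + r5 * cg_dir
        pent_names = ("CG", "ND1", "CE1", "NE2", "CD2")
        pent = ring_coords(5, r5)
        rot = _rotation_between(np.array([1.0, 0.0, 0.0]), (cg - centre) / r5)
        pent = pent @ rot.T + centre
        for name, xyz in zip(pent_names, pent):
            put(name, "N" if name.startswith("N") else "C", xyz)
        put("HD2", "H", atoms["CD2"][1] + 1.09 * _radial(atoms["CD2"][1], centre))
        put("HE1", "H", atoms["CE1"][1] + 1.09 * _radial(atoms["CE1"][1], centre))
        put("HE2", "H", atoms["NE2"][1] + 1.01 * _radial(atoms["NE2"][1], centre))
    elif resname in ("ASP", "ASN"):
        cg = cb + 1.5 * cg_dir
        d1 = Rotation.from_euler("z", 120, degrees=True).apply(cg_dir)
        d2 = Rotation.from_euler("z", -120, degrees=True).apply(cg_dir)
        put("CG", "C", cg)
        if resname == "ASP":
            put("OD1", "O", cg + 1.25 * d1)
            put("OD2", "O", cg + 1.25 * d2)
        else:
            put("OD1", "O", cg + 1.23 * d1)
            nd2 = cg + 1.33 * d2
            put("ND2", "N", nd2)
            put("HD21", "H", nd2 + 1.01 * d2)
            put(
                "HD22",
                "H",
                nd2 + 1.01 * Rotation.from_euler("z", -120, degrees=True).apply(d2),
            )
    elif resname in ("GLU", "GLN"):
        cg = cb + 1.53 * cg_dir
        cd_dir = Rotation.from_euler("z", 60, degrees=True).apply(cg_dir)
        cd = cg + 1.52 * cd_dir
        put("CG", "C", cg)
        put("CD", "C", cd)
        d1 = Rotation.from_euler("z", 120, degrees=True).apply(cd_dir)
        d2 = Rotation.from_euler("z", -120, degrees=True).apply(cd_dir)
        if resname == "GLU":
            put("OE1", "O", cd + 1.25 * d1)
            put("OE2", "O", cd + 1.25 * d2)
        else:
            put("OE1", "O", cd + 1.23 * d1)
            ne2 = cd + 1.33 * d2
            put("NE2", "N", ne2)
            put("HE21", "H", ne2 + 1.01 * d2)
            put(
                "HE22",
                "H",
                ne2 + 1.01 * Rotation.from_euler("z", -120, degrees=True).apply(d2),
            )
        for h1, h2, centre_atom, nb1, nb2 in (("HG2", "HG3", cg, cb, cd),):
            dirs = _tetra_dirs(nb1 - centre_atom, np.array([0.0, 0.0, 1.0]))
            picked = _pick_h_dirs(centre_atom, dirs, [nb2])
            put(h1, "H", centre_atom + 1.09 * picked[0])
            put(h2, "H", centre_atom + 1.09 * picked[1])
    elif resname == "ARG":
        cg = cb + 1.53 * cg_dir
        cd_dir = Rotation.from_euler("z", 60, degrees=True).apply(cg_dir)
        cd = cg + 1.52 * cd_dir
        ne_dir = Rotation.from_euler("z", -60, degrees=True).apply(cd_dir)
        ne = cd + 1.46 * ne_dir
        cz_dir = Rotation.from_euler("z", 60, degrees=True).apply(ne_dir)
        cz = ne + 1.33 * cz_dir
        put("CG", "C", cg)
        put("CD", "C", cd)
        put("NE", "N", ne)
        put("CZ", "C", cz)
        d1 = Rotation.from_euler("z", 120, degrees=True).apply(cz_dir)
        d2 = Rotation.from_euler("z", -120, degrees=True).apply(cz_dir)
        nh1, nh2 = cz + 1.33 * d1, cz + 1.33 * d2
        put("NH1", "N", nh1)
        put("NH2", "N", nh2)
        put("HE", "H", ne + 1.01 * Rotation.from_euler("z", -120, degrees=True).apply(cz_dir))
        for nh, dd, tag in ((nh1, d1, "1"), (nh2, d2, "2")):
            put(f"HH{tag}1", "H", nh + 1.01 * dd)
            put(
                f"HH{tag}2",
                "H",
                nh + 1.01 * Rotation.from_euler("z", 120 if tag == "2" else -120, degrees=True).apply(dd),
            )
        for h1, h2, centre_atom, nb1, nb2 in (
            ("HG2", "HG3", cg, cb, cd),
            ("HD2", "HD3", cd, cg, ne),
        ):
            dirs = _tetra_dirs(nb1 - centre_atom, np.array([0.0, 0.0, 1.0]))
            picked = _pick_h_dirs(centre_atom, dirs, [nb2])
            put(h1, "H", centre_atom + 1.09 * picked[0])
            put(h2, "H", centre_atom + 1.09 * picked[1])
    elif resname in ("ALA", "GLY"):
        pass
    else:
        raise ValueError(f"no idealized template for {resname}")

    # Backbone: CA tetrahedral to CB (or to N for glycine), then N, C, O.
    if resname == "GLY":
        ca = np.array([0.0, 0.0, 0.0])
    else:
        if resname not in ("ALA",):
            first = atoms[
                "CG" if "CG" in atoms else "CD"
            ][1]
        else:
            first = cb + np.array([0.0, 1.5, 0.0])
        dirs = _tetra_dirs((first - cb), np.array([0.0, 0.0, 1.0]))
        ca = cb + 1.53 * dirs[0]
        put("CB", "C", cb)
        hb_dirs = [d for d in dirs[1:]]
        if resname == "ALA":
            put("HB1", "H", cb + 1.09 * hb_dirs[0])
            put("HB2", "H", cb + 1.09 * hb_dirs[1])
            axis = (first - cb) / np.linalg.norm(first - cb)
            put("HB3", "H", cb + 1.09 * axis)
        else:
            put("HB2", "H", cb + 1.09 * hb_dirs[0])
            put("HB3", "H", cb + 1.09 * hb_dirs[1])
    put("CA", "C", ca)
    ca_dirs = _tetra_dirs(cb - ca if resname != "GLY" else np.array([0.0, -1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    n = ca + 1.46 * ca_dirs[0]
    c = ca + 1.52 * ca_dirs[1]
    put("N", "N", n)
    put("C", "C", c)
    if resname == "GLY":
        put("HA2", "H", ca + 1.09 * ca_dirs[2])
        put("HA3", "H", ca + 1.09 * (np.array([0.0, -1.0, 0.0])))
    else:
        put("HA", "H", ca + 1.09 * ca_dirs[2])
    co_dir = _tetra_dirs(ca - c, np.array([0.0, 0.0, 1.0]))[0]
    put("O", "O", c + 1.23 * co_dir)
    put("H", "H", n + 1.01 * _tetra_dirs(ca - n, np.array([0.0, 0.0, 1.0]))[0])

    return [
        AtomRecord(
            name=name,
            element=element,
            coords=tuple(float(x) for x in xyz),
            residue_name=resname,
            residue_index=index,
            chain_id=chain,
        )
        for name, (element, xyz) in atoms.items()
    ]


def _radial(point: np.ndarray, centre: np.ndarray) -> np.ndarray:
    v = point - centre
    return v / np.linalg.norm(v)


def _pick_h_dirs(centre, dirs, occupied_positions):
    """Drop tetrahedral slots already pointing at bonded neighbours."""
    free = []
    for d in dirs:
        if all(
            np.dot(d, (p - centre) / np.linalg.norm(p - centre)) < 0.8
            for p in occupied_positions
        ):
            free.append(d)
    return free


def make_peptide(
    sequence: Sequence[str], chain: str = "A", spacing: float = 3.8
) -> list[AtomRecord]:
    """A short idealized peptide: residues translated along x.

    Residue i's carbonyl and residue i+1's amide nitrogen end up within
    bonding distance of each other, so backbone amide planes
    (C_i, O_i, N_{i+1}, H_{i+1}) extract normally.  Geometry is
    schematic (no Ramachandran realism) but hydrogen-complete.
    """
    atoms: list[AtomRecord] = []
    for i, resname in enumerate(sequence, start=1):
        res = make_residue(resname, chain=chain, index=i)
        shift = np.array([spacing * (i - 1), 0.0, 0.0])
        for a in res:
            atoms.append(
                AtomRecord(
                    name=a.name,
                    element=a.element,
                    coords=tuple(float(x) for x in (a.xyz + shift)),
                    residue_name=a.residue_name,
                    residue_index=i,
                    chain_id=chain,
                )
            )
    return atoms


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path | None = None) -> str:
    """Write atom records as PDB text (single model)."""
    buf = io.StringIO()
    for serial, a in enumerate(atoms, start=1):
        name = a.name if len(a.name) >= 4 else f"{a.name:<3s}"
        buf.write(
            f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.residue_name:<3s} "
            f"{a.chain_id}{a.residue_index:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
        )
    buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
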