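"""The Vernon geometric criterion (VGC) for pi-pi contacts.

Two sp2 planes are in pi-pi contact when (i) after projecting the atoms
of each plane 1.7 angstrom (the van der Waals radius of carbon) along
the plane normal toward the partner, at least two cross-plane atom
pairs lie within 1.5 angstrom of each other, and (ii) the absolute dot
product of the two unit plane normals is at least 0.8 (inter-plane
angle between 0 and ~36 degrees).  The criterion is purely geometric:
residue charge and environment play no role.

All three thresholds and the pair count are parameters
(:class:`VGCParams`) because the hard cutoffs make downstream counts
sensitive to their exact values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import PlanarGroup


class DegenerateGeometryError(ValueError):
    """Raised when a point set does not define a plane."""


@dataclass(frozen=True)
class Plane:
    """Total-least-squares plane through a set of points."""

    centroid: np.ndarray
    unit_normal: np.ndarray
    rms_deviation: float


@dataclass(frozen=True)
class VGCParams:
    """Thresholds of the geometric criterion (defaults as published)."""

    projection_distance: float = 1.7  # A, carbon vdW radius
    pair_distance_cutoff: float = 1.5  # A
    normal_dot_cutoff: float = 0.8
    min_pairs: int = 2

    def __post_init__(self) -> None:
        if self.projection_distance <= 0 or self.pair_distance_cutoff <= 0:
            raise ValueError("distances must be positive")
        if not 0 < self.normal_dot_cutoff <= 1:
            raise ValueError("normal_dot_cutoff must lie in (0, 1]")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


@dataclass(frozen=True)
class ContactRecord:
    """Diagnostics for one candidate plane pair."""

    group_a: str
    group_b: str
    pair_type: str  # SCSC | SCBB | BBBB
    subclass: str  # e.g. "aromatic-charged"
    n_close_pairs: int
    min_projected_distance: float
    second_min_projected_distance: float
    normal_dot: float
    is_pi_contact: bool


def fit_plane(coords: Sequence[Sequence[float]] | np.ndarray) -> Plane:
    """Fit a plane by total least squares (SVD of the centered points).

    The returned normal minimizes the sum of squared point-to-plane
    distances; its sign is arbitrary, so callers either take ``|dot|``
    or orient it explicitly.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sing, vt = np.linalg.svd(centered, full_matrices=False)
    # Collinear points: the second singular value vanishes.
    if sing[1] <= 1e-10 * max(sing[0], 1.0):
        raise DegenerateGeometryError("points are collinear; no unique plane")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(centroid=centroid, unit_normal=normal, rms_deviation=rms)


def _oriented_normals(plane_a: Plane, plane_b: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Orient each plane's normal toward the other plane's centroid.

    Projecting "toward" the partner is the reading under which the
    1.7 A displacement models van der Waals surface contact.  When the
    centroids coincide the direction is ambiguous; the two normals are
    then pointed away from each other so the projected surfaces pass
    through one another symmetrically.
    """
    direction = plane_b.centroid - plane_a.centroid
    if np.linalg.norm(direction) < 1e-12:
        n_a = plane_a.unit_normal
        n_b = plane_b.unit_normal
        if np.dot(n_b, n_a) > 0:
            n_b = -n_b
        return n_a, n_b
    n_a = plane_a.unit_normal
    if np.dot(n_a, direction) < 0:
        n_a = -n_a
    n_b = plane_b.unit_normal
    if np.dot(n_b, -direction) < 0:
        n_b = -n_b
    return n_a, n_b


def projected_pair_distances(
    group_a: PlanarGroup,
    group_b: PlanarGroup,
    d_proj: float = 1.7,
    plane_a: Plane | None = None,
    plane_b: Plane | None = None,
    both_signs: bool = False,
) -> np.ndarray:
    """Cross-group distances between atoms projected along plane normals.

    Every atom of group a is displaced ``d_proj`` along a's normal
    oriented toward b's centroid, and vice versa; the returned matrix
    holds all cross-group pairwise distances of the projected positions.
    With ``both_signs`` the elementwise minimum over the four sign
    combinations is returned (a sensitivity-check mode).
    """
    if plane_a is None:
        plane_a = fit_plane(group_a.coords)
    if plane_b is None:
        plane_b = fit_plane(group_b.coords)
    if both_signs:
        mats = []
        for sa in (1.0, -1.0):
            for sb in (1.0, -1.0):
                pa = group_a.coords + sa * d_proj * plane_a.unit_normal
                pb = group_b.coords + sb * d_proj * plane_b.unit_normal
                mats.append(cdist(pa, pb))
        return np.minimum.reduce(mats)
    n_a, n_b = _oriented_normals(plane_a, plane_b)
    proj_a = group_a.coords + d_proj * n_a
    proj_b = group_b.coords + d_proj * n_b
    return cdist(proj_a, proj_b)


def pair_type_of(group_a: PlanarGroup, group_b: PlanarGroup) -> str:
    kinds = sorted(("BB" if g.is_backbone else "SC") for g in (group_a, group_b))
    return "".join(reversed(kinds))  # SC before BB: SCSC, SCBB, BBBB


def subclass_of(group_a: PlanarGroup, group_b: PlanarGroup) -> str:
    return "-".join(sorted((group_a.residue_class, group_b.residue_class)))


def vgc_test(
    group_a: PlanarGroup,
    group_b: PlanarGroup,
    params: VGCParams = VGCParams(),
) -> ContactRecord:
    """Apply the geometric criterion to one pair of planar groups.

    Diagnostics (close-pair count, minimum projected distances, normal
    dot) are populated whether or not the pair qualifies.  Ties at the
    cutoffs count as passing (the rules are <= and >=).
    """
    plane_a = fit_plane(group_a.coords)
    plane_b = fit_plane(group_b.coords)
    dmat = projected_pair_distances(
        group_a, group_b, params.projection_distance, plane_a, plane_b
    )
    flat = np.sort(dmat.ravel())
    n_close = int(np.count_nonzero(dmat <= params.pair_distance_cutoff))
    normal_dot = float(abs(np.dot(plane_a.unit_normal, plane_b.unit_normal)))
    normal_dot = min(normal_dot, 1.0)
    is_contact = n_close >= params.min_pairs and normal_dot >= params.normal_dot_cutoff
    return ContactRecord(
        group_a=group_a.group_id,
        group_b=group_b.group_id,
        pair_type=pair_type_of(group_a, group_b),
        subclass=subclass_of(group_a, group_b),
        n_close_pairs=n_close,
        min_projected_distance=float(flat[0]),
        second_min_projected_distance=float(flat[1]) if flat.size > 1 else float("inf"),
        normal_dot=normal_dot,
        is_pi_contact=bool(is_contact),
    )


def default_exclusions(group_a: PlanarGroup, group_b: PlanarGroup) -> bool:
    """True when a pair must not be evaluated as a noncovalent contact.

    Excluded: pairs sharing any atom; backbone amides of directly
    adjacent peptide units (sharing a residue); a side chain against its
    own residue's backbone amide(s).  Covalently coupled planes are not
    noncovalent contacts.
    """
    if group_a.group_id == group_b.group_id:
        return True
    if group_a.atom_keys() & group_b.atom_keys():
        return True
    res_a = {(group_a.source[0], i) for i in group_a.source[1:]}
    res_b = {(group_b.source[0], i) for i in group_b.source[1:]}
    if group_a.is_backbone and group_b.is_backbone:
        return bool(res_a & res_b)
    if group_a.is_backbone != group_b.is_backbone:
        return bool(res_a & res_b)  # side chain vs its own amide
    return False


def scan_pairs(
    groups: Sequence[PlanarGroup],
    params: VGCParams = VGCParams(),
    exclusions: Callable[[PlanarGroup, PlanarGroup], bool] = default_exclusions,
) -> list[ContactRecord]:
    """Evaluate the criterion over all unordered, non-excluded pairs.

    Output order is deterministic: groups are sorted by chain and
    residue index, and pairs are emitted in lexicographic order.
    """
    ordered = sorted(groups, key=lambda g: (g.source[0], g.source[1], g.group_id))
    records: list[ContactRecord] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if exclusions is not None and exclusions(a, b):
                continue
            records.append(vgc_test(a, b, params))
    return records


CONTACT_TABLE_COLUMNS = (
    "group_a",
    "group_b",
    "pair_type",
    "subclass",
    "n_close_pairs",
    "min_projected_distance",
    "second_min_projected_distance",
    "normal_dot",
    "is_pi_contact",
)


def contacts_to_dataframe(records: Iterable[ContactRecord]):
    """Contact records as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        {col: getattr(r, col) for col in CONTACT_TABLE_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=list(CONTACT_TABLE_COLUMNS))
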