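"""Independent brute-force reference for the geometric criterion.

Shares no code with the package implementation: the plane is fitted by
eigendecomposition of the coordinate covariance matrix, projections and
pair distances are computed with explicit loops.
"""

import math

import numpy as np


def covariance_plane(points):
    """Centroid and least-squares unit normal via eigh of the covariance."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    normal = eigvecs[:, 0]  # smallest eigenvalue
    rms = math.sqrt(sum(float(np.dot(p, normal)) ** 2 for p in centered) / len(pts))
    return centroid, normal, rms


def brute_force_contact(
    coords_a,
    coords_b,
    d_proj=1.7,
    pair_cutoff=1.5,
    dot_cutoff=0.8,
    min_pairs=2,
):
    """(is_contact, n_close_pairs, normal_dot) by direct arithmetic."""
    ca, na, _ = covariance_plane(coords_a)
    cb, nb, _ = covariance_plane(coords_b)
    to_b = cb - ca
    if float(np.dot(na, to_b)) < 0:
        na = -na
    if float(np.dot(nb, -to_b)) < 0:
        nb = -nb
    proj_a = [p + d_proj * na for p in np.asarray(coords_a, dtype=float)]
    proj_b = [q + d_proj * nb for q in np.asarray(coords_b, dtype=float)]
    n_close = 0
    for p in proj_a:
        for q in proj_b:
            if math.dist(p, q) <= pair_cutoff:
                n_close += 1
    dot = abs(float(np.dot(na, nb)))
    return (n_close >= min_pairs and dot >= dot_cutoff), n_close, dot


def random_dimer_coords(rng, ring_size=6, radius=1.39):
    """Two rings: one at the origin, one randomly rotated and translated."""
    angles = 2.0 * np.pi * np.arange(ring_size) / ring_size
    ring = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(ring_size)]
    )
    # Random rotation from a normalized quaternion.
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = direction * rng.uniform(1.0, 8.0)
    return ring, ring @ rot.T + offset
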