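"""Signed ternary composition of decomposition terms, and contact typing.

Each dimer is placed on a three-axis composition diagram by the ratios

    r_X = dE_X / (|dE_disp| + |dE_orb| + |dE_term|),   X in {disp, orb, term}

where the numerator keeps its sign.  Dispersion and orbital terms are
always stabilizing (negative), while the third term -- either the
frozen energy (elec + Pauli + solvation) or, in the "elst" variant,
electrostatics alone -- can take either sign, so its vertex is split
into a positive and a negative triangle.  The absolute ratios sum to
one.

Classification of a contact's energetic character:

* ion-ion           -- both monomers charged; monopole electrostatics
                       dominates and the pair is not usefully discussed
                       as pi stacking.
* ion-pi            -- exactly one monomer charged; orbital and
                       dispersion terms balance against electrostatics.
* Hunter-Sanders    -- neutral pi contact whose gas-phase permanent
                       electrostatics is repulsive (the textbook
                       quadrupole-repulsion picture).
* vdW / CFH         -- neutral pair with attractive electrostatics that
                       is nonetheless outweighed by Pauli repulsion
                       (|dE_pauli| > |dE_elec|): pi stacking governed by
                       dispersion-vs-Pauli balance.
* indeterminate     -- anything else (e.g. neutral with an attractive
                       frozen energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .eda import EDAComponents, EDARecord, frozen_and_orbital, total_interaction

LABELS = ("vdw_cfh", "hunter_sanders", "ion_pi", "ion_ion", "indeterminate")


class UndefinedPointError(ValueError):
    """All three composition terms vanish; the ratio is undefined."""


@dataclass(frozen=True)
class TernaryPoint:
    """Signed composition ratios; absolute values sum to one."""

    r_disp: float
    r_orb: float
    r_signed: float
    variant: str  # "frz" or "elst"
    denominator: float  # kJ/mol


@dataclass(frozen=True)
class ClassLabel:
    label: str
    evidence: Mapping[str, bool]


@dataclass
class SummaryReport:
    n_records: int
    counts_by_pair_type: dict[str, int]
    counts_by_subclass: dict[str, int]
    pi_contacts_by_pair_type: dict[str, int]
    n_pi_contacts: int
    label_counts: dict[str, int]
    hs_fraction_pct: int  # of all pi contacts, pooled, nearest integer
    hs_fraction_by_pair_type: dict[str, float]
    energy_range_by_pair_type: dict[str, tuple[float, float]]  # (min, max) kJ/mol

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "counts_by_pair_type": self.counts_by_pair_type,
            "counts_by_subclass": self.counts_by_subclass,
            "pi_contacts_by_pair_type": self.pi_contacts_by_pair_type,
            "n_pi_contacts": self.n_pi_contacts,
            "label_counts": self.label_counts,
            "hs_fraction_pct": self.hs_fraction_pct,
            "hs_fraction_by_pair_type": self.hs_fraction_by_pair_type,
            "energy_range_by_pair_type": {
                k: list(v) for k, v in self.energy_range_by_pair_type.items()
            },
        }

    def to_text(self) -> str:
        lines = [f"records: {self.n_records}  pi contacts: {self.n_pi_contacts}"]
        for pt in sorted(self.counts_by_pair_type):
            lo, hi = self.energy_range_by_pair_type[pt]
            lines.append(
                f"  {pt}: {self.counts_by_pair_type[pt]} records, "
                f"{self.pi_contacts_by_pair_type.get(pt, 0)} pi contacts, "
                f"total energy {lo:.1f} .. {hi:.1f} kJ/mol"
            )
        lines.append("labels: " + ", ".join(
            f"{k}={v}" for k, v in sorted(self.label_counts.items())
        ))
        lines.append(
            f"Hunter-Sanders fraction of pi contacts: {self.hs_fraction_pct}%"
        )
        return "\n".join(lines)


def ternary_coordinates(c: EDAComponents, variant: str = "frz") -> TernaryPoint:
    """Signed composition ratios of one record.

    ``variant="frz"`` uses the frozen energy (elec + Pauli + solvation)
    on the signed vertex; ``variant="elst"`` subtracts Pauli repulsion
    out, leaving permanent electrostatics (plus the solvation
    correction for PCM records, which lives on the electrostatic side
    of the ledger).
    """
    frz, orb = frozen_and_orbital(c)
    if variant == "frz":
        term = frz
    elif variant == "elst":
        term = c.elec + c.solv_correction
    else:
        raise ValueError(f"unknown ternary variant {variant!r}")
    denominator = abs(c.disp) + abs(orb) + abs(term)
    if denominator <= 0:
        raise UndefinedPointError("all composition terms are zero")
    return TernaryPoint(
        r_disp=c.disp / denominator,
        r_orb=orb / denominator,
        r_signed=term / denominator,
        variant=variant,
        denominator=denominator,
    )


def classify(record: EDARecord) -> ClassLabel:
    """Assign one energetic-character label from gas-phase components.

    Rules are evaluated in documented order, first match wins:
    (1) both monomers charged -> ion-ion; (2) exactly one charged ->
    ion-pi; (3) neutral pi contact with repulsive gas-phase
    electrostatics -> Hunter-Sanders; (4) neutral, attractive
    electrostatics but repulsive frozen energy -> vdW/CFH;
    (5) indeterminate.
    """
    if record.charges is None or len(record.charges) != 2:
        raise ValueError(f"{record.dimer_id}: monomer charges unknown")
    qa, qb = record.charges
    c = record.components_gas
    frz, _ = frozen_and_orbital(c)
    evidence = {
        "both_charged": qa != 0 and qb != 0,
        "one_charged": (qa != 0) != (qb != 0),
        "is_pi_contact": bool(record.is_pi_contact),
        "elec_repulsive": c.elec > 0,
        "frz_repulsive": frz > 0,
    }
    if evidence["both_charged"]:
        label = "ion_ion"
    elif evidence["one_charged"]:
        label = "ion_pi"
    elif evidence["is_pi_contact"] and evidence["elec_repulsive"]:
        label = "hunter_sanders"
    elif not evidence["elec_repulsive"] and evidence["frz_repulsive"]:
        label = "vdw_cfh"
    else:
        label = "indeterminate"
    return ClassLabel(label=label, evidence=evidence)


def summarize(
    records: Sequence[EDARecord],
    contacts: Sequence | None = None,
) -> SummaryReport:
    """Aggregate counts, labels and energy ranges over a record set.

    When geometric contact records are supplied they must reconcile
    with the decomposition records: contact pairs are keyed by
    ``dimer_id`` stored on the record, and orphans raise.
    """
    records = list(records)
    if contacts is not None:
        known = {r.dimer_id for r in records}
        contact_ids = {getattr(c, "dimer_id", f"{c.group_a}|{c.group_b}") for c in contacts}
        orphans = contact_ids - known
        if orphans:
            raise ValueError(
                "contacts reference unknown dimer ids: " + ", ".join(sorted(orphans))
            )

    counts_by_pair_type: dict[str, int] = {}
    counts_by_subclass: dict[str, int] = {}
    pi_by_pair_type: dict[str, int] = {}
    label_counts: dict[str, int] = {lbl: 0 for lbl in LABELS}
    energy_range: dict[str, tuple[float, float]] = {}
    n_pi = 0
    n_hs = 0
    hs_by_pt: dict[str, list[int]] = {}

    for r in records:
        pt = r.pair_type or "?"
        counts_by_pair_type[pt] = counts_by_pair_type.get(pt, 0) + 1
        sc = r.subclass or "?"
        counts_by_subclass[sc] = counts_by_subclass.get(sc, 0) + 1
        total = total_interaction(r.components_gas)
        lo, hi = energy_range.get(pt, (total, total))
        energy_range[pt] = (min(lo, total), max(hi, total))
        label = classify(r).label
        label_counts[label] = label_counts.get(label, 0) + 1
        if r.is_pi_contact:
            n_pi += 1
            pi_by_pair_type[pt] = pi_by_pair_type.get(pt, 0) + 1
            hs_num, hs_den = hs_by_pt.get(pt, (0, 0))
            is_hs = label == "hunter_sanders"
            hs_by_pt[pt] = (hs_num + int(is_hs), hs_den + 1)
            n_hs += int(is_hs)

    hs_pct = int(round(100.0 * n_hs / n_pi)) if n_pi else 0
    hs_by_pair_type = {
        pt: 100.0 * num / den for pt, (num, den) in hs_by_pt.items() if den
    }
    return SummaryReport(
        n_records=len(records),
        counts_by_pair_type=counts_by_pair_type,
        counts_by_subclass=counts_by_subclass,
        pi_contacts_by_pair_type=pi_by_pair_type,
        n_pi_contacts=n_pi,
        label_counts=label_counts,
        hs_fraction_pct=hs_pct,
        hs_fraction_by_pair_type=hs_by_pair_type,
        energy_range_by_pair_type=energy_range,
    )


def points_to_dataframe(
    records: Sequence[EDARecord],
    variants: Sequence[str] = ("frz", "elst"),
    environments: Sequence[str] = ("gas",),
):
    """Ternary coordinates per record, variant and environment (CSV-ready)."""
    import pandas as pd

    rows = []
    for r in records:
        for env in environments:
            if env == "pcm" and r.components_pcm is None:
                continue
            c = r.components(env)
            for variant in variants:
                p = ternary_coordinates(c, variant)
                rows.append(
                    {
                        "dimer_id": r.dimer_id,
                        "environment": env,
                        "variant": variant,
                        "r_disp": p.r_disp,
                        "r_orb": p.r_orb,
                        "r_signed": p.r_signed,
                        "denominator": p.denominator,
                        "is_pi_contact": r.is_pi_contact,
                        "subclass": r.subclass,
                        "pair_type": r.pair_type,
                    }
                )
    return pd.DataFrame(rows)


def plot_ternary(
    points: Iterable[TernaryPoint],
    path,
    title: str = "",
    highlight: Sequence[bool] | None = None,
) -> None:
    """Two-triangle scatter of ternary points (requires matplotlib).

    Points with a repulsive signed term are drawn in the right-hand
    (positive) triangle, attractive ones mirrored into the left-hand
    triangle.  Rendering is auxiliary; the coordinates are the contract.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    points = list(points)
    highlight = list(highlight) if highlight is not None else [False] * len(points)

    fig, ax = plt.subplots(figsize=(8, 4))
    for sign, x0 in ((1.0, 0.55), (-1.0, -0.55)):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2], [0.0, 0.0]])
        tri = tri + [x0 - 0.5, 0.0]
        ax.plot(tri[:, 0], tri[:, 1], color="0.4", lw=1)
    for p, hot in zip(points, highlight):
        a, b, c = abs(p.r_disp), abs(p.r_orb), abs(p.r_signed)
        x0 = 0.55 if p.r_signed >= 0 else -0.55
        x = x0 - 0.5 + b + 0.5 * c
        y = np.sqrt(3) / 2 * c
        ax.plot(
            x, y,
            marker="D" if hot else "o",
            ms=4 if hot else 3,
            color="k" if hot else "tab:blue",
            ls="none",
        )
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
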