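"""Energy-decomposition bookkeeping for dimer interaction energies.

The total interaction energy of a dimer is split into five terms:
permanent electrostatics, Pauli repulsion, dispersion, polarization and
charge transfer,

    dE_int = dE_elec + dE_pauli + dE_disp + dE_pol + dE_ct.

Electrostatics and Pauli repulsion are grouped as the "frozen" energy;
polarization and charge transfer as the "orbital" energy.  In a
dielectric environment (PCM) every term except dispersion acquires a
solvated value, and a separate solvation correction enters the frozen
(electrostatic) side of the ledger; dispersion is assumed unchanged by
the continuum.

This module performs only the arithmetic over supplied component
values; no quantum chemistry happens here.  The canonical unit is
kJ/mol; kcal/mol inputs are converted on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184

COMPONENT_NAMES = ("elec", "pauli", "disp", "pol", "ct")

#: Accepted aliases for component fields in foreign JSON schemas.
DEFAULT_FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "elec": ("elec", "elst", "electrostatics", "E_elec", "cls_elec"),
    "pauli": ("pauli", "exchange", "E_pauli", "mod_pauli", "pauli_repulsion"),
    "disp": ("disp", "dispersion", "E_disp"),
    "pol": ("pol", "polarization", "polarisation", "E_pol"),
    "ct": ("ct", "charge_transfer", "E_ct"),
    "solv_correction": ("solv_correction", "solv", "E_solv", "delta_solv"),
    "epsilon": ("epsilon", "eps", "dielectric"),
}


class EnvironmentError_(ValueError):
    """Gas-phase / solvated bookkeeping mixed up."""


@dataclass(frozen=True)
class EDAComponents:
    """The five decomposition terms plus solvation, in kJ/mol."""

    elec: float
    pauli: float
    disp: float
    pol: float
    ct: float
    solv_correction: float = 0.0
    environment: str = "gas"  # "gas" or "pcm"
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon < 1.0:
            raise ValueError(f"dielectric constant must be >= 1, got {self.epsilon}")
        if self.environment == "gas":
            if self.solv_correction != 0.0:
                raise EnvironmentError_(
                    "gas-phase components cannot carry a solvation correction"
                )
            if self.epsilon != 1.0:
                raise EnvironmentError_("gas phase requires epsilon = 1")
        if self.disp > 0:
            logger.warning("dispersion %+.3f kJ/mol is repulsive (unphysical)", self.disp)
        if self.pauli < 0:
            logger.warning("Pauli term %+.3f kJ/mol is attractive (unphysical)", self.pauli)


@dataclass
class EDARecord:
    """Decomposition data for one dimer, gas phase and optionally PCM."""

    dimer_id: str
    pair_type: str
    subclass: str
    charges: tuple[int, int]
    components_gas: EDAComponents
    components_pcm: EDAComponents | None = None
    is_pi_contact: bool = False
    extra: dict = field(default_factory=dict)

    def components(self, environment: str = "gas") -> EDAComponents:
        if environment == "gas":
            return self.components_gas
        if environment == "pcm":
            if self.components_pcm is None:
                raise EnvironmentError_(
                    f"{self.dimer_id}: no PCM components available"
                )
            return self.components_pcm
        raise ValueError(f"unknown environment {environment!r}")


def frozen_and_orbital(c: EDAComponents) -> tuple[float, float]:
    """Frozen (elec + Pauli + solvation) and orbital (pol + ct) energies."""
    return (c.elec + c.pauli + c.solv_correction, c.pol + c.ct)


def total_interaction(c: EDAComponents) -> float:
    """Total interaction energy: the sum of all terms, kJ/mol."""
    return c.elec + c.pauli + c.disp + c.pol + c.ct + c.solv_correction


def solvate(
    gas: EDAComponents,
    elec_s: float,
    pauli_s: float,
    pol_s: float,
    ct_s: float,
    solv_correction: float,
    epsilon: float = 78.39,
) -> EDAComponents:
    """Build the PCM-tagged components from a gas-phase record.

    Dispersion is copied unchanged from the gas phase (the continuum is
    assumed not to touch it); all other terms are replaced by their
    solvated values and the solvation correction is recorded on the
    frozen/electrostatic side.
    """
    if gas.environment != "gas":
        raise EnvironmentError_("solvate() expects gas-phase components")
    return EDAComponents(
        elec=elec_s,
        pauli=pauli_s,
        disp=gas.disp,
        pol=pol_s,
        ct=ct_s,
        solv_correction=solv_correction,
        environment="pcm",
        epsilon=epsilon,
    )


def _resolve(entry: Mapping, aliases: Sequence[str]):
    for key in aliases:
        if key in entry:
            return entry[key]
    return None


def _components_from_dict(
    entry: Mapping,
    environment: str,
    scale: float,
    field_aliases: Mapping[str, Sequence[str]],
) -> EDAComponents:
    values = {}
    for name in COMPONENT_NAMES:
        value = _resolve(entry, field_aliases[name])
        if value is None:
            raise KeyError(name)
        values[name] = float(value) * scale
    solv = _resolve(entry, field_aliases["solv_correction"])
    eps = _resolve(entry, field_aliases["epsilon"])
    if environment == "gas":
        return EDAComponents(**values)
    return EDAComponents(
        **values,
        solv_correction=float(solv or 0.0) * scale,
        environment="pcm",
        epsilon=float(eps) if eps is not None else 78.39,
    )


def read_eda_json(
    path: str | Path,
    field_map: Mapping[str, Sequence[str]] | None = None,
) -> list[EDARecord]:
    """Read decomposition records from JSON.

    The native schema is a list of objects::

        {"dimer_id": "...", "pair_type": "SCSC",
         "subclass": "aromatic-aromatic", "charges": [0, 0],
         "is_pi_contact": true, "units": "kJ/mol",
         "gas": {"elec": ..., "pauli": ..., "disp": ..., "pol": ..., "ct": ...},
         "pcm": {..., "solv_correction": ..., "epsilon": 78.39}}

    Foreign schemas are handled by alias tables (``field_map`` extends
    :data:`DEFAULT_FIELD_ALIASES`), so schema drift stays out of the
    logic.  ``units: "kcal/mol"`` triggers conversion to kJ/mol.
    Malformed records are logged and skipped; valid ones are returned.
    """
    aliases = dict(DEFAULT_FIELD_ALIASES)
    if field_map:
        for key, extra in field_map.items():
            aliases[key] = tuple(extra) + tuple(aliases.get(key, ()))
    payload = json.loads(Path(path).read_text())
    if isinstance(payload, Mapping):
        payload = payload.get("records", payload.get("dimers", []))
    records: list[EDARecord] = []
    for i, entry in enumerate(payload):
        dimer_id = str(entry.get("dimer_id", entry.get("id", f"record-{i}")))
        try:
            units = str(entry.get("units", "kJ/mol")).lower()
            scale = KCAL_TO_KJ if "kcal" in units else 1.0
            gas_entry = entry.get("gas", entry.get("gas_phase"))
            if gas_entry is None:
                raise KeyError("gas")
            gas = _components_from_dict(gas_entry, "gas", scale, aliases)
            pcm_entry = entry.get("pcm", entry.get("solvated"))
            pcm = (
                _components_from_dict(pcm_entry, "pcm", scale, aliases)
                if pcm_entry is not None
                else None
            )
            charges = entry.get("charges", (0, 0))
            known = {
                "dimer_id", "id", "pair_type", "subclass", "charges",
                "is_pi_contact", "units", "gas", "gas_phase", "pcm", "solvated",
            }
            records.append(
                EDARecord(
                    dimer_id=dimer_id,
                    pair_type=str(entry.get("pair_type", "")),
                    subclass=str(entry.get("subclass", "")),
                    charges=(int(charges[0]), int(charges[1])),
                    components_gas=gas,
                    components_pcm=pcm,
                    is_pi_contact=bool(entry.get("is_pi_contact", False)),
                    extra={k: v for k, v in entry.items() if k not in known},
                )
            )
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            logger.error("skipping malformed EDA record %s: %r", dimer_id, exc)
    return records


def record_to_dict(record: EDARecord) -> dict:
    """Native-schema dict for one record (inverse of :func:`read_eda_json`)."""
    out = {
        "dimer_id": record.dimer_id,
        "pair_type": record.pair_type,
        "subclass": record.subclass,
        "charges": list(record.charges),
        "is_pi_contact": record.is_pi_contact,
        "units": "kJ/mol",
        "gas": {n: getattr(record.components_gas, n) for n in COMPONENT_NAMES},
    }
    if record.components_pcm is not None:
        pcm = record.components_pcm
        out["pcm"] = {n: getattr(pcm, n) for n in COMPONENT_NAMES}
        out["pcm"]["solv_correction"] = pcm.solv_correction
        out["pcm"]["epsilon"] = pcm.epsilon
    if record.extra:
        out.update(record.extra)
    return out


def write_eda_json(records: Iterable[EDARecord], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([record_to_dict(r) for r in records], indent=1)
    )


def records_to_dataframe(records: Sequence[EDARecord], environment: str = "gas"):
    """All components and derived terms as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        try:
            c = r.components(environment)
        except EnvironmentError_:
            continue
        frz, orb = frozen_and_orbital(c)
        rows.append(
            {
                "dimer_id": r.dimer_id,
                "pair_type": r.pair_type,
                "subclass": r.subclass,
                "charge_a": r.charges[0],
                "charge_b": r.charges[1],
                "is_pi_contact": r.is_pi_contact,
                "environment": c.environment,
                "epsilon": c.epsilon,
                "elec": c.elec,
                "pauli": c.pauli,
                "disp": c.disp,
                "pol": c.pol,
                "ct": c.ct,
                "solv_correction": c.solv_correction,
                "frz": frz,
                "orb": orb,
                "total": total_interaction(c),
            }
        )
    return pd.DataFrame(rows)
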