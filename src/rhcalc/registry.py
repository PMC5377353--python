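"""Registry of solute parameters with a JSON round trip.

Ships the built-in constants for the common crystallization precipitants:
the three salts with published ion counts and specific-volume factors
(sodium chloride, ammonium sulfate, sodium malonate) and the standard PEG
grades, all with the effective monomer mass m = 38 g/mol.  Users can save
and reload registries, and add their own solutes, through a small
versioned JSON schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Union

from .core import PolymerParams, SaltParams
from .errors import DomainError, RegistryError

__all__ = [
    "SoluteRecord",
    "Registry",
    "builtin_registry",
    "load_registry",
    "save_registry",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Aliases resolving to canonical registry names (normalized form).
_ALIASES = {
    "nacl": "sodium chloride",
    "(nh4)2so4": "ammonium sulfate",
    "ammonium sulphate": "ammonium sulfate",
    "na malonate": "sodium malonate",
}


def _normalize(name: str) -> str:
    """Case-insensitive, whitespace-collapsed lookup key."""
    return " ".join(name.lower().split())


@dataclass(frozen=True)
class SoluteRecord:
    """A named solute with its model parameters and provenance."""

    name: str
    kind: str  # "salt" or "polymer"
    params: Union[SaltParams, PolymerParams]
    source: str = "user"

    def __post_init__(self) -> None:
        if self.kind not in ("salt", "polymer"):
            raise RegistryError(
                f"{self.name}: kind must be 'salt' or 'polymer', "
                f"got {self.kind!r}"
            )
        expected = SaltParams if self.kind == "salt" else PolymerParams
        if not isinstance(self.params, expected):
            raise RegistryError(
                f"{self.name}: kind {self.kind!r} requires "
                f"{expected.__name__} params"
            )


class Registry:
    """A mapping of solute names to records.

    Lookup is case-insensitive with whitespace normalization and a small
    alias table ("NaCl" resolves to "sodium chloride").
    """

    def __init__(self, records: Iterable[SoluteRecord] = ()) -> None:
        self._records: Dict[str, SoluteRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SoluteRecord) -> None:
        key = _normalize(record.name)
        if key in self._records:
            raise RegistryError(f"duplicate solute name: {record.name!r}")
        self._records[key] = record

    def lookup(self, name: str) -> SoluteRecord:
        key = _normalize(name)
        key = _ALIASES.get(key, key)
        try:
            return self._records[key]
        except KeyError:
            raise RegistryError(
                f"unknown solute {name!r}; available: "
                + ", ".join(sorted(self._records))
            ) from None

    def __contains__(self, name: str) -> bool:
        key = _normalize(name)
        return _ALIASES.get(key, key) in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def names(self) -> List[str]:
        return [rec.name for rec in self._records.values()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self._records == other._records


#: Published (x, y) constants: ion count and salt specific volume (L/mol).
_BUILTIN_SALTS = [
    ("sodium chloride", 2, 0.027),
    ("ammonium sulfate", 2, 0.074),
    ("sodium malonate", 3, 0.095),
]

#: Standard PEG grades; nominal molecular weight from the product name.
_BUILTIN_PEGS = [200, 400, 1000, 3350, 6000, 8000, 20000]

_BUILTIN_SOURCE = "built-in"


def builtin_registry() -> Registry:
    """Registry seeded with the published salt and PEG constants."""
    reg = Registry()
    for name, x, y in _BUILTIN_SALTS:
        reg.add(
            SoluteRecord(
                name=name,
                kind="salt",
                params=SaltParams(name=name, x_ions=x, y_volume=y),
                source=_BUILTIN_SOURCE,
            )
        )
    for n in _BUILTIN_PEGS:
        name = f"PEG {n}"
        reg.add(
            SoluteRecord(
                name=name,
                kind="polymer",
                params=PolymerParams(name=name, n_mw=float(n), m_monomer=38.0),
                source=_BUILTIN_SOURCE,
            )
        )
    return reg


def _record_to_dict(rec: SoluteRecord) -> dict:
    d = {"name": rec.name, "kind": rec.kind, "source": rec.source}
    if rec.kind == "salt":
        d["x_ions"] = rec.params.x_ions
        d["y_volume"] = rec.params.y_volume
    else:
        d["n_mw"] = rec.params.n_mw
        d["m_monomer"] = rec.params.m_monomer
    return d


def _record_from_dict(d: dict) -> SoluteRecord:
    try:
        name = d["name"]
        kind = d["kind"]
    except KeyError as exc:
        raise RegistryError(f"record missing required field {exc}: {d!r}")
    source = d.get("source", "user")
    try:
        if kind == "salt":
            for fld in ("x_ions", "y_volume"):
                if fld not in d:
                    raise RegistryError(
                        f"salt record {name!r} missing field {fld!r}"
                    )
            params = SaltParams(
                name=name,
                x_ions=float(d["x_ions"]),
                y_volume=float(d["y_volume"]),
            )
        elif kind == "polymer":
            if "n_mw" not in d:
                raise RegistryError(
                    f"polymer record {name!r} missing field 'n_mw'"
                )
            if "m_monomer" in d:
                m = float(d["m_monomer"])
            else:
                m = 38.0
                logger.warning(
                    "polymer record %r has no m_monomer; defaulting to 38",
                    name,
                )
            params = PolymerParams(name=name, n_mw=float(d["n_mw"]), m_monomer=m)
        else:
            raise RegistryError(
                f"record {name!r}: unknown kind {kind!r} "
                "(expected 'salt' or 'polymer')"
            )
    except DomainError as exc:
        raise RegistryError(f"record {name!r}: invalid parameters: {exc}")
    return SoluteRecord(name=name, kind=kind, params=params, source=source)


def save_registry(registry: Registry, path) -> None:
    """Write a registry to ``path`` as versioned JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "solutes": [_record_to_dict(rec) for rec in registry],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_registry(path) -> Registry:
    """Read a registry from a JSON file written by :func:`save_registry`.

    ``load(save(R))`` reproduces ``R`` exactly.  Malformed JSON, unknown
    kinds, duplicate names and invariant-violating parameters all raise
    :class:`RegistryError` naming the offending record.
    """
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RegistryError(f"{path}: not valid JSON: {exc}")
    if not isinstance(payload, dict) or "solutes" not in payload:
        raise RegistryError(f"{path}: missing top-level 'solutes' list")
    version = payload.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise RegistryError(
            f"{path}: unsupported schema_version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    reg = Registry()
    for d in payload["solutes"]:
        reg.add(_record_from_dict(d))
    return reg
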