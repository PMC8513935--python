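"""Immutable registry of the model's empirical parameters.

Every number used by the model lives in the CSV files under
``ssipsolv/data/`` — solvent descriptor sets for water and non-polar
organic solvents, two-domain descriptor sets for polar solvent classes
(ethers, nitriles, ketones, alcohols), per-functional-group SSIP
templates keyed by a SMARTS-like atom-environment code, and the pi-face
acceptor values for alkyl-substituted six-membered aromatic rings.

Each value carries a provenance tag:

``experimental_1to1``
    taken directly from experimental 1:1 H-bond complexation data;
``optimised``
    calibrated by rmsd minimisation against partition free energies;
``assumed``
    secondary-site value chosen by a documented package convention
    (see docs/methods.md);
``fixed``
    definitional (e.g. the zero offsets of the reference solvents).

The registry is read-only; :meth:`Registry.with_params` returns a
modified *copy* and is the handle used by the fitting machinery.
"""

from __future__ import annotations

import csv
import difflib
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .errors import UnknownGroupError, UnknownSolventError

DONOR = "donor"
ACCEPTOR = "acceptor"

PROVENANCE_TAGS = ("experimental_1to1", "optimised", "assumed", "fixed")

#: codes recognised by the assignment rules that deliberately carry no SSIPs
#: (e.g. a quaternary sp3 carbon, which is buried and makes no surface contact)
EMPTY_CODES = frozenset({"[CX4H0]"})

_SIMPLE_FIELDS = ("alpha_s", "c_alpha", "beta_s", "c_beta", "c0")
_POLAR_FIELDS = (
    "alpha_s1",
    "c_alpha1",
    "beta_s1",
    "c_beta1",
    "alpha_s2",
    "c_alpha2",
    "beta_s2",
    "c_beta2",
    "c0",
)

_SYNONYMS = {
    "n-hexadecane": "hexadecane",
    "hexadecan": "hexadecane",
    "n-hexane": "hexane",
    "ccl4": "carbon tetrachloride",
    "tetrachloromethane": "carbon tetrachloride",
    "carbontetrachloride": "carbon tetrachloride",
    "dcm": "dichloromethane",
    "methylene chloride": "dichloromethane",
    "dce": "1,2-dichloroethane",
    "perfluorohexane": "perfluoroalkane",
    "thf": "tetrahydrofuran",
    "ether": "diethyl ether",
    "dibutyl ether": "di-n-butyl ether",
    "meoh": "methanol",
    "etoh": "ethanol",
    "isopropanol": "propan-2-ol",
    "isobutanol": "2-methylpropan-1-ol",
    "tert-butanol": "2-methylpropan-2-ol",
    "t-butanol": "2-methylpropan-2-ol",
    "octanol": "octan-1-ol",
    "n-octanol": "octan-1-ol",
    "2-butanone": "butanone",
    "mek": "butanone",
}


@dataclass(frozen=True)
class SSIPSlot:
    """One template slot of a functional-group entry."""

    role: str  # DONOR or ACCEPTOR
    value: float  # dimensionless H-bond polarity
    count: int  # number of identical SSIPs contributed per matched unit
    provenance: str = "experimental_1to1"
    note: str = ""

    def __post_init__(self) -> None:
        if self.role not in (DONOR, ACCEPTOR):
            raise ValueError(f"role must be donor/acceptor, got {self.role!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValueError(f"SSIP value must be finite and positive, got {self.value}")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance tag {self.provenance!r}")


@dataclass(frozen=True)
class GroupParameterEntry:
    """SSIP template for one atom-environment code."""

    group_code: str
    ssips: tuple[SSIPSlot, ...]

    @property
    def n_donor(self) -> int:
        return sum(s.count for s in self.ssips if s.role == DONOR)

    @property
    def n_acceptor(self) -> int:
        return sum(s.count for s in self.ssips if s.role == ACCEPTOR)


@dataclass(frozen=True)
class SimpleSolvent:
    """One-site-pair solvent descriptor set.

    ``alpha_s``/``beta_s`` are the dimensionless donor/acceptor
    polarities of the solvent sites; ``c_alpha``/``c_beta`` (kJ mol^-1)
    quantify the solvent-solvent interactions disrupted on solvating a
    solute site; ``c0`` (kJ mol^-1) is the whole-molecule offset
    relative to n-hexadecane.
    """

    name: str
    alpha_s: float
    c_alpha: float
    beta_s: float
    c_beta: float
    c0: float
    provenance: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not (self.alpha_s > 0 and self.beta_s > 0):
            raise ValueError("alpha_s and beta_s must be positive")


@dataclass(frozen=True)
class SiteFractions:
    """Per-member interaction-site fractions of a two-domain solvent.

    Stored as integer SSIP counts of the member molecule; the fractions
    are derived so that each donor/acceptor pair sums to exactly 1.
    """

    member: str
    smiles: str
    n_alpha1: int
    n_alpha2: int
    n_beta1: int
    n_beta2: int

    @property
    def f_alpha1(self) -> float:
        return self.n_alpha1 / (self.n_alpha1 + self.n_alpha2)

    @property
    def f_alpha2(self) -> float:
        return 1.0 - self.f_alpha1

    @property
    def f_beta1(self) -> float:
        return self.n_beta1 / (self.n_beta1 + self.n_beta2)

    @property
    def f_beta2(self) -> float:
        return 1.0 - self.f_beta1


@dataclass(frozen=True)
class TwoDomainSolvent:
    """Polar solvent class with a non-polar (1) and a polar (2) domain.

    Ethers have no polar donor site: ``alpha_s2``/``c_alpha2`` are None
    and every member has ``f_alpha2 == 0``.
    """

    class_name: str
    alpha_s1: float
    c_alpha1: float
    beta_s1: float
    c_beta1: float
    alpha_s2: float | None
    c_alpha2: float | None
    beta_s2: float
    c_beta2: float
    c0: float
    members: Mapping[str, SiteFractions]
    provenance: Mapping[str, str] | None = None

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(self.members)

    def fractions(self, member: str) -> SiteFractions:
        key = member.strip().lower()
        try:
            return self.members[key]
        except KeyError:
            raise UnknownSolventError(
                f"{member!r} is not a member of the {self.class_name} class; "
                f"members: {', '.join(self.members)}"
            ) from None


Solvent = Union[SimpleSolvent, TwoDomainSolvent]


def _read_rows(path: Path | None, package_file: str) -> list[dict[str, str]]:
    if path is not None:
        with open(path, newline="") as fh:
            return list(csv.DictReader(fh))
    ref = resources.files("ssipsolv.data").joinpath(package_file)
    with ref.open(newline="") as fh:
        return list(csv.DictReader(fh))


def _float(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


class Registry:
    """The full, read-only parameter set of the model.

    Use :func:`load_registry` (or the module-level :data:`DEFAULT_REGISTRY`)
    to obtain one; use :meth:`with_params` to derive modified copies
    during calibration.
    """

    def __init__(
        self,
        simple: Mapping[str, SimpleSolvent],
        polar: Mapping[str, TwoDomainSolvent],
        groups: Mapping[str, GroupParameterEntry],
        pi_faces: Mapping[int, float],
    ) -> None:
        self._simple = dict(simple)
        self._polar = dict(polar)
        self._groups = dict(groups)
        self._pi_faces = dict(pi_faces)
        # member name -> class name
        self._member_index = {
            m: cls.class_name for cls in self._polar.values() for m in cls.members
        }

    # -- lookups ---------------------------------------------------------
    @property
    def simple_solvent_names(self) -> tuple[str, ...]:
        return tuple(self._simple)

    @property
    def polar_class_names(self) -> tuple[str, ...]:
        return tuple(self._polar)

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(self._member_index)

    @property
    def group_codes(self) -> tuple[str, ...]:
        return tuple(self._groups)

    @property
    def pi_faces(self) -> Mapping[int, float]:
        return dict(self._pi_faces)

    def _canonical(self, name: str) -> str:
        key = " ".join(name.strip().lower().split())
        return _SYNONYMS.get(key, key)

    def resolve_solvent(self, name: str) -> tuple[Solvent, str | None]:
        """Resolve a name to ``(solvent, member)``.

        ``member`` is None for simple solvents and for a polar class
        requested by its class name; it is the member name when a
        specific polar solvent (e.g. "tetrahydrofuran") was requested.
        """
        key = self._canonical(name)
        if key in self._simple:
            return self._simple[key], None
        if key in self._polar:
            return self._polar[key], None
        if key in self._member_index:
            return self._polar[self._member_index[key]], key
        candidates = (
            list(self._simple) + list(self._polar) + list(self._member_index)
        )
        near = difflib.get_close_matches(key, candidates, n=3, cutoff=0.5)
        hint = f"; did you mean: {', '.join(near)}?" if near else ""
        raise UnknownSolventError(f"unknown solvent {name!r}{hint}")

    def solvent(self, name: str) -> Solvent:
        """Return the descriptor set for a registered solvent name."""
        return self.resolve_solvent(name)[0]

    def group(self, code: str) -> GroupParameterEntry:
        """Return the SSIP template for an atom-environment code."""
        try:
            return self._groups[code]
        except KeyError:
            raise UnknownGroupError(
                f"no SSIP template for group code {code!r}; registered codes: "
                f"{', '.join(self._groups)}"
            ) from None

    def pi_face_beta(self, n_alkyl: int) -> float:
        """Pi-face acceptor value for a six-membered aromatic ring with
        ``n_alkyl`` alkyl substituents; raises KeyError if unregistered."""
        return self._pi_faces[n_alkyl]

    # -- parameter addressing (used by the fitting machinery) ------------
    def get_param(self, path: str) -> float:
        """Fetch one scalar by path.

        Paths: ``solvent:<name>:<field>``, ``polar:<class>:<field>``,
        ``group:<code>:<slot-index>``, ``pi:<n_alkyl>``.
        """
        kind, *rest = path.split(":")
        if kind == "solvent":
            name, field = rest[0], rest[1]
            return getattr(self._simple[self._canonical(name)], field)
        if kind == "polar":
            name, field = rest[0], rest[1]
            return getattr(self._polar[self._canonical(name)], field)
        if kind == "group":
            code, idx = ":".join(rest[:-1]), int(rest[-1])
            return self._groups[code].ssips[idx].value
        if kind == "pi":
            return self._pi_faces[int(rest[0])]
        raise KeyError(f"bad parameter path {path!r}")

    def with_params(self, updates: Mapping[str, float]) -> "Registry":
        """Return a copy of the registry with the addressed scalars replaced."""
        simple = dict(self._simple)
        polar = dict(self._polar)
        groups = dict(self._groups)
        pi = dict(self._pi_faces)
        for path, value in updates.items():
            kind, *rest = path.split(":")
            if kind == "solvent":
                name, field = self._canonical(rest[0]), rest[1]
                simple[name] = replace(simple[name], **{field: float(value)})
            elif kind == "polar":
                name, field = self._canonical(rest[0]), rest[1]
                polar[name] = replace(polar[name], **{field: float(value)})
            elif kind == "group":
                code, idx = ":".join(rest[:-1]), int(rest[-1])
                entry = groups[code]
                slots = list(entry.ssips)
                slots[idx] = replace(slots[idx], value=float(value))
                groups[code] = replace(entry, ssips=tuple(slots))
            elif kind == "pi":
                pi[int(rest[0])] = float(value)
            else:
                raise KeyError(f"bad parameter path {path!r}")
        return Registry(simple, polar, groups, pi)

    # -- serialisation ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write the registry back to its four on-disk CSV tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "solvents_simple.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "field", "value", "units", "provenance", "note"])
            for s in self._simple.values():
                prov = s.provenance or {}
                for field in _SIMPLE_FIELDS:
                    units = "dimensionless" if field in ("alpha_s", "beta_s") else "kJ/mol"
                    w.writerow(
                        [s.name, field, repr(getattr(s, field)), units,
                         prov.get(field, "optimised"), ""]
                    )
        with open(directory / "solvents_polar.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "field", "value", "units", "provenance", "note"])
            for p in self._polar.values():
                prov = p.provenance or {}
                for field in _POLAR_FIELDS:
                    units = "kJ/mol" if field.startswith("c") else "dimensionless"
                    val = getattr(p, field)
                    w.writerow(
                        [p.class_name, field, "" if val is None else repr(val),
                         units, prov.get(field, "optimised"), ""]
                    )
        with open(directory / "polar_members.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["member", "class", "smiles", "n_alpha1", "n_alpha2", "n_beta1", "n_beta2"]
            )
            for p in self._polar.values():
                for f in p.members.values():
                    w.writerow(
                        [f.member, p.class_name, f.smiles,
                         f.n_alpha1, f.n_alpha2, f.n_beta1, f.n_beta2]
                    )
        with open(directory / "groups.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "role", "value", "count", "units", "provenance", "note"])
            for entry in self._groups.values():
                for slot in entry.ssips:
                    w.writerow(
                        [entry.group_code, slot.role, repr(slot.value), slot.count,
                         "dimensionless", slot.provenance, slot.note]
                    )
        with open(directory / "aromatic_pi.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["n_alkyl", "beta", "units", "provenance", "note"])
            for n, beta in sorted(self._pi_faces.items()):
                w.writerow([n, repr(beta), "dimensionless", "experimental_1to1", ""])


def load_registry(directory: str | Path | None = None) -> Registry:
    """Load the registry from ``directory`` (default: the bundled data files)."""
    base = Path(directory) if directory is not None else None

    def rows(name: str) -> list[dict[str, str]]:
        return _read_rows(base / name if base else None, name)

    simple: dict[str, SimpleSolvent] = {}
    fields: dict[str, dict[str, float]] = {}
    prov: dict[str, dict[str, str]] = {}
    for row in rows("solvents_simple.csv"):
        name = row["name"].strip().lower()
        fields.setdefault(name, {})[row["field"]] = float(row["value"])
        prov.setdefault(name, {})[row["field"]] = row["provenance"]
    for name, vals in fields.items():
        simple[name] = SimpleSolvent(name=name, provenance=prov[name], **vals)

    member_rows: dict[str, list[SiteFractions]] = {}
    for row in rows("polar_members.csv"):
        frac = SiteFractions(
            member=row["member"].strip().lower(),
            smiles=row["smiles"],
            n_alpha1=int(row["n_alpha1"]),
            n_alpha2=int(row["n_alpha2"]),
            n_beta1=int(row["n_beta1"]),
            n_beta2=int(row["n_beta2"]),
        )
        member_rows.setdefault(row["class"].strip().lower(), []).append(frac)

    polar: dict[str, TwoDomainSolvent] = {}
    pfields: dict[str, dict[str, float | None]] = {}
    pprov: dict[str, dict[str, str]] = {}
    for row in rows("solvents_polar.csv"):
        name = row["class"].strip().lower()
        pfields.setdefault(name, {})[row["field"]] = _float(row["value"])
        pprov.setdefault(name, {})[row["field"]] = row["provenance"]
    for name, vals in pfields.items():
        members = {f.member: f for f in member_rows.get(name, [])}
        polar[name] = TwoDomainSolvent(
            class_name=name, members=members, provenance=pprov[name], **vals
        )

    groups: dict[str, GroupParameterEntry] = {}
    slots: dict[str, list[SSIPSlot]] = {}
    for row in rows("groups.csv"):
        slots.setdefault(row["code"], []).append(
            SSIPSlot(
                role=row["role"],
                value=float(row["value"]),
                count=int(row["count"]),
                provenance=row["provenance"],
                note=row.get("note", ""),
            )
        )
    for code, slotlist in slots.items():
        groups[code] = GroupParameterEntry(group_code=code, ssips=tuple(slotlist))

    pi = {int(r["n_alkyl"]): float(r["beta"]) for r in rows("aromatic_pi.csv")}
    return Registry(simple, polar, groups, pi)


DEFAULT_REGISTRY = load_registry()


def get_solvent(name: str, registry: Registry | None = None) -> Solvent:
    """Descriptor set for a registered solvent (case-insensitive, synonyms ok)."""
    return (registry or DEFAULT_REGISTRY).solvent(name)


def get_group_params(group_code: str, registry: Registry | None = None) -> GroupParameterEntry:
    """SSIP template for a registered atom-environment code."""
    return (registry or DEFAULT_REGISTRY).group(group_code)
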