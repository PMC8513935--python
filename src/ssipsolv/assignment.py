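"""Rule-based SSIP assignment from chemical structure.

A molecule is converted into a multiset of surface site interaction
points (SSIPs) by deterministic atom typing: every heavy atom receives
exactly one SMARTS-like group code describing the atom and its directly
bonded neighbours, each code maps to a registered SSIP template, and
six-membered aromatic rings contribute two additional pi-face acceptor
SSIPs (one per face), whose value depends on the number of alkyl
substituents on the ring.

The assignment is structural and integer-valued: hydrogens attached to
sp3/aromatic carbons each contribute one donor (alpha) and, for sp3 CH,
one acceptor (beta); lone pairs and pi systems contribute acceptors.
Electronegative neighbours (O, N, S) leave alkyl C-H parameters
unchanged; only chlorine polarises adjacent C-H donors (alpha 1.2 ->
1.6).  Atom environments without a registered template raise
:class:`~ssipsolv.errors.UnassignedAtomError` rather than defaulting
silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .errors import (
    StructureParseError,
    UnassignedAtomError,
    UnsupportedFeatureError,
    UnsupportedRingError,
)
from .parameters import (
    ACCEPTOR,
    DONOR,
    EMPTY_CODES,
    DEFAULT_REGISTRY,
    Registry,
)

RDLogger.DisableLog("rdApp.error")

PI_FACE_LABEL = "pi-face"


@dataclass(frozen=True)
class SSIP:
    """One surface site interaction point."""

    role: str  # donor or acceptor
    value: float  # dimensionless polarity (alpha for donors, beta for acceptors)
    label: str  # group code or "pi-face"
    atom_index: int | None = None  # origin heavy atom; None for ring pi-faces


@dataclass(frozen=True)
class AtomCode:
    """Group code assigned to one heavy atom.

    ``multiplicity`` is the number of template applications for the atom
    (the attached-H count for per-CH-bond codes, otherwise 1).
    """

    atom_index: int
    code: str
    multiplicity: int = 1


@dataclass
class SSIPProfile:
    """The SSIP multiset representing one molecule."""

    smiles: str
    ssips: list[SSIP] = field(default_factory=list)
    molecule_id: str | None = None
    notes: tuple[str, ...] = ()

    @property
    def n_alpha(self) -> int:
        return sum(1 for s in self.ssips if s.role == DONOR)

    @property
    def n_beta(self) -> int:
        return sum(1 for s in self.ssips if s.role == ACCEPTOR)

    @property
    def n_total(self) -> int:
        return len(self.ssips)

    @property
    def alphas(self) -> list[float]:
        return [s.value for s in self.ssips if s.role == DONOR]

    @property
    def betas(self) -> list[float]:
        return [s.value for s in self.ssips if s.role == ACCEPTOR]

    def as_multiset(self) -> Counter:
        """Order-independent content, for equality across SMILES renumberings."""
        return Counter((s.role, round(s.value, 10), s.label) for s in self.ssips)


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Aromaticity perception follows RDKit's default model.  Charged or
    isotopically labelled species are outside the model and rejected.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # retry without sanitisation to distinguish syntax from chemistry
        raw = Chem.MolFromSmiles(smiles, sanitize=False)
        if raw is None:
            raise StructureParseError(f"could not parse SMILES {smiles!r}")
        raise StructureParseError(
            f"SMILES {smiles!r} parsed but failed valence/aromaticity sanitisation"
        )
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise UnsupportedFeatureError(
                f"charged species are not supported (atom {atom.GetIdx()} in {smiles!r})"
            )
        if atom.GetIsotope() != 0:
            raise UnsupportedFeatureError(
                f"isotope labels are not supported (atom {atom.GetIdx()} in {smiles!r})"
            )
    return mol


def _describe(atom: Chem.Atom) -> str:
    nbrs = sorted(n.GetSymbol() for n in atom.GetNeighbors())
    return (
        f"{atom.GetSymbol()}(aromatic={atom.GetIsAromatic()}, "
        f"H={atom.GetTotalNumHs()}, neighbours={'/'.join(nbrs) or 'none'})"
    )


def _is_sp3_carbon(atom: Chem.Atom) -> bool:
    return (
        atom.GetAtomicNum() == 6
        and not atom.GetIsAromatic()
        and atom.GetHybridization() == Chem.HybridizationType.SP3
    )


def _code_for_atom(atom: Chem.Atom) -> AtomCode:
    """Deterministic group code for one heavy atom (order-independent)."""
    idx = atom.GetIdx()
    z = atom.GetAtomicNum()
    nh = atom.GetTotalNumHs()
    nbrs = list(atom.GetNeighbors())

    if z == 6:
        if atom.GetIsAromatic():
            if nh == 1:
                return AtomCode(idx, "[cH]")
            if nh == 0:
                heavy = [n for n in nbrs if not n.GetIsAromatic()]
                if len(heavy) == 1 and _is_sp3_carbon(heavy[0]):
                    return AtomCode(idx, "[c][CX4]")
            raise UnassignedAtomError(
                f"no SSIP template for aromatic environment {_describe(atom)}; "
                "only CH and alkyl-substituted aromatic carbons are parameterised"
            )
        hyb = atom.GetHybridization()
        if hyb == Chem.HybridizationType.SP3:
            if nh == 0:
                return AtomCode(idx, "[CX4H0]")
            code = (
                "[CX4H]Cl"
                if any(n.GetAtomicNum() == 17 for n in nbrs)
                else "[CX4H]"
            )
            return AtomCode(idx, code, multiplicity=nh)
        if hyb == Chem.HybridizationType.SP2:
            dbl_o = [
                n
                for n in nbrs
                if n.GetAtomicNum() == 8
                and atom.GetOwningMol()
                .GetBondBetweenAtoms(idx, n.GetIdx())
                .GetBondType()
                == Chem.BondType.DOUBLE
            ]
            if dbl_o:
                c_nbrs = [n for n in nbrs if n.GetAtomicNum() == 6]
                if nh == 0 and len(c_nbrs) == 2 and all(map(_is_sp3_carbon, c_nbrs)):
                    return AtomCode(idx, "[CX3]=[OX1]")
                raise UnassignedAtomError(
                    f"only dialkyl ketone carbonyls are parameterised; got {_describe(atom)}"
                )
        if hyb == Chem.HybridizationType.SP:
            n_triple = [
                n
                for n in nbrs
                if n.GetAtomicNum() == 7
                and atom.GetOwningMol()
                .GetBondBetweenAtoms(idx, n.GetIdx())
                .GetBondType()
                == Chem.BondType.TRIPLE
            ]
            if n_triple and nh == 0:
                c_nbrs = [n for n in nbrs if n.GetAtomicNum() == 6]
                if len(c_nbrs) == 1 and _is_sp3_carbon(c_nbrs[0]):
                    return AtomCode(idx, "[CX2]#[NX1]")
            raise UnassignedAtomError(
                f"only alkyl nitrile sp carbons are parameterised; got {_describe(atom)}"
            )
        raise UnassignedAtomError(f"no SSIP template for carbon {_describe(atom)}")

    if z == 8:
        if nh == 2 and not nbrs:
            return AtomCode(idx, "[OH2]")
        if nh == 1 and len(nbrs) == 1 and _is_sp3_carbon(nbrs[0]):
            return AtomCode(idx, "[OX2H][CX4]")
        if nh == 0 and len(nbrs) == 2 and all(map(_is_sp3_carbon, nbrs)):
            return AtomCode(idx, "[OX2]([CX4])[CX4]")
        if (
            nh == 0
            and len(nbrs) == 1
            and nbrs[0].GetAtomicNum() == 6
            and atom.GetOwningMol()
            .GetBondBetweenAtoms(idx, nbrs[0].GetIdx())
            .GetBondType()
            == Chem.BondType.DOUBLE
        ):
            return AtomCode(idx, "[OX1]=[CX3]")
        raise UnassignedAtomError(
            f"no SSIP template for oxygen environment {_describe(atom)} "
            "(phenols, esters and acids are not parameterised)"
        )

    if z == 7:
        if len(nbrs) == 1 and nbrs[0].GetAtomicNum() == 6 and (
            atom.GetOwningMol()
            .GetBondBetweenAtoms(idx, nbrs[0].GetIdx())
            .GetBondType()
            == Chem.BondType.TRIPLE
        ):
            return AtomCode(idx, "[NX1]#[CX2]")
        raise UnassignedAtomError(
            f"no SSIP template for nitrogen environment {_describe(atom)} "
            "(amines and amides are not parameterised)"
        )

    if z == 17:
        if len(nbrs) == 1 and _is_sp3_carbon(nbrs[0]):
            return AtomCode(idx, "Cl[CX4]")
        raise UnassignedAtomError(
            f"only alkyl chlorides are parameterised; got {_describe(atom)}"
        )

    raise UnassignedAtomError(f"no SSIP template for element {_describe(atom)}")


def assign_atom_codes(mol: Chem.Mol) -> list[AtomCode]:
    """One group code per heavy atom, invariant to atom input order."""
    return [_code_for_atom(atom) for atom in mol.GetAtoms()]


def _aromatic_six_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    rings = []
    for ring in Chem.GetSymmSSSR(mol):
        atoms = tuple(ring)
        if len(atoms) == 6 and all(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in atoms
        ):
            rings.append(atoms)
    return rings


def build_ssip_profile(
    codes: Sequence[AtomCode],
    mol: Chem.Mol,
    registry: Registry | None = None,
    molecule_id: str | None = None,
) -> SSIPProfile:
    """Assemble the SSIP multiset from atom codes plus aromatic ring terms."""
    registry = registry or DEFAULT_REGISTRY
    smiles = Chem.MolToSmiles(mol)
    ssips: list[SSIP] = []
    code_by_atom = {c.atom_index: c.code for c in codes}

    for ac in codes:
        if ac.code in EMPTY_CODES:
            continue
        entry = registry.group(ac.code)
        for slot in entry.ssips:
            for _ in range(slot.count * ac.multiplicity):
                ssips.append(SSIP(slot.role, slot.value, ac.code, ac.atom_index))

    notes: list[str] = []
    rings = _aromatic_six_rings(mol)
    for ring in rings:
        n_alkyl = sum(1 for i in ring if code_by_atom.get(i) == "[c][CX4]")
        try:
            beta = registry.pi_face_beta(n_alkyl)
        except KeyError:
            raise UnsupportedRingError(
                f"no pi-face value registered for a six-membered aromatic ring "
                f"with {n_alkyl} alkyl substituents "
                f"(registered: {sorted(registry.pi_faces)})"
            ) from None
        ssips.append(SSIP(ACCEPTOR, beta, PI_FACE_LABEL, None))
        ssips.append(SSIP(ACCEPTOR, beta, PI_FACE_LABEL, None))
    if len(rings) > 1:
        notes.append(f"pi-face SSIPs assigned per six-membered ring ({len(rings)} rings)")

    return SSIPProfile(smiles=smiles, ssips=ssips, molecule_id=molecule_id, notes=tuple(notes))


def assign(
    smiles: str,
    registry: Registry | None = None,
    molecule_id: str | None = None,
) -> SSIPProfile:
    """SMILES -> SSIP profile in one call."""
    mol = parse_structure(smiles)
    return build_ssip_profile(assign_atom_codes(mol), mol, registry, molecule_id)


def ssip_count_from_liquid(
    molar_concentration: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> int:
    """Advisory SSIP count for a pure liquid of the given molarity.

    Nearest integer (ties to even) of ``220 / [liquid]``; a design
    check on the templates, never an override of them.
    """
    if molar_concentration <= 0:
        raise ValueError(
            f"molar concentration must be positive, got {molar_concentration}"
        )
    return round(constants.target_ssip_concentration / molar_concentration)


def ssip_concentration(profile: SSIPProfile, molar_concentration: float) -> float:
    """Total SSIP concentration (M) of a pure liquid of this molecule."""
    if molar_concentration <= 0:
        raise ValueError(
            f"molar concentration must be positive, got {molar_concentration}"
        )
    return (profile.n_alpha + profile.n_beta) * molar_concentration


# -- two-domain solvent support ------------------------------------------

_POLAR_ACCEPTOR_CODES = frozenset(
    {"[OX2H][CX4]", "[OX2]([CX4])[CX4]", "[OX1]=[CX3]", "[CX3]=[OX1]",
     "[CX2]#[NX1]", "[NX1]#[CX2]"}
)


def solvent_site_fractions(smiles: str, registry: Registry | None = None) -> dict[str, int]:
    """Domain site counts of a polar solvent molecule.

    Donor SSIPs in the polar domain (2) are the hydroxyl O-H and any C-H
    on carbons directly bonded to a carbonyl or nitrile carbon
    (activated C-H); acceptor SSIPs in the polar domain are those of the
    heteroatom-containing functional group (lone pairs and pi systems).
    Everything else is in the non-polar domain (1).  Returns counts
    ``{"n_alpha1": ..., "n_alpha2": ..., "n_beta1": ..., "n_beta2": ...}``.
    """
    registry = registry or DEFAULT_REGISTRY
    mol = parse_structure(smiles)
    codes = assign_atom_codes(mol)
    code_by_atom = {c.atom_index: c for c in codes}

    activated_c: set[int] = set()
    for ac in codes:
        if ac.code in ("[CX3]=[OX1]", "[CX2]#[NX1]"):
            for n in mol.GetAtomWithIdx(ac.atom_index).GetNeighbors():
                if _is_sp3_carbon(n):
                    activated_c.add(n.GetIdx())

    counts = {"n_alpha1": 0, "n_alpha2": 0, "n_beta1": 0, "n_beta2": 0}
    profile = build_ssip_profile(codes, mol, registry)
    for s in profile.ssips:
        if s.role == DONOR:
            polar = (
                s.label == "[OX2H][CX4]"
                or s.label == "[OH2]"
                or (s.atom_index in activated_c and s.label.startswith("[CX4H]"))
            )
            counts["n_alpha2" if polar else "n_alpha1"] += 1
        else:
            polar = s.label in _POLAR_ACCEPTOR_CODES
            counts["n_beta2" if polar else "n_beta1"] += 1
    return counts
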