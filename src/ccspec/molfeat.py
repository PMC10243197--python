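"""Corrected group-contribution (CGC) molecular featurization.

A molecule (SMILES) plus a solvent-polarity scalar is mapped to a fixed
151-dimensional descriptor vector laid out as::

    [ group counts (58) | A, B conjugation (2) | electronic block (90) | solvent (1) ]

The group block counts occurrences of a fixed fragment vocabulary (ring
groups, non-ring groups with phenyl-attached "(ph)" variants, substitution
position slots for isolated / two-fused / linear three-fused aromatic ring
systems, aromatic-aromatic and aromatic-aliphatic linkages, and bridging
C=C descriptors), with an "Other groups" overflow for anything unmatched.
A is the total number of conjugated double bonds, B the size of the largest
single conjugated system.  The electronic block is a frozen list of E-state,
VSA-partitioned (MOE-type), topological and connectivity indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeGraph",
    "RingSystemClass",
    "GroupVector",
    "ConjugationDescriptors",
    "DescriptorVector",
    "GROUP_KEYS",
    "ELECTRONIC_DESCRIPTORS",
    "DESCRIPTOR_LENGTH",
    "parse_molecule",
    "classify_ring_systems",
    "count_groups",
    "conjugation_descriptors",
    "electronic_descriptors",
    "assemble_descriptor_vector",
    "featurize",
    "descriptor_names",
    "solvent_polarity_table",
    "lookup_solvent_polarity",
]

# ---------------------------------------------------------------------------
# Vocabulary

#: Substitution-position and linkage descriptors.
POSITION_KEYS = (
    "N1(ortho-)",
    "N1(meta-)",
    "N1(para-)",
    "N2(alpha)",
    "N2(beta)",
    "N3(alpha)",
    "N3(beta)",
    "N3(gamma)",
    "Ar-Ar",
    "Ar-R",
)

#: Ring-attributed groups (includes the bridging >C=C< linkage descriptors).
RING_KEYS = (
    ">C=(Ring)",
    "-CH=(Ring)",
    "-N=(Ring)",
    ">N+=(Ring)",
    "-CH2-(Ring)",
    "-HC<(Ring)",
    ">C<(Ring)",
    "-O-(Ring)",
    ">C=O(Ring)",
    "-N<(Ring)",
    "-NH-(Ring)",
    "-S-(Ring)",
    "-COO-(Ring)",
    ">C=C<(1)",
    ">C=C<(2)",
)

#: Non-ring groups; "(ph)" variants apply when the group's anchor atom is
#: bonded to an aromatic carbon.
NONRING_KEYS = (
    "-OH",
    "-OH(ph)",
    "-NH2",
    "-NH2(ph)",
    "-C=O(-N<)",
    "-C=O(-N<)(ph)",
    "-N<",
    "-N<(ph)",
    ">C<",
    "-CH3",
    "-S-",
    "-S-(ph)",
    "-O-",
    "-O-(ph)",
    "-F",
    "-F(ph)",
    "-Cl",
    "-Cl(ph)",
    "-Br",
    "-Br(ph)",
    "-C=O",
    "-OCO-(ph)",
    "-I",
    "-I(ph)",
    "-COOH",
    "-COO-",
    "-NO2",
    "-C#N",
    "-N<(C=O)",
    "-N<(C=O)(ph)",
    "-SO2",
    "-SO2(-N<)",
)

OTHER_KEY = "Other groups"

#: Canonical key order of the group block (58 slots).
GROUP_KEYS: tuple[str, ...] = POSITION_KEYS + RING_KEYS + NONRING_KEYS + (OTHER_KEY,)

_GROUP_INDEX = {k: i for i, k in enumerate(GROUP_KEYS)}

#: Attribution tag for ring-fusion atoms: they are carried by the fused-ring
#: structural descriptors (N2/N3) rather than by an atom-level group.
FUSION_TAG = "__ring_fusion__"

#: Frozen electronic/topological block (90 entries), all rdkit.Chem.Descriptors
#: names.  E-state block, MOE-type VSA partitions, topological and
#: connectivity indices, ring and pharmacophore counts.
ELECTRONIC_DESCRIPTORS: tuple[str, ...] = (
    # E-state
    *[f"EState_VSA{i}" for i in range(1, 12)],
    *[f"VSA_EState{i}" for i in range(1, 11)],
    "MaxEStateIndex",
    "MinEStateIndex",
    "MaxAbsEStateIndex",
    "MinAbsEStateIndex",
    # MOE-type surface-area partitions
    *[f"PEOE_VSA{i}" for i in range(1, 15)],
    *[f"SMR_VSA{i}" for i in range(1, 11)],
    *[f"SlogP_VSA{i}" for i in range(1, 13)],
    "TPSA",
    "LabuteASA",
    # topological
    "BalabanJ",
    "BertzCT",
    "HallKierAlpha",
    "AvgIpc",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    # connectivity
    "Chi0",
    "Chi1",
    "Chi0n",
    "Chi1n",
    "Chi2n",
    "Chi3n",
    "Chi4n",
    "Chi0v",
    "Chi1v",
    "Chi2v",
    "Chi3v",
    "Chi4v",
    # ring / pharmacophore counts
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumSaturatedRings",
    "RingCount",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "FractionCSP3",
)

_ELECTRONIC_FNS = [getattr(Descriptors, name) for name in ELECTRONIC_DESCRIPTORS]

N_GROUP = len(GROUP_KEYS)  # 58
N_CONJ = 2
N_ELECTRONIC = len(ELECTRONIC_DESCRIPTORS)  # 90
DESCRIPTOR_LENGTH = N_GROUP + N_CONJ + N_ELECTRONIC + 1  # 151

#: Block offsets within the descriptor vector.
BLOCK_OFFSETS = {
    "group": (0, N_GROUP),
    "conjugation": (N_GROUP, N_GROUP + N_CONJ),
    "electronic": (N_GROUP + N_CONJ, N_GROUP + N_CONJ + N_ELECTRONIC),
    "solvent": (DESCRIPTOR_LENGTH - 1, DESCRIPTOR_LENGTH),
}


def descriptor_names() -> list[str]:
    """Names of all 151 descriptor slots in canonical order."""
    return (
        list(GROUP_KEYS)
        + ["A(conj_total)", "B(conj_largest)"]
        + list(ELECTRONIC_DESCRIPTORS)
        + ["solvent_polarity"]
    )


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RingSystemClass:
    """A fused cluster of pi-conjugated rings with substituent positions.

    kind 'isolated' labels positions from {ortho, meta, para} (one label per
    unordered substituent pair); 'two_fused' labels each substituent alpha or
    beta (naphthalene-like); 'three_fused' adds gamma for the middle ring of
    a linear (anthracene-like) fusion.  Angular three-ring fusions and
    systems of four or more rings are 'unsupported'.
    """

    kind: str
    atoms: frozenset[int]
    rings: tuple[tuple[int, ...], ...]
    fusion_atoms: frozenset[int]
    substituent_positions: tuple[str, ...]


@dataclass(frozen=True)
class MoleculeGraph:
    """A parsed molecule with aromaticity perceived and ring systems found.

    Construction canonicalizes the input SMILES, so two spellings of the
    same molecule yield identical graphs and identical descriptors.
    """

    mol: Chem.Mol
    canonical_smiles: str
    ring_systems: tuple[RingSystemClass, ...]

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_aromatic_atoms(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetIsAromatic())


@dataclass(frozen=True)
class GroupVector:
    """Counts over the fixed group vocabulary plus an attribution map.

    ``attribution`` maps every heavy-atom index to the vocabulary key it was
    attributed to, to ``"Other groups"``, or to the ring-fusion tag; it
    witnesses that each heavy atom is attributed exactly once.
    """

    counts: np.ndarray
    attribution: dict[int, str] = field(compare=False)

    def __getitem__(self, key: str) -> int:
        return int(self.counts[_GROUP_INDEX[key]])

    def as_array(self) -> np.ndarray:
        return self.counts.astype(float)

    def nonzero(self) -> dict[str, int]:
        return {k: int(c) for k, c in zip(GROUP_KEYS, self.counts) if c}


@dataclass(frozen=True)
class ConjugationDescriptors:
    """A: total conjugated double bonds; B: size of the largest system."""

    A: int
    B: int

    def __post_init__(self) -> None:
        if not (0 <= self.B <= self.A):
            raise ValueError(f"invalid conjugation descriptors A={self.A}, B={self.B}")


@dataclass(frozen=True)
class DescriptorVector:
    """The assembled 151-entry stage-1 feature vector."""

    values: np.ndarray
    block_offsets: dict[str, tuple[int, int]] = field(compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (DESCRIPTOR_LENGTH,):
            raise ValueError(f"descriptor vector must have length {DESCRIPTOR_LENGTH}")
        object.__setattr__(self, "values", v)

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_offsets[name]
        return self.values[lo:hi]


# ---------------------------------------------------------------------------
# Parsing and ring perception


def _is_pi_ring(mol: Chem.Mol, ring: tuple[int, ...]) -> bool:
    """A ring is pi-conjugated if every ring carbon is aromatic or doubly
    bonded; heteroatoms (ether O, amine N, thioether S ...) are exempt."""
    for idx in ring:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetIsAromatic():
            continue
        if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
            continue
        return False
    return True


def _fused_components(rings: list[tuple[int, ...]]) -> list[list[int]]:
    """Group ring indices into components sharing at least one bond (2 atoms)."""
    n = len(rings)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if len(set(rings[i]) & set(rings[j])) >= 2:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _substituent_atoms(mol: Chem.Mol, ring_atom: int, system: frozenset[int]) -> list[int]:
    """Heavy neighbours outside the ring system, excluding exocyclic
    double-bonded atoms (a ring C=O's oxygen is part of the ring group,
    not a substituent)."""
    out = []
    atom = mol.GetAtomWithIdx(ring_atom)
    for b in atom.GetBonds():
        nbr = b.GetOtherAtom(atom)
        if nbr.GetIdx() in system or nbr.GetAtomicNum() == 1:
            continue
        if b.GetBondType() != Chem.BondType.SINGLE and not b.GetIsAromatic():
            continue
        out.append(nbr.GetIdx())
    return out


def _classify_system(mol: Chem.Mol, rings: list[tuple[int, ...]]) -> RingSystemClass:
    atoms = frozenset(a for r in rings for a in r)
    ring_sets = [set(r) for r in rings]
    fusion = frozenset(
        a
        for i, r in enumerate(ring_sets)
        for a in r
        if any(a in r2 for j, r2 in enumerate(ring_sets) if j != i)
    )
    n = len(rings)
    positions: list[str] = []

    if n == 1:
        kind = "isolated"
        ring = rings[0]
        if len(ring) == 6:
            bearers = [a for a in ring if _substituent_atoms(mol, a, atoms)]
            # one label per unordered pair of substituent-bearing positions
            order = {a: i for i, a in enumerate(ring)}
            sub_counts = {a: len(_substituent_atoms(mol, a, atoms)) for a in bearers}
            slots: list[int] = []
            for a in bearers:
                slots.extend([order[a]] * sub_counts[a])
            for i in range(len(slots)):
                for j in range(i + 1, len(slots)):
                    d = abs(slots[i] - slots[j]) % 6
                    d = min(d, 6 - d)
                    if d == 1:
                        positions.append("ortho")
                    elif d == 2:
                        positions.append("meta")
                    elif d == 3:
                        positions.append("para")
    elif n == 2:
        kind = "two_fused"
        for a in sorted(atoms - fusion):
            subs = _substituent_atoms(mol, a, atoms)
            if not subs:
                continue
            nbrs = {nb.GetIdx() for nb in mol.GetAtomWithIdx(a).GetNeighbors()}
            label = "alpha" if nbrs & fusion else "beta"
            positions.extend([label] * len(subs))
    elif n == 3:
        # middle ring = the one fused to both others; linear iff its two
        # non-fusion atoms are not adjacent (anthracene yes, phenanthrene no)
        shared = [sum(len(ring_sets[i] & ring_sets[j]) >= 2 for j in range(3) if j != i) for i in range(3)]
        if 2 not in shared:
            kind = "unsupported"
        else:
            mid = ring_sets[shared.index(2)]
            free = sorted(mid - fusion)
            adjacent = (
                len(free) == 2
                and mol.GetBondBetweenAtoms(free[0], free[1]) is not None
            )
            if len(free) != 2 or adjacent:
                kind = "unsupported"
            else:
                kind = "three_fused"
                for a in sorted(atoms - fusion):
                    subs = _substituent_atoms(mol, a, atoms)
                    if not subs:
                        continue
                    if a in mid:
                        label = "gamma"
                    else:
                        nbrs = {nb.GetIdx() for nb in mol.GetAtomWithIdx(a).GetNeighbors()}
                        label = "alpha" if nbrs & fusion else "beta"
                    positions.extend([label] * len(subs))
    else:
        kind = "unsupported"

    if kind == "unsupported":
        logger.warning(
            "unsupported fused ring system (%d rings); atoms counted as 'Other groups'", n
        )
    return RingSystemClass(kind, atoms, tuple(rings), fusion, tuple(positions))


def parse_molecule(smiles: str) -> MoleculeGraph:
    """Parse a SMILES into a MoleculeGraph with ring systems enumerated.

    The molecule is re-parsed from its canonical SMILES so that atom order,
    kekulization and every downstream descriptor are independent of the
    input spelling.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)

    ring_info = mol.GetRingInfo().AtomRings()
    pi_rings = [tuple(r) for r in ring_info if _is_pi_ring(mol, tuple(r))]
    systems = []
    for comp in _fused_components(pi_rings):
        rings = [pi_rings[i] for i in sorted(comp)]
        systems.append(_classify_system(mol, rings))
    systems.sort(key=lambda s: min(s.atoms))
    return MoleculeGraph(mol, canonical, tuple(systems))


def classify_ring_systems(g: MoleculeGraph) -> list[RingSystemClass]:
    """Ring systems classified by fused-ring count with position labels."""
    return list(g.ring_systems)


# ---------------------------------------------------------------------------
# Group counting

_HALOGEN_KEY = {9: "-F", 17: "-Cl", 35: "-Br", 53: "-I"}


def _is_ph_attached(mol: Chem.Mol, idx: int, pi_atoms: frozenset[int]) -> bool:
    atom = mol.GetAtomWithIdx(idx)
    return any(
        nb.GetAtomicNum() == 6 and nb.GetIdx() in pi_atoms for nb in atom.GetNeighbors()
    )


def _ph(key: str, mol: Chem.Mol, idx: int, pi_atoms: frozenset[int]) -> str:
    return key + "(ph)" if _is_ph_attached(mol, idx, pi_atoms) else key


def count_groups(g: MoleculeGraph) -> GroupVector:
    """Attribute every heavy atom to one vocabulary group (or Other groups)
    and count linkage/position descriptors.

    Conventions fixed by the worked input-vector example:

    * ring-fusion atoms are carried by the fused-system descriptors (N2/N3)
      and are not counted as >C=;
    * bridging >C=C<(1)/(2) on a ring double bond is a linkage count only
      (the carbons keep their ring groups); on a chain double bond it
      consumes both carbons;
    * a group takes its "(ph)" variant iff its anchor atom bonds an
      aromatic carbon.
    """
    mol = g.mol
    counts = np.zeros(N_GROUP, dtype=int)
    attribution: dict[int, str] = {}
    pi_atoms = frozenset(a for s in g.ring_systems for a in s.atoms)
    supported_pi = frozenset(
        a for s in g.ring_systems if s.kind != "unsupported" for a in s.atoms
    )

    def bump(key: str, n: int = 1) -> None:
        counts[_GROUP_INDEX[key]] += n

    def attribute(idx: int, key: str, *, count: bool = True) -> None:
        if idx in attribution:
            raise AssertionError(f"atom {idx} attributed twice ({attribution[idx]} / {key})")
        attribution[idx] = key
        if count and key not in (OTHER_KEY, FUSION_TAG):
            bump(key)
        elif key == OTHER_KEY:
            bump(OTHER_KEY)

    # --- position and linkage descriptors from ring systems
    for system in g.ring_systems:
        if system.kind == "isolated":
            for pos in system.substituent_positions:
                bump(f"N1({pos}-)")
        elif system.kind == "two_fused":
            for pos in system.substituent_positions:
                bump(f"N2({pos})")
        elif system.kind == "three_fused":
            for pos in system.substituent_positions:
                bump(f"N3({pos})")

    # Ar-Ar: bonds joining two different pi ring systems; Ar-R: bonds from a
    # supported pi system to an sp3 carbon.
    atom_system = {a: i for i, s in enumerate(g.ring_systems) for a in s.atoms}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        si, sj = atom_system.get(i), atom_system.get(j)
        if si is not None and sj is not None and si != sj:
            bump("Ar-Ar")
        elif (si is None) != (sj is None):
            ring_side, chain_side = (i, j) if si is not None else (j, i)
            if ring_side in supported_pi:
                chain_atom = mol.GetAtomWithIdx(chain_side)
                if (
                    chain_atom.GetAtomicNum() == 6
                    and chain_atom.GetHybridization() == Chem.HybridizationType.SP3
                ):
                    bump("Ar-R")

    # --- bridging C=C descriptors (localized olefinic double bonds)
    chain_cc_consumed: set[int] = set()
    for i, j in _bridge_cc_bonds(mol):
        a1, a2 = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)

        def aromatic_contact(atom: Chem.Atom, partner: Chem.Atom) -> bool:
            return any(
                nb.GetIdx() != partner.GetIdx() and nb.GetIsAromatic() and nb.GetAtomicNum() == 6
                for nb in atom.GetNeighbors()
            )

        c1 = aromatic_contact(a1, a2)
        c2 = aromatic_contact(a2, a1)
        if c1 and c2:
            bump(">C=C<(1)")
        elif c1 or c2:
            bump(">C=C<(2)")
        else:
            continue
        for atom in (a1, a2):
            if not atom.IsInRing():
                chain_cc_consumed.add(atom.GetIdx())

    for idx in chain_cc_consumed:
        # chain carbons of a bridging C=C are consumed by the linkage group
        attribution[idx] = ">C=C<(chain)"

    # --- ring-system atoms
    for system in g.ring_systems:
        if system.kind == "unsupported":
            for idx in sorted(system.atoms):
                attribute(idx, OTHER_KEY)
            continue
        for idx in sorted(system.atoms):
            if idx in system.fusion_atoms:
                attribute(idx, FUSION_TAG)
                continue
            _attribute_ring_atom(mol, idx, attribute, attribution)

    # --- non-pi ring atoms (aliphatic rings)
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in attribution or not atom.IsInRing():
            continue
        _attribute_ring_atom(mol, idx, attribute, attribution)

    # --- chain functional groups, composite first
    _attribute_chain_atoms(mol, attribute, attribution, pi_atoms)

    # --- leftovers
    for atom in mol.GetAtoms():
        if atom.GetIdx() not in attribution:
            attribute(atom.GetIdx(), OTHER_KEY)

    return GroupVector(counts, attribution)


def _double_bonded_neighbors(atom: Chem.Atom, z: int) -> list[Chem.Atom]:
    return [
        b.GetOtherAtom(atom)
        for b in atom.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(atom).GetAtomicNum() == z
    ]


def _attribute_ring_atom(mol, idx, attribute, attribution) -> None:
    """Attribute one ring atom to a ring-column group."""
    atom = mol.GetAtomWithIdx(idx)
    z = atom.GetAtomicNum()
    nh = atom.GetTotalNumHs()
    if z == 6:
        ket_o = [
            o
            for o in _double_bonded_neighbors(atom, 8)
            if not o.IsInRing() and o.GetIdx() not in attribution
        ]
        if ket_o:
            # ring ester (lactone) in a saturated ring collapses to -COO-(Ring)
            if not atom.GetIsAromatic() and not _in_pi_context(atom):
                ring_o = [
                    nb
                    for nb in atom.GetNeighbors()
                    if nb.GetAtomicNum() == 8 and nb.IsInRing() and nb.GetIdx() not in attribution
                ]
                if ring_o:
                    attribute(idx, "-COO-(Ring)")
                    attribution[ket_o[0].GetIdx()] = "-COO-(Ring)"
                    attribution[ring_o[0].GetIdx()] = "-COO-(Ring)"
                    return
            attribute(idx, ">C=O(Ring)")
            attribution[ket_o[0].GetIdx()] = ">C=O(Ring)"
            return
        sp2 = atom.GetIsAromatic() or any(
            b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()
        )
        if sp2:
            attribute(idx, "-CH=(Ring)" if nh >= 1 else ">C=(Ring)")
        else:
            if nh >= 2:
                attribute(idx, "-CH2-(Ring)")
            elif nh == 1:
                attribute(idx, "-HC<(Ring)")
            else:
                attribute(idx, ">C<(Ring)")
    elif z == 7:
        if atom.GetFormalCharge() > 0:
            attribute(idx, ">N+=(Ring)")
        elif nh >= 1:
            attribute(idx, "-NH-(Ring)")
        elif atom.GetIsAromatic() and atom.GetDegree() == 2:
            attribute(idx, "-N=(Ring)")
        elif any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
            attribute(idx, "-N=(Ring)")
        else:
            attribute(idx, "-N<(Ring)")
    elif z == 8:
        attribute(idx, "-O-(Ring)")
    elif z == 16:
        attribute(idx, "-S-(Ring)")
    else:
        attribute(idx, OTHER_KEY)


def _in_pi_context(atom: Chem.Atom) -> bool:
    """True when the atom sits in a ring that carries any double/aromatic bond."""
    mol = atom.GetOwningMol()
    for ring in mol.GetRingInfo().AtomRings():
        if atom.GetIdx() not in ring:
            continue
        for i, a in enumerate(ring):
            b = mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % len(ring)])
            if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def _attribute_chain_atoms(mol, attribute, attribution, pi_atoms) -> None:
    """Attribute non-ring atoms: composite groups first, then single-atom ones."""

    # nitro
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetIdx() in attribution or atom.IsInRing():
            continue
        oxy = [
            nb
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 8 and nb.GetDegree() == 1 and nb.GetIdx() not in attribution
        ]
        if len(oxy) == 2:
            attribute(atom.GetIdx(), "-NO2")
            for o in oxy:
                attribution[o.GetIdx()] = "-NO2"

    # sulfonyl / sulfonamide
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 16 or atom.GetIdx() in attribution or atom.IsInRing():
            continue
        oxy = [
            o for o in _double_bonded_neighbors(atom, 8) if o.GetIdx() not in attribution
        ]
        if len(oxy) >= 2:
            has_n = any(nb.GetAtomicNum() == 7 for nb in atom.GetNeighbors())
            attribute(atom.GetIdx(), "-SO2(-N<)" if has_n else "-SO2")
            for o in oxy[:2]:
                attribution[o.GetIdx()] = attribution[atom.GetIdx()]

    # carbon-centred composites: acid, ester, amide, nitrile, carbonyl
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIdx() in attribution or atom.IsInRing():
            continue
        idx = atom.GetIdx()
        ket_o = [
            o
            for o in _double_bonded_neighbors(atom, 8)
            if o.GetDegree() == 1 and o.GetIdx() not in attribution
        ]
        single_o = [
            nb
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 8
            and nb.GetIdx() not in attribution
            and mol.GetBondBetweenAtoms(idx, nb.GetIdx()).GetBondType() == Chem.BondType.SINGLE
        ]
        amide_n = [
            nb
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 7 and nb.GetIdx() not in attribution and not nb.IsInRing()
        ]
        if ket_o:
            acid_o = [o for o in single_o if o.GetTotalNumHs() >= 1 and o.GetDegree() == 1]
            ester_o = [o for o in single_o if o.GetDegree() == 2]
            if acid_o:
                attribute(idx, "-COOH")
                attribution[ket_o[0].GetIdx()] = "-COOH"
                attribution[acid_o[0].GetIdx()] = "-COOH"
            elif ester_o:
                o = ester_o[0]
                key = "-OCO-(ph)" if _is_ph_attached(mol, o.GetIdx(), pi_atoms) else "-COO-"
                attribute(idx, key)
                attribution[ket_o[0].GetIdx()] = key
                attribution[o.GetIdx()] = key
            elif amide_n:
                key = _ph("-C=O(-N<)", mol, idx, pi_atoms)
                attribute(idx, key)
                attribution[ket_o[0].GetIdx()] = key
                n = amide_n[0]
                nkey = _ph("-N<(C=O)", mol, n.GetIdx(), pi_atoms)
                attribute(n.GetIdx(), nkey)
            else:
                attribute(idx, "-C=O")
                attribution[ket_o[0].GetIdx()] = "-C=O"
            continue
        triple_n = [
            b.GetOtherAtom(atom)
            for b in atom.GetBonds()
            if b.GetBondType() == Chem.BondType.TRIPLE
            and b.GetOtherAtom(atom).GetAtomicNum() == 7
        ]
        if triple_n and triple_n[0].GetIdx() not in attribution:
            attribute(idx, "-C#N")
            attribution[triple_n[0].GetIdx()] = "-C#N"

    # amide N adjacent to a ring carbonyl (imide-type N outside the ring)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetIdx() in attribution or atom.IsInRing():
            continue
        acyl = [
            nb
            for nb in atom.GetNeighbors()
            if nb.GetAtomicNum() == 6 and attribution.get(nb.GetIdx()) == ">C=O(Ring)"
        ]
        if acyl:
            attribute(atom.GetIdx(), _ph("-N<(C=O)", mol, atom.GetIdx(), pi_atoms))

    # single-atom groups
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in attribution or atom.IsInRing():
            continue
        z = atom.GetAtomicNum()
        nh = atom.GetTotalNumHs()
        if z in _HALOGEN_KEY:
            attribute(idx, _ph(_HALOGEN_KEY[z], mol, idx, pi_atoms))
        elif z == 8:
            if nh >= 1 and atom.GetDegree() == 1:
                attribute(idx, _ph("-OH", mol, idx, pi_atoms))
            elif atom.GetDegree() == 2:
                attribute(idx, _ph("-O-", mol, idx, pi_atoms))
            else:
                attribute(idx, OTHER_KEY)
        elif z == 7:
            if atom.GetFormalCharge() != 0:
                attribute(idx, OTHER_KEY)
            elif nh >= 2 and atom.GetDegree() == 1:
                attribute(idx, _ph("-NH2", mol, idx, pi_atoms))
            elif nh == 0 and atom.GetDegree() == 3:
                attribute(idx, _ph("-N<", mol, idx, pi_atoms))
            else:
                attribute(idx, OTHER_KEY)  # secondary -NH- has no chain slot
        elif z == 16:
            if nh == 0 and atom.GetDegree() == 2:
                attribute(idx, _ph("-S-", mol, idx, pi_atoms))
            else:
                attribute(idx, OTHER_KEY)
        elif z == 6:
            if nh == 3 and atom.GetDegree() == 1:
                attribute(idx, "-CH3")
            elif atom.GetDegree() == 4:
                attribute(idx, ">C<")
            else:
                attribute(idx, OTHER_KEY)  # chain CH2 / CH / sp2 C have no slot
        else:
            attribute(idx, OTHER_KEY)


def _bridge_cc_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Localized olefinic C=C bonds eligible for the bridging >C=C< descriptors.

    Eligible are explicit (non-aromatic) carbon-carbon double bonds, plus
    kekule C=C bonds of aromatic-perceived rings that carry an exocyclic
    carbonyl (pyranone-type rings, which the aromaticity model may flag
    aromatic but which behave as localized polyene systems).  Bonds touching
    a plain aromatic ring (benzene-like, no ring carbonyl) never qualify.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    rings = mol.GetRingInfo().AtomRings()

    def ring_is_aromatic(ring: tuple[int, ...]) -> bool:
        return all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)

    def ring_has_carbonyl(ring: tuple[int, ...]) -> bool:
        for a in ring:
            atom = mol.GetAtomWithIdx(a)
            for b in atom.GetBonds():
                nbr = b.GetOtherAtom(atom)
                if (
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and nbr.GetIdx() not in ring
                    and nbr.GetAtomicNum() in (7, 8, 16)
                ):
                    return True
        return False

    plain_aromatic_atoms = set()
    carbonyl_aromatic_rings = []
    for ring in rings:
        if not ring_is_aromatic(ring):
            continue
        if ring_has_carbonyl(ring):
            carbonyl_aromatic_rings.append(set(ring))
        else:
            plain_aromatic_atoms.update(ring)

    out = []
    for bond in kek.GetBonds():
        if bond.GetBondType() != Chem.BondType.DOUBLE:
            continue
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a1.GetAtomicNum() != 6 or a2.GetAtomicNum() != 6:
            continue
        i, j = a1.GetIdx(), a2.GetIdx()
        if not mol.GetBondBetweenAtoms(i, j).GetIsAromatic():
            out.append((i, j))
        elif (
            i not in plain_aromatic_atoms
            and j not in plain_aromatic_atoms
            and any(i in r and j in r for r in carbonyl_aromatic_rings)
        ):
            out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# Conjugation descriptors


def conjugation_descriptors(g: MoleculeGraph) -> ConjugationDescriptors:
    """Count conjugated double bonds: A in total, B in the largest system.

    The canonical kekulized structure is traversed for maximal alternating
    multiple/single systems; two multiple bonds are conjugated when a single
    bond joins an endpoint of one to an endpoint of the other (cumulated
    double bonds sharing an atom are not).  Systems of at least two multiple
    bonds count toward A.
    """
    mol = Chem.Mol(g.mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    multiple = [
        b
        for b in mol.GetBonds()
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
    ]
    if not multiple:
        return ConjugationDescriptors(0, 0)
    bond_of_atom: dict[int, list[int]] = {}
    for k, b in enumerate(multiple):
        bond_of_atom.setdefault(b.GetBeginAtomIdx(), []).append(k)
        bond_of_atom.setdefault(b.GetEndAtomIdx(), []).append(k)
    parent = list(range(len(multiple)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE:
            continue
        for ki in bond_of_atom.get(b.GetBeginAtomIdx(), []):
            for kj in bond_of_atom.get(b.GetEndAtomIdx(), []):
                if ki != kj:
                    parent[find(ki)] = find(kj)
    sizes: dict[int, int] = {}
    for k in range(len(multiple)):
        r = find(k)
        sizes[r] = sizes.get(r, 0) + 1
    conj = [s for s in sizes.values() if s >= 2]
    A = sum(conj)
    B = max(conj, default=0)
    return ConjugationDescriptors(A, B)


# ---------------------------------------------------------------------------
# Electronic block and assembly


def electronic_descriptors(g: MoleculeGraph) -> np.ndarray:
    """The frozen 90-entry E-state / MOE-VSA / topological / connectivity block."""
    vals = np.array([fn(g.mol) for fn in _ELECTRONIC_FNS], dtype=float)
    return np.nan_to_num(vals, nan=0.0, posinf=0.0, neginf=0.0)


def assemble_descriptor_vector(
    gv: GroupVector,
    cd: ConjugationDescriptors,
    el: np.ndarray,
    solvent_polarity: float,
) -> DescriptorVector:
    """Concatenate [groups | A, B | electronic | solvent] into the 151-vector."""
    el = np.asarray(el, dtype=float)
    if el.shape != (N_ELECTRONIC,):
        raise ValueError(
            f"electronic block must have length {N_ELECTRONIC}, got {el.shape}"
        )
    values = np.concatenate(
        [gv.as_array(), [float(cd.A), float(cd.B)], el, [float(solvent_polarity)]]
    )
    return DescriptorVector(values, dict(BLOCK_OFFSETS))


def featurize(smiles: str, solvent_polarity: float = 0.0) -> DescriptorVector:
    """SMILES + solvent polarity -> the 151-dimensional descriptor vector."""
    g = parse_molecule(smiles)
    return assemble_descriptor_vector(
        count_groups(g),
        conjugation_descriptors(g),
        electronic_descriptors(g),
        solvent_polarity,
    )


# ---------------------------------------------------------------------------
# Solvent polarity lookup

_SOLVENT_CSV = Path(__file__).parent / "data" / "solvent_polarity.csv"


def solvent_polarity_table(path: str | Path | None = None) -> pd.DataFrame:
    """The shipped solvent -> normalized polarity lookup (editable CSV)."""
    return pd.read_csv(path or _SOLVENT_CSV)


def lookup_solvent_polarity(solvent: str | float, table: pd.DataFrame | None = None) -> float:
    """Resolve a solvent name (or pass through a numeric value) to polarity."""
    try:
        return float(solvent)
    except (TypeError, ValueError):
        pass
    table = table if table is not None else solvent_polarity_table()
    names = table.iloc[:, 0].astype(str).str.lower()
    hit = table[names == str(solvent).strip().lower()]
    if hit.empty:
        raise KeyError(f"unknown solvent {solvent!r}; add it to the polarity table")
    return float(hit.iloc[0, 1])


def featurize_table(
    df: pd.DataFrame, solvent_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Featurize a DataFrame with columns id, smiles, solvent into a matrix.

    Returns a DataFrame indexed by id whose 151 columns are the descriptor
    slots in canonical order.
    """
    rows = []
    ids = []
    for _, rec in df.iterrows():
        pol = lookup_solvent_polarity(rec["solvent"], solvent_table)
        rows.append(featurize(str(rec["smiles"]), pol).values)
        ids.append(rec["id"])
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=descriptor_names())
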