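"""Reference chemical spaces: loading, canonicalization and toy enumeration.

A *reference space* is a finite set of molecules, stored as canonical SMILES,
that a generative model is benchmarked against (the motivating example is
GDB-13, the exhaustive enumeration of drug-like molecules up to 13 heavy
atoms).  Membership is always decided by comparing RDKit canonical SMILES —
one toolkit, one canonical dialect.

Because the real database is ~10^9 molecules, this module also ships a *toy
enumerator* that exhaustively generates a miniature analogue (a few hundred
to a few thousand molecules over {C, N, O} with GDB-style filters), so the
full benchmark pipeline can run offline on one CPU.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger


RDLogger.DisableLog("rdApp.*")  # parse failures are data, not log spam

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSpace",
    "EnumerationFilters",
    "default_filters",
    "canonicalize",
    "load_space",
    "save_space",
    "carbon_skeleton",
    "enumerate_toy_space",
    "check_filters",
    "heavy_atom_count",
]

#: Exhaustive enumeration refuses to run above this many heavy atoms.
MAX_ENUMERABLE_ATOMS = 7

_VALENCE = {"C": 4, "N": 3, "O": 2}


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES of ``smiles``, or ``None`` if it does not parse.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    Unparseable input yields ``None`` rather than raising, so corrupt lines
    never abort batch processing.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


@dataclass(frozen=True)
class ReferenceSpace:
    """An indexed finite chemical space of canonical SMILES.

    ``skeletons`` holds the canonical carbon skeletons (every heavy atom
    replaced by carbon, every bond single) of all members; it is used to test
    whether an outside molecule's graph topology exists in the space.
    """

    molecules: frozenset[str]
    skeletons: frozenset[str] = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return len(self.molecules)

    @property
    def p(self) -> float:
        """Uniform per-molecule probability 1/n."""
        return 1.0 / self.n

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.molecules

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.molecules))

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_smiles(
        cls, smiles: Iterable[str], *, compute_skeletons: bool = True
    ) -> "ReferenceSpace":
        """Canonicalize, drop failures, dedupe, and derive skeletons."""
        canon = {c for s in smiles if (c := canonicalize(s)) is not None}
        if not canon:
            raise ValueError("no valid molecules given")
        skel = (
            frozenset(carbon_skeleton(s) for s in canon)
            if compute_skeletons
            else frozenset()
        )
        return cls(molecules=frozenset(canon), skeletons=skel)


def load_space(path: str | Path) -> tuple[ReferenceSpace, dict]:
    """Read a one-SMILES-per-line file into a :class:`ReferenceSpace`.

    Returns the space plus a stats dict ``{n, parse_failures,
    duplicates_removed}`` (written as a JSON sidecar by the CLI).  Raises if
    the file is empty or more than half the lines fail to parse (almost
    certainly the wrong file).
    """
    path = Path(path)
    lines = [
        ln.split("\t")[0].strip()
        for ln in path.read_text().splitlines()
        if ln.strip()
    ]
    if not lines:
        raise ValueError(f"{path}: empty SMILES file")
    canon: set[str] = set()
    failures = 0
    total = 0
    for s in lines:
        total += 1
        c = canonicalize(s)
        if c is None:
            failures += 1
        else:
            canon.add(c)
    if failures > total / 2:
        raise ValueError(
            f"{path}: {failures}/{total} lines failed to parse — wrong file?"
        )
    if not canon:
        raise ValueError(f"{path}: no valid molecules")
    if failures:
        logger.warning("%s: %d/%d lines failed to parse", path, failures, total)
    space = ReferenceSpace.from_smiles(canon)
    stats = {
        "n": space.n,
        "parse_failures": failures,
        "duplicates_removed": total - failures - space.n,
    }
    return space, stats


def save_space(space: ReferenceSpace, path: str | Path, stats: dict | None = None) -> None:
    """Write the space sorted, one SMILES per line, with a JSON sidecar."""
    path = Path(path)
    path.write_text("\n".join(sorted(space.molecules)) + "\n")
    sidecar = {"n": space.n}
    if stats:
        sidecar.update(stats)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def carbon_skeleton(smiles: str) -> str:
    """Canonical SMILES of the molecule's carbon skeleton.

    Every heavy atom becomes a neutral carbon and every bond becomes single;
    the result depends only on the molecular graph, so substituting one
    heteroatom for another leaves it unchanged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        atom.SetIsAromatic(False)
        atom.SetNumRadicalElectrons(0)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


@dataclass(frozen=True)
class EnumerationFilters:
    """The constraint set that defines a (toy) enumerated space.

    Patterns are SMARTS strings keyed by a unique human-readable label; the
    labels reappear verbatim when out-of-space molecules are annotated with
    the constraints they break.  All predicates are pure: the same molecule
    always gets the same verdict.
    """

    max_heavy_atoms: int = 5
    allowed_elements: frozenset[str] = frozenset({"C", "N", "O"})
    #: heteroatoms-per-carbon ceiling (the GDB enumerations cap this ratio);
    #: None disables the rule; a carbon-free molecule has infinite ratio
    max_heteroatom_ratio: float | None = 1.0
    disallowed_group_patterns: dict[str, str] = field(
        default_factory=lambda: {
            "peroxide": "[OX2][OX2]",
            "allene": "[CX2](=*)=*",
        }
    )
    disallowed_heteroatom_neighbor_patterns: dict[str, str] = field(
        default_factory=lambda: {"n_n_single": "[NX3]-[NX3]"}
    )
    #: bond-placement rules, e.g. no triple bond inside a (small) ring
    bond_rules: dict[str, str] = field(default_factory=lambda: {"ring_triple_bond": "[R]#[R]"})
    allowed_skeletons: frozenset[str] | None = None

    def __post_init__(self) -> None:
        labels = (
            list(self.disallowed_group_patterns)
            + list(self.disallowed_heteroatom_neighbor_patterns)
            + list(self.bond_rules)
        )
        if len(labels) != len(set(labels)):
            raise ValueError("filter pattern labels must be unique")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnumerationFilters":
        cfg = json.loads(Path(path).read_text())
        kwargs: dict = {}
        for key in (
            "max_heavy_atoms",
            "max_heteroatom_ratio",
            "disallowed_group_patterns",
            "disallowed_heteroatom_neighbor_patterns",
            "bond_rules",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "allowed_elements" in cfg:
            kwargs["allowed_elements"] = frozenset(cfg["allowed_elements"])
        if cfg.get("allowed_skeletons") is not None:
            kwargs["allowed_skeletons"] = frozenset(cfg["allowed_skeletons"])
        return cls(**kwargs)


def default_filters(max_heavy_atoms: int = 5) -> EnumerationFilters:
    """The documented default GDB-style filter set at toy scale.

    The real GDB-13 functional-group list is much larger; this small set
    (peroxides, allenes, N–N single bonds, in-ring triple bonds, a 1:1
    heteroatom/carbon cap) is illustrative, not authoritative.
    """
    return EnumerationFilters(max_heavy_atoms=max_heavy_atoms)


def _compiled(patterns: dict[str, str]) -> list[tuple[str, Chem.Mol]]:
    out = []
    for label, smarts in patterns.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad SMARTS for {label!r}: {smarts!r}")
        out.append((label, patt))
    return out


def check_filters(
    smiles: str,
    filters: EnumerationFilters,
    space: ReferenceSpace | None = None,
) -> list[str]:
    """Labels of every enumeration constraint that ``smiles`` violates.

    A member of an enumerated space checked against that space's own filters
    returns the empty list.  Order of labels is deterministic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    labels: list[str] = []
    if mol.GetNumHeavyAtoms() > filters.max_heavy_atoms:
        labels.append("heavy_atom_count")
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if not symbols <= filters.allowed_elements:
        labels.append("element_set")
    if filters.max_heteroatom_ratio is not None:
        n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
        n_hetero = mol.GetNumHeavyAtoms() - n_carbon
        ratio = n_hetero / n_carbon if n_carbon else float("inf")
        if ratio > filters.max_heteroatom_ratio:
            labels.append("heteroatom_ratio")
    for label, patt in _compiled(filters.disallowed_group_patterns):
        if mol.HasSubstructMatch(patt):
            labels.append(f"functional_group:{label}")
    for label, patt in _compiled(filters.disallowed_heteroatom_neighbor_patterns):
        if mol.HasSubstructMatch(patt):
            labels.append("heteroatom_neighbors")
            break
    for label, patt in _compiled(filters.bond_rules):
        if mol.HasSubstructMatch(patt):
            labels.append("bond_rule")
            break
    skeletons = filters.allowed_skeletons
    if skeletons is None and space is not None:
        skeletons = space.skeletons
    if skeletons is not None and carbon_skeleton(smiles) not in skeletons:
        labels.append("graph_topology")
    return labels


def _grow_candidates(smiles: str, elements: list[str], max_atoms: int, max_rings: int) -> Iterator[str]:
    """All one-step extensions of a molecule: attach an atom or close a ring."""
    mol = Chem.MolFromSmiles(smiles)
    n_atoms = mol.GetNumHeavyAtoms()
    ring_count = mol.GetRingInfo().NumRings()
    free_h = [a.GetTotalNumHs() for a in mol.GetAtoms()]
    # (a) attach a new atom by a bond of order 1..3
    if n_atoms < max_atoms:
        for i in range(n_atoms):
            for elem in elements:
                for order in (1, 2, 3):
                    if free_h[i] < order or _VALENCE[elem] < order:
                        continue
                    rw = Chem.RWMol(mol)
                    j = rw.AddAtom(Chem.Atom(elem))
                    rw.AddBond(i, j, Chem.BondType.values[order])
                    yield from _finish(rw)
    # (b) close one ring with a bond of order 1..3 between existing atoms
    if ring_count < max_rings and n_atoms >= 3:
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if mol.GetBondBetweenAtoms(i, j) is not None:
                    continue
                for order in (1, 2, 3):
                    if free_h[i] < order or free_h[j] < order:
                        continue
                    rw = Chem.RWMol(mol)
                    rw.AddBond(i, j, Chem.BondType.values[order])
                    yield from _finish(rw)


def _finish(rw: Chem.RWMol) -> Iterator[str]:
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError):
        return
    yield Chem.MolToSmiles(out)


def estimate_enumeration_count(max_heavy_atoms: int, n_elements: int) -> int:
    """Loose upper-bound estimate of raw structures, for the guard message."""
    # labeled trees (Cayley) x element choices x up to 3 bond orders per edge
    total = 0
    for a in range(1, max_heavy_atoms + 1):
        trees = max(1, a ** max(0, a - 2))
        total += trees * (n_elements ** a) * (3 ** max(0, a - 1))
    return total


def enumerate_toy_space(
    filters: EnumerationFilters | None = None,
    *,
    max_rings: int = 1,
) -> ReferenceSpace:
    """Exhaustively enumerate a miniature reference space under ``filters``.

    Connected molecular graphs over the allowed elements are grown atom by
    atom (bond orders 1–3, at most ``max_rings`` ring closures), with
    canonical-SMILES dedup at every step; the filter set is then applied and
    survivors form the space.  Deterministic: two runs with the same filters
    yield identical spaces.  Refuses ``max_heavy_atoms`` above
    ``MAX_ENUMERABLE_ATOMS`` since the structure count explodes.
    """
    if filters is None:
        filters = default_filters()
    if filters.max_heavy_atoms > MAX_ENUMERABLE_ATOMS:
        est = estimate_enumeration_count(
            filters.max_heavy_atoms, len(filters.allowed_elements)
        )
        raise ValueError(
            f"refusing exhaustive enumeration above {MAX_ENUMERABLE_ATOMS} heavy "
            f"atoms (requested {filters.max_heavy_atoms}; roughly {est:.1e} raw "
            "structures)"
        )
    elements = sorted(filters.allowed_elements & set(_VALENCE))
    if not elements:
        raise ValueError("no enumerable elements (supported: C, N, O)")
    seen: set[str] = set()
    frontier = []
    for elem in elements:
        c = canonicalize(elem)
        if c is not None:
            seen.add(c)
            frontier.append(c)
    while frontier:
        nxt = set()
        for smi in frontier:
            for cand in _grow_candidates(
                smi, elements, filters.max_heavy_atoms, max_rings
            ):
                if cand not in seen:
                    seen.add(cand)
                    nxt.add(cand)
        frontier = sorted(nxt)
    members = sorted(
        s for s in seen if not check_filters(s, filters, space=None)
    )
    if not members:
        raise ValueError("filters rejected every enumerated structure")
    return ReferenceSpace.from_smiles(members)
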