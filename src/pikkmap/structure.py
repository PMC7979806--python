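"""Structure models: PDB reading, position mapping, distances, clusters, domains.

Cryo-EM models of the giant PIKK enzyme complexes routinely lack density for
disordered stretches, so residues present in the protein sequence can be
absent from the coordinate model.  The model therefore tracks unresolved
author-numbering gaps explicitly, and position mapping reports them rather
than silently dropping the residue.

Reading rules: first MODEL only; HETATM records, waters and hydrogens are
dropped; for alternate locations the highest-occupancy conformer is kept
(ties broken toward altloc 'A').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "DomainMap",
    "PDBFormatError",
    "read_pdb",
    "map_position",
    "residue_distance",
    "cluster_residues",
    "annotate_domain",
    "read_domain_map",
    "default_domain_map",
]


class PDBFormatError(ValueError):
    """Raised for malformed or empty PDB coordinate files."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Chains, ordered residues and atoms with Angstrom coordinates."""

    chains: list[str]
    residues: dict[str, list[Residue]]  # chain id -> ordered residues
    unresolved: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, str], Residue] = {}
        for chain, residues in self.residues.items():
            for r in residues:
                key = (chain, r.number, r.icode)
                if key in self._index:
                    raise ValueError(f"duplicate residue {key}")
                self._index[key] = r
                for a in r.atoms:
                    if not np.isfinite([a.x, a.y, a.z]).all():
                        raise ValueError(f"non-finite coordinate in residue {key}")

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        return self._index[(chain, number, icode)]

    def all_residues(self) -> list[Residue]:
        return [r for chain in self.chains for r in self.residues[chain]]

    def all_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.all_residues() for a in r.atoms]

    def chain_span(self, chain: str) -> tuple[int, int]:
        numbers = [r.number for r in self.residues[chain]]
        return min(numbers), max(numbers)

    def is_unresolved(self, chain: str, number: int) -> bool:
        return any(lo <= number <= hi for lo, hi in self.unresolved.get(chain, []))


def _prescan_pdb(path: Path) -> None:
    """Validate coordinate fields so malformed lines error with a line number."""
    saw_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            saw_atom = saw_atom or line.startswith("ATOM")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                raise PDBFormatError(
                    f"{path}: malformed coordinate field at line {lineno}"
                ) from None
    if not saw_atom:
        raise PDBFormatError(f"{path}: no ATOM records")


def read_pdb(path: str | Path) -> StructureModel:
    """Read a fixed-column PDB coordinate file into a :class:`StructureModel`.

    Unresolved stretches are inferred from gaps in author numbering within
    each chain.
    """
    path = Path(path)
    _prescan_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_waters()
    st.remove_hydrogens()
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no models")
    model = st[0]  # first MODEL only

    chains: list[str] = []
    residues: dict[str, list[Residue]] = {}
    for chain in model:
        res_list: list[Residue] = []
        for res in chain:
            if res.het_flag == "H":
                continue  # HETATM (ligands, ions) dropped
            # altloc: keep the highest-occupancy conformer per atom name,
            # ties broken toward altloc 'A' (then lexicographically).
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                else:
                    cand = (-atom.occ, atom.altloc or "A")
                    best = (-prev.occ, prev.altloc or "A")
                    if cand < best:
                        by_name[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    x=a.pos.x,
                    y=a.pos.y,
                    z=a.pos.z,
                    occupancy=a.occ,
                )
                for a in by_name.values()
            ]
            if atoms:
                res_list.append(
                    Residue(
                        chain=chain.name,
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=atoms,
                    )
                )
        if res_list:
            chains.append(chain.name)
            residues[chain.name] = res_list

    if not chains:
        raise PDBFormatError(f"{path}: no polymer residues after filtering")

    unresolved: dict[str, list[tuple[int, int]]] = {}
    for chain in chains:
        gaps = []
        numbers = [r.number for r in residues[chain]]
        for a, b in zip(numbers, numbers[1:]):
            if b > a + 1:
                gaps.append((a + 1, b - 1))
        unresolved[chain] = gaps
    return StructureModel(chains=chains, residues=residues, unresolved=unresolved)


def map_position(
    model: StructureModel, chain: str, seq_pos: int, offset: int = 0
) -> Optional[Residue]:
    """Map a 1-based protein position onto a structure residue.

    ``offset`` converts protein numbering to author numbering
    (``author = seq_pos + offset``).  Returns the residue, or ``None`` when
    the position falls in an unresolved (disordered) gap.  Positions outside
    the chain span raise ``IndexError``.
    """
    if chain not in model.residues:
        raise KeyError(f"unknown chain {chain!r}")
    author = seq_pos + offset
    lo, hi = model.chain_span(chain)
    if not (lo <= author <= hi):
        raise IndexError(
            f"position {seq_pos} (author {author}) outside chain {chain} span {lo}..{hi}"
        )
    try:
        return model.residue(chain, author)
    except KeyError:
        if model.is_unresolved(chain, author):
            return None
        raise IndexError(f"author number {author} absent from chain {chain}")


def _heavy_coords(res: Residue) -> np.ndarray:
    coords = [a.coord for a in res.atoms if a.element != "H"]
    if not coords:
        raise ValueError(f"residue {res.key} has no heavy atoms")
    return np.array(coords)


def residue_distance(
    model: StructureModel,
    res_a: tuple[str, int] | Residue,
    res_b: tuple[str, int] | Residue,
    mode: str = "ca",
) -> float:
    """Euclidean distance between two resolved residues in Angstrom.

    ``mode="ca"`` measures between C-alpha atoms; ``mode="min_heavy"``
    takes the minimum over all heavy-atom pairs.
    """
    def _resolve(r):
        if isinstance(r, Residue):
            return r
        chain, num = r
        if model.is_unresolved(chain, num):
            raise ValueError(f"residue {r} is unresolved in the model")
        try:
            return model.residue(chain, num)
        except KeyError:
            raise ValueError(f"residue {r} is not in the model") from None

    ra, rb = _resolve(res_a), _resolve(res_b)
    if mode == "ca":
        ca_a, ca_b = ra.atom("CA"), rb.atom("CA")
        if ca_a is None or ca_b is None:
            raise ValueError("C-alpha atom missing; use mode='min_heavy'")
        return float(np.linalg.norm(ca_a.coord - ca_b.coord))
    if mode == "min_heavy":
        A, B = _heavy_coords(ra), _heavy_coords(rb)
        diff = A[:, None, :] - B[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())
    raise ValueError("mode must be 'ca' or 'min_heavy'")


def cluster_residues(
    model: StructureModel,
    residues: Sequence[tuple[str, int]],
    cutoff: float,
    mode: str = "ca",
) -> list[list[tuple[str, int]]]:
    """Single-linkage spatial clusters of residues.

    Clusters are the connected components of the graph joining residue pairs
    whose distance is at most ``cutoff`` Angstrom.  Returned in order of
    first appearance; members sorted.
    """
    residues = list(residues)
    if not residues:
        return []
    n = len(residues)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if residue_distance(model, residues[i], residues[j], mode) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[tuple[str, int]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(residues[i])
    return [sorted(groups[root]) for root in sorted(groups)]


@dataclass
class DomainMap:
    """Named 1-based inclusive intervals over a protein sequence.

    Top-level domains must not overlap; sub-motifs (e.g. TRD3 inside FAT,
    PRD inside the kinase domain) may nest inside a parent interval.
    """

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, start, end in self.intervals:
            if start < 1 or start > end:
                raise ValueError(f"bad interval {name}: {start}..{end}")

    def names(self) -> list[str]:
        return [name for name, _, _ in self.intervals]

    def interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.intervals:
            if n == name:
                return (s, e)
        raise KeyError(name)

    def length(self, name: str) -> int:
        s, e = self.interval(name)
        return e - s + 1


def annotate_domain(dmap: DomainMap, position: int) -> str:
    """Innermost (shortest) interval containing ``position``, or 'unannotated'."""
    if position < 1:
        raise ValueError("position must be >= 1")
    hits = [
        (end - start, name)
        for name, start, end in dmap.intervals
        if start <= position <= end
    ]
    if not hits:
        return "unannotated"
    return min(hits)[1]


def read_domain_map(path: str | Path) -> DomainMap:
    """Read a BED-like TSV (columns: name, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: domain map needs columns {sorted(required)}")
    return DomainMap(
        [(str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
    )


def default_domain_map(gene: str) -> DomainMap:
    """Bundled domain annotation for ATM, ATR or MEC1.

    Only boundaries with a published basis are pre-filled (TRD3; the
    ~400-residue C-terminal kinase domain); users supply the rest by editing
    the shipped TSVs or providing their own.
    """
    from importlib import resources

    name = gene.lower()
    ref = resources.files("pikkmap.data") / f"domains_{name}.tsv"
    if not ref.is_file():
        raise KeyError(f"no bundled domain map for {gene!r}")
    with resources.as_file(ref) as p:
        return read_domain_map(p)


def write_clusters(
    clusters: list[list[tuple[str, int]]], path: str | Path
) -> pd.DataFrame:
    rows = [
        {"cluster": ci, "chain": chain, "position": pos, "size": len(members)}
        for ci, members in enumerate(clusters, start=1)
        for chain, pos in members
    ]
    df = pd.DataFrame(rows, columns=["cluster", "chain", "position", "size"])
    df.to_csv(path, sep="\t", index=False)
    return df
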