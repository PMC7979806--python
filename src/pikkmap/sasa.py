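"""Shrake-Rupley solvent-accessible surface area and burial classification.

Surface exposure of a residue decides whether a cancer-associated mutation
plausibly disrupts a protein-protein interface (solvent accessible) or the
fold/regulatory core (buried).  Rendered-model eyeballing is replaced by a
reproducible computation: each atom is expanded by the probe radius and
sampled with a deterministic golden-spiral point lattice; points falling
inside any neighbouring expanded sphere are occluded.  Per-residue areas
are normalised by theoretical per-residue maxima to give relative SASA, and
residues at or above a relative-SASA threshold are classed as surface.

No randomness is involved: for a fixed point count the result is bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._refdata import MAX_SASA, VDW_RADII
from .structure import StructureModel

__all__ = [
    "ResidueSASA",
    "SASAProfile",
    "sphere_points",
    "shrake_rupley",
    "classify_burial",
    "BurialSummary",
]

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_N_POINTS = 960
DEFAULT_BURIAL_THRESHOLD = 0.25  # relative SASA at/above which a residue is surface


@dataclass
class ResidueSASA:
    chain: str
    number: int
    name: str
    sasa: float  # absolute, Angstrom^2
    rel_sasa: Optional[float]  # fraction of the residue type's theoretical max
    burial: Optional[str] = None  # surface | buried (set by classify_burial)


@dataclass
class SASAProfile:
    """Per-residue absolute and relative accessible areas of one model."""

    residues: dict[tuple[str, int], ResidueSASA]
    probe_radius: float
    n_points: int

    def total(self) -> float:
        return sum(r.sasa for r in self.residues.values())


@dataclass
class BurialSummary:
    threshold: float
    n_surface: int
    n_buried: int

    @property
    def n_resolved(self) -> int:
        return self.n_surface + self.n_buried

    @property
    def surface_fraction(self) -> float:
        return self.n_surface / self.n_resolved if self.n_resolved else float("nan")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors.

    The points are near-uniform on the sphere and involve no RNG, so SASA
    values are reproducible bit-for-bit for a fixed ``n``.
    """
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radius(element: str, default_radius: Optional[float]) -> float:
    try:
        return VDW_RADII[element]
    except KeyError:
        if default_radius is not None:
            return default_radius
        raise ValueError(
            f"no van der Waals radius for element {element!r}; "
            "pass default_radius to accept a fallback"
        ) from None


def shrake_rupley(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    default_radius: Optional[float] = None,
    include_hydrogens: bool = False,
) -> SASAProfile:
    """Per-residue solvent-accessible surface area of a structure model.

    Relative SASA uses theoretical per-residue-type maxima; residue types
    outside the standard twenty get ``rel_sasa=None``.
    """
    entries = []  # (residue key, residue name, coord, expanded radius)
    for res in model.all_residues():
        for atom in res.atoms:
            if atom.element == "H" and not include_hydrogens:
                continue
            r = _atom_radius(atom.element, default_radius)
            entries.append((res.key, res.name, atom.coord, r + probe_radius))
    if not entries:
        raise ValueError("model has no atoms eligible for SASA")

    coords = np.array([e[2] for e in entries])
    radii = np.array([e[3] for e in entries])
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    areas = np.zeros(len(entries))
    for i in range(len(entries)):
        pts = coords[i] + radii[i] * unit
        neighbours = tree.query_ball_point(coords[i], radii[i] + max_r)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points

    per_res: dict[tuple[str, int], ResidueSASA] = {}
    for (key, resname, _, _), area in zip(entries, areas):
        if key not in per_res:
            chain, number = key
            per_res[key] = ResidueSASA(chain, number, resname, 0.0, None)
        per_res[key].sasa += float(area)
    for rs in per_res.values():
        ref = MAX_SASA.get(rs.name)
        rs.rel_sasa = rs.sasa / ref if ref else None
    return SASAProfile(per_res, probe_radius=probe_radius, n_points=n_points)


def classify_burial(
    profile: SASAProfile, threshold: float = DEFAULT_BURIAL_THRESHOLD
) -> BurialSummary:
    """Classify each resolved residue as surface (rel SASA >= threshold) or buried.

    Mutates the profile's ``burial`` fields in place and returns the summary
    counts over resolved residues.  Unresolved residues never appear in a
    SASA profile; callers mapping sequence positions report them separately.
    """
    n_surface = n_buried = 0
    for rs in profile.residues.values():
        rel = rs.rel_sasa if rs.rel_sasa is not None else 0.0
        if rel >= threshold:
            rs.burial = "surface"
            n_surface += 1
        else:
            rs.burial = "buried"
            n_buried += 1
    return BurialSummary(threshold=threshold, n_surface=n_surface, n_buried=n_buried)


def write_sasa_table(profile: SASAProfile, path: str | Path) -> pd.DataFrame:
    rows = [
        {
            "chain": rs.chain,
            "resnum": rs.number,
            "resname": rs.name,
            "sasa_A2": round(rs.sasa, 3),
            "rel_sasa": round(rs.rel_sasa, 4) if rs.rel_sasa is not None else "",
            "class": rs.burial or "",
        }
        for rs in profile.residues.values()
    ]
    df = pd.DataFrame(rows, columns=["chain", "resnum", "resname", "sasa_A2", "rel_sasa", "class"])
    df.to_csv(path, sep="\t", index=False)
    return df
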