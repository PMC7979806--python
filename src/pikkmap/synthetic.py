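"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the shapes of the real inputs without any download:

* a tumor cohort with per-cancer-type mutation hotspots, written in the
  mutation-table dialect the catalog module reads;
* ortholog sequences diverged to a target percent identity with protected
  (never substituted) conserved cores, plus the true pairwise alignment;
* toy structures (ideal alpha-helix trace or cubic-lattice ball) whose
  surface/buried ground truth follows from geometry alone.

Each generator is driven by a single explicitly seeded RNG stream and writes
its ground truth alongside the outputs as JSON, so identical (spec, seed)
always reproduce identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._refdata import AA1_TO_3
from .catalog import CONSEQUENCES

__all__ = [
    "CohortSpec",
    "OrthologSpec",
    "ToyStructureSpec",
    "SimulatedCohort",
    "SimulatedOrtholog",
    "SimulatedStructure",
    "simulate_cohort",
    "simulate_ortholog",
    "simulate_structure",
    "random_protein",
]

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(length: int, seed: int) -> str:
    """A random protein sequence over the standard alphabet."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AA_ORDER), size=length))


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSpec:
    """Specification of a synthetic tumor cohort.

    ``hotspots`` plants per-cancer-type missense hotspot positions, each hit
    independently per sample with probability ``hotspot_prob``.  Background
    mutations arise per residue per sample at ``background_rate`` and draw
    their consequence class from ``consequence_mix``.  Defaults reflect the
    noiseless end-to-end study condition (no background noise; hotspots hot
    enough that every planted residue is observed in a ~60+ sample stratum).
    """

    gene: str = "ATM"
    cohort_size: int = 200
    cancer_types: dict[str, int] = field(
        default_factory=lambda: {"colorectal": 70, "endometrial": 70, "lymphoma": 60}
    )
    hotspots: dict[str, list[int]] = field(
        default_factory=lambda: {
            "colorectal": [120, 450, 981, 1130],
            "endometrial": [87, 450, 702, 1090],
            "lymphoma": [33, 560, 981, 1200],
        }
    )
    hotspot_prob: float = 0.25
    background_rate: float = 0.0
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.70, "truncation": 0.20, "inframe": 0.08, "other": 0.02
        }
    )
    protein_seq: Optional[str] = None
    protein_length: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hotspot_prob <= 1.0 and 0.0 <= self.background_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.consequence_mix.values()) - 1.0) > 1e-9:
            raise ValueError("consequence_mix fractions must sum to 1")
        if set(self.consequence_mix) - set(CONSEQUENCES):
            raise ValueError("consequence_mix keys must be consequence classes")
        if sum(self.cancer_types.values()) > self.cohort_size:
            raise ValueError("per-type sample counts exceed cohort_size")
        for ctype, positions in self.hotspots.items():
            if ctype not in self.cancer_types:
                raise ValueError(f"hotspots given for unknown cancer type {ctype!r}")
            if any(p < 1 or p > self.length for p in positions):
                raise ValueError("hotspot positions outside the protein")

    @property
    def length(self) -> int:
        return len(self.protein_seq) if self.protein_seq else self.protein_length

    def ref_aa(self, pos: int) -> str:
        if self.protein_seq:
            return self.protein_seq[pos - 1]
        return _AA_ORDER[pos % len(_AA_ORDER)]


@dataclass
class SimulatedCohort:
    rows: list[dict]
    truth: dict

    def write(self, table_path: str | Path, truth_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.rows,
            columns=["gene", "sample_id", "cancer_type", "protein_change", "mutation_type"],
        ).to_csv(table_path, sep="\t", index=False)
        _write_json(self.truth, truth_path)


def _write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _substitute(aa: str, rng: np.random.Generator) -> str:
    choices = [c for c in _AA_ORDER if c != aa]
    return choices[int(rng.integers(len(choices)))]


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw a synthetic mutation table and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    observed: dict[str, set[int]] = {t: set() for t in spec.cancer_types}
    counts = {c: 0 for c in CONSEQUENCES}
    mix_classes = list(spec.consequence_mix)
    mix_probs = np.array([spec.consequence_mix[c] for c in mix_classes])

    for ctype, n_samples in spec.cancer_types.items():
        for s in range(n_samples):
            sample_id = f"{ctype.upper()[:4]}-{s + 1:04d}"
            for pos in spec.hotspots.get(ctype, []):
                if rng.random() < spec.hotspot_prob:
                    ref = spec.ref_aa(pos)
                    alt = _substitute(ref, rng)
                    rows.append(
                        {
                            "gene": spec.gene,
                            "sample_id": sample_id,
                            "cancer_type": ctype,
                            "protein_change": f"{ref}{pos}{alt}",
                            "mutation_type": "missense",
                        }
                    )
                    observed[ctype].add(pos)
                    counts["missense"] += 1
            if spec.background_rate > 0.0:
                n_bg = rng.binomial(spec.length, spec.background_rate)
                positions = rng.choice(spec.length, size=n_bg, replace=False) + 1
                for pos in sorted(int(p) for p in positions):
                    cls = mix_classes[int(rng.choice(len(mix_classes), p=mix_probs))]
                    ref = spec.ref_aa(pos)
                    if cls == "missense":
                        change = f"{ref}{pos}{_substitute(ref, rng)}"
                        observed[ctype].add(pos)
                    elif cls == "truncation":
                        change = f"{ref}{pos}*"
                    elif cls == "inframe":
                        change = f"{ref}{pos}del"
                    else:
                        change = f"{ref}{pos}_splice"
                    rows.append(
                        {
                            "gene": spec.gene,
                            "sample_id": sample_id,
                            "cancer_type": ctype,
                            "protein_change": change,
                            "mutation_type": cls,
                        }
                    )
                    counts[cls] += 1

    truth = {
        "gene": spec.gene,
        "cohort_size": spec.cohort_size,
        "seed": spec.seed,
        "planted_hotspots": {t: sorted(p) for t, p in spec.hotspots.items()},
        "observed_missense": {t: sorted(s) for t, s in observed.items()},
        "n_records": len(rows),
        "consequence_counts": counts,
    }
    return SimulatedCohort(rows=rows, truth=truth)


# ---------------------------------------------------------------------------
# orthologs


@dataclass
class OrthologSpec:
    """Divergence target for one simulated ortholog.

    ``target_identity`` is the fraction of ancestral positions left
    identical; ``protected`` positions are never substituted or deleted
    (the conserved core).  ``indel_rate`` is the per-position probability of
    a deletion (half) or an insertion after the position (half).
    """

    name: str
    target_identity: float
    protected: frozenset[int] = frozenset()
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must lie in (0, 1]")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must lie in [0, 1)")


@dataclass
class SimulatedOrtholog:
    name: str
    sequence: str
    row_ancestral: str  # gapped ancestral row of the true alignment
    row_ortholog: str
    conserved_positions: list[int]  # ancestral positions left identical
    realized_identity: float
    truth: dict

    def write_fasta(self, path: str | Path, ancestral_id: str = "ancestral") -> None:
        """True pairwise alignment as a 2-row aligned FASTA."""
        with open(path, "w") as fh:
            fh.write(f">{ancestral_id}\n{self.row_ancestral}\n")
            fh.write(f">{self.name}\n{self.row_ortholog}\n")


def simulate_ortholog(ancestral: str, spec: OrthologSpec) -> SimulatedOrtholog:
    """Diverge ``ancestral`` to the target identity with a protected core.

    Substitutions never reproduce the original residue; the realized
    identity (identical aligned positions over ancestral length) lands
    within one percentage point of the target.  A target below the
    protected-core floor, or incompatible with the drawn indels, raises
    ``ValueError``.
    """
    L = len(ancestral)
    if any(p < 1 or p > L for p in spec.protected):
        raise ValueError("protected positions outside the ancestral sequence")
    rng = np.random.default_rng(spec.seed)

    deleted: set[int] = set()
    insertions: dict[int, str] = {}  # insert after this ancestral position
    if spec.indel_rate > 0.0:
        for pos in range(1, L + 1):
            if pos not in spec.protected and rng.random() < spec.indel_rate / 2.0:
                deleted.add(pos)
            if rng.random() < spec.indel_rate / 2.0:
                insertions[pos] = _AA_ORDER[int(rng.integers(20))]

    retained = [p for p in range(1, L + 1) if p not in deleted]
    target_identical = round(spec.target_identity * L)
    n_subs = len(retained) - target_identical
    substitutable = [p for p in retained if p not in spec.protected]
    if n_subs < 0:
        raise ValueError("indels alone already exceed the divergence target")
    if n_subs > len(substitutable):
        raise ValueError(
            f"target identity {spec.target_identity} is below the floor set by "
            f"the protected core ({len(spec.protected)}/{L} protected)"
        )
    subs_at = set(
        int(p) for p in rng.choice(substitutable, size=n_subs, replace=False)
    )

    row_a: list[str] = []
    row_b: list[str] = []
    for pos in range(1, L + 1):
        aa = ancestral[pos - 1]
        if pos in deleted:
            row_a.append(aa)
            row_b.append("-")
        elif pos in subs_at:
            row_a.append(aa)
            row_b.append(_substitute(aa, rng))
        else:
            row_a.append(aa)
            row_b.append(aa)
        if pos in insertions:
            row_a.append("-")
            row_b.append(insertions[pos])

    sequence = "".join(c for c in row_b if c != "-")
    conserved = [p for p in retained if p not in subs_at]
    realized = len(conserved) / L
    if abs(realized - spec.target_identity) > 0.01:
        raise ValueError(
            f"realized identity {realized:.3f} misses target "
            f"{spec.target_identity:.3f} by more than one percentage point"
        )
    truth = {
        "name": spec.name,
        "seed": spec.seed,
        "target_identity": spec.target_identity,
        "realized_identity": realized,
        "protected": sorted(spec.protected),
        "conserved_positions": conserved,
        "n_substitutions": len(subs_at),
        "n_deleted": len(deleted),
        "n_inserted": len(insertions),
    }
    return SimulatedOrtholog(
        name=spec.name,
        sequence=sequence,
        row_ancestral="".join(row_a),
        row_ortholog="".join(row_b),
        conserved_positions=conserved,
        realized_identity=realized,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# toy structures


@dataclass
class ToyStructureSpec:
    """A toy C-alpha-only poly-alanine structure with burial ground truth.

    ``helix``: an ideal alpha-helix trace (rise 1.5 A per residue, 100 deg
    per residue, radius 2.3 A); every residue is ground-truth surface.
    ``lattice_ball``: C-alpha atoms on a cubic lattice filling a ball;
    ground truth buried iff all six lattice neighbours are occupied.  The
    default 4.5 A spacing gives interior residues a relative SASA well
    below, and face residues well above, the 0.25 burial threshold, so the
    geometric truth and the SASA classifier agree by construction.
    """

    arrangement: str = "lattice_ball"
    n_residues: int = 200
    spacing: float = 4.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrangement not in ("helix", "lattice_ball"):
            raise ValueError("arrangement must be 'helix' or 'lattice_ball'")
        if self.n_residues < 1 or self.spacing <= 0:
            raise ValueError("need n_residues >= 1 and spacing > 0")


@dataclass
class SimulatedStructure:
    spec: ToyStructureSpec
    coords: np.ndarray  # (n, 3) C-alpha coordinates, Angstrom
    burial_truth: dict[int, str]  # residue number -> surface | buried

    def write_pdb(self, path: str | Path, chain: str = "A") -> None:
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(self.coords, start=1):
                fh.write(
                    f"ATOM  {i:5d}  CA  ALA {chain}{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {'C':>2s}\n"
                )
            fh.write("TER\nEND\n")

    def write_truth(self, path: str | Path) -> None:
        _write_json(
            {
                "arrangement": self.spec.arrangement,
                "spacing": self.spec.spacing,
                "burial": {str(k): v for k, v in self.burial_truth.items()},
            },
            path,
        )


def simulate_structure(spec: ToyStructureSpec) -> SimulatedStructure:
    """Generate the toy structure and its geometric burial ground truth."""
    if spec.arrangement == "helix":
        i = np.arange(spec.n_residues)
        theta = np.deg2rad(100.0) * i
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
        truth = {n + 1: "surface" for n in range(spec.n_residues)}
        return SimulatedStructure(spec=spec, coords=coords, burial_truth=truth)

    # lattice_ball: take the n lattice points closest to the origin
    # (deterministic tie-break on coordinates).
    r_max = int(np.ceil(spec.n_residues ** (1.0 / 3.0))) + 2
    pts = [
        (i * i + j * j + k * k, i, j, k)
        for i in range(-r_max, r_max + 1)
        for j in range(-r_max, r_max + 1)
        for k in range(-r_max, r_max + 1)
    ]
    pts.sort()
    chosen = [(i, j, k) for _, i, j, k in pts[: spec.n_residues]]
    occupied = set(chosen)
    truth = {}
    for n, (i, j, k) in enumerate(chosen, start=1):
        neighbours = [
            (i + 1, j, k), (i - 1, j, k),
            (i, j + 1, k), (i, j - 1, k),
            (i, j, k + 1), (i, j, k - 1),
        ]
        truth[n] = "buried" if all(nb in occupied for nb in neighbours) else "surface"
    coords = np.array(chosen, dtype=float) * spec.spacing
    return SimulatedStructure(spec=spec, coords=coords, burial_truth=truth)
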