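"""Mutation-catalog ingestion and per-gene summary statistics.

This module reads cBioPortal-style mutation export tables (one row per
somatic mutation call), classifies each protein change into the display
categories used by cBioPortal (missense / truncation / in-frame / other),
and computes the quantities the downstream analysis is built on: per-gene
sample-level mutation frequencies and per-cancer-type sets of mutated
residues.

Positions are 1-based protein coordinates throughout.  The cohort size is a
required input because samples without any mutation in the queried genes are
absent from mutation exports and cannot be inferred from them.
"""

from __future__ import annotations

import decimal
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._refdata import AA1

__all__ = [
    "CONSEQUENCES",
    "MutationRecord",
    "MutationCatalog",
    "ResidueEntry",
    "ResidueSet",
    "GeneFrequency",
    "parse_protein_change",
    "load_catalog",
    "write_catalog",
    "gene_mutation_frequency",
    "mutated_residues",
    "consequence_counts",
    "round_half_up",
]

CONSEQUENCES = ("missense", "truncation", "inframe", "other")

#: Accepted header synonyms for the input TSV dialect (cBioPortal exports).
COLUMN_SYNONYMS = {
    "gene": "gene",
    "hugo_symbol": "gene",
    "sample_id": "sample_id",
    "sample id": "sample_id",
    "tumor_sample_barcode": "sample_id",
    "cancer_type": "cancer_type",
    "cancer type": "cancer_type",
    "protein_change": "protein_change",
    "protein change": "protein_change",
    "hgvsp_short": "protein_change",
    "mutation_type": "mutation_type",
    "mutation type": "mutation_type",
}

_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_POSITION_RE = re.compile(r"([A-Z]?)(\d+)")


class CatalogFormatError(ValueError):
    """Raised for malformed catalog files or rows."""


@dataclass(frozen=True)
class MutationRecord:
    """One mutation call: a (sample, mutation) row of the export table."""

    gene: str
    sample_id: str
    cancer_type: str
    protein_change: str
    consequence: str
    position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if self.position is not None and self.position < 1:
            raise ValueError("position must be >= 1 when present")
        if self.consequence == "missense":
            if self.ref_aa == self.alt_aa:
                raise ValueError("missense requires ref_aa != alt_aa")
            if self.ref_aa not in AA1 or self.alt_aa not in AA1:
                raise ValueError("missense requires standard one-letter codes")


@dataclass
class MutationCatalog:
    """An ordered collection of mutation records with the cohort size.

    ``cohort_size`` is the total number of tumor samples profiled, which may
    (and usually does) exceed the number of samples bearing a mutation in
    any particular gene.
    """

    records: list[MutationRecord]
    cohort_size: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_samples = len({r.sample_id for r in self.records})
        if self.cohort_size < n_samples:
            raise ValueError(
                f"cohort_size ({self.cohort_size}) is smaller than the number "
                f"of distinct samples with records ({n_samples})"
            )

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene, None)
        return list(seen)

    def cancer_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.cancer_type, None)
        return list(seen)


@dataclass
class ResidueEntry:
    cancer_types: set[str]
    n_records: int
    alt_residues: set[str]


@dataclass
class ResidueSet:
    """Set of mutated residue positions of one gene, with per-position detail."""

    gene: str
    entries: dict[int, ResidueEntry]

    def positions(self) -> set[int]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


class GeneFrequency:
    """Sample-level mutation frequency of one gene within a cohort.

    A sample counts once per gene no matter how many mutations it carries.
    ``percent_rounded`` applies half-up rounding to one decimal, the
    convention used when such frequencies are reported (e.g. "5.5%").
    """

    def __init__(self, gene: str, mutated_samples: int, cohort_size: int):
        self.gene = gene
        self.mutated_samples = mutated_samples
        self.cohort_size = cohort_size
        self.percent = 100.0 * mutated_samples / cohort_size
        self.percent_rounded = round_half_up(self.percent, 1)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneFrequency({self.gene}: {self.mutated_samples}/"
            f"{self.cohort_size} = {self.percent_rounded}%)"
        )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (so 2.25 -> 2.3), not banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def parse_protein_change(change: str) -> dict:
    """Classify an HGVS-p-like protein change string.

    Classification grammar (mirroring cBioPortal display categories):

    * contains ``*`` or ends in ``fs`` (frameshift)  -> truncation
    * contains ``del``/``ins``/``dup`` without ``fs`` -> inframe
    * single substitution ``[A-Z][0-9]+[A-Z]`` with two standard, distinct
      residues -> missense
    * anything else (splice, ``X``, unknown grammars) -> other, position absent

    An optional ``p.`` prefix is tolerated.  An empty string signals a
    malformed row and raises :class:`CatalogFormatError`.
    """
    if not isinstance(change, str) or not change.strip():
        raise CatalogFormatError("empty protein change string")
    s = change.strip()
    if s.startswith("p."):
        s = s[2:]

    def _position(text: str) -> Optional[tuple[Optional[str], int]]:
        m = _POSITION_RE.search(text)
        if not m:
            return None
        ref = m.group(1) if m.group(1) in AA1 else None
        return ref, int(m.group(2))

    if "*" in s or s.endswith("fs") or "fs" in s:
        pos = _position(s)
        return {
            "consequence": "truncation",
            "position": pos[1] if pos else None,
            "ref_aa": pos[0] if pos else None,
            "alt_aa": None,
        }
    low = s.lower()
    if any(tok in low for tok in ("del", "ins", "dup")):
        pos = _position(s)
        return {
            "consequence": "inframe",
            "position": pos[1] if pos else None,
            "ref_aa": pos[0] if pos else None,
            "alt_aa": None,
        }
    m = _MISSENSE_RE.match(s)
    if m and m.group(1) in AA1 and m.group(3) in AA1 and m.group(1) != m.group(3):
        return {
            "consequence": "missense",
            "position": int(m.group(2)),
            "ref_aa": m.group(1),
            "alt_aa": m.group(3),
        }
    return {"consequence": "other", "position": None, "ref_aa": None, "alt_aa": None}


def _normalise_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if key in COLUMN_SYNONYMS:
            mapping[col] = COLUMN_SYNONYMS[key]
    return mapping


def load_catalog(
    path: str | Path,
    cohort_size: int,
    genes: Optional[Sequence[str]] = None,
) -> MutationCatalog:
    """Read a tab-separated mutation export into a :class:`MutationCatalog`.

    Parameters
    ----------
    path:
        TSV file with a header row naming gene / sample / cancer-type /
        protein-change columns (cBioPortal export headers are accepted).
    cohort_size:
        Total number of tumor samples profiled in the cohort.
    genes:
        Optional gene filter; rows for other genes are skipped.

    Raises
    ------
    CatalogFormatError
        If a mandatory column is missing or a row lacks a sample id /
        protein change (the offending row number is reported).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    df = df.rename(columns=_normalise_columns(df.columns))
    for col in ("gene", "sample_id", "cancer_type", "protein_change"):
        if col not in df.columns:
            raise CatalogFormatError(f"missing mandatory column: {col}")

    gene_filter = set(genes) if genes is not None else None
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        gene = getattr(row, "gene").strip()
        if gene_filter is not None and gene not in gene_filter:
            continue
        sample = getattr(row, "sample_id").strip()
        if not sample:
            raise CatalogFormatError(f"row {i}: missing sample id")
        if not gene:
            raise CatalogFormatError(f"row {i}: missing gene symbol")
        change = getattr(row, "protein_change")
        try:
            parsed = parse_protein_change(change)
        except CatalogFormatError as exc:
            raise CatalogFormatError(f"row {i}: {exc}") from exc
        records.append(
            MutationRecord(
                gene=gene,
                sample_id=sample,
                cancer_type=getattr(row, "cancer_type").strip(),
                protein_change=change.strip(),
                **parsed,
            )
        )
    return MutationCatalog(
        records=records,
        cohort_size=cohort_size,
        provenance={"source": str(path), "n_rows": len(records)},
    )


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog back to the input TSV dialect (round-trip safe)."""
    rows = [
        {
            "gene": r.gene,
            "sample_id": r.sample_id,
            "cancer_type": r.cancer_type,
            "protein_change": r.protein_change,
            "mutation_type": r.consequence,
        }
        for r in catalog.records
    ]
    pd.DataFrame(
        rows, columns=["gene", "sample_id", "cancer_type", "protein_change", "mutation_type"]
    ).to_csv(path, sep="\t", index=False)


def gene_mutation_frequency(catalog: MutationCatalog, gene: str) -> GeneFrequency:
    """Fraction of cohort samples carrying at least one mutation in ``gene``."""
    if catalog.cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    samples = {r.sample_id for r in catalog.records if r.gene == gene}
    return GeneFrequency(gene, len(samples), catalog.cohort_size)


def mutated_residues(
    catalog: MutationCatalog,
    gene: str,
    cancer_type: Optional[str] = None,
    consequences: Iterable[str] = ("missense",),
) -> ResidueSet:
    """Positions of ``gene`` mutated to a different residue(s).

    The default consequence filter keeps missense changes only, i.e. residues
    "mutated to a different residue"; records whose protein change carries no
    position are never counted.  Multiple alternative residues at one
    position collapse into a single entry.
    """
    wanted = set(consequences)
    unknown = wanted - set(CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
    if cancer_type is not None:
        known = set(catalog.cancer_types())
        if cancer_type not in known:
            raise ValueError(
                f"unknown cancer type {cancer_type!r}; known types: {sorted(known)}"
            )
    entries: dict[int, ResidueEntry] = {}
    for r in catalog.records:
        if r.gene != gene or r.consequence not in wanted or r.position is None:
            continue
        if cancer_type is not None and r.cancer_type != cancer_type:
            continue
        entry = entries.setdefault(r.position, ResidueEntry(set(), 0, set()))
        entry.cancer_types.add(r.cancer_type)
        entry.n_records += 1
        if r.alt_aa is not None:
            entry.alt_residues.add(r.alt_aa)
    return ResidueSet(gene=gene, entries=dict(sorted(entries.items())))


def consequence_counts(catalog: MutationCatalog, gene: str) -> dict[str, int]:
    """Counts of records per consequence class; a partition of the gene's rows."""
    counts = {c: 0 for c in CONSEQUENCES}
    for r in catalog.records:
        if r.gene == gene:
            counts[r.consequence] += 1
    return counts


def write_gene_summary(
    catalog: MutationCatalog, genes: Sequence[str], path: str | Path
) -> pd.DataFrame:
    """Per-gene summary table: frequency plus consequence-class counts."""
    rows = []
    for gene in genes:
        freq = gene_mutation_frequency(catalog, gene)
        counts = consequence_counts(catalog, gene)
        rows.append(
            {
                "gene": gene,
                "mutated_samples": freq.mutated_samples,
                "cohort": freq.cohort_size,
                "frequency_pct": freq.percent_rounded,
                **{f"n_{c}": counts[c] for c in CONSEQUENCES},
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_residue_set(rs: ResidueSet, path: str | Path) -> pd.DataFrame:
    rows = [
        {
            "gene": rs.gene,
            "position": pos,
            "cancer_types": ",".join(sorted(e.cancer_types)),
            "n_records": e.n_records,
            "alt_residues": ",".join(sorted(e.alt_residues)),
        }
        for pos, e in rs.entries.items()
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "position", "cancer_types", "n_records", "alt_residues"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
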