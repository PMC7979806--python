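"""Cross-species residue correspondence and conservation calling.

The analysis asks, for each human ATM/ATR residue mutated in cancer, whether
the same amino acid sits at the aligned column in a yeast ortholog (Mec1
and/or Tel1).  Externally produced multiple alignments (e.g. Clustal-Omega
output) are accepted as authoritative when provided; a pairwise global
aligner with affine gap penalties is included so the whole pipeline can run
self-contained.

Gap cost convention: a gap run of length L costs ``gap_open + (L-1) *
gap_extend`` — opening the run costs ``gap_open``, each additional gapped
position costs ``gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import AlignIO
from Bio.Align import substitution_matrices

from ._refdata import AA1

__all__ = [
    "AlignParams",
    "AlignedPair",
    "ResidueCorrespondence",
    "ConservationCall",
    "global_align",
    "read_alignment",
    "pair_from_alignment",
    "percent_identity",
    "identity_report",
    "correspondence",
    "map_residue",
    "call_conserved",
    "summarize_conservation",
    "hr_block_alignment",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignParams:
    """Aligner parameters: substitution matrix and affine gap penalties."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def substitution_matrix(self):
        return substitution_matrices.load(self.matrix)


@dataclass
class AlignedPair:
    """A pairwise global alignment: two equal-length gapped rows."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: Optional[float] = None
    params: Optional[AlignParams] = None

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        for i, (a, b) in enumerate(zip(self.row_a, self.row_b), start=1):
            if a == "-" and b == "-":
                raise ValueError(f"column {i} is gapped in both rows")

    @property
    def seq_a(self) -> str:
        return self.row_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.row_b.replace("-", "")

    def __len__(self) -> int:
        return len(self.row_a)


@dataclass
class ResidueCorrespondence:
    """Monotonic 1-based position map between two aligned sequences."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if not (a1 < a2 and b1 < b2):
                raise ValueError("correspondence must be strictly increasing")

    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}


@dataclass
class ConservationCall:
    """Conservation status of one human residue across designated orthologs."""

    human_pos: int
    human_aa: str
    status: dict[str, str]  # ortholog id -> identical | substituted | gap
    conserved: bool


def _validate_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    allowed = AA1 | {"X"}
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(f"{label}: illegal character {ch!r} at position {i}")


def global_align(
    seq_a: str,
    seq_b: str,
    params: AlignParams = AlignParams(),
    id_a: str = "a",
    id_b: str = "b",
) -> AlignedPair:
    """Optimal global alignment with affine gaps (Gotoh's algorithm).

    Traceback ties are broken deterministically: diagonal is preferred, then
    up (gap in ``seq_b``), then left (gap in ``seq_a``), so alignments are
    bit-reproducible for fixed parameters.
    """
    _validate_sequence(seq_a, id_a)
    _validate_sequence(seq_b, id_b)
    sub = params.substitution_matrix()
    go, ge = params.gap_open, params.gap_extend
    n, m = len(seq_a), len(seq_b)

    # M: seq_a[i] aligned to seq_b[j]; X: gap in seq_b (consume a); Y: gap in seq_a.
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = -go - (j - 1) * ge

    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + sub[ai, seq_b[j - 1]]
            Xi[j] = max(max(Mi1[j], Yi1[j]) - go, Xi1[j] - ge)
            Yi[j] = max(max(Mi[j - 1], Xi[j - 1]) - go, Yi[j - 1] - ge)

    score = max(M[n][m], X[n][m], Y[n][m])

    # Traceback; preference order diagonal (M) > up (X) > left (Y).
    row_a: list[str] = []
    row_b: list[str] = []
    i, j = n, m
    if M[i][j] >= X[i][j] and M[i][j] >= Y[i][j]:
        state = "M"
    elif X[i][j] >= Y[i][j]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            row_a.append(seq_a[i - 1])
            row_b.append(seq_b[j - 1])
            prev = M[i][j] - sub[seq_a[i - 1], seq_b[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i][j] == prev:
                state = "M"
            elif X[i][j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            row_a.append(seq_a[i - 1])
            row_b.append("-")
            here = X[i][j]
            i -= 1
            if M[i][j] - go == here:
                state = "M"
            elif X[i][j] - ge == here:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            row_a.append("-")
            row_b.append(seq_b[j - 1])
            here = Y[i][j]
            j -= 1
            if M[i][j] - go == here:
                state = "M"
            elif X[i][j] - go == here:
                state = "X"
            else:
                state = "Y"
    return AlignedPair(
        id_a=id_a,
        id_b=id_b,
        row_a="".join(reversed(row_a)),
        row_b="".join(reversed(row_b)),
        score=score,
        params=params,
    )


def read_alignment(path: str | Path, format: str = "fasta"):
    """Read an aligned FASTA or Clustal file.

    Returns an :class:`AlignedPair` for two-row alignments, otherwise the
    Biopython ``MultipleSeqAlignment``.  Ragged rows and duplicate ids raise
    ``ValueError``.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids")
    if len(msa) == 2:
        return AlignedPair(
            id_a=msa[0].id, id_b=msa[1].id, row_a=str(msa[0].seq), row_b=str(msa[1].seq)
        )
    return msa


def pair_from_alignment(msa, id_a: str, id_b: str) -> AlignedPair:
    """Extract a pairwise alignment (two named rows) from a multi-row MSA.

    Columns gapped in both chosen rows are dropped so the pair invariants hold.
    """
    if isinstance(msa, AlignedPair):
        return msa
    by_id = {rec.id: str(rec.seq) for rec in msa}
    try:
        ra, rb = by_id[id_a], by_id[id_b]
    except KeyError as exc:
        raise KeyError(f"sequence {exc} not in alignment") from exc
    cols = [(a, b) for a, b in zip(ra, rb) if not (a == "-" and b == "-")]
    return AlignedPair(
        id_a=id_a,
        id_b=id_b,
        row_a="".join(a for a, _ in cols),
        row_b="".join(b for _, b in cols),
    )


def percent_identity(pair: AlignedPair, denominator: str = "columns") -> float:
    """Percent identity of a pairwise alignment.

    ``denominator="columns"`` divides identical columns by the alignment
    length; ``"shorter_seq"`` divides by the shorter ungapped sequence.
    """
    identical = sum(1 for a, b in zip(pair.row_a, pair.row_b) if a == b and a != "-")
    if denominator == "columns":
        denom = len(pair)
    elif denominator == "shorter_seq":
        denom = min(len(pair.seq_a), len(pair.seq_b))
    else:
        raise ValueError("denominator must be 'columns' or 'shorter_seq'")
    return 100.0 * identical / denom


def identity_report(pair: AlignedPair) -> dict[str, float]:
    """Both identity conventions side by side."""
    return {
        "identity_pct_columns": percent_identity(pair, "columns"),
        "identity_pct_shorter_seq": percent_identity(pair, "shorter_seq"),
    }


def correspondence(pair: AlignedPair) -> ResidueCorrespondence:
    """Column-wise 1-based position map between the two sequences of a pair."""
    pairs: list[tuple[int, int]] = []
    unmatched_a: list[int] = []
    unmatched_b: list[int] = []
    pa = pb = 0
    for a, b in zip(pair.row_a, pair.row_b):
        if a != "-":
            pa += 1
        if b != "-":
            pb += 1
        if a != "-" and b != "-":
            pairs.append((pa, pb))
        elif a != "-":
            unmatched_a.append(pa)
        else:
            unmatched_b.append(pb)
    return ResidueCorrespondence(pairs, unmatched_a, unmatched_b)


def map_residue(
    corr: ResidueCorrespondence, pos: int, from_seq: str = "a"
) -> Optional[int]:
    """Map a position across the correspondence; ``None`` marks a gap.

    Raises ``IndexError`` when the position lies outside the sequence span.
    """
    if from_seq == "a":
        mapping, unmatched = corr.a_to_b(), corr.unmatched_a
    elif from_seq == "b":
        mapping, unmatched = corr.b_to_a(), corr.unmatched_b
    else:
        raise ValueError("from_seq must be 'a' or 'b'")
    length = max([*mapping.keys(), *unmatched], default=0)
    if pos < 1 or pos > length:
        raise IndexError(f"position {pos} outside sequence span 1..{length}")
    return mapping.get(pos)


def call_conserved(
    positions,
    human_seq: str,
    ortholog_alignments: dict[str, AlignedPair],
    mode: str = "identity",
) -> list[ConservationCall]:
    """Call conservation of human residue positions against orthologs.

    Each alignment must carry the human sequence as its first row (``row_a``);
    a residue is conserved iff the identical amino acid occupies the aligned
    column in at least one designated ortholog.  ``mode="similar"`` relaxes
    identity to a positive BLOSUM62 substitution score (off by default; the
    strict-identity convention is the headline definition).

    ``positions`` may be an iterable of 1-based positions or a catalog
    :class:`~pikkmap.catalog.ResidueSet`.
    """
    if mode not in ("identity", "similar"):
        raise ValueError("mode must be 'identity' or 'similar'")
    sub = substitution_matrices.load("BLOSUM62") if mode == "similar" else None
    if hasattr(positions, "positions"):
        positions = positions.positions()
    positions = sorted(positions)
    maps = {}
    for name, pair in ortholog_alignments.items():
        if pair.seq_a != human_seq:
            raise ValueError(
                f"alignment {name!r}: ungapped first row does not match the "
                "stated human sequence"
            )
        maps[name] = (correspondence(pair), pair.seq_b)
    calls = []
    for pos in positions:
        if pos < 1 or pos > len(human_seq):
            raise IndexError(f"position {pos} outside human sequence")
        aa = human_seq[pos - 1]
        status = {}
        for name, (corr, seq_b) in maps.items():
            partner = corr.a_to_b().get(pos)
            if partner is None:
                status[name] = "gap"
            elif seq_b[partner - 1] == aa:
                status[name] = "identical"
            else:
                status[name] = "substituted"
        conserved = any(s == "identical" for s in status.values())
        if not conserved and sub is not None:
            for name, (corr, seq_b) in maps.items():
                partner = corr.a_to_b().get(pos)
                if partner is not None and sub[aa, seq_b[partner - 1]] > 0:
                    conserved = True
                    break
        calls.append(
            ConservationCall(
                human_pos=pos, human_aa=aa, status=status, conserved=conserved
            )
        )
    return calls


def summarize_conservation(calls: Sequence[ConservationCall]) -> dict[str, int]:
    return {
        "n_tested": len(calls),
        "n_conserved": sum(c.conserved for c in calls),
    }


def hr_block_alignment(seqs: Sequence[str]) -> list[int]:
    """Columns (1-based) identical across all rows of a short aligned block.

    Used for HEAT-repeat region blocks where a handful of positions are
    conserved across Mec1, ATR, ATM and Tel1.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("block rows must have equal length")
    return [
        i + 1
        for i in range(length)
        if seqs[0][i] != "-" and all(s[i] == seqs[0][i] for s in seqs[1:])
    ]


def write_correspondence(
    pair: AlignedPair, path: str | Path
) -> None:
    """TSV of the residue correspondence: pos_a, aa_a, pos_b, aa_b, status."""
    import pandas as pd

    rows = []
    pa = pb = 0
    for a, b in zip(pair.row_a, pair.row_b):
        if a != "-":
            pa += 1
        if b != "-":
            pb += 1
        if a != "-" and b != "-":
            status = "identical" if a == b else "substituted"
            rows.append((pa, a, pb, b, status))
        elif a != "-":
            rows.append((pa, a, "", "-", "gap"))
        else:
            rows.append(("", "-", pb, b, "gap"))
    pd.DataFrame(rows, columns=["pos_a", "aa_a", "pos_b", "aa_b", "status"]).to_csv(
        path, sep="\t", index=False
    )
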