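"""Readers and writers for every external representation the pipeline touches.

Coordinate convention: 1-based, inclusive ranges, throughout (the CT-file
convention). Sequences are stored as RNA; DNA input (T) is converted to U.

Formats
-------
FASTA                  transcripts (biopython SeqIO behind the scenes)
counts TSV             transcript_id, pos, ref_base, coverage, sub_count, del_count
annotation TSV         gene, transcript_id, start_codon_pos, cds_end_pos
mask TSV               transcript_id, kind (primer|editing|modified), start, end
CT / dot-bracket       secondary structure; optional accessibility TSV
constraint file        RNAstructure SHAPE-style "pos value", -999 = no data
reactivity TSV         transcript_id, pos, ref_base, channel, raw_rate,
                       normalized, mask_reason
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

COUNTS_COLUMNS = ["transcript_id", "pos", "ref_base", "coverage", "sub_count", "del_count"]
ANNOTATION_COLUMNS = ["gene", "transcript_id", "start_codon_pos", "cds_end_pos"]
MASK_COLUMNS = ["transcript_id", "kind", "start", "end"]
REACTIVITY_COLUMNS = [
    "transcript_id", "pos", "ref_base", "channel", "raw_rate", "normalized", "mask_reason",
]

NO_DATA = -999.0  # SHAPE-style sentinel for "no constraint at this position"


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """An analysis unit: one amplified transcript with its RNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"transcript {self.id!r}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"transcript {self.id!r}: non-ACGU characters {sorted(bad)} "
                "(ambiguity codes are not supported)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """Start codon and CDS end of one gene, on its transcript's coordinates."""

    gene: str
    transcript_id: str
    start_codon_pos: int  # 1-based, first nucleotide of the start codon
    cds_end_pos: int      # 1-based, inclusive (last nucleotide of the stop codon)

    def validate(self, transcript_length: int | None = None) -> None:
        if not 1 <= self.start_codon_pos < self.cds_end_pos:
            raise FormatError(
                f"gene {self.gene!r}: need 1 <= start_codon_pos < cds_end_pos, "
                f"got {self.start_codon_pos}, {self.cds_end_pos}"
            )
        if (self.cds_end_pos - self.start_codon_pos + 1) % 3 != 0:
            raise FormatError(f"gene {self.gene!r}: CDS length not divisible by 3")
        if transcript_length is not None and self.cds_end_pos > transcript_length:
            raise FormatError(
                f"gene {self.gene!r}: cds_end_pos {self.cds_end_pos} beyond "
                f"transcript length {transcript_length}"
            )


@dataclass
class MaskSet:
    """Positions excluded from reactivity analysis for one transcript."""

    primer_ranges: list[tuple[int, int]] = field(default_factory=list)
    editing_sites: list[int] = field(default_factory=list)
    modified_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.primer_ranges = sorted(set((int(a), int(b)) for a, b in self.primer_ranges))
        for a, b in self.primer_ranges:
            if a < 1 or b < a:
                raise FormatError(f"invalid primer range [{a},{b}]")
        self.editing_sites = sorted(set(int(p) for p in self.editing_sites))
        self.modified_sites = sorted(set(int(p) for p in self.modified_sites))
        if any(p < 1 for p in self.editing_sites + self.modified_sites):
            raise FormatError("mask positions must be >= 1")

    def in_primer(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.primer_ranges)


@dataclass
class ReferenceStructure:
    """Pairing map plus solvent-accessibility mask for a validation transcript.

    ``partner`` is 1-based: partner[i-1] == j means positions i and j pair;
    0 means unpaired. ``solvent_accessible`` defaults to all-True when no
    accessibility data accompanies the structure.
    """

    transcript_id: str
    partner: np.ndarray
    solvent_accessible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.partner = np.asarray(self.partner, dtype=int)
        n = self.partner.size
        if self.solvent_accessible is None:
            self.solvent_accessible = np.ones(n, dtype=bool)
        self.solvent_accessible = np.asarray(self.solvent_accessible, dtype=bool)
        if self.solvent_accessible.size != n:
            raise FormatError("accessibility mask length != structure length")
        for i0, j in enumerate(self.partner):
            i = i0 + 1
            if j == 0:
                continue
            if not 1 <= j <= n:
                raise FormatError(f"position {i}: partner {j} out of range")
            if j == i:
                raise FormatError(f"position {i} paired with itself")
            if self.partner[j - 1] != i:
                raise FormatError(
                    f"asymmetric pairing: {i} -> {j} but {j} -> {self.partner[j - 1]}"
                )

    @property
    def length(self) -> int:
        return int(self.partner.size)

    @property
    def unpaired(self) -> np.ndarray:
        return self.partner == 0

    def pairs(self) -> list[tuple[int, int]]:
        """(i, j) with i < j, 1-based."""
        return [(i + 1, int(j)) for i, j in enumerate(self.partner) if j > i + 1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Transcript]:
    """Read transcripts from FASTA; the header token before the first
    whitespace is the id; T is converted to U."""
    out: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append(Transcript(id=rec.id, sequence=str(rec.seq)))
    return out


def write_fasta(transcripts, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for k in range(0, t.length, width):
                fh.write(t.sequence[k:k + width] + "\n")


# ---------------------------------------------------------------------------
# counts table
# ---------------------------------------------------------------------------

def read_counts_table(path) -> pd.DataFrame:
    """Read a per-position mutation-count table.

    Returns a DataFrame with columns
    ``transcript_id, pos, ref_base, coverage, sub_count, del_count``
    (positions 1-based). Rows with ``sub_count + del_count > coverage``,
    negative counts or ``pos <= 0`` are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "ref_base": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts table missing column(s) {missing}")
    df = df[COUNTS_COLUMNS].copy()
    for col in ("pos", "coverage", "sub_count", "del_count"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if (df["pos"] <= 0).any():
        raise FormatError("counts table: pos must be >= 1 (1-based coordinates)")
    if (df[["coverage", "sub_count", "del_count"]] < 0).any().any():
        raise FormatError("counts table: negative counts")
    over = df["sub_count"] + df["del_count"] > df["coverage"]
    if over.any():
        row = df[over].iloc[0]
        raise FormatError(
            f"counts table: sub_count + del_count > coverage at "
            f"{row.transcript_id}:{row.pos}"
        )
    df["ref_base"] = df["ref_base"].str.upper().str.replace("T", "U")
    if not df["ref_base"].isin(list(RNA_ALPHABET)).all():
        raise FormatError("counts table: ref_base must be one of A,C,G,U(T)")
    return df


def write_counts_table(df: pd.DataFrame, path) -> None:
    df[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation and mask tables
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "transcript_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        ann = GeneAnnotation(
            gene=row.gene,
            transcript_id=row.transcript_id,
            start_codon_pos=int(row.start_codon_pos),
            cds_end_pos=int(row.cds_end_pos),
        )
        ann.validate()
        out.append(ann)
    return out


def write_annotation(annotations, path) -> None:
    pd.DataFrame(
        [(a.gene, a.transcript_id, a.start_codon_pos, a.cds_end_pos) for a in annotations],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_masks(path) -> dict[str, MaskSet]:
    """Read the mask table into one MaskSet per transcript.

    ``kind`` is primer (a range), editing or modified (single sites; the
    ``end`` column is ignored for sites and may repeat ``start``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "kind": str})
    missing = [c for c in MASK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mask table missing column(s) {missing}")
    raw: dict[str, dict[str, list]] = {}
    for row in df.itertuples(index=False):
        d = raw.setdefault(row.transcript_id, {"primer": [], "editing": [], "modified": []})
        if row.kind == "primer":
            d["primer"].append((int(row.start), int(row.end)))
        elif row.kind in ("editing", "modified"):
            d[row.kind].append(int(row.start))
        else:
            raise FormatError(f"unknown mask kind {row.kind!r}")
    return {
        tid: MaskSet(
            primer_ranges=d["primer"],
            editing_sites=d["editing"],
            modified_sites=d["modified"],
        )
        for tid, d in raw.items()
    }


def write_masks(masks: dict[str, MaskSet], path) -> None:
    rows = []
    for tid, m in masks.items():
        rows += [(tid, "primer", a, b) for a, b in m.primer_ranges]
        rows += [(tid, "editing", p, p) for p in m.editing_sites]
        rows += [(tid, "modified", p, p) for p in m.modified_sites]
    pd.DataFrame(rows, columns=MASK_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# secondary structure: CT and dot-bracket
# ---------------------------------------------------------------------------

def read_structure(path_or_string, format: str = "ct", *, transcript_id: str | None = None,
                   accessibility: np.ndarray | None = None) -> ReferenceStructure:
    """Parse a CT file or a dot-bracket string into a ReferenceStructure.

    Dot-bracket supports nested pairs only; CT supports arbitrary (crossing)
    pairs. When no accessibility mask is supplied every position is treated
    as solvent-accessible.
    """
    if format == "ct":
        tid, partner = _parse_ct(path_or_string)
        return ReferenceStructure(
            transcript_id=transcript_id or tid,
            partner=partner,
            solvent_accessible=accessibility,
        )
    if format == "dotbracket":
        partner = parse_dotbracket(path_or_string)
        return ReferenceStructure(
            transcript_id=transcript_id or "structure",
            partner=partner,
            solvent_accessible=accessibility,
        )
    raise ValueError(f"unknown structure format {format!r}")


def parse_dotbracket(db: str) -> np.ndarray:
    """Matched-bracket string -> 1-based partner array (0 = unpaired)."""
    partner = np.zeros(len(db), dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced brackets: unmatched ')' at {i}")
            j = stack.pop()
            partner[j - 1] = i
            partner[i - 1] = j
        elif ch != ".":
            raise FormatError(f"dot-bracket: unexpected character {ch!r} at {i}")
    if stack:
        raise FormatError(f"unbalanced brackets: unmatched '(' at {stack[-1]}")
    return partner


def _parse_ct(path) -> tuple[str, np.ndarray]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise FormatError("CT header must start with the sequence length") from exc
    title = header[1] if len(header) > 1 else "structure"
    if len(lines) - 1 != n:
        raise FormatError(f"CT: header says {n} rows, found {len(lines) - 1}")
    partner = np.zeros(n, dtype=int)
    for ln in lines[1:]:
        f = ln.split()
        if len(f) < 6:
            raise FormatError(f"CT row too short: {ln!r}")
        i, j = int(f[0]), int(f[4])
        if not 1 <= i <= n:
            raise FormatError(f"CT row index {i} out of range")
        partner[i - 1] = j
    # symmetry is re-validated by ReferenceStructure.__post_init__
    return title, partner


def write_ct(structure: ReferenceStructure, sequence: str, path) -> None:
    n = structure.length
    if len(sequence) != n:
        raise FormatError("sequence length != structure length")
    with open(path, "w") as fh:
        fh.write(f"{n} {structure.transcript_id}\n")
        for i in range(1, n + 1):
            nxt = i + 1 if i < n else 0
            fh.write(
                f"{i} {sequence[i - 1]} {i - 1} {nxt} {int(structure.partner[i - 1])} {i}\n"
            )


def to_dotbracket(structure: ReferenceStructure) -> str:
    """Render a nested structure as a dot-bracket string (crossing pairs
    raise, since they cannot be expressed with one bracket level)."""
    pairs = structure.pairs()
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise FormatError("structure contains crossing pairs")
    out = ["."] * structure.length
    for i, j in pairs:
        out[i - 1], out[j - 1] = "(", ")"
    return "".join(out)


def read_accessibility(path, length: int) -> np.ndarray:
    """Read a per-position solvent-accessibility mask (TSV: pos, accessible)."""
    df = pd.read_csv(path, sep="\t")
    if not {"pos", "accessible"} <= set(df.columns):
        raise FormatError("accessibility table needs columns pos, accessible")
    acc = np.zeros(length, dtype=bool)
    pos = df["pos"].astype(int).to_numpy()
    if (pos < 1).any() or (pos > length).any():
        raise FormatError("accessibility position out of range")
    acc[pos - 1] = df["accessible"].astype(bool).to_numpy()
    return acc


def write_accessibility(accessible: np.ndarray, path) -> None:
    pd.DataFrame(
        {"pos": np.arange(1, len(accessible) + 1), "accessible": accessible.astype(int)}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reactivity profiles and constraint files
# ---------------------------------------------------------------------------

def write_reactivity(profile: pd.DataFrame, path) -> None:
    profile[REACTIVITY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_reactivity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in REACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"reactivity table missing column(s) {missing}")
    return df


def write_constraints(profile: pd.DataFrame, transcript: Transcript, path,
                      channels: tuple[str, ...] = ("AC",)) -> None:
    """Export a SHAPE-style soft-constraint file for one transcript.

    Two columns (position, value), one line per transcript position in
    order. Only normalized reactivities of the requested channels are
    emitted (A/C by default, matching how reactivities are passed to
    folding engines); masked positions and other channels get -999.
    """
    sub = profile[profile["transcript_id"] == transcript.id]
    if sub.empty or sub["normalized"].isna().all():
        raise ValueError(
            f"profile has no normalized reactivities for transcript {transcript.id!r}"
        )
    values = {}
    for row in sub.itertuples(index=False):
        if (
            row.mask_reason == "none"
            and row.channel in channels
            and not pd.isna(row.normalized)
        ):
            values[int(row.pos)] = float(row.normalized)
    with open(path, "w") as fh:
        for pos in range(1, transcript.length + 1):
            v = values.get(pos, NO_DATA)
            fh.write(f"{pos}\t{v:.4f}\n" if v != NO_DATA else f"{pos}\t-999\n")


def read_constraints(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            p, v = re.split(r"\s+", ln.strip())[:2]
            rows.append((int(p), float(v)))
    return pd.DataFrame(rows, columns=["pos", "value"])
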