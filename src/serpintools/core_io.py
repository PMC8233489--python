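"""Domain types and I/O for protein sequences, coding sequences and alignments.

The toolkit operates on a protein superfamily: collections of amino-acid
sequences (optionally paired with their coding DNA and a taxonomy), seed
multiple alignments, and the reactive-center-loop hinge motif that marks
inhibitory competence in serpins.  Conventions used throughout the toolkit:
0-based indices, half-open intervals, lower median for even-length inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "PROTEIN_ALPHABET",
    "SequenceRecord",
    "CdsRecord",
    "Alignment",
    "HingeMotif",
    "HINGE_MOTIF",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "length_filter",
    "hinge_motif_scan",
    "translate_cds",
]

#: The 20 standard residues plus the ambiguity letter X.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

GAP_CHARS = frozenset("-.~")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class SequenceRecord:
    """A protein sequence with identifier and optional metadata.

    Parameters
    ----------
    id:
        Unique, nonempty identifier.
    sequence:
        Amino-acid string over the 20 standard letters plus ``X``.
    taxonomy:
        Optional ordered rank labels, most inclusive first
        (e.g. superkingdom → species).
    annotations:
        Free-text labels marking experimental characterization.
    description:
        FASTA description text after the first whitespace, if any.
    """

    id: str
    sequence: str
    taxonomy: Optional[tuple[str, ...]] = None
    annotations: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} must be nonempty")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains letters outside the protein "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsRecord:
    """Coding DNA paired with a protein record of the same id.

    ``has_stop`` records the per-record length convention: with a trailing
    stop codon ``len(cds) == 3 * len(protein) + 3``, without one
    ``len(cds) == 3 * len(protein)``.
    """

    id: str
    cds: str
    genome_gc: float
    has_stop: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("cds id must be nonempty")
        bad = set(self.cds) - DNA_ALPHABET
        if bad:
            raise ValueError(f"cds {self.id!r} has non-DNA letters: {sorted(bad)}")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"cds {self.id!r} length not divisible by 3")
        if not 0.0 <= self.genome_gc <= 1.0:
            raise ValueError("genome_gc must be a fraction in [0, 1]")

    @property
    def protein(self) -> str:
        """Translation of the CDS (trailing stop dropped)."""
        return translate_cds(self.cds)

    def check_against(self, record: SequenceRecord) -> None:
        """Validate length convention and translation against a protein record."""
        expected = 3 * len(record.sequence) + (3 if self.has_stop else 0)
        if len(self.cds) != expected:
            raise ValueError(
                f"cds {self.id!r} length {len(self.cds)} != expected {expected}"
            )
        translated = self.protein
        # N-containing codons translate to X and are not compared.
        for a, b in zip(translated, record.sequence):
            if a != "X" and a != b:
                raise ValueError(
                    f"cds {self.id!r} translation does not match protein sequence"
                )


@dataclass
class Alignment:
    """A multiple sequence alignment: rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]
    #: Optional per-column annotations, e.g. a Stockholm ``#=GC RF`` line.
    column_annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            ragged = [rid for rid, s in self.rows
                      if len(s) != len(self.rows[0][1])]
            raise FormatError(f"ragged alignment rows: {ragged}")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids in alignment: {dup}")
        if self.column_count == 0:
            raise ValueError("alignment must have at least one column")
        for key, ann in self.column_annotations.items():
            if len(ann) != self.column_count:
                raise ValueError(
                    f"column annotation {key!r} length {len(ann)} != "
                    f"column count {self.column_count}"
                )

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def degapped(self, row_id: str) -> str:
        seq = dict(self.rows)[row_id]
        return "".join(c for c in seq if c not in GAP_CHARS)

    def resolved_mask(self, key: str = "RF") -> Optional[list[bool]]:
        """Boolean per-column mask from a reference annotation line.

        A column is *resolved* when the annotation character is not a gap
        symbol.  Returns None when the annotation is absent.
        """
        ann = self.column_annotations.get(key)
        if ann is None:
            return None
        return [c not in GAP_CHARS for c in ann]

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)


@dataclass(frozen=True)
class HingeMotif:
    """Positional residue sets for the RCL hinge, positions P17 through P9.

    The consensus hinge of inhibitory serpins is E-x-G-T-E-A-A-A-A with the
    second position (the x) restricted to E, K or R.
    """

    pattern: tuple[frozenset[str], ...] = (
        frozenset("E"), frozenset("EKR"), frozenset("G"), frozenset("T"),
        frozenset("E"), frozenset("A"), frozenset("A"), frozenset("A"),
        frozenset("A"),
    )
    position_labels: tuple[str, ...] = (
        "P17", "P16", "P15", "P14", "P13", "P12", "P11", "P10", "P9",
    )

    def __post_init__(self) -> None:
        assert len(self.pattern) == 9 and len(self.position_labels) == 9

    def __len__(self) -> int:
        return len(self.pattern)


#: The default serpin hinge motif (P17-P9: ExGTEAAAA, x: E/K/R).
HINGE_MOTIF = HingeMotif()

_HINGE_RE = re.compile(r"(?=(E[EKR]GTEAAAA))")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein records from a FASTA file.

    Raises :class:`FormatError` for duplicate ids or malformed records
    (reported with a line number); an empty file yields an empty list.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() == "":
        return []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected '>' header before sequence data"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(),
                           description=desc)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from aligned FASTA or Stockholm.

    Stockholm per-column annotation lines (``#=GC``) are retained in
    ``column_annotations``; the ``RF`` line doubles as the resolved-column
    mask for profile construction.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        # Parse leniently, then let the Alignment invariant flag ragged rows.
        rows = [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(path), "fasta")]
        return Alignment(rows=rows)
    aln = AlignIO.read(str(path), "stockholm")
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    anns = dict(getattr(aln, "column_annotations", {}) or {})
    # Biopython exposes "#=GC RF" as "reference_annotation".
    renames = {"reference_annotation": "RF", "secondary_structure": "SS_cons"}
    anns = {renames.get(k, k): v for k, v in anns.items()}
    return Alignment(rows=rows, column_annotations=anns)


def write_alignment(alignment: Alignment, path: str | Path,
                    format: str = "fasta", width: int = 60) -> None:
    """Write an alignment as aligned FASTA or Stockholm (with #=GC lines)."""
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for rid, seq in alignment.rows:
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        return
    if format != "stockholm":
        raise ValueError(f"unsupported alignment format {format!r}")
    renames = {"RF": "RF", "SS_cons": "SS_cons"}
    name_w = max(len(rid) for rid, _ in alignment.rows)
    name_w = max(name_w, max((len(f"#=GC {renames.get(k, k)}")
                              for k in alignment.column_annotations), default=0))
    with path.open("w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, seq in alignment.rows:
            fh.write(f"{rid:<{name_w}} {seq}\n")
        for key, ann in alignment.column_annotations.items():
            tag = f"#=GC {renames.get(key, key)}"
            fh.write(f"{tag:<{name_w}} {ann}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def lower_median(values: Sequence[int]) -> int:
    """Lower median: the element at index (n-1)//2 of the sorted values."""
    if not values:
        raise ValueError("median of empty sequence")
    return sorted(values)[(len(values) - 1) // 2]


def length_filter(
    records: Sequence[SequenceRecord], tolerance: float = 0.25
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Drop records more than 25% shorter or longer than the median length.

    The comparison is strict: a record whose length equals exactly
    ``(1 ± tolerance) × median`` is kept.  The median is the lower median,
    so it is always a realized length and the filter is idempotent.

    Returns ``(kept, removed)`` in input order.
    """
    if not records:
        raise ValueError("length_filter requires at least one record")
    med = lower_median([len(r) for r in records])
    lo, hi = (1.0 - tolerance) * med, (1.0 + tolerance) * med
    kept = [r for r in records if lo <= len(r) <= hi]
    removed = [r for r in records if not lo <= len(r) <= hi]
    return kept, removed


def hinge_motif_scan(
    record: SequenceRecord | str, motif: HingeMotif = HINGE_MOTIF
) -> list[tuple[int, str]]:
    """Find all (possibly overlapping) hinge-motif windows in a sequence.

    Returns 0-based start indices with the matched 9-mer.  Windows
    containing the ambiguity letter X never match.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if motif is HINGE_MOTIF:
        return [(m.start(), m.group(1)) for m in _HINGE_RE.finditer(seq)]
    hits = []
    k = len(motif)
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if all(c in allowed for c, allowed in zip(window, motif.pattern)):
            hits.append((i, window))
    return hits


# Standard genetic code; built once from Biopython's table.
def _codon_table() -> tuple[dict[str, str], frozenset[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table), frozenset(table.stop_codons)


_FORWARD, _STOPS = _codon_table()


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    Codons containing N translate to X; a trailing stop codon is dropped;
    an internal stop raises an error naming the codon index.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"cds length {len(cds)} not divisible by 3")
    protein = []
    n_codons = len(cds) // 3
    for k in range(n_codons):
        codon = cds[3 * k: 3 * k + 3]
        if "N" in codon:
            protein.append("X")
        elif codon in _STOPS:
            if k == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon index {k}")
        else:
            protein.append(_FORWARD[codon])
    return "".join(protein)


def write_filter_report(
    kept: Sequence[SequenceRecord], removed: Sequence[SequenceRecord],
    path: str | Path, tolerance: float = 0.25,
) -> None:
    """TSV report of the length filter: id, length, kept/removed, reason."""
    med = lower_median([len(r) for r in list(kept) + list(removed)])
    with Path(path).open("w") as fh:
        fh.write("id\tlength\tstatus\treason\n")
        for r in kept:
            fh.write(f"{r.id}\t{len(r)}\tkept\t-\n")
        for r in removed:
            side = "long" if len(r) > med else "short"
            fh.write(f"{r.id}\t{len(r)}\tremoved\t>{tolerance:.0%}_{side}_of_median_{med}\n")
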