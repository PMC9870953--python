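"""Alignment I/O, degenerate-primer trimming, and translation QC.

Handles the sequence-level plumbing of a COI barcode dataset: reading and
writing aligned FASTA/NEXUS, matching/trimming degenerate PCR primers
(IUPAC codes), and the pre-analysis translation check that flags sequences
with internal stop codons (pseudogenes, frameshifts, miscalls).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignedSeqSet",
    "PrimerPair",
    "QCReport",
    "TrimLog",
    "AlignmentError",
    "FastaParseError",
    "IUPAC_CODES",
    "iupac_match",
    "read_fasta",
    "write_fasta",
    "read_nexus",
    "write_nexus",
    "trim_primers",
    "translation_qc",
    "reverse_complement",
]

# Degeneracy sets for the 15 IUPAC nucleotide codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

_VALID_SYMBOLS = frozenset(IUPAC_CODES) | {"-"}


class AlignmentError(ValueError):
    """Raised when records violate alignment invariants (ragged, duplicate IDs...)."""


class FastaParseError(ValueError):
    """Raised for syntactically malformed FASTA input."""


@dataclass(frozen=True)
class AlignedSeqSet:
    """An aligned set of equal-length DNA sequences keyed by unique sample IDs.

    Sequences are uppercase strings over the IUPAC nucleotide alphabet plus
    ``-`` (alignment gap). ``U`` is mapped to ``T`` on construction.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty sequence set")
        cleaned = []
        for sid, seq in self.records:
            if not sid:
                raise AlignmentError("empty sample_id")
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - _VALID_SYMBOLS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains non-IUPAC symbols: {sorted(bad)}"
                )
            cleaned.append((sid, seq))
        lengths = {len(s) for _, s in cleaned}
        if len(lengths) != 1:
            by_len: dict[int, list[str]] = {}
            for sid, s in cleaned:
                by_len.setdefault(len(s), []).append(sid)
            raise AlignmentError(f"unequal sequence lengths: {by_len}")
        if lengths == {0}:
            raise AlignmentError("zero-length alignment")
        ids = [sid for sid, _ in cleaned]
        dupes = [sid for sid, k in Counter(ids).items() if k > 1]
        if dupes:
            raise AlignmentError(f"duplicate sample_ids: {dupes}")
        object.__setattr__(self, "records", tuple(cleaned))

    @property
    def length(self) -> int:
        """Alignment length L in columns."""
        return len(self.records[0][1])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> str:
        for sid, seq in self.records:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def subset(self, sample_ids) -> "AlignedSeqSet":
        """Restrict to the given sample IDs, keeping record order."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"sample_ids not in alignment: {sorted(missing)}")
        return AlignedSeqSet(tuple(r for r in self.records if r[0] in wanted))

    def select_columns(self, columns) -> "AlignedSeqSet":
        """Project the alignment onto an ordered subset of 0-based columns."""
        cols = list(columns)
        return AlignedSeqSet(
            tuple((sid, "".join(seq[c] for c in cols)) for sid, seq in self.records)
        )


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate PCR primer pair; reverse is 5'->3' on the opposite strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            p = p.upper()
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC symbols: {sorted(bad)}")
            object.__setattr__(self, name, p)


# The primer pair used for the ~658 bp COI-5' barcode amplicon.
GAZ_F2 = "CCAACCAYAAAGATATWGGTAC"
GAZ_R2 = "GGATGACCAAARAACCAAAA"
COI_PRIMERS = PrimerPair(GAZ_F2, GAZ_R2)


def reverse_complement(seq: str) -> str:
    """Reverse complement respecting IUPAC degeneracy (R<->Y, K<->M, ...)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide symbol {exc.args[0]!r}") from None


def iupac_match(code: str, base: str) -> bool:
    """True iff `base` (A/C/G/T) lies in the degeneracy set of IUPAC `code`."""
    code = code.upper()
    base = base.upper()
    if code not in IUPAC_CODES:
        raise ValueError(f"unknown IUPAC code {code!r}")
    if base not in "ACGT" or len(base) != 1:
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    return base in IUPAC_CODES[code]


def _codes_compatible(code_a: str, code_b: str) -> bool:
    """True iff two IUPAC codes share at least one concrete base."""
    return bool(IUPAC_CODES[code_a] & IUPAC_CODES[code_b])


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> AlignedSeqSet:
    """Read a multi-record aligned FASTA file into an :class:`AlignedSeqSet`.

    Raises :class:`FastaParseError` for malformed syntax and
    :class:`AlignmentError` for ragged alignments or duplicate IDs.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: no records found")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaParseError(f"{path}: no records found")
    return AlignedSeqSet(tuple(records))


def _to_msa(seqs: AlignedSeqSet) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sid, description="", annotations={"molecule_type": "DNA"})
        for sid, seq in seqs.records
    )


def write_fasta(seqs: AlignedSeqSet, path) -> None:
    SeqIO.write(list(_to_msa(seqs)), str(path), "fasta")


def write_nexus(seqs: AlignedSeqSet, path) -> None:
    """Write a standard NEXUS DATA block (NTAX, NCHAR, DATATYPE=DNA, MATRIX)."""
    AlignIO.write(_to_msa(seqs), str(path), "nexus")


def read_nexus(path) -> AlignedSeqSet:
    aln = AlignIO.read(str(path), "nexus")
    return AlignedSeqSet(tuple((rec.id, str(rec.seq)) for rec in aln))


# ---------------------------------------------------------------------------
# Primer trimming


@dataclass
class TrimLog:
    """Per-sample record of what :func:`trim_primers` did.

    Column coordinates in entries are 1-based inclusive; internal slicing is
    0-based half-open.
    """

    entries: list[dict] = field(default_factory=list)
    fwd_columns: tuple[int, int] | None = None  # 0-based half-open
    rev_columns: tuple[int, int] | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tfwd_trimmed\trev_trimmed\tmismatches\n")
            for e in self.entries:
                fh.write(
                    f"{e['sample_id']}\t{e['fwd_trimmed']}\t{e['rev_trimmed']}\t{e['mismatches']}\n"
                )


def _best_match(seq: str, primer: str, offsets) -> tuple[int | None, int]:
    """Best (offset, mismatches) of `primer` against `seq` over candidate offsets.

    A sequence position matches when its symbol's degeneracy set intersects the
    primer code's; gaps never match. Ties go to the earliest offset.
    """
    best_off, best_mm = None, len(primer) + 1
    for off in offsets:
        window = seq[off : off + len(primer)]
        if len(window) < len(primer):
            continue
        mm = sum(
            1
            for p, s in zip(primer, window)
            if s == "-" or not _codes_compatible(p, s)
        )
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def trim_primers(
    seqs: AlignedSeqSet,
    primers: PrimerPair = COI_PRIMERS,
    max_mismatch: int = 1,
    window_slack: int = 10,
) -> tuple[AlignedSeqSet, TrimLog]:
    """Remove primer-covered columns from both ends of an alignment.

    The forward primer is searched in the leading ``len(primer)+window_slack``
    columns and the reverse complement of the reverse primer in the trailing
    window. Trimming removes whole columns (the modal matching interval over
    samples), so the output stays a valid alignment; per-sample outcomes are
    recorded in the returned :class:`TrimLog`. Sequences without a match are
    left logged as untrimmed; if no sequence matches at an end, no columns are
    removed at that end.
    """
    L = seqs.length
    fwd = primers.forward
    rev_rc = reverse_complement(primers.reverse)
    if len(fwd) >= L or len(rev_rc) >= L:
        raise ValueError("primer length must be shorter than the alignment")

    fwd_window = range(0, min(window_slack, L - len(fwd)) + 1)
    rev_start_min = max(0, L - len(rev_rc) - window_slack)
    rev_window = range(rev_start_min, L - len(rev_rc) + 1)

    per_sample = []
    fwd_offsets: Counter[int] = Counter()
    rev_offsets: Counter[int] = Counter()
    for sid, seq in seqs.records:
        f_off, f_mm = _best_match(seq, fwd, fwd_window)
        r_off, r_mm = _best_match(seq, rev_rc, rev_window)
        f_hit = f_off is not None and f_mm <= max_mismatch
        r_hit = r_off is not None and r_mm <= max_mismatch
        if f_hit:
            fwd_offsets[f_off] += 1
        if r_hit:
            rev_offsets[r_off] += 1
        per_sample.append((sid, f_hit, r_hit, (f_mm if f_hit else 0) + (r_mm if r_hit else 0)))

    log = TrimLog()
    drop: set[int] = set()
    if fwd_offsets:
        off = fwd_offsets.most_common(1)[0][0]
        log.fwd_columns = (off, off + len(fwd))
        drop.update(range(off, off + len(fwd)))
    if rev_offsets:
        off = rev_offsets.most_common(1)[0][0]
        log.rev_columns = (off, off + len(rev_rc))
        drop.update(range(off, off + len(rev_rc)))

    for sid, f_hit, r_hit, mm in per_sample:
        log.entries.append(
            {
                "sample_id": sid,
                "fwd_trimmed": bool(f_hit and log.fwd_columns),
                "rev_trimmed": bool(r_hit and log.rev_columns),
                "mismatches": mm,
            }
        )

    if not drop:
        return seqs, log
    keep = [c for c in range(L) if c not in drop]
    if not keep:
        raise AlignmentError("primer trimming removed every column")
    return seqs.select_columns(keep), log


# ---------------------------------------------------------------------------
# Translation QC


@dataclass(frozen=True)
class QCRow:
    sample_id: str
    frame_used: int
    internal_stop_count: int

    @property
    def passed(self) -> bool:
        return self.internal_stop_count == 0


@dataclass(frozen=True)
class QCReport:
    rows: tuple[QCRow, ...]

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def failures(self) -> tuple[QCRow, ...]:
        return tuple(r for r in self.rows if not r.passed)


def _internal_stops(seq: str, frame: int, stop_codons: frozenset[str]) -> int:
    """Count internal stop codons in one forward frame.

    Codons containing a gap or ambiguity code are skipped; the final (possibly
    terminal) codon of the frame is not counted as internal.
    """
    codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
    if not codons:
        return 0
    stops = 0
    for codon in codons[:-1]:
        if set(codon) <= set("ACGT") and codon in stop_codons:
            stops += 1
    return stops


def translation_qc(seqs: AlignedSeqSet, genetic_code: int = 1) -> QCReport:
    """Translate each sequence in its best forward frame and count internal stops.

    The frame (0/1/2) minimising internal stop codons is chosen per sequence;
    ties go to the lowest frame. ``genetic_code`` is an NCBI translation table
    id (1 = standard code).
    """
    if seqs.length < 3:
        raise ValueError("alignment shorter than one codon")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stop_codons = frozenset(table.stop_codons)
    rows = []
    for sid, seq in seqs.records:
        counts = [_internal_stops(seq, f, stop_codons) for f in (0, 1, 2)]
        frame = int(min(range(3), key=lambda f: counts[f]))
        rows.append(QCRow(sample_id=sid, frame_used=frame, internal_stop_count=counts[frame]))
    return QCReport(rows=tuple(rows))
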