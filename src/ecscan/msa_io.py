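"""Alignment I/O: MAF, aligned FASTA and Stockholm in; BED6 out.

Parsing of the standard formats is delegated to Bio.AlignIO; this module
normalises everything into the internal alignment model (RNA alphabet,
optional genome anchoring with MAF semantics: 0-based starts in
source-strand coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import AlignIO

from . import _alphabet as ab
from .fold import SecondaryStructure

__all__ = [
    "FormatError",
    "AlignedSequence",
    "Alignment",
    "StructuredFamily",
    "read_maf",
    "read_fasta_alignment",
    "read_stockholm",
    "write_fasta_alignment",
    "write_stockholm",
    "write_maf",
    "write_bed",
]


class FormatError(ValueError):
    """Malformed or unsupported input."""


@dataclass
class AlignedSequence:
    """One gapped row of an alignment, optionally genome-anchored.

    For MAF input the id is "species.chromosome"; `src_start` is the 0-based
    start of the ungapped sequence on the source strand, `src_size` the
    length of the source sequence.
    """

    id: str
    residues: str
    src_start: Optional[int] = None
    src_strand: Optional[str] = None
    src_size: Optional[int] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty residue string")
        if self.src_size is not None and self.ungapped_length > self.src_size:
            raise ValueError(f"{self.id}: ungapped length exceeds srcSize")

    @property
    def ungapped_length(self):
        return len(self.residues) - self.residues.count("-")

    @property
    def species(self):
        return self.id.split(".", 1)[0]

    @property
    def anchored(self):
        return self.src_start is not None and self.src_strand is not None

    @property
    def chrom(self):
        parts = self.id.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]


class Alignment:
    """An ordered stack of equal-length gapped sequences."""

    def __init__(self, sequences, reference_index=None):
        sequences = list(sequences)
        if not sequences:
            raise FormatError("alignment with no sequences")
        n_cols = len(sequences[0].residues)
        for s in sequences:
            if len(s.residues) != n_cols:
                raise FormatError(f"ragged alignment: row {s.id}")
        ids = [s.id for s in sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        self.sequences = sequences
        self.n_cols = n_cols
        self.reference_index = reference_index
        self._codes = None

    @classmethod
    def from_strings(cls, pairs, reference_index=None):
        """Build from (id, residues) pairs; residues are normalised."""
        seqs = [AlignedSequence(i, ab.normalize(r)) for i, r in pairs]
        return cls(seqs, reference_index=reference_index)

    @property
    def n_seqs(self):
        return len(self.sequences)

    @property
    def ids(self):
        return [s.id for s in self.sequences]

    @property
    def reference(self):
        if self.reference_index is None:
            raise ValueError("alignment has no designated reference row")
        return self.sequences[self.reference_index]

    def encoded(self):
        """(n_seqs, n_cols) int8 matrix over the internal alphabet."""
        if self._codes is None:
            self._codes = np.vstack([ab.encode(s.residues) for s in self.sequences])
        return self._codes

    def slice_columns(self, start, stop):
        """Column window [start, stop); genome anchors are re-derived."""
        seqs = []
        for s in self.sequences:
            text = s.residues[start:stop]
            if s.anchored:
                prefix = s.residues[:start]
                offset = len(prefix) - prefix.count("-")
                seqs.append(
                    AlignedSequence(s.id, text, s.src_start + offset, s.src_strand, s.src_size)
                )
            else:
                seqs.append(AlignedSequence(s.id, text))
        return Alignment(seqs, reference_index=self.reference_index)

    def take_rows(self, indices):
        indices = list(indices)
        ref = None
        if self.reference_index is not None and self.reference_index in indices:
            ref = indices.index(self.reference_index)
        return Alignment([self.sequences[i] for i in indices], reference_index=ref)

    def reverse_complement(self):
        """Reverse-complement every row; anchors keep MAF strand semantics
        (start re-expressed on the opposite strand)."""
        seqs = []
        for s in self.sequences:
            text = ab.reverse_complement(s.residues)
            if s.anchored and s.src_size is not None:
                new_start = s.src_size - (s.src_start + s.ungapped_length)
                strand = "-" if s.src_strand == "+" else "+"
                seqs.append(AlignedSequence(s.id, text, new_start, strand, s.src_size))
            else:
                seqs.append(AlignedSequence(s.id, text))
        return Alignment(seqs, reference_index=self.reference_index)

    def __repr__(self):
        return f"Alignment({self.n_seqs} seqs x {self.n_cols} cols)"


@dataclass
class StructuredFamily:
    """An alignment with a consensus secondary-structure annotation."""

    alignment: Alignment
    ss_cons: SecondaryStructure
    id: str = ""

    def __post_init__(self):
        if self.ss_cons.length != self.alignment.n_cols:
            raise FormatError("SS_cons length does not match the alignment")


# ---------------------------------------------------------------------------
# readers

def _norm_or_raise(text, where):
    try:
        return ab.normalize(text)
    except ValueError as exc:
        raise FormatError(f"{where}: {exc}") from exc


def read_maf(stream):
    """Parse a MAF file into genome-anchored alignments, one per block.

    Per-species duplicate rows (segmental duplications) are resolved by
    keeping the first-listed row per species.  "e"/"i"/"q" lines are
    ignored by the underlying parser.
    """
    out = []
    try:
        blocks = list(AlignIO.parse(stream, "maf"))
    except ValueError as exc:
        raise FormatError(f"malformed MAF: {exc}") from exc
    for b_idx, block in enumerate(blocks):
        seqs = []
        seen_species = set()
        for rec in block:
            species = rec.id.split(".", 1)[0]
            if species in seen_species:
                continue
            seen_species.add(species)
            text = _norm_or_raise(str(rec.seq), f"MAF block {b_idx}, row {rec.id}")
            size = rec.annotations["size"]
            ungapped = len(text) - text.count("-")
            if ungapped != size:
                raise FormatError(
                    f"MAF block {b_idx}, row {rec.id}: size {size} != "
                    f"{ungapped} ungapped residues"
                )
            strand = "+" if rec.annotations["strand"] == 1 else "-"
            seqs.append(
                AlignedSequence(
                    rec.id, text, rec.annotations["start"], strand,
                    rec.annotations["srcSize"],
                )
            )
        lengths = {len(s.residues) for s in seqs}
        if len(lengths) > 1:
            raise FormatError(f"MAF block {b_idx}: unequal row lengths")
        out.append(Alignment(seqs))
    return out


def read_fasta_alignment(stream):
    """Aligned FASTA -> Alignment (no genome anchoring)."""
    records = list(AlignIO.read(stream, "fasta")) if _peek_nonempty(stream) else []
    if not records:
        raise FormatError("empty FASTA alignment")
    seqs = [
        AlignedSequence(rec.id, _norm_or_raise(str(rec.seq), rec.id))
        for rec in records
    ]
    return Alignment(seqs)


def _peek_nonempty(stream):
    pos = stream.tell()
    chunk = stream.read(1)
    stream.seek(pos)
    return bool(chunk)


_WUSS_OPEN = set("<([{")
_WUSS_CLOSE = set(">)]}")


def reduce_wuss(wuss):
    """WUSS -> plain dot-bracket: every bracket family maps to "()";
    pseudoknot letters and unpaired glyphs map to '.'."""
    out = []
    for ch in wuss:
        if ch in _WUSS_OPEN:
            out.append("(")
        elif ch in _WUSS_CLOSE:
            out.append(")")
        else:
            out.append(".")
    return "".join(out)


def read_stockholm(stream, family_id=""):
    """Single-alignment Stockholm with a #=GC SS_cons line -> StructuredFamily."""
    try:
        block = AlignIO.read(stream, "stockholm")
    except ValueError as exc:
        raise FormatError(f"malformed Stockholm: {exc}") from exc
    ss = block.column_annotations.get("secondary_structure")
    if ss is None:
        raise FormatError("Stockholm alignment lacks an SS_cons annotation")
    seqs = [
        AlignedSequence(rec.id, _norm_or_raise(str(rec.seq), rec.id))
        for rec in block
    ]
    aln = Alignment(seqs)
    db = reduce_wuss(ss)
    try:
        ss_cons = SecondaryStructure.from_dot_bracket(db)
    except ValueError as exc:
        raise FormatError(f"bad SS_cons after WUSS reduction: {exc}") from exc
    return StructuredFamily(aln, ss_cons, id=family_id)


# ---------------------------------------------------------------------------
# writers

def write_fasta_alignment(aln, stream, as_dna=False, width=70):
    """Write an aligned FASTA; `as_dna` converts U back to T."""
    for s in aln.sequences:
        text = s.residues.replace("U", "T") if as_dna else s.residues
        stream.write(f">{s.id}\n")
        for k in range(0, len(text), width):
            stream.write(text[k : k + width] + "\n")


def write_stockholm(family, stream):
    """Write a StructuredFamily as Stockholm 1.0 with SS_cons."""
    stream.write("# STOCKHOLM 1.0\n")
    if family.id:
        stream.write(f"#=GF ID {family.id}\n")
    width = max(len(s.id) for s in family.alignment.sequences)
    width = max(width, len("#=GC SS_cons"))
    for s in family.alignment.sequences:
        stream.write(f"{s.id:<{width}} {s.residues}\n")
    stream.write(f"{'#=GC SS_cons':<{width}} {family.ss_cons.dot_bracket}\n//\n")


def write_maf(alignments, stream):
    """Write genome-anchored alignments as MAF blocks."""
    stream.write("##maf version=1 scoring=none\n")
    for aln in alignments:
        stream.write("a score=0.0\n")
        for s in aln.sequences:
            if not s.anchored:
                raise ValueError(f"row {s.id} is not genome-anchored")
            stream.write(
                f"s {s.id} {s.src_start} {s.ungapped_length} {s.src_strand} "
                f"{s.src_size} {s.residues}\n"
            )
        stream.write("\n")


def _bed_score(pred):
    """BED requires an integer score; map |z|/10 (z modes) or p (probability
    mode) onto 0-1000, keeping the raw score in the name field."""
    if pred.score is None:
        return 0
    if pred.mode == "highmpi":
        return int(round(1000 * min(1.0, max(0.0, pred.score))))
    return int(round(1000 * min(1.0, abs(pred.score) / 10.0)))


def write_bed(predictions, stream):
    """Write genome-anchored predictions as BED6 (0-based half-open).

    The name field encodes "mode|MPI|MPI_SD|H|GC|gap|raw_score".  Returns
    the number of rows written.  Overlapping predictions are written as-is
    (clustering is a separate step).
    """
    n = 0
    for p in predictions:
        if p.chrom is None or p.genome_start is None or p.genome_end is None:
            raise ValueError("prediction is not genome-anchored")
        st = p.stats
        name = (
            f"{p.mode}|{st.mpi:.1f}|{st.mpi_sd:.1f}|{st.shannon:.3f}|"
            f"{st.gc:.1f}|{st.gap:.1f}|"
            + ("NA" if p.score is None else f"{p.score:.4f}")
        )
        stream.write(
            f"{p.chrom}\t{p.genome_start}\t{p.genome_end}\t{name}\t"
            f"{_bed_score(p)}\t{p.strand}\n"
        )
        n += 1
    return n
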