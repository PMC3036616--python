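"""In-frame codon alignment container and FASTA I/O.

A :class:`CodonAlignment` holds one gene's haplotype sample from one population:
equal-length in-frame coding sequences, one record per allele, tagged with the
lineage (Type ``A``/``B``) and sampling context (``sympatric``/``allopatric``/
``divergence_panel``).  FASTA headers use the dialect ``alleleID|lineage|context``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import GENETIC_CODE, NUCLEOTIDES, STOP

VALID_CHARS = set("ACGTN-")
LINEAGES = ("A", "B")
CONTEXTS = ("sympatric", "allopatric", "divergence_panel")


class AlignmentValidationError(ValueError):
    """Raised when records violate the codon-alignment invariants."""


@dataclass
class CodonAlignment:
    """A gene's in-frame haplotype sample with lineage and context labels.

    The reading frame starts at position 0; the length must be a multiple of 3;
    no ungapped, unambiguous codon may be a stop.
    """

    gene_name: str
    sequences: list[str]
    ids: list[str]
    lineage: str | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        self.sequences = [s.upper() for s in self.sequences]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.sequences) != len(self.ids):
            raise AlignmentValidationError("ids and sequences differ in number")
        if not self.sequences:
            raise AlignmentValidationError("alignment must contain >= 1 sequence")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentValidationError("allele ids are not unique")
        length = len(self.sequences[0])
        for rid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise AlignmentValidationError(
                    f"record {rid!r}: length {len(seq)} != {length} (ragged alignment)"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentValidationError(
                    f"record {rid!r}: invalid characters {sorted(bad)}"
                )
        if length % 3 != 0:
            raise AlignmentValidationError(
                f"alignment length {length} is not a multiple of 3"
            )
        if self.lineage is not None and self.lineage not in LINEAGES:
            raise AlignmentValidationError(f"unknown lineage {self.lineage!r}")
        if self.context is not None and self.context not in CONTEXTS:
            raise AlignmentValidationError(f"unknown context {self.context!r}")
        for rid, seq in zip(self.ids, self.sequences):
            for k in range(0, length, 3):
                codon = seq[k : k + 3]
                if all(b in NUCLEOTIDES for b in codon) and GENETIC_CODE[codon] == STOP:
                    raise AlignmentValidationError(
                        f"record {rid!r}: stop codon {codon} at nucleotide {k}"
                    )

    # -- basic views --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.sequences[seq_index][3 * codon_index : 3 * codon_index + 3]

    def clean_codon_mask(self) -> np.ndarray:
        """Boolean mask over codon columns where every sequence is unambiguous ACGT.

        All per-site statistics are computed on this region (complete deletion at
        codon granularity), so that total and site-class statistics share one
        denominator set.
        """
        mask = np.ones(self.n_codons, dtype=bool)
        for seq in self.sequences:
            arr = np.frombuffer(seq.encode(), dtype="S1").reshape(-1, 3)
            ok = np.isin(arr, [b"A", b"C", b"G", b"T"]).all(axis=1)
            mask &= ok
        return mask

    def subset(self, indices: Sequence[int]) -> "CodonAlignment":
        return CodonAlignment(
            gene_name=self.gene_name,
            sequences=[self.sequences[i] for i in indices],
            ids=[self.ids[i] for i in indices],
            lineage=self.lineage,
            context=self.context,
        )


# -- FASTA dialect ----------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    parts = header.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1] or None, parts[2] or None
    return parts[0], None, None


def read_fasta(path: str | Path, gene_name: str | None = None) -> CodonAlignment:
    """Read a codon alignment from FASTA with ``id|lineage|context`` headers.

    Lineage/context fields are taken from the first record carrying them; all
    alignment invariants are enforced and violations name the offending record.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    lineage = context = None
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, lin, ctx = _parse_header(rec.id)
        ids.append(rid)
        seqs.append(str(rec.seq).upper())
        lineage = lineage or lin
        context = context or ctx
    if not ids:
        raise AlignmentValidationError(f"{path}: no FASTA records")
    return CodonAlignment(
        gene_name=gene_name or path.stem,
        sequences=seqs,
        ids=ids,
        lineage=lineage,
        context=context,
    )


def write_fasta(alignment: CodonAlignment, path: str | Path) -> None:
    """Write the alignment in the header dialect; read∘write is the identity."""
    records = []
    for rid, seq in zip(alignment.ids, alignment.sequences):
        header = f"{rid}|{alignment.lineage or ''}|{alignment.context or ''}"
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
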