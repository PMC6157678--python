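"""MHC exon-2 allele handling.

Alleles at a class II locus (e.g. DRB1, DQA1, DQA2) are short, pre-aligned,
indel-free exon-2 nucleotide sequences. This module translates them,
collapses synonymous alleles into shared protein classes, and computes
amino-acid Hamming distances, optionally restricted to the putative
antigen-binding sites (ABS) of the peptide-binding groove.

Coordinates are 1-based amino-acid alignment columns in all user-facing
interfaces (ABS masks, error messages).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

from matechoice.errors import (
    AlignmentError,
    ConfigError,
    InvalidSequenceError,
    MateChoiceError,
    PseudogeneError,
)

_VALID_NT = re.compile(r"^[ACGT]+$")


def translate_exon2(nt_seq: str, frame_offset: int = 0) -> str:
    """Translate an exon-2 fragment with the standard nuclear code.

    Parameters
    ----------
    nt_seq
        Nucleotide sequence, A/C/G/T only (case-insensitive). Exon-2
        amplicons may start mid-codon, hence ``frame_offset``.
    frame_offset
        Number of leading bases (0-2) to drop before translating.
        A trailing partial codon is silently dropped.

    Returns
    -------
    str
        Amino-acid sequence of the complete codons.

    Raises
    ------
    InvalidSequenceError
        On characters outside A/C/G/T.
    PseudogeneError
        On an internal stop codon (naming the 0-based codon index).
    """
    if frame_offset not in (0, 1, 2):
        raise ConfigError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = nt_seq.upper()
    if not _VALID_NT.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {bad}")
    coding = seq[frame_offset:]
    if len(coding) < 3:
        raise InvalidSequenceError(
            f"fewer than one complete codon after dropping {frame_offset} bases"
        )
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(table=1))
    stop = aa.find("*")
    if stop != -1:
        raise PseudogeneError(stop)
    return aa


@dataclass(frozen=True)
class Allele:
    """A named exon-2 allele at one MHC locus.

    ``protein_class`` is an integer label shared by alleles whose
    translations are identical (synonymous alleles); ``None`` until
    :func:`assign_protein_classes` has run.
    """

    name: str
    nt_seq: str
    aa_seq: str
    protein_class: int | None = None


@dataclass(frozen=True)
class AbsMask:
    """Antigen-binding-site positions for one locus.

    ``positions`` are 1-based amino-acid alignment columns.
    """

    locus: str
    positions: tuple[int, ...]

    def __post_init__(self):
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        if not pos:
            raise ConfigError(f"empty ABS mask for locus {self.locus}")
        if pos[0] < 1:
            raise ConfigError(f"ABS positions are 1-based; got {pos[0]}")
        object.__setattr__(self, "positions", pos)


@dataclass
class LocusAlleleDb:
    """All known alleles at one locus, plus its optional ABS mask.

    All amino-acid sequences at a locus must have equal length: exon-2
    class II alleles are length-conserved and input is assumed
    pre-aligned without indels.
    """

    locus: str
    alleles: dict[str, Allele] = field(default_factory=dict)
    mask: AbsMask | None = None

    def __post_init__(self):
        self._check_lengths()

    def _check_lengths(self):
        lengths = {len(a.aa_seq) for a in self.alleles.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus}: unequal aa lengths {sorted(lengths)}; "
                "alleles must be pre-aligned and indel-free"
            )
        if self.mask is not None and lengths:
            L = lengths.pop()
            if self.mask.positions[-1] > L:
                raise ConfigError(
                    f"locus {self.locus}: ABS position {self.mask.positions[-1]} "
                    f"exceeds aa length {L}"
                )

    @property
    def aa_length(self) -> int:
        if not self.alleles:
            raise MateChoiceError(f"locus {self.locus} has no alleles")
        return len(next(iter(self.alleles.values())).aa_seq)

    def get(self, name: str) -> Allele:
        try:
            return self.alleles[name]
        except KeyError:
            raise KeyError(f"unknown allele {name!r} at locus {self.locus}") from None

    def n_protein_classes(self) -> int:
        classes = {a.protein_class for a in self.alleles.values()}
        if None in classes:
            raise MateChoiceError(
                f"locus {self.locus}: protein classes not assigned"
            )
        return len(classes)


def assign_protein_classes(db: LocusAlleleDb) -> LocusAlleleDb:
    """Label alleles with protein classes, collapsing synonymous alleles.

    Classes are numbered 1..K in order of first appearance (insertion
    order of the allele dict); alleles with identical amino-acid
    sequences share a class. Returns a new db; the input is untouched.
    """
    seen: dict[str, int] = {}
    out: dict[str, Allele] = {}
    for name, allele in db.alleles.items():
        if not allele.aa_seq:
            raise MateChoiceError(f"allele {name} has no translation")
        cls = seen.setdefault(allele.aa_seq, len(seen) + 1)
        out[name] = replace(allele, protein_class=cls)
    return LocusAlleleDb(locus=db.locus, alleles=out, mask=db.mask)


def aa_distance(aa_a: str, aa_b: str, mask: AbsMask | None = None) -> int:
    """Hamming distance between two equal-length amino-acid strings.

    With a mask, only the masked 1-based columns are compared; the
    masked distance can therefore never exceed the unmasked one.
    """
    if len(aa_a) != len(aa_b):
        raise AlignmentError(
            f"unequal sequence lengths {len(aa_a)} vs {len(aa_b)}"
        )
    if mask is not None:
        if mask.positions[-1] > len(aa_a):
            raise AlignmentError(
                f"mask position {mask.positions[-1]} beyond length {len(aa_a)}"
            )
        return sum(1 for p in mask.positions if aa_a[p - 1] != aa_b[p - 1])
    return sum(1 for x, y in zip(aa_a, aa_b) if x != y)


def read_allele_fasta(
    path,
    locus: str,
    frame_offset: int = 0,
    abs_positions: list[int] | None = None,
) -> LocusAlleleDb:
    """Load one locus's alleles from FASTA.

    Record ids are ``Locus*AlleleName`` (e.g. ``DRB1*01``); the part
    before the first ``*`` must match ``locus`` case-insensitively. Ids
    without a ``*`` are taken as bare allele names. Translation and
    protein-class assignment happen on load.
    """
    alleles: dict[str, Allele] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if "*" in rid:
            rec_locus, _, name = rid.partition("*")
            if rec_locus.upper() != locus.upper():
                raise ConfigError(
                    f"record {rid!r} does not belong to locus {locus!r}"
                )
        else:
            name = rid
        if name in alleles:
            raise ConfigError(f"duplicate allele name {name!r} at locus {locus}")
        nt = str(rec.seq).upper()
        aa = translate_exon2(nt, frame_offset)
        alleles[name] = Allele(name=name, nt_seq=nt, aa_seq=aa)
    mask = AbsMask(locus, tuple(abs_positions)) if abs_positions else None
    return assign_protein_classes(LocusAlleleDb(locus=locus, alleles=alleles, mask=mask))
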