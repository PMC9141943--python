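"""Reference locus model and sequence-level utilities.

The screening target is a single bacterial gene locus (the *L. crispatus*
amylopullulanase gene and its flanks).  This module holds the coordinate
system every downstream module works in: 1-based, inclusive intervals, with
the protein-coding sequence (CDS) given as a closed interval on the locus.
It also provides the small sequence primitives the screen needs: IUPAC
degenerate-motif scanning (used for the catabolite-responsive-element site
upstream of the gene), reverse-complement palindrome testing, and the
primer/amplicon arithmetic used to predict PCR product sizes around the
gene start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC",
    "InvalidMotifError",
    "InvalidSequenceError",
    "Locus",
    "MotifHit",
    "CRE_MOTIF",
    "revcomp",
    "scan_motif",
    "is_palindromic",
    "amplicon_size",
    "cds_coordinate",
]

#: IUPAC nucleotide codes and their expansion sets.
IUPAC: dict[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Consensus catabolite-responsive-element (cre) motif.
CRE_MOTIF = "TGWAANCGNTNWCA"

_STOPS = {"TAA", "TAG", "TGA"}


class InvalidMotifError(ValueError):
    """Motif contains a character that is not an IUPAC nucleotide code."""


class InvalidSequenceError(ValueError):
    """Subject sequence contains a character outside {A, C, G, T}."""


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(seq: str) -> None:
    if not set(seq) <= {"A", "C", "G", "T"}:
        bad = sorted(set(seq) - {"A", "C", "G", "T"})
        raise InvalidSequenceError(f"non-ACGT character(s) in sequence: {bad}")


@dataclass(frozen=True)
class Locus:
    """A reference gene locus with its coding interval and named features.

    Coordinates are 1-based and inclusive throughout.  ``features`` maps
    feature names (e.g. ``signal_peptide``, ``cre_site``) to (start, end)
    intervals in locus coordinates.
    """

    id: str
    seq: str
    cds_start: int
    cds_end: int
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_acgt(self.seq)
        if not (1 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"CDS interval [{self.cds_start}, {self.cds_end}] out of bounds "
                f"for locus of length {len(self.seq)}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length is not a multiple of 3")
        for name, (s, e) in self.features.items():
            if not (1 <= s <= e <= len(self.seq)):
                raise ValueError(f"feature {name!r} interval ({s}, {e}) out of bounds")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start - 1 : self.cds_end]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def translate_cds(self) -> str:
        """Translate the CDS (bacterial table), including the terminal '*'."""
        return str(Seq(self.cds_seq).translate(table=11))

    # ---- I/O ------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write([SeqRecord(Seq(self.seq), id=self.id, description="")], str(path), "fasta")

    def gene_model_dict(self) -> dict:
        return {
            "id": self.id,
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "features": {k: list(v) for k, v in self.features.items()},
        }

    def to_gene_model_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.gene_model_dict(), indent=2) + "\n")

    def to_features_bed(self, path: str | Path) -> None:
        """Write CDS + features as BED (0-based half-open on write)."""
        lines = [f"{self.id}\t{self.cds_start - 1}\t{self.cds_end}\tCDS"]
        for name, (s, e) in sorted(self.features.items()):
            lines.append(f"{self.id}\t{s - 1}\t{e}\t{name}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_fasta(cls, fasta: str | Path, gene_model: str | Path) -> "Locus":
        """Load from a FASTA sequence plus a JSON gene model or BED file.

        JSON sidecars carry 1-based inclusive fields; BED intervals are
        0-based half-open and converted on read (the CDS is the record
        named ``CDS``).
        """
        record = next(SeqIO.parse(str(fasta), "fasta"))
        seq = str(record.seq).upper()
        gene_model = Path(gene_model)
        if gene_model.suffix == ".json":
            model = json.loads(gene_model.read_text())
            return cls(
                id=model.get("id", record.id),
                seq=seq,
                cds_start=model["cds_start"],
                cds_end=model["cds_end"],
                features={k: tuple(v) for k, v in model.get("features", {}).items()},
            )
        cds = None
        features: dict[str, tuple[int, int]] = {}
        for line in gene_model.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start0, end0, name = line.split("\t")[:4]
            interval = (int(start0) + 1, int(end0))
            if name == "CDS":
                cds = interval
            else:
                features[name] = interval
        if cds is None:
            raise ValueError(f"no CDS record in gene model {gene_model}")
        return cls(id=record.id, seq=seq, cds_start=cds[0], cds_end=cds[1], features=features)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One degenerate-motif match: 1-based forward-strand start, strand, mismatches."""

    position: int
    strand: str
    mismatches: int


def _mismatches(window: str, pattern_sets: list[frozenset[str]], cap: int) -> int:
    """Per-position IUPAC mismatch count, short-circuiting above ``cap``."""
    mm = 0
    for base, allowed in zip(window, pattern_sets):
        if base not in allowed:
            mm += 1
            if mm > cap:
                break
    return mm


def scan_motif(seq: str, motif: str, max_mismatch: int = 0) -> list[MotifHit]:
    """Scan both strands of ``seq`` for IUPAC-degenerate ``motif`` matches.

    A window matches when the number of positions whose base is outside the
    motif character's expansion set is at most ``max_mismatch``.  Hits are
    reported in forward-strand coordinates (1-based start of the window),
    sorted by position then strand.  When a window is its own reverse
    complement the forward- and reverse-strand hits are the same physical
    site; only the forward-strand hit is reported.
    """
    motif = motif.upper()
    if not motif or not set(motif) <= set(IUPAC):
        bad = sorted(set(motif) - set(IUPAC))
        raise InvalidMotifError(f"invalid IUPAC code(s) in motif: {bad or 'empty motif'}")
    seq = seq.upper()
    _check_acgt(seq)
    if len(motif) > len(seq):
        return []

    fwd = [IUPAC[c] for c in motif]
    rev = [IUPAC[c] for c in revcomp(motif)]
    hits: list[MotifHit] = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        mm = _mismatches(window, fwd, max_mismatch)
        fwd_hit = mm <= max_mismatch
        if fwd_hit:
            hits.append(MotifHit(i + 1, "+", mm))
        # A reverse-strand hit at this window means revcomp(window) matches
        # the motif, i.e. the window matches the reverse-complemented pattern.
        mm_rc = _mismatches(window, rev, max_mismatch)
        if mm_rc <= max_mismatch:
            if fwd_hit and window == revcomp(window):
                continue  # self-reverse-complement site: one physical hit
            hits.append(MotifHit(i + 1, "-", mm_rc))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def is_palindromic(seq: str) -> bool:
    """True iff ``seq`` equals its own reverse complement.

    Odd-length sequences return False (the middle base would have to be its
    own complement, which no DNA base is).
    """
    seq = seq.upper()
    _check_acgt(seq)
    if len(seq) % 2 == 1:
        return False
    return seq == revcomp(seq)


def amplicon_size(upstream_offset: int, downstream_end: int) -> int:
    """Predicted PCR product size from primer offsets around the gene start.

    ``upstream_offset`` is how many bp upstream of the CDS start the forward
    primer's 5' end anneals; ``downstream_end`` is the locus position of the
    reverse primer's 3'-most base, counted downstream of the CDS start.  The
    product spans both, so its length is simply their sum.
    """
    if upstream_offset < 0 or downstream_end < 0:
        raise ValueError("primer offsets must be non-negative")
    return upstream_offset + downstream_end


def cds_coordinate(locus: Locus, pos: int) -> tuple[str, int | None, int | None]:
    """Map a locus position to (region, codon_index, codon_offset).

    ``region`` is ``upstream``, ``CDS`` or ``downstream``; within the CDS,
    ``codon_index`` is the 1-based codon number and ``codon_offset`` the
    1-based position within the codon.
    """
    if not (1 <= pos <= len(locus)):
        raise ValueError(f"position {pos} outside locus of length {len(locus)}")
    if pos < locus.cds_start:
        return ("upstream", None, None)
    if pos > locus.cds_end:
        return ("downstream", None, None)
    off = pos - locus.cds_start
    return ("CDS", off // 3 + 1, off % 3 + 1)
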