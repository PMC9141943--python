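"""Single-target read alignment: seed-and-extend local alignment with SAM I/O.

The screen only ever maps reads against one reference gene locus (and,
for clipped-tail classification, a handful of transposase representatives),
so a general-purpose mapper is replaced by a dependency-light seed-and-extend
aligner: exact k-mer seeding on the forward strand (reverse-strand queries
are reverse-complemented), then exact affine-gap Smith-Waterman on a
reference window around each seeded diagonal band.  Alignment is local:
read ends that do not belong to the best local alignment are reported as
soft clips, which is exactly the evidence the structural-variant stage
consumes at insertion/deletion junctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from . import _swkernel
from .locusmodel import Locus, revcomp

__all__ = [
    "AlignerParams",
    "AlignedRead",
    "index_reference",
    "align_read",
    "align_reads",
    "write_sam",
    "read_sam",
]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; anything else as 4 (never matches)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignerParams:
    """Seeding and scoring parameters.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``band_width``
    pads the reference window around the seeded diagonals and must be at
    least the largest indel expected within a single read.  Alignments
    scoring below ``min_report_score`` are reported unmapped; terminal soft
    clips shorter than ``min_softclip_report`` are ignored by downstream
    breakpoint evidence.
    """

    seed_k: int = 15
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    band_width: int = 32
    min_report_score: int = 40
    min_softclip_report: int = 10
    full_dp_max_ref: int = 20000  # seedless fallback cap (single-locus scale)

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")


@dataclass(frozen=True)
class AlignedRead:
    """A read placement on the locus.

    ``cigar`` is a tuple of (op, length) runs over {M, I, D, S}; ``seq`` is
    stored in reference orientation (reverse-complemented for '-' strand
    alignments, SAM convention).  ``ref_start`` is the 1-based locus
    position of the first aligned base (0 when unmapped).
    """

    read_id: str
    seq: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    strand: str
    edit_distance: int
    mapped: bool
    score: int

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        """1-based inclusive locus position of the last aligned base."""
        return self.ref_start + self.ref_span - 1

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def left_clip_seq(self) -> str:
        return self.seq[: self.left_clip]

    @property
    def right_clip_seq(self) -> str:
        return self.seq[len(self.seq) - self.right_clip :]


def index_reference(locus_seq: str, seed_k: int = 15) -> dict[str, list[int]]:
    """Exact k-mer index: k-mer -> 1-based forward-strand start positions."""
    if len(locus_seq) < seed_k:
        raise ValueError("reference shorter than seed length")
    index: dict[str, list[int]] = {}
    for i in range(len(locus_seq) - seed_k + 1):
        index.setdefault(locus_seq[i : i + seed_k], []).append(i + 1)
    return index


def _merge_runs(ops: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return tuple(merged)


def _left_align_indels(cigar: list[tuple[str, int]], query: str, ref: str,
                       ref_start0: int) -> tuple[tuple[str, int], ...]:
    """Shift I/D runs left within repeats for stable variant coordinates.

    A deletion may shift left one base when the reference base entering the
    deleted block equals the base leaving it; likewise for insertions on the
    query.  Only score-neutral shifts (through a preceding M run) are made.
    """
    changed = True
    while changed:
        changed = False
        qpos = 0
        rpos = ref_start0
        for idx, (op, n) in enumerate(cigar):
            if op in ("I", "D") and idx > 0 and cigar[idx - 1][0] == "M":
                # qpos/rpos point at the start of this run; keep >= 1 aligned
                # base before the indel so the alignment never leads with I/D
                shift = 0
                max_shift = cigar[idx - 1][1] - 1
                if op == "D":
                    while (shift < max_shift
                           and ref[rpos - shift - 1] == ref[rpos + n - shift - 1]):
                        shift += 1
                else:
                    while (shift < max_shift
                           and query[qpos - shift - 1] == query[qpos + n - shift - 1]):
                        shift += 1
                if shift:
                    cigar[idx - 1] = ("M", cigar[idx - 1][1] - shift)
                    if idx + 1 < len(cigar) and cigar[idx + 1][0] == "M":
                        cigar[idx + 1] = ("M", cigar[idx + 1][1] + shift)
                    else:
                        cigar.insert(idx + 1, ("M", shift))
                    cigar[:] = [c for c in _merge_runs(cigar)]
                    changed = True
                    break
            if op in ("M", "S", "I"):
                qpos += n
            if op in ("M", "D"):
                rpos += n
    return _merge_runs(cigar)


def _edit_distance(cigar: Iterable[tuple[str, int]], query: str, ref: str,
                   ref_start0: int) -> int:
    nm = 0
    qpos = 0
    rpos = ref_start0
    for op, n in cigar:
        if op == "M":
            nm += sum(1 for a, b in zip(query[qpos : qpos + n],
                                        ref[rpos : rpos + n]) if a != b)
            qpos += n
            rpos += n
        elif op == "I":
            nm += n
            qpos += n
        elif op == "D":
            nm += n
            rpos += n
        else:  # S
            qpos += n
    return nm


def _candidate_windows(q: str, index: dict[str, list[int]],
                       ref_len: int, params: AlignerParams) -> list[tuple[int, int]]:
    k = params.seed_k
    diags: set[int] = set()
    for i in range(0, len(q) - k + 1):
        for p in index.get(q[i : i + k], ()):
            diags.add((p - 1) - i)
    if not diags:
        return []
    ordered = sorted(diags)
    groups: list[list[int]] = [[ordered[0]]]
    for d in ordered[1:]:
        if d - groups[-1][-1] <= params.band_width:
            groups[-1].append(d)
        else:
            groups.append([d])
    windows = []
    for g in groups:
        start = max(0, g[0] - params.band_width)
        end = min(ref_len, g[-1] + len(q) + params.band_width)
        windows.append((start, end))
    return windows


def _unmapped(read_id: str, seq: str) -> AlignedRead:
    return AlignedRead(read_id=read_id, seq=seq, ref_start=0, cigar=(),
                       strand="+", edit_distance=0, mapped=False, score=0)


def align_read(read_id: str, seq: str, index: dict[str, list[int]],
               locus_seq: str, params: AlignerParams = AlignerParams(),
               ref_codes: np.ndarray | None = None) -> AlignedRead:
    """Best local placement of one read on the reference.

    Both strands are seeded; each seeded diagonal band is resolved by exact
    affine-gap local alignment on the padded reference window, and the best
    score wins (ties: lowest ``ref_start``, then '+' strand).  If neither
    strand seeds at all and the reference is small, a full-matrix alignment
    is attempted before declaring the read unmapped.
    """
    if ref_codes is None:
        ref_codes = encode(locus_seq)
    best: tuple[int, int, int] | None = None  # (-score, ref_start0, strand_idx)
    best_payload = None
    queries = (seq, revcomp(seq))
    windows = [_candidate_windows(q, index, len(locus_seq), params) for q in queries]
    if not windows[0] and not windows[1] and len(locus_seq) <= params.full_dp_max_ref:
        windows = [[(0, len(locus_seq))], [(0, len(locus_seq))]]
    for strand_idx, (q, wins) in enumerate(zip(queries, windows)):
        if not wins:
            continue
        q_codes = encode(q)
        for wstart, wend in wins:
            score, q0, q1, t0, t1, ops = _swkernel.sw_align(
                q_codes, ref_codes[wstart:wend], params.match, params.mismatch,
                params.gap_open, params.gap_extend)
            if score <= 0:
                continue
            key = (-int(score), wstart + int(t0), strand_idx)
            if best is None or key < best:
                best = key
                best_payload = (q, int(q0), int(q1), wstart + int(t0), ops.copy())
    if best is None or -best[0] < params.min_report_score:
        return _unmapped(read_id, seq)

    score = -best[0]
    strand = "+" if best[2] == 0 else "-"
    q, q0, q1, t0, ops = best_payload
    runs: list[tuple[str, int]] = []
    if q0:
        runs.append(("S", q0))
    opmap = {_swkernel.OP_M: "M", _swkernel.OP_I: "I", _swkernel.OP_D: "D"}
    runs.extend((opmap[int(o)], 1) for o in ops)
    if len(q) - q1:
        runs.append(("S", len(q) - q1))
    cigar = list(_merge_runs(runs))
    cigar = list(_left_align_indels(cigar, q, locus_seq, t0))
    nm = _edit_distance(cigar, q, locus_seq, t0)
    return AlignedRead(read_id=read_id, seq=q, ref_start=t0 + 1,
                       cigar=tuple(cigar), strand=strand,
                       edit_distance=nm, mapped=True, score=score)


def align_reads(reads: Iterable, locus: Locus,
                params: AlignerParams = AlignerParams()) -> list[AlignedRead]:
    """Align an iterable of (id, seq) records (e.g. simcohort ReadRecords)."""
    index = index_reference(locus.seq, params.seed_k)
    ref_codes = encode(locus.seq)
    out = []
    for r in reads:
        rid, seq = (r.id, r.seq) if hasattr(r, "seq") else r
        out.append(align_read(rid, seq, index, locus.seq, params, ref_codes))
    return out


# ---------------------------------------------------------------------------
# SAM I/O (plain-text SAM via pysam)
# ---------------------------------------------------------------------------

_PYSAM_OPS = {"M": 0, "I": 1, "D": 2, "S": 4}
_PYSAM_OPS_REV = {v: k for k, v in _PYSAM_OPS.items()}


def write_sam(alignments: Iterable[AlignedRead], locus: Locus,
              path: str | Path) -> None:
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.id, "LN": len(locus)}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.seq
            if aln.mapped:
                seg.flag = 16 if aln.strand == "-" else 0
                seg.reference_id = 0
                seg.reference_start = aln.ref_start - 1
                seg.mapping_quality = 60
                seg.cigartuples = [(_PYSAM_OPS[op], n) for op, n in aln.cigar]
                seg.set_tag("NM", aln.edit_distance)
                seg.set_tag("AS", aln.score)
            else:
                seg.flag = 4
                seg.mapping_quality = 0
            out.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignedRead], str, int]:
    """Read a SAM file back into AlignedReads; returns (reads, ref name, len)."""
    alns = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_name = fh.references[0] if fh.nreferences else ""
        ref_len = fh.lengths[0] if fh.nreferences else 0
        records = enumerate(fh, start=1)
        lineno = 0
        while True:
            try:
                lineno, seg = next(records, (None, None))
                if seg is None:
                    break
                if seg.is_unmapped:
                    alns.append(_unmapped(seg.query_name, seg.query_sequence or ""))
                    continue
                cigar = tuple((_PYSAM_OPS_REV[op], n) for op, n in seg.cigartuples)
                alns.append(AlignedRead(
                    read_id=seg.query_name,
                    seq=seg.query_sequence or "",
                    ref_start=seg.reference_start + 1,
                    cigar=cigar,
                    strand="-" if seg.is_reverse else "+",
                    edit_distance=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    mapped=True,
                    score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                ))
            except (KeyError, ValueError, OSError) as exc:
                raise ValueError(
                    f"malformed SAM record at or after record "
                    f"{lineno or len(alns) + 1}: {exc}") from exc
    return alns, ref_name, ref_len
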