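"""Structural-variant detection from clipped reads, plus transposase evidence.

Large events do not appear in the pileup: at an insertion or deletion
junction, locally aligned reads stop and their remainders are soft-clipped.
This module clusters clip positions into breakpoints, pairs breakpoints
into insertion/deletion calls, estimates each event's sample frequency as
clipped / (clipped + cleanly spanning) reads at the junction, and then asks
whether the clipped tails (plus reads the locus could not place at all)
match a non-redundant transposase database — the signature of a mobile
element inserted into the gene.

The transposase database is built by greedy incremental clustering at 95%
identity (longest sequence first; identity = matching columns / alignment
columns of a semi-global alignment of the shorter sequence onto the
longer).  A sample supplies transposase-insertion evidence only when more
than ``transposase_read_threshold`` (default 20) of its reads match the
database — and the evidence only ever annotates an independently supported
insertion call, it never creates one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .align import AlignedRead, AlignerParams, align_read, encode, index_reference
from .locusmodel import Locus

__all__ = [
    "SVParams",
    "BreakpointCluster",
    "StructuralVariant",
    "TransposaseDB",
    "TransposaseClassification",
    "pairwise_identity",
    "detect_breakpoints",
    "call_structural_variants",
    "cluster_sequences",
    "classify_clipped_reads",
    "attach_transposase_evidence",
    "write_sv_table",
]


@dataclass(frozen=True)
class SVParams:
    min_sv_support: int = 10        # reads required to report a breakpoint/SV
    cluster_window: int = 5         # bp window for merging clip positions
    transposase_read_threshold: int = 20  # strictly-more-than triggers the flag
    min_tail_length: int = 20       # clipped tails shorter than this cannot re-map
    high_freq_threshold: float = 0.70


@dataclass(frozen=True)
class BreakpointCluster:
    """Clips piling up at one locus position.

    ``side`` is ``right`` when reads align up to ``pos`` and clip after it
    (junction to the right of ``pos``), ``left`` when reads clip before
    ``pos`` and start aligning at it.  ``span_reads`` counts reads aligned
    cleanly across the junction.
    """

    pos: int
    side: str
    clip_reads: int
    span_reads: int
    clip_tails: tuple[str, ...]

    @property
    def frequency(self) -> float:
        total = self.clip_reads + self.span_reads
        return self.clip_reads / total if total else 0.0


@dataclass(frozen=True)
class StructuralVariant:
    type: str                      # insertion | deletion | unresolved
    start: int
    end: int
    support_reads: int
    frequency: float
    clip_tails: tuple[str, ...] = ()
    transposase: tuple[str, int] | None = None

    @property
    def high_frequency(self) -> bool:
        return self.frequency >= 0.70


def _cluster_positions(events: list[tuple[int, str]], window: int
                       ) -> list[tuple[int, list[int]]]:
    """Greedy 1-D clustering: indices of events within ``window`` of a run."""
    if not events:
        return []
    order = sorted(range(len(events)), key=lambda i: events[i][0])
    clusters: list[list[int]] = [[order[0]]]
    for i in order[1:]:
        if events[i][0] - events[clusters[-1][-1]][0] <= window:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    out = []
    for members in clusters:
        modal = Counter(events[i][0] for i in members).most_common()
        modal.sort(key=lambda kv: (-kv[1], kv[0]))
        out.append((modal[0][0], members))
    return out


def detect_breakpoints(alignments: Sequence[AlignedRead], locus: Locus,
                       params: SVParams = SVParams(),
                       min_softclip_report: int = 10) -> list[BreakpointCluster]:
    """Cluster soft-clip positions into supported breakpoints.

    Only clips of at least ``min_softclip_report`` bp count as evidence;
    clusters below ``min_sv_support`` clipped reads are dropped.
    """
    rights: list[tuple[int, str]] = []
    lefts: list[tuple[int, str]] = []
    intervals: list[tuple[int, int]] = []  # cleanly aligned spans per read
    for aln in alignments:
        if not aln.mapped:
            continue
        intervals.append((aln.ref_start, aln.ref_end))
        if aln.right_clip >= min_softclip_report:
            rights.append((aln.ref_end, aln.right_clip_seq))
        if aln.left_clip >= min_softclip_report:
            lefts.append((aln.ref_start, aln.left_clip_seq))

    def spans(junction_left: int) -> int:
        # Reads aligned cleanly across the junction between junction_left
        # and junction_left+1.  Micro-homology at an insertion lets junction
        # reads align a base or two past the true breakpoint, so a spanning
        # read must cover at least min_softclip_report aligned bases on each
        # side — the mirror of the clip-evidence threshold.
        m = min_softclip_report
        return sum(1 for s, e in intervals
                   if s <= junction_left - m + 1 and e >= junction_left + m)

    clusters = []
    for side, events in (("right", rights), ("left", lefts)):
        for modal_pos, members in _cluster_positions(events, params.cluster_window):
            if len(members) < params.min_sv_support:
                continue
            junction_left = modal_pos if side == "right" else modal_pos - 1
            clusters.append(BreakpointCluster(
                pos=modal_pos, side=side, clip_reads=len(members),
                span_reads=spans(junction_left),
                clip_tails=tuple(events[i][1] for i in members)))
    clusters.sort(key=lambda c: (c.pos, c.side))
    return clusters


def _remap_tails(tails: Sequence[str], locus: Locus,
                 aligner: AlignerParams, params: SVParams,
                 index, ref_codes) -> list[AlignedRead]:
    out = []
    for tail in tails:
        if len(tail) < params.min_tail_length:
            continue
        aln = align_read("tail", tail, index, locus.seq, aligner, ref_codes)
        if aln.mapped:
            out.append(aln)
    return out


def call_structural_variants(clusters: Sequence[BreakpointCluster],
                             locus: Locus,
                             params: SVParams = SVParams(),
                             aligner: AlignerParams = AlignerParams()
                             ) -> list[StructuralVariant]:
    """Pair breakpoint clusters into insertion/deletion calls.

    A right-clip and a left-clip cluster at the same junction make an
    insertion.  A right/left pair whose clipped tails re-map to the locus
    across a gap makes a deletion spanning the gap (frequency averaged over
    the two breakpoints).  Unpaired clusters are reported ``unresolved``.
    """
    index = index_reference(locus.seq, aligner.seed_k)
    ref_codes = encode(locus.seq)
    rights = [c for c in clusters if c.side == "right"]
    lefts = [c for c in clusters if c.side == "left"]
    used: set[int] = set()
    svs: list[StructuralVariant] = []

    for r in rights:
        # deletion: right-clip tails should land at a distal left cluster
        remapped = _remap_tails(r.clip_tails, locus, aligner, params,
                                index, ref_codes)
        landing = Counter(a.ref_start for a in remapped
                          if a.ref_start - r.pos > params.cluster_window)
        paired = False
        if landing:
            target = landing.most_common(1)[0][0]
            for li, l in enumerate(lefts):
                if li in used or abs(l.pos - target) > params.cluster_window:
                    continue
                used.add(li)
                svs.append(StructuralVariant(
                    type="deletion", start=r.pos + 1, end=l.pos - 1,
                    support_reads=r.clip_reads + l.clip_reads,
                    frequency=(r.frequency + l.frequency) / 2,
                    clip_tails=r.clip_tails + l.clip_tails))
                paired = True
                break
        if paired:
            continue
        # insertion: matching left cluster at the same junction
        for li, l in enumerate(lefts):
            if li in used or abs(l.pos - (r.pos + 1)) > params.cluster_window:
                continue
            used.add(li)
            svs.append(StructuralVariant(
                type="insertion", start=r.pos, end=r.pos,
                support_reads=r.clip_reads + l.clip_reads,
                frequency=(r.frequency + l.frequency) / 2,
                clip_tails=r.clip_tails + l.clip_tails))
            paired = True
            break
        if not paired:
            svs.append(StructuralVariant(
                type="unresolved", start=r.pos, end=r.pos,
                support_reads=r.clip_reads, frequency=r.frequency,
                clip_tails=r.clip_tails))
    for li, l in enumerate(lefts):
        if li not in used:
            svs.append(StructuralVariant(
                type="unresolved", start=l.pos, end=l.pos,
                support_reads=l.clip_reads, frequency=l.frequency,
                clip_tails=l.clip_tails))
    svs.sort(key=lambda s: (s.start, s.type))
    return svs


# ---------------------------------------------------------------------------
# Transposase database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransposaseDB:
    representatives: Mapping[str, str]   # id -> sequence
    cluster_map: Mapping[str, str]       # member id -> representative id
    identity_threshold: float = 0.95


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned onto the longer.

    Semi-global alignment (end gaps on the longer sequence are free);
    identity = matching columns / alignment columns.
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    matches = columns - res["editDistance"]
    return matches / columns if columns else 0.0


def cluster_sequences(seqs: Mapping[str, str],
                      identity_threshold: float = 0.95) -> TransposaseDB:
    """Greedy incremental clustering into a non-redundant database.

    Sequences are processed longest first (ties broken by id); each joins
    the first existing representative it matches at >= the identity
    threshold, else founds a new cluster.  Deterministic.
    """
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: dict[str, str] = {}
    cluster_map: dict[str, str] = {}
    for name in order:
        seq = seqs[name]
        joined = None
        for rep_id in reps:
            if pairwise_identity(seq, reps[rep_id]) >= identity_threshold:
                joined = rep_id
                break
        if joined is None:
            reps[name] = seq
            joined = name
        cluster_map[name] = joined
    return TransposaseDB(representatives=reps, cluster_map=cluster_map,
                         identity_threshold=identity_threshold)


def write_transposase_db(db: TransposaseDB, fasta_path: str | Path,
                         map_path: str | Path) -> None:
    from .simcohort import write_fasta
    write_fasta(dict(db.representatives), fasta_path)
    lines = ["member\trepresentative"]
    lines += [f"{m}\t{r}" for m, r in sorted(db.cluster_map.items())]
    Path(map_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Clipped-read classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransposaseClassification:
    per_element: Mapping[str, int]
    total: int
    flag: bool  # True iff total is STRICTLY greater than the threshold


def classify_clipped_reads(sequences: Iterable[str], db: TransposaseDB,
                           params: SVParams = SVParams(),
                           aligner: AlignerParams = AlignerParams()
                           ) -> TransposaseClassification:
    """Count clipped tails / unmapped reads matching the transposase database.

    Each sequence is aligned (same aligner, same scoring) against every
    representative and credited to its best-scoring one when the score
    reaches the aligner's reporting threshold.  The per-sample evidence
    flag requires strictly more than ``transposase_read_threshold`` matches.
    """
    counts: Counter[str] = Counter()
    if db.representatives:
        indexes = {rid: (index_reference(rseq, aligner.seed_k), encode(rseq))
                   for rid, rseq in db.representatives.items()}
        for seq in sequences:
            if len(seq) < aligner.seed_k:
                continue
            best_id, best_score, best_start = None, 0, 0
            for rid in sorted(db.representatives):
                idx, codes = indexes[rid]
                aln = align_read("q", seq, idx, db.representatives[rid],
                                 aligner, codes)
                if aln.mapped and (aln.score > best_score
                                   or (aln.score == best_score and best_id is None)):
                    best_id, best_score, best_start = rid, aln.score, aln.ref_start
            if best_id is not None and best_score >= aligner.min_report_score:
                counts[best_id] += 1
    total = sum(counts.values())
    return TransposaseClassification(
        per_element=dict(counts), total=total,
        flag=total > params.transposase_read_threshold)


def attach_transposase_evidence(svs: Sequence[StructuralVariant],
                                classification: TransposaseClassification,
                                db: TransposaseDB,
                                params: SVParams = SVParams(),
                                aligner: AlignerParams = AlignerParams()
                                ) -> list[StructuralVariant]:
    """Annotate flagged insertion SVs with their modal matching element.

    Only insertion calls gain a transposase annotation, and only when the
    sample-level classification flag fired; the element is chosen from the
    SV's own breakpoint tails.
    """
    out = []
    for sv in svs:
        if sv.type != "insertion" or not classification.flag:
            out.append(sv)
            continue
        tails = [t for t in sv.clip_tails if len(t) >= params.min_tail_length]
        local = classify_clipped_reads(tails, db, params, aligner)
        if local.per_element:
            modal = max(local.per_element,
                        key=lambda e: (local.per_element[e], e))
            count = classification.per_element.get(modal,
                                                   local.per_element[modal])
            out.append(replace(sv, transposase=(modal, count)))
        else:
            out.append(sv)
    return out


def write_sv_table(svs_by_sample: Mapping[str, Sequence[StructuralVariant]],
                   path: str | Path) -> None:
    lines = ["sample\ttype\tstart\tend\tsupport_reads\tfrequency"
             "\ttransposase\ttransposase_reads"]
    for sample in sorted(svs_by_sample):
        for sv in svs_by_sample[sample]:
            elem, n = sv.transposase if sv.transposase else ("", "")
            lines.append(f"{sample}\t{sv.type}\t{sv.start}\t{sv.end}"
                         f"\t{sv.support_reads}\t{sv.frequency:.4f}\t{elem}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")
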