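"""Pooled small-variant calling, filtering and codon-aware impact annotation.

The caller treats each sample as a pooled population rather than a diploid
individual: any non-reference allele at a position is emitted with its
continuous allele frequency (alt reads / depth) once it clears three minima
(site depth >= 10, alt reads >= 2, alt fraction >= 0.01).  Across samples,
variants are reported when they reach >= 0.05 allele frequency in at least
three samples.  Per-sample calls are annotated against the gene model:
frameshift or stop-gain/start-loss changes are HIGH impact, amino-acid
changes and in-frame indels MODERATE, synonymous changes LOW, and anything
outside the CDS MODIFIER.  Calls at >= 0.7 allele frequency are flagged as
high-frequency (the disruption evidence used for sample classification).

Before any of this runs, a sample must pass the coverage gate: by default
every CDS position needs depth >= 10 ("full length" coverage of the gene).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from .align import AlignedRead
from .locusmodel import Locus, cds_coordinate

__all__ = [
    "CallingParams",
    "Pileup",
    "PileupColumn",
    "GateResult",
    "VariantObservation",
    "SmallVariant",
    "Impact",
    "normalize_variant",
    "pileup",
    "coverage_gate",
    "call_sample_variants",
    "joint_filter",
    "annotate_impact",
    "high_frequency_flags",
    "write_vcf",
    "read_vcf",
    "write_af_matrix",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"
Impact = str


@dataclass(frozen=True)
class CallingParams:
    """Thresholds for pooled-frequency calling and multi-sample filtering."""

    min_coverage: int = 10
    min_alt_count: int = 2
    min_alt_fraction: float = 0.01
    report_min_af: float = 0.05
    min_prevalence_samples: int = 3
    high_freq_threshold: float = 0.70
    coverage_gate_fraction: float = 1.0  # fraction of CDS positions at depth >= min

    def __post_init__(self) -> None:
        if not (0 <= self.min_alt_fraction <= self.report_min_af
                <= self.high_freq_threshold <= 1):
            raise ValueError(
                "need 0 <= min_alt_fraction <= report_min_af <= high_freq_threshold <= 1")


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    pos: int
    depth: int
    base_counts: Mapping[str, int]
    deletion_obs: Mapping[tuple[int, str, str], int]
    insertion_obs: Mapping[tuple[int, str, str], int]


class Pileup:
    """Per-position depth and allele observations for one sample.

    Soft-clipped bases contribute nothing to any column; deleted positions
    count toward depth (the read covers them informatively).  Indels are
    recorded at their left-anchored, normalized (pos, ref, alt) key.
    """

    def __init__(self, locus: Locus) -> None:
        self.locus = locus
        L = len(locus)
        self.depth = np.zeros(L + 1, dtype=np.int32)
        self.base_counts = np.zeros((4, L + 1), dtype=np.int32)
        self.indel_obs: Counter[tuple[int, str, str]] = Counter()

    def column(self, pos: int) -> PileupColumn:
        dels = {k: v for k, v in self.indel_obs.items()
                if k[0] == pos and len(k[1]) > len(k[2])}
        ins = {k: v for k, v in self.indel_obs.items()
               if k[0] == pos and len(k[1]) < len(k[2])}
        return PileupColumn(
            pos=pos, depth=int(self.depth[pos]),
            base_counts={b: int(self.base_counts[i, pos]) for i, b in enumerate(_BASES)},
            deletion_obs=dels, insertion_obs=ins)


def normalize_variant(pos: int, ref: str, alt: str,
                      ref_seq: str) -> tuple[int, str, str]:
    """Left-align and minimalize a (pos, ref, alt) allele pair (VCF style).

    Shared suffixes are trimmed (extending left with the previous reference
    base when an allele would become empty), then shared prefixes are
    trimmed while keeping at least one base in each allele.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        if pos == 1:
            break
        pos -= 1
        prev = ref_seq[pos - 1]
        ref, alt = prev + ref[:-1], prev + alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    return pos, ref, alt


def pileup(alignments: Iterable[AlignedRead], locus: Locus) -> Pileup:
    p = Pileup(locus)
    enc = {b: i for i, b in enumerate(_BASES)}
    L = len(locus)
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.ref_start + aln.ref_span - 1 > L:
            raise ValueError(
                f"alignment of {aln.read_id} extends past locus end")
        qpos = 0
        rpos = aln.ref_start  # 1-based next reference position
        for op, n in aln.cigar:
            if op == "S":
                qpos += n
            elif op == "M":
                p.depth[rpos : rpos + n] += 1
                for j in range(n):
                    code = enc.get(aln.seq[qpos + j])
                    if code is not None:
                        p.base_counts[code, rpos + j] += 1
                qpos += n
                rpos += n
            elif op == "D":
                p.depth[rpos : rpos + n] += 1
                anchor = rpos - 1
                if anchor >= 1:
                    key = normalize_variant(
                        anchor,
                        locus.seq[anchor - 1 : anchor + n],
                        locus.seq[anchor - 1],
                        locus.seq)
                    p.indel_obs[key] += 1
                rpos += n
            elif op == "I":
                anchor = rpos - 1
                if anchor >= 1:
                    key = normalize_variant(
                        anchor,
                        locus.seq[anchor - 1],
                        locus.seq[anchor - 1] + aln.seq[qpos : qpos + n],
                        locus.seq)
                    p.indel_obs[key] += 1
                qpos += n
    return p


# ---------------------------------------------------------------------------
# Coverage gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateResult:
    included: bool
    fraction_covered: float
    depth_track: np.ndarray  # per-base depth, index 1..len(locus)


def coverage_gate(pile: Pileup, locus: Locus,
                  params: CallingParams = CallingParams()) -> GateResult:
    """Sample inclusion rule: the CDS must be covered at depth >= min_coverage.

    ``coverage_gate_fraction`` sets which fraction of CDS positions must
    reach the minimum (default: all of them — full-length coverage).
    """
    cds_depth = pile.depth[locus.cds_start : locus.cds_end + 1]
    frac = float(np.mean(cds_depth >= params.min_coverage))
    return GateResult(included=frac >= params.coverage_gate_fraction,
                      fraction_covered=frac, depth_track=pile.depth)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantObservation:
    """One sample's evidence for one allele."""

    pos: int
    ref: str
    alt: str
    type: str  # snv | insertion | deletion
    alt_count: int
    depth: int
    impact: Impact | None = None

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "snv"
    return "insertion" if len(alt) > len(ref) else "deletion"


def call_sample_variants(pile: Pileup, locus: Locus,
                         params: CallingParams = CallingParams(),
                         annotate: bool = True) -> list[VariantObservation]:
    """Emit every allele meeting the pooled-calling minima for one sample."""
    out: list[VariantObservation] = []
    enc = {b: i for i, b in enumerate(_BASES)}
    counts = pile.base_counts
    depth = pile.depth
    # SNVs: candidate positions where some non-reference base has >= min count
    ref_codes = np.fromiter((enc[b] for b in locus.seq), dtype=np.int8,
                            count=len(locus))
    nonref = counts[:, 1:].copy()
    nonref[ref_codes, np.arange(len(locus))] = 0
    cand = np.nonzero((nonref >= params.min_alt_count).any(axis=0))[0] + 1
    for pos in cand:
        d = int(depth[pos])
        if d < params.min_coverage:
            continue
        ref_base = locus.seq[pos - 1]
        for i, base in enumerate(_BASES):
            if base == ref_base:
                continue
            c = int(counts[i, pos])
            if c >= params.min_alt_count and c / d >= params.min_alt_fraction:
                out.append(VariantObservation(int(pos), ref_base, base, "snv", c, d))
    # indels (already normalized keys; depth taken at the anchor)
    for (pos, ref, alt), c in sorted(pile.indel_obs.items()):
        d = int(depth[pos])
        if d < params.min_coverage or c < params.min_alt_count:
            continue
        if c / d < params.min_alt_fraction:
            continue
        out.append(VariantObservation(pos, ref, alt, _variant_type(ref, alt), c, d))
    out.sort(key=lambda v: (v.pos, v.ref, v.alt))
    if annotate:
        out = [VariantObservation(v.pos, v.ref, v.alt, v.type, v.alt_count,
                                  v.depth, annotate_impact(v, locus))
               for v in out]
    return out


# ---------------------------------------------------------------------------
# Multi-sample filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmallVariant:
    """A cohort-level variant with per-sample evidence.

    ``per_sample`` maps sample id -> (alt_count, depth); allele frequencies
    are derived.  ``prevalence`` counts samples at af >= report_min_af.
    """

    pos: int
    ref: str
    alt: str
    type: str
    impact: Impact
    per_sample: Mapping[str, tuple[int, int]]
    prevalence: int

    def af(self, sample: str) -> float:
        ac, dp = self.per_sample.get(sample, (0, 0))
        return ac / dp if dp else 0.0

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def joint_filter(observations: Mapping[str, Sequence[VariantObservation]],
                 locus: Locus,
                 params: CallingParams = CallingParams()) -> list[SmallVariant]:
    """Merge per-sample observations and apply the cohort reporting filter.

    A variant is retained iff its allele frequency is >= ``report_min_af``
    in at least ``min_prevalence_samples`` samples; retained records keep
    every sample's evidence, including sub-threshold observations.
    """
    merged: dict[tuple[int, str, str], dict[str, tuple[int, int]]] = {}
    for sample, obs_list in observations.items():
        for v in obs_list:
            merged.setdefault(v.key, {})[sample] = (v.alt_count, v.depth)
    out = []
    for key in sorted(merged):
        per_sample = merged[key]
        prev = sum(1 for ac, dp in per_sample.values()
                   if dp and ac / dp >= params.report_min_af)
        if prev < params.min_prevalence_samples:
            continue
        pos, ref, alt = key
        v = VariantObservation(pos, ref, alt, _variant_type(ref, alt), 0, 0)
        out.append(SmallVariant(pos=pos, ref=ref, alt=alt, type=v.type,
                                impact=annotate_impact(v, locus),
                                per_sample=dict(per_sample), prevalence=prev))
    return out


# ---------------------------------------------------------------------------
# Impact annotation
# ---------------------------------------------------------------------------

def annotate_impact(variant, locus: Locus) -> Impact:
    """Classify a (pos, ref, alt) variant against the gene model.

    HIGH: frameshift indel, stop gain, start or stop codon loss, or an indel
    straddling a CDS boundary.  MODERATE: amino-acid change or in-frame
    indel.  LOW: synonymous SNV.  MODIFIER: entirely outside the CDS.
    """
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    if len(ref) == len(alt) == 1:
        region, codon_idx, codon_off = cds_coordinate(locus, pos)
        if region != "CDS":
            return MODIFIER
        codon_start = locus.cds_start + (codon_idx - 1) * 3
        ref_codon = locus.seq[codon_start - 1 : codon_start + 2]
        alt_codon = (ref_codon[: codon_off - 1] + alt + ref_codon[codon_off:])
        if codon_idx == 1 and alt_codon != "ATG":
            return HIGH  # start loss
        if alt_codon in _STOPS and ref_codon not in _STOPS:
            return HIGH  # stop gain
        if ref_codon in _STOPS and alt_codon not in _STOPS:
            return HIGH  # stop loss
        ref_aa = str(Seq(ref_codon).translate(table=11))
        alt_aa = str(Seq(alt_codon).translate(table=11))
        return LOW if ref_aa == alt_aa else MODERATE
    # indel: the changed bases sit to the right of the left anchor base
    if len(ref) > 1:  # deletion of ref[pos+1 .. pos+len(ref)-1]
        del_start, del_end = pos + 1, pos + len(ref) - 1
        if del_end < locus.cds_start or del_start > locus.cds_end:
            return MODIFIER
        if del_start < locus.cds_start or del_end > locus.cds_end:
            return HIGH  # straddles a CDS boundary
    else:  # insertion between pos and pos+1
        if not (locus.cds_start <= pos < locus.cds_end):
            return MODIFIER
    net = abs(len(ref) - len(alt))
    return HIGH if net % 3 else MODERATE


def high_frequency_flags(variants_by_sample: Mapping[str, Sequence[VariantObservation]],
                         params: CallingParams = CallingParams()
                         ) -> list[tuple[str, VariantObservation]]:
    """(sample, variant) pairs at allele frequency >= the 0.7 threshold."""
    flagged = []
    for sample in sorted(variants_by_sample):
        for v in variants_by_sample[sample]:
            if v.af >= params.high_freq_threshold:
                flagged.append((sample, v))
    return flagged


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _vcf_header(locus: Locus, samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={locus.id},length={len(locus)}>")
    header.add_line('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">')
    header.add_line('##INFO=<ID=IMPACT,Number=1,Type=String,'
                    'Description="Predicted impact on the gene product">')
    header.add_line('##INFO=<ID=PREV,Number=1,Type=Integer,'
                    'Description="Samples with AF above the reporting threshold">')
    header.add_line('##FORMAT=<ID=AO,Number=1,Type=Integer,Description="Alternate observations">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth at site">')
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(variants: Sequence[SmallVariant], locus: Locus,
              path: str | Path) -> None:
    """Write cohort variants as VCF 4.2 (per-sample AO/DP; AF derivable)."""
    samples = sorted({s for v in variants for s in v.per_sample})
    header = _vcf_header(locus, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: x.key):
            rec = out.new_record(contig=locus.id, start=v.pos - 1,
                                 stop=v.pos - 1 + len(v.ref),
                                 alleles=(v.ref, v.alt))
            rec.info["TYPE"] = v.type
            rec.info["IMPACT"] = v.impact
            rec.info["PREV"] = v.prevalence
            for s in samples:
                ac, dp = v.per_sample.get(s, (0, 0))
                rec.samples[s]["AO"] = ac
                rec.samples[s]["DP"] = dp
            out.write(rec)


def read_vcf(path: str | Path) -> list[SmallVariant]:
    out = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            per_sample = {}
            for s in rec.samples:
                ac = rec.samples[s]["AO"]
                dp = rec.samples[s]["DP"]
                if dp:
                    per_sample[s] = (int(ac), int(dp))
            out.append(SmallVariant(
                pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                type=rec.info["TYPE"], impact=rec.info["IMPACT"],
                per_sample=per_sample, prevalence=int(rec.info["PREV"])))
    return out


def write_af_matrix(variants: Sequence[SmallVariant], path: str | Path) -> None:
    """Variant-by-sample allele-frequency matrix (TSV)."""
    samples = sorted({s for v in variants for s in v.per_sample})
    lines = ["variant\timpact\t" + "\t".join(samples)]
    for v in sorted(variants, key=lambda x: x.key):
        name = f"{v.pos}:{v.ref}>{v.alt}"
        lines.append(name + f"\t{v.impact}\t"
                     + "\t".join(f"{v.af(s):.4f}" for s in samples))
    Path(path).write_text("\n".join(lines) + "\n")
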