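"""Per-sample disruption calls, cohort summaries, and pipeline orchestration.

A sample's gene copy is called *disrupted* when the dominant strain carries
convincing loss-of-function evidence: a HIGH-impact small variant (frameshift,
stop gain, start loss) at allele frequency >= 0.7, or a structural variant at
frequency >= 0.7.  When the firing structural variant carries transposase
evidence, the mobile-element cause is recorded alongside.  Samples that fail
the coverage gate are reported ``insufficient_coverage`` and excluded from
the prevalence denominator; a sample with several causes still counts once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .align import AlignerParams, align_reads, read_sam, write_sam
from .locusmodel import Locus
from .simcohort import ReadRecord
from .smallvar import (CallingParams, GateResult, HIGH, VariantObservation,
                       call_sample_variants, coverage_gate, joint_filter,
                       pileup, write_af_matrix, write_vcf)
from .svscan import (SVParams, StructuralVariant, TransposaseDB,
                     attach_transposase_evidence, call_structural_variants,
                     classify_clipped_reads, cluster_sequences,
                     detect_breakpoints, write_sv_table)

__all__ = [
    "SampleCall",
    "CohortSummary",
    "GroupSummary",
    "PipelineConfig",
    "classify_sample",
    "summarize_cohort",
    "stratify",
    "run_pipeline",
    "display_percent",
]

INSUFFICIENT = "insufficient_coverage"
INTACT = "intact"
DISRUPTED = "disrupted"


def display_percent(fraction: float) -> int:
    """Whole-percent display rounding, half away from zero (62/270 -> 23)."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    status: str  # insufficient_coverage | intact | disrupted
    causes: tuple[str, ...]
    evidence: tuple[tuple[str, float], ...]  # (event label, frequency)

    def __post_init__(self) -> None:
        if (self.status == DISRUPTED) != bool(self.causes):
            raise ValueError("causes must be non-empty iff status is disrupted")


def classify_sample(sample_id: str, gate: GateResult,
                    variants: Sequence[VariantObservation],
                    svs: Sequence[StructuralVariant],
                    params: CallingParams = CallingParams()) -> SampleCall:
    """Combine small-variant and SV evidence into one disruption call.

    ``variants`` are the sample's own annotated calls; ``svs`` its supported
    structural variants.  Transposase read counts alone never disrupt — they
    only annotate a frequency-qualified insertion call.
    """
    if not gate.included:
        return SampleCall(sample_id, INSUFFICIENT, (), ())
    causes: set[str] = set()
    evidence: list[tuple[str, float]] = []
    hf = params.high_freq_threshold
    for v in variants:
        if v.impact == HIGH and v.af >= hf:
            causes.add("high_impact_small_variant")
            evidence.append((f"{v.pos}:{v.ref}>{v.alt}", round(v.af, 4)))
    for sv in svs:
        if sv.frequency >= hf:
            causes.add("structural_variant")
            label = f"{sv.type}:{sv.start}-{sv.end}"
            if sv.transposase:
                causes.add("transposase_insertion")
                label += f":{sv.transposase[0]}"
            evidence.append((label, round(sv.frequency, 4)))
    status = DISRUPTED if causes else INTACT
    return SampleCall(sample_id, status, tuple(sorted(causes)), tuple(evidence))


@dataclass(frozen=True)
class CohortSummary:
    n_samples_total: int
    n_covered: int
    n_disrupted: int
    cause_counts: Mapping[str, int]

    @property
    def fraction_disrupted(self) -> float:
        return self.n_disrupted / self.n_covered if self.n_covered else 0.0

    @property
    def percent_disrupted(self) -> int:
        return display_percent(self.fraction_disrupted)


def summarize_cohort(calls: Sequence[SampleCall]) -> CohortSummary:
    """Cohort prevalence with union counting (multi-cause samples count once)."""
    if not calls:
        raise ValueError("need at least one sample call")
    covered = [c for c in calls if c.status != INSUFFICIENT]
    disrupted = [c for c in covered if c.status == DISRUPTED]
    cause_counts: dict[str, int] = {}
    for c in disrupted:
        for cause in c.causes:
            cause_counts[cause] = cause_counts.get(cause, 0) + 1
    return CohortSummary(n_samples_total=len(calls), n_covered=len(covered),
                         n_disrupted=len(disrupted), cause_counts=cause_counts)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_covered: int
    n_disrupted: int

    @property
    def fraction(self) -> float:
        return self.n_disrupted / self.n_covered if self.n_covered else 0.0

    @property
    def percent(self) -> int:
        return display_percent(self.fraction)


def stratify(calls: Sequence[SampleCall],
             metadata: Mapping[str, str]) -> list[GroupSummary]:
    """Per-group prevalence rows; samples without a label fall into 'unknown'."""
    groups: dict[str, list[SampleCall]] = {}
    for c in calls:
        if c.status == INSUFFICIENT:
            continue
        groups.setdefault(metadata.get(c.sample_id, "unknown"), []).append(c)
    return [GroupSummary(g, len(members),
                         sum(1 for m in members if m.status == DISRUPTED))
            for g, members in sorted(groups.items())]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs for a full screening run.

    Each sample entry maps an id to either a FASTQ path (reads are aligned)
    or a SAM path (pre-aligned).  The transposase database FASTA is the raw
    (possibly redundant) set; it is clustered at 95% identity on load.
    """

    reference_fasta: str
    gene_model: str
    samples: Mapping[str, Mapping[str, str]]  # id -> {"fastq": ...} | {"sam": ...}
    out_dir: str
    transposase_fasta: str | None = None
    metadata: Mapping[str, str] | None = None
    calling: CallingParams = field(default_factory=CallingParams)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    sv: SVParams = field(default_factory=SVParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            return str(base / p) if p and not Path(p).is_absolute() else p

        samples = {s["id"]: {k: resolve(v) for k, v in s.items() if k != "id"}
                   for s in raw["samples"]}
        meta = raw.get("metadata")
        if isinstance(meta, str):
            meta = {line.split("\t")[0]: line.split("\t")[1]
                    for line in Path(resolve(meta)).read_text().splitlines()
                    if line.strip() and not line.startswith("#")}
        return cls(
            reference_fasta=resolve(raw["reference"]),
            gene_model=resolve(raw["gene_model"]),
            samples=samples,
            out_dir=resolve(raw["out_dir"]),
            transposase_fasta=resolve(raw.get("transposase_db")),
            metadata=meta,
            calling=CallingParams(**raw.get("calling_params", {})),
            aligner=AlignerParams(**raw.get("aligner_params", {})),
            sv=SVParams(**raw.get("sv_params", {})),
        )


@dataclass(frozen=True)
class PipelineResult:
    calls: tuple[SampleCall, ...]
    summary: CohortSummary
    groups: tuple[GroupSummary, ...]
    variants: tuple
    svs_by_sample: Mapping[str, tuple[StructuralVariant, ...]]
    out_dir: Path


def _read_fastq(path: str) -> list[ReadRecord]:
    from Bio import SeqIO
    return [ReadRecord(r.id, str(r.seq).upper())
            for r in SeqIO.parse(path, "fastq")]


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Align -> call small variants -> scan SVs -> classify -> summarize.

    Fully deterministic for fixed inputs; writes per-sample SAMs, the cohort
    VCF and allele-frequency matrix, SV and sample-call tables, the cohort
    summary and a JSON run manifest into ``config.out_dir``.
    """
    for key in ("reference_fasta", "gene_model"):
        p = getattr(config, key)
        if not Path(p).exists():
            raise FileNotFoundError(f"{key} not found: {p}")
    for sid, entry in config.samples.items():
        path = entry.get("fastq") or entry.get("sam")
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"input for sample {sid} not found: {path}")
    if config.transposase_fasta and not Path(config.transposase_fasta).exists():
        raise FileNotFoundError(
            f"transposase database not found: {config.transposase_fasta}")

    out_dir = Path(config.out_dir)
    (out_dir / "sam").mkdir(parents=True, exist_ok=True)
    locus = Locus.from_fasta(config.reference_fasta, config.gene_model)
    db = TransposaseDB({}, {})
    if config.transposase_fasta:
        db = cluster_sequences(_read_fasta(config.transposase_fasta))

    calls: list[SampleCall] = []
    obs_by_sample: dict[str, list[VariantObservation]] = {}
    svs_by_sample: dict[str, tuple[StructuralVariant, ...]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sid in sorted(config.samples):
        entry = config.samples[sid]
        if "sam" in entry:
            alignments, _, _ = read_sam(entry["sam"])
        else:
            reads = _read_fastq(entry["fastq"])
            alignments = align_reads(reads, locus, config.aligner)
            write_sam(alignments, locus, out_dir / "sam" / f"{sid}.sam")
        pile = pileup(alignments, locus)
        gate = coverage_gate(pile, locus, config.calling)
        variants: list[VariantObservation] = []
        svs: tuple[StructuralVariant, ...] = ()
        if gate.included:
            variants = call_sample_variants(pile, locus, config.calling)
            clusters = detect_breakpoints(alignments, locus, config.sv,
                                          config.aligner.min_softclip_report)
            sv_list = call_structural_variants(clusters, locus, config.sv,
                                               config.aligner)
            if db.representatives:
                tails = [t for a in alignments if a.mapped
                         for t in (a.left_clip_seq, a.right_clip_seq)
                         if len(t) >= config.aligner.min_softclip_report]
                tails += [a.seq for a in alignments if not a.mapped]
                cls = classify_clipped_reads(tails, db, config.sv, config.aligner)
                sv_list = attach_transposase_evidence(sv_list, cls, db,
                                                      config.sv, config.aligner)
            svs = tuple(sv_list)
        obs_by_sample[sid] = variants
        svs_by_sample[sid] = svs
        calls.append(classify_sample(sid, gate, variants, svs, config.calling))
        counts[sid] = {"alignments": sum(1 for a in alignments if a.mapped),
                       "unmapped": sum(1 for a in alignments if not a.mapped),
                       "small_variants": len(variants), "svs": len(svs),
                       "gate_included": int(gate.included)}

    cohort_variants = joint_filter(obs_by_sample, locus, config.calling)
    summary = summarize_cohort(calls)
    groups = tuple(stratify(calls, config.metadata)) if config.metadata else ()

    write_vcf(cohort_variants, locus, out_dir / "variants.vcf")
    write_af_matrix(cohort_variants, out_dir / "af_matrix.tsv")
    write_sv_table(svs_by_sample, out_dir / "svs.tsv")
    lines = ["sample\tstatus\tcauses\tevidence"]
    for c in calls:
        ev = ";".join(f"{label}@{freq}" for label, freq in c.evidence)
        lines.append(f"{c.sample_id}\t{c.status}\t{','.join(c.causes)}\t{ev}")
    (out_dir / "sample_calls.tsv").write_text("\n".join(lines) + "\n")
    s = summary
    (out_dir / "cohort_summary.tsv").write_text(
        "n_samples_total\tn_covered\tn_disrupted\tfraction_disrupted\tpercent\n"
        f"{s.n_samples_total}\t{s.n_covered}\t{s.n_disrupted}"
        f"\t{s.fraction_disrupted:.4f}\t{s.percent_disrupted}\n")
    if groups:
        glines = ["group\tn_covered\tn_disrupted\tpercent"]
        glines += [f"{g.group}\t{g.n_covered}\t{g.n_disrupted}\t{g.percent}"
                   for g in groups]
        (out_dir / "groups.tsv").write_text("\n".join(glines) + "\n")
    manifest = {
        "version": __version__,
        "parameters": {
            "calling": vars(config.calling),
            "aligner": {k: v for k, v in vars(config.aligner).items()},
            "sv": vars(config.sv),
        },
        "stage_counts": counts,
        "n_cohort_variants": len(cohort_variants),
        "summary": {"n_samples_total": s.n_samples_total,
                    "n_covered": s.n_covered, "n_disrupted": s.n_disrupted},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(calls=tuple(calls), summary=summary, groups=groups,
                          variants=tuple(cohort_variants),
                          svs_by_sample=svs_by_sample, out_dir=out_dir)
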