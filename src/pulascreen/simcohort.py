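"""Synthetic cohort generator with machine-readable ground truth.

Builds a mock amylopullulanase-like locus, plants the variant archetypes
observed in the reference strain collection (a 2-nt signal-peptide
deletion, premature stop codons, mobile-element insertions, a large
deletion) into haplotypes, and simulates per-sample shotgun read sets that
are mixtures of intact and edited haplotypes at specified frequencies.

Every sample comes with a :class:`TruthRecord` stating where each edit
lies, the allele frequency it should be recovered at (the summed mixture
proportions of the haplotypes carrying it), and the expected sample-level
intact/disrupted classification — enabling parameter-recovery tests of
the whole screening pipeline.

The read model is deliberately simple: single-end reads, uniform start
positions, uniform strand, and an independent per-base substitution error
(default 1e-3); no indel errors, quality ramps, PCR duplicates or
contamination.  Fixed seeds give byte-identical FASTQ output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .locusmodel import Locus, cds_coordinate, revcomp

__all__ = [
    "Edit",
    "HaplotypeSpec",
    "Haplotype",
    "SampleSpec",
    "PlantedEvent",
    "TruthRecord",
    "ReadRecord",
    "ParameterError",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "CRE_SITE_SEQ",
    "make_locus",
    "apply_edits",
    "build_haplotype",
    "preset_haplotypes",
    "simulate_reads",
    "make_transposase_set",
    "write_fastq",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

#: Primer pair flanking the gene start (forward 5' end 42 bp upstream of the
#: CDS start; reverse primer's locus-coordinate end 257 bp downstream of it).
FORWARD_PRIMER = "GCAAATGAAAGCGCATACGTTT"
REVERSE_PRIMER = "TGTTGACGCTGCTTTGCTT"

#: The cre-like operator planted in the upstream flank: a true
#: reverse-complement palindrome matching the cre consensus at one mismatch.
CRE_SITE_SEQ = "TGTTATCGATAACA"

#: Edits at least this long count as structural rather than small variants.
SV_LENGTH_THRESHOLD = 50


class ParameterError(ValueError):
    """Simulator parameters are infeasible or inconsistent."""


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.empty(len(arr), dtype=np.uint8)
    for code, char in enumerate(b"ACGT"):
        out[arr == char] = code
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def make_locus(cds_length_codons: int = 1500, flank_bp: int = 171, seed: int = 0) -> Locus:
    """Build a random locus with an in-frame CDS and planted regulatory motifs.

    The CDS starts with ATG, ends with TAA and contains no internal in-frame
    stop codon.  A cre-like palindrome is planted in the upstream flank.  For
    loci large enough (CDS >= 87 codons, flanks >= 76 bp) the primer pair
    used for the 299-bp amplicon around the gene start is planted at its
    stated offsets, and codons 52, 69 and 75 are fixed to TAC so that a
    single C->A substitution at CDS positions 156, 207 or 225 creates a
    premature stop codon (the positions reported for the natural variants).
    """
    if cds_length_codons < 40:
        raise ParameterError("cds_length_codons must be >= 40")
    if flank_bp < 50:
        raise ParameterError("flank_bp must be >= 50")
    rng = np.random.default_rng(seed)

    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]
    body = [non_stop[i] for i in rng.integers(0, len(non_stop), cds_length_codons - 2)]
    codons = ["ATG"] + body + ["TAA"]

    if cds_length_codons >= 87:
        for idx in (52, 69, 75):  # 1-based codon numbers; third base = C
            codons[idx - 1] = "TAC"
        cds = list("".join(codons))
        # Reverse primer annealing region: CDS positions 239..257 carry the
        # primer's reverse complement; base 238 is fixed so no in-frame stop
        # can arise at the junction.
        cds[237] = "G"
        cds[238:257] = revcomp(REVERSE_PRIMER)
        cds = "".join(cds)
    else:
        cds = "".join(codons)

    up = _decode(rng.integers(0, 4, flank_bp).astype(np.uint8))
    down = _decode(rng.integers(0, 4, flank_bp).astype(np.uint8))

    cre_start = 21  # flank coordinate of the planted cre site
    up = up[: cre_start - 1] + CRE_SITE_SEQ + up[cre_start - 1 + len(CRE_SITE_SEQ):]
    features = {"cre_site": (cre_start, cre_start + len(CRE_SITE_SEQ) - 1)}
    if flank_bp >= 76:
        # Forward primer: 5' end exactly 42 bp upstream of the CDS start.
        p0 = flank_bp - 42  # 0-based index into the upstream flank
        up = up[:p0] + FORWARD_PRIMER + up[p0 + len(FORWARD_PRIMER):]

    seq = up + cds + down
    cds_start = flank_bp + 1
    cds_end = flank_bp + len(cds)
    features["promoter"] = (max(1, cds_start - 60), cds_start - 1)
    features["signal_peptide"] = (cds_start, min(cds_end, cds_start + 74))

    locus = Locus(id=f"locus_sim_{seed}", seq=seq, cds_start=cds_start,
                  cds_end=cds_end, features=features)
    protein = locus.translate_cds()
    assert "*" not in protein[:-1] and protein[-1] == "*"
    return locus


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edit:
    """One planted change, positioned on the reference locus (1-based).

    * ``snv``: single-base substitution at ``position`` (``ref`` -> ``alt``).
    * ``deletion``: ``length`` bases removed starting at ``position``.
    * ``insertion``: ``alt`` inserted between ``position`` and ``position+1``.
    * ``element_insertion``: the sequence named by ``element_id`` inserted
      between ``position`` and ``position+1``.
    """

    kind: str
    position: int
    ref: str | None = None
    alt: str | None = None
    length: int | None = None
    element_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"snv", "deletion", "insertion", "element_insertion"}:
            raise ParameterError(f"unknown edit kind {self.kind!r}")
        if self.kind == "snv":
            if not (self.ref and self.alt and len(self.ref) == 1 == len(self.alt)
                    and self.ref != self.alt):
                raise ParameterError("snv needs single-base ref != alt")
        if self.kind == "deletion" and not (self.length and self.length >= 1):
            raise ParameterError("deletion needs length >= 1")
        if self.kind == "insertion" and not self.alt:
            raise ParameterError("insertion needs an alt sequence")
        if self.kind == "element_insertion" and not self.element_id:
            raise ParameterError("element_insertion needs an element_id")

    def span(self) -> tuple[int, int]:
        """Locus interval occupied by the edit (insertions anchor on one base)."""
        if self.kind == "deletion":
            return (self.position, self.position + self.length - 1)
        return (self.position, self.position)


@dataclass(frozen=True)
class HaplotypeSpec:
    id: str
    edits: tuple[Edit, ...] = ()

    def __post_init__(self) -> None:
        prev_end = 0
        for e in self.edits:
            s, t = e.span()
            if s <= prev_end:
                raise ParameterError(f"edits overlap or are unsorted at position {s}")
            prev_end = t


@dataclass(frozen=True)
class Haplotype:
    """An edited haplotype sequence plus its locus->haplotype coordinate map."""

    spec: HaplotypeSpec
    seq: str
    locus_to_hap: tuple[int, ...]  # index = locus pos (1-based); -1 = deleted

    @property
    def id(self) -> str:
        return self.spec.id

    def map_position(self, locus_pos: int) -> int | None:
        """Haplotype coordinate (1-based) of a locus position, None if deleted."""
        hp = self.locus_to_hap[locus_pos]
        return None if hp < 0 else hp


def apply_edits(locus: Locus, spec: HaplotypeSpec,
                elements: Mapping[str, str] | None = None) -> tuple[str, tuple[int, ...]]:
    """Apply a haplotype's edits to the locus sequence.

    Returns the edited sequence and a coordinate map ``m`` with
    ``m[locus_pos]`` = 1-based haplotype position (or -1 where the locus
    base was deleted); index 0 is unused.
    """
    seq = locus.seq
    out: list[str] = []
    cmap = [-1] * (len(seq) + 1)
    cursor = 1  # next locus position to copy

    def copy_through(pos: int) -> None:
        nonlocal cursor
        for p in range(cursor, pos + 1):
            cmap[p] = len(out) + 1
            out.append(seq[p - 1])
        cursor = pos + 1

    for e in spec.edits:
        if e.span()[1] > len(seq) or e.position < 1:
            raise ParameterError(f"edit at {e.position} outside the locus")
        if e.kind == "snv":
            if seq[e.position - 1] != e.ref:
                raise ParameterError(
                    f"snv ref mismatch at {e.position}: locus has {seq[e.position - 1]}")
            copy_through(e.position - 1)
            cmap[e.position] = len(out) + 1
            out.append(e.alt)
            cursor = e.position + 1
        elif e.kind == "deletion":
            copy_through(e.position - 1)
            cursor = e.position + e.length
        elif e.kind in ("insertion", "element_insertion"):
            ins = e.alt if e.kind == "insertion" else (elements or {}).get(e.element_id)
            if ins is None:
                raise ParameterError(f"unknown element {e.element_id!r}")
            copy_through(e.position)
            out.extend(ins)
    copy_through(len(seq))
    return "".join(out), tuple(cmap)


def build_haplotype(locus: Locus, spec: HaplotypeSpec,
                    elements: Mapping[str, str] | None = None) -> Haplotype:
    seq, cmap = apply_edits(locus, spec, elements)
    return Haplotype(spec=spec, seq=seq, locus_to_hap=cmap)


def preset_haplotypes(locus: Locus, element_id: str | None = None) -> dict[str, HaplotypeSpec]:
    """The canonical genotype archetypes of the reference strain collection.

    * ``intact``: the unedited gene (wild type).
    * ``frameshift_del``: 2-nt deletion in the signal peptide (CDS 156-157),
      the RL09/RL02-like frameshift.
    * ``stopgain_156`` / ``stopgain_207`` / ``stopgain_225``: C->A
      substitutions creating premature stop codons at the reported
      N-terminal positions.
    * ``element_insertion``: mobile-element (transposase) insertion after
      CDS position 100, RL06/RL07-like (needs ``element_id``).
    * ``large_deletion``: 800-bp deletion starting at CDS position 101,
      RL05-like.

    The exact placement of the frameshift and the large deletion within the
    N-terminal region is this simulator's own choice; the strains' true
    coordinates are not published.
    """
    cs = locus.cds_start
    presets = {
        "intact": HaplotypeSpec("intact"),
        "frameshift_del": HaplotypeSpec(
            "frameshift_del", (Edit("deletion", cs + 155, length=2),)),
        "large_deletion": HaplotypeSpec(
            "large_deletion",
            (Edit("deletion", cs + 100,
                  length=min(800, locus.cds_end - (cs + 100) + 1)),)),
    }
    for cds_pos in (156, 207, 225):
        p = cs + cds_pos - 1
        presets[f"stopgain_{cds_pos}"] = HaplotypeSpec(
            f"stopgain_{cds_pos}",
            (Edit("snv", p, ref=locus.seq[p - 1], alt="A"),))
    if element_id is not None:
        presets["element_insertion"] = HaplotypeSpec(
            "element_insertion",
            (Edit("element_insertion", cs + 99, element_id=element_id),))
    return presets


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEvent:
    kind: str
    position: int          # locus coordinate
    af: float              # expected allele frequency
    disruptive: bool
    causes: tuple[str, ...]
    ref: str | None = None
    alt: str | None = None
    length: int | None = None
    element_id: str | None = None


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    events: tuple[PlantedEvent, ...]
    classification: str    # "intact" | "disrupted"
    causes: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "classification": self.classification,
            "causes": list(self.causes),
            "events": [vars(e) | {"causes": list(e.causes)} for e in self.events],
        }


def _classify_edit(locus: Locus, edit: Edit) -> tuple[bool, tuple[str, ...]]:
    """Is this edit expected to disrupt the gene, and through which evidence?

    Classification is by construction, independent of the variant caller:
    element insertions and long indels are structural; short CDS indels of
    non-multiple-of-3 length are frameshifts; SNVs disrupt only when they
    create a stop codon or break the start codon.
    """
    region, codon_idx, codon_off = cds_coordinate(
        locus, min(edit.position, len(locus)))
    if edit.kind == "element_insertion":
        return True, ("structural_variant", "transposase_insertion")
    if edit.kind in ("deletion", "insertion"):
        length = edit.length if edit.kind == "deletion" else len(edit.alt)
        if length >= SV_LENGTH_THRESHOLD:
            return True, ("structural_variant",)
        if region != "CDS":
            return False, ()
        if length % 3 != 0:
            return True, ("high_impact_small_variant",)
        return False, ()
    # snv
    if region != "CDS":
        return False, ()
    codon_start = locus.cds_start + (codon_idx - 1) * 3
    codon = list(locus.seq[codon_start - 1 : codon_start + 2])
    codon[codon_off - 1] = edit.alt
    new_codon = "".join(codon)
    if new_codon in _STOPS and codon_start + 2 < locus.cds_end:
        return True, ("high_impact_small_variant",)
    if codon_idx == 1 and new_codon != "ATG":
        return True, ("high_impact_small_variant",)
    return False, ()


def edit_vcf_key(locus: Locus, edit: Edit) -> tuple[int, str, str]:
    """The normalized (pos, ref, alt) key a caller should report this edit at."""
    from .smallvar import normalize_variant
    if edit.kind == "snv":
        return normalize_variant(edit.position, edit.ref, edit.alt, locus.seq)
    if edit.kind == "deletion":
        a = edit.position - 1
        if a < 1:
            raise ParameterError("deletion at locus start has no left anchor")
        return normalize_variant(a, locus.seq[a - 1 : a + edit.length],
                                 locus.seq[a - 1], locus.seq)
    if edit.kind == "insertion":
        a = edit.position
        return normalize_variant(a, locus.seq[a - 1],
                                 locus.seq[a - 1] + edit.alt, locus.seq)
    raise ParameterError(f"no small-variant key for edit kind {edit.kind!r}")


def make_truth(locus: Locus, sample: "SampleSpec",
               haplotypes: Mapping[str, Haplotype],
               high_freq_threshold: float = 0.7) -> TruthRecord:
    af_by_edit: dict[Edit, float] = {}
    for hap_id, prop in sample.mixture.items():
        if prop <= 0:
            continue
        for e in haplotypes[hap_id].spec.edits:
            af_by_edit[e] = af_by_edit.get(e, 0.0) + prop
    events = []
    causes: set[str] = set()
    disrupted = False
    for e, af in sorted(af_by_edit.items(), key=lambda kv: kv[0].position):
        disruptive, edit_causes = _classify_edit(locus, e)
        events.append(PlantedEvent(
            kind=e.kind, position=e.position, af=round(af, 10),
            disruptive=disruptive, causes=edit_causes,
            ref=e.ref, alt=e.alt, length=e.length, element_id=e.element_id))
        if disruptive and af >= high_freq_threshold:
            disrupted = True
            causes.update(edit_causes)
    return TruthRecord(
        sample_id=sample.id, events=tuple(events),
        classification="disrupted" if disrupted else "intact",
        causes=tuple(sorted(causes)))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSpec:
    """One simulated sample: a haplotype mixture with a coverage target."""

    id: str
    mixture: Mapping[str, float]
    mean_depth: float = 50.0
    read_length: int = 150
    sub_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        props = list(self.mixture.values())
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ParameterError("mixture proportions must be >= 0 and sum to 1")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be positive")
        if not (0 <= self.sub_error_rate < 0.25):
            raise ParameterError("sub_error_rate must be in [0, 0.25)")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str


def simulate_reads(sample: SampleSpec, haplotypes: Mapping[str, Haplotype],
                   locus: Locus | None = None,
                   high_freq_threshold: float = 0.7,
                   ) -> tuple[list[ReadRecord], TruthRecord | None]:
    """Simulate a sample's single-end read set from its haplotype mixture.

    Per haplotype, the read count is Poisson with mean
    ``mean_depth * proportion * len(haplotype) / read_length``; start
    positions and strands are uniform; each base is substituted with
    probability ``sub_error_rate`` (uniformly among the three alternatives).
    A fixed ``sample.seed`` makes the output byte-identical.  The truth
    record is computed when ``locus`` is given.
    """
    rng = np.random.default_rng(sample.seed)
    reads: list[ReadRecord] = []
    rl = sample.read_length
    for hap_id in sorted(sample.mixture):
        prop = sample.mixture[hap_id]
        if prop <= 0:
            continue
        hap = haplotypes[hap_id]
        L = len(hap.seq)
        if rl > L:
            raise ParameterError(
                f"read_length {rl} exceeds haplotype {hap_id} length {L}")
        n = int(rng.poisson(sample.mean_depth * prop * L / rl))
        if n == 0:
            continue
        codes = _encode(hap.seq)
        starts = rng.integers(0, L - rl + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        mat = codes[starts[:, None] + np.arange(rl)[None, :]]
        minus = strands == 1
        mat[minus] = 3 - mat[minus][:, ::-1]
        if sample.sub_error_rate > 0:
            mask = rng.random((n, rl)) < sample.sub_error_rate
            k = int(mask.sum())
            if k:
                mat[mask] = (mat[mask] + rng.integers(1, 4, size=k)) % 4
        for i in range(n):
            strand = "-" if strands[i] else "+"
            reads.append(ReadRecord(
                id=f"{sample.id}|{hap_id}|{i}|{starts[i] + 1}|{strand}",
                seq=_decode(mat[i])))
    truth = None
    if locus is not None:
        truth = make_truth(locus, sample, haplotypes, high_freq_threshold)
    return reads, truth


# ---------------------------------------------------------------------------
# Transposase set
# ---------------------------------------------------------------------------

def make_transposase_set(n_families: int = 3, copies_per_family: int = 4,
                         length_bp: int = 1000,
                         within_family_divergence: float = 0.02,
                         seed: int = 7) -> tuple[dict[str, str], dict[str, str]]:
    """Emulate a redundant mobile-element gene set with known family truth.

    Each family has a consensus sequence (shipped as its first copy) plus
    copies substituted at ``within_family_divergence`` per base from the
    consensus, so member-to-consensus identity is ~``1 - divergence`` and
    stays above the 95% clustering threshold; distinct families are random
    and far below it.  Returns (id -> sequence, id -> family id).
    """
    if n_families < 1 or copies_per_family < 1:
        raise ParameterError("need at least one family and one copy")
    if length_bp < 100:
        raise ParameterError("length_bp must be >= 100")
    if not (0 <= within_family_divergence < 0.05):
        raise ParameterError(
            "within_family_divergence must be < 0.05 to keep families separable")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    families: dict[str, str] = {}
    for f in range(n_families):
        fam = f"tnpfam{f}"
        base = rng.integers(0, 4, length_bp).astype(np.uint8)
        for c in range(copies_per_family):
            codes = base.copy()
            if c > 0 and within_family_divergence > 0:
                mask = rng.random(length_bp) < within_family_divergence
                k = int(mask.sum())
                codes[mask] = (codes[mask] + rng.integers(1, 4, size=k)) % 4
            name = f"{fam}_copy{c}"
            seqs[name] = _decode(codes)
            families[name] = fam
    return seqs, families


# ---------------------------------------------------------------------------
# Standard demonstration cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSim:
    """A fully specified synthetic cohort, ready to simulate or write out."""

    locus: Locus
    elements: dict[str, str]
    element_families: dict[str, str]
    haplotypes: dict[str, Haplotype]
    samples: tuple[SampleSpec, ...]


def standard_cohort(seed: int = 0, mean_depth: float = 50.0,
                    read_length: int = 150, sub_error_rate: float = 0.001,
                    cds_length_codons: int = 1500, flank_bp: int = 171,
                    ) -> CohortSim:
    """The canonical 12-sample cohort of genotype archetypes.

    Three samples each of: intact gene; 2-nt frameshift deletion; mobile
    element insertion; and one each of the premature-stop genotypes at CDS
    positions 156, 207 and 225.  Every sample is a pure (frequency-1.0)
    genotype.  All randomness derives from ``seed``.
    """
    locus = make_locus(cds_length_codons, flank_bp, seed=seed)
    elements, families = make_transposase_set(seed=seed + 1)
    element_id = sorted(elements)[0]
    specs = preset_haplotypes(locus, element_id=element_id)
    haplotypes = {hid: build_haplotype(locus, spec, elements)
                  for hid, spec in specs.items()}
    genotypes = (["intact"] * 3 + ["frameshift_del"] * 3
                 + ["element_insertion"] * 3
                 + ["stopgain_156", "stopgain_207", "stopgain_225"])
    samples = tuple(
        SampleSpec(id=f"s{i + 1:02d}", mixture={g: 1.0},
                   mean_depth=mean_depth, read_length=read_length,
                   sub_error_rate=sub_error_rate,
                   seed=(seed * 131 + 17 * i + 3) % 2**31)
        for i, g in enumerate(genotypes))
    return CohortSim(locus=locus, elements=elements, element_families=families,
                     haplotypes=haplotypes, samples=samples)


def write_cohort(sim: CohortSim, out_dir: str | Path) -> Path:
    """Write a cohort to disk (FASTA/FASTQ/JSON/YAML); returns the config path.

    The emitted ``cohort.yaml`` can be fed directly to the screening
    pipeline; ``truth.json`` holds the planted ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.locus.to_fasta(out / "reference.fa")
    sim.locus.to_gene_model_json(out / "gene_model.json")
    sim.locus.to_features_bed(out / "features.bed")
    write_fasta(sim.elements, out / "transposases.fa")
    truths = []
    sample_entries = []
    for sample in sim.samples:
        reads, truth = simulate_reads(sample, sim.haplotypes, sim.locus)
        write_fastq(reads, out / f"{sample.id}.fq")
        truths.append(truth)
        sample_entries.append({"id": sample.id, "fastq": f"{sample.id}.fq"})
    write_truth_json(truths, out / "truth.json")
    config = {
        "reference": "reference.fa",
        "gene_model": "gene_model.json",
        "transposase_db": "transposases.fa",
        "samples": sample_entries,
        "out_dir": "results",
    }
    import yaml
    (out / "cohort.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return out / "cohort.yaml"


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_truth_json(truths: list[TruthRecord], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([t.to_dict() for t in truths], indent=2) + "\n")
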