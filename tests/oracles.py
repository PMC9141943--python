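"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the
alignment oracle is a plain full-matrix Smith-Waterman scorer, and the
impact oracle classifies a variant by textually applying it to the locus
sequence and comparing the translated proteins.
"""

from __future__ import annotations

from Bio.Seq import Seq

NEG = -(10**9)


def sw_score(q: str, t: str, match: int = 2, mismatch: int = -3,
             gap_open: int = -5, gap_extend: int = -2) -> int:
    """Exhaustive local alignment score with affine gaps.

    A gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fp = F[i], F[i - 1]
        ti = t
        for j in range(1, n + 1):
            e = max(Hi[j - 1] + gap_open + gap_extend, Ei[j - 1] + gap_extend)
            f = max(Hp[j] + gap_open + gap_extend, Fp[j] + gap_extend)
            s = match if qi == ti[j - 1] else mismatch
            h = max(0, Hp[j - 1] + s, e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best = h
    return best


def impact_oracle(locus, pos: int, ref: str, alt: str) -> str:
    """Translate-and-compare impact classification for a (pos, ref, alt) variant."""
    seq = locus.seq
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "variant ref mismatch"
    if len(ref) == 1 and len(alt) == 1:
        if pos < locus.cds_start or pos > locus.cds_end:
            return "MODIFIER"
        edited = seq[: pos - 1] + alt + seq[pos:]
        ref_prot = str(Seq(seq[locus.cds_start - 1 : locus.cds_end]).translate(table=11))
        alt_cds = edited[locus.cds_start - 1 : locus.cds_end]
        if alt_cds[:3] != "ATG":
            return "HIGH"
        alt_prot = str(Seq(alt_cds).translate(table=11))
        ref_stop = ref_prot.index("*") if "*" in ref_prot else len(ref_prot)
        alt_stop = alt_prot.index("*") if "*" in alt_prot else len(alt_prot)
        if alt_stop < ref_stop:
            return "HIGH"  # premature stop
        if ref_prot.endswith("*") and not alt_prot.endswith("*"):
            return "HIGH"  # stop loss
        return "LOW" if alt_prot == ref_prot else "MODERATE"
    # indel, anchored on the base at pos
    if len(ref) > 1:  # deletion of ref[pos+1 .. pos+len(ref)-1]
        lo, hi = pos + 1, pos + len(ref) - 1
        if hi < locus.cds_start or lo > locus.cds_end:
            return "MODIFIER"
        if lo < locus.cds_start or hi > locus.cds_end:
            return "HIGH"
    else:  # insertion between pos and pos+1
        if not (locus.cds_start <= pos < locus.cds_end):
            return "MODIFIER"
    return "HIGH" if abs(len(ref) - len(alt)) % 3 else "MODERATE"
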