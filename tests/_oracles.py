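"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take a different computational route from the library:
whole-sequence splice-edit-translate-diff instead of per-codon arithmetic,
exhaustive window enumeration instead of the two-pointer scan, sort-based
quantiles instead of numpy, and full permutation enumeration for small-n
p-values.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ugtscape.gene_models import TranscriptModel
from ugtscape.records import VariantClass


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


def oracle_snv_class(tm: TranscriptModel, c: int, alt_t: str) -> VariantClass:
    """Splice the whole CDS, apply the edit, translate, diff proteins."""
    ref_prot = _translate(tm.cds_seq)
    mutant = tm.cds_seq[: c - 1] + alt_t + tm.cds_seq[c:]
    mut_prot = _translate(mutant)
    if c <= 3:
        return VariantClass.TRANSLATION_START_SITE
    if mut_prot == ref_prot:
        return VariantClass.SILENT
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b]
    i = diffs[0]
    if ref_prot[i] == "*":
        return VariantClass.NONSTOP
    if mut_prot[i] == "*":
        return VariantClass.NONSENSE
    return VariantClass.MISSENSE


def oracle_indel_class(length: int, is_deletion: bool) -> VariantClass:
    if length % 3:
        return (
            VariantClass.FRAME_SHIFT_DEL if is_deletion else VariantClass.FRAME_SHIFT_INS
        )
    return VariantClass.IN_FRAME_DEL if is_deletion else VariantClass.IN_FRAME_INS


def oracle_hotspots(
    positions: list[int], window_bp: int, min_count: int
) -> list[tuple[int, ...]]:
    """Exhaustive all-windows scan.

    Slides a window of width ``window_bp`` over every possible start
    coordinate, marks qualifying windows, and unions the events covered by
    overlapping qualifying windows into clusters (sorted member tuples).
    """
    if not positions:
        return []
    pos = sorted(positions)
    lo, hi = pos[0], pos[-1]
    qualifying: list[set[int]] = []  # sets of event indices
    for start in range(lo - window_bp + 1, hi + 1):
        end = start + window_bp - 1
        members = {i for i, p in enumerate(pos) if start <= p <= end}
        if len(members) >= min_count:
            qualifying.append(members)
    clusters: list[set[int]] = []
    for members in qualifying:
        merged = [c for c in clusters if c & members]
        untouched = [c for c in clusters if not (c & members)]
        union = set(members)
        for c in merged:
            union |= c
        clusters = untouched + [union]
    return sorted(tuple(sorted(pos[i] for i in c)) for c in clusters)


def oracle_quantile(values: list[float], q: float) -> float:
    """Sort-based linear-interpolation quantile (independent of numpy)."""
    s = sorted(values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def oracle_iqr_flags(counts: dict[str, float], k: float) -> set[str]:
    values = list(counts.values())
    q1 = oracle_quantile(values, 0.25)
    q3 = oracle_quantile(values, 0.75)
    cut = q3 + k * (q3 - q1)
    return {s for s, n in counts.items() if n > cut}


def oracle_conserved_columns(seqs: dict[str, str]) -> list[int]:
    """Plain per-column scan: 1-based indices of fully identical, gap-free
    columns."""
    members = list(seqs)
    length = len(seqs[members[0]])
    out = []
    for col in range(length):
        chars = {seqs[m][col] for m in members}
        if len(chars) == 1 and "-" not in chars:
            out.append(col + 1)
    return out


def oracle_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p-value for the Spearman coefficient."""
    from scipy.stats import spearmanr

    r_obs = abs(spearmanr(x, y).statistic)
    n_extreme = 0
    n_total = 0
    for perm in itertools.permutations(range(len(y))):
        r = abs(spearmanr(x, y[list(perm)]).statistic)
        n_total += 1
        if r >= r_obs - 1e-12:
            n_extreme += 1
    return n_extreme / n_total
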