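"""Independent reference implementations used only to check the package.

These deliberately avoid the package's alignment engine and shortcuts:
infix edit distance comes from Biopython's dynamic-programming pairwise
aligner, read assignment is a single pass over the union of both assemblies,
interval overlap counting is the quadratic all-pairs loop, and Spearman is
the textbook rank formula.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

from twocchip.mapcount import (
    MatchParams,
    OUTCOME_AMBIGUOUS,
    OUTCOME_PRODUCT,
    OUTCOME_UNMAPPED,
    ReadAssignment,
)


def make_infix_aligner() -> Align.PairwiseAligner:
    """Global DP scoring whose negated score is the infix edit distance.

    Match 0, mismatch/gap -1, and free end gaps on the read side make the
    optimal score equal minus the minimum edit distance of the reference
    aligned as a contiguous block inside the read.
    """
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 0.0
    a.mismatch_score = -1.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    a.end_deletion_score = 0.0
    return a


_ALIGNER = make_infix_aligner()


def infix_distance(ref: str, read: str) -> int:
    return int(-_ALIGNER.score(read, ref))


def _gated_hits(seq, refs, min_match, min_identity):
    hits = []
    if len(seq) < min_match:
        return hits
    for rid, s in refs:
        if len(s) < min_match:
            continue
        d = infix_distance(s, seq)
        if 1 - d / len(s) >= min_identity - 1e-12:
            hits.append((rid, float(len(s) - d)))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def brute_force_assign(reads, reference, params: MatchParams) -> list[ReadAssignment]:
    """Single-pass assignment over the union of both assemblies."""
    full = [(p.product_id, p.sequence) for p in reference.full_products]
    unpaired = [(u.ref_id, u.sequence) for u in reference.unpaired]
    unpaired_by_id = {u.ref_id: u for u in reference.unpaired}
    product_barcode = {p.product_id: p.barcode_id for p in reference.full_products}
    out = []
    for read_id, seq in reads:
        fh = _gated_hits(seq, full, params.min_match_full, params.min_identity)
        top = [h for h in fh if h[1] == fh[0][1]] if fh else []
        if len(top) == 1:
            pid = top[0][0]
            out.append(ReadAssignment(read_id, OUTCOME_PRODUCT, pid,
                                      product_barcode[pid], top[0][1]))
            continue
        uh = _gated_hits(seq, unpaired, params.min_match_unpaired, params.min_identity)
        utop = [h for h in uh if h[1] == uh[0][1]] if uh else []
        if len(utop) == 1:
            u = unpaired_by_id[utop[0][0]]
            out.append(ReadAssignment(read_id, u.category, None, u.barcode_id,
                                      utop[0][1]))
        elif utop or len(top) > 1:
            out.append(ReadAssignment(read_id, OUTCOME_AMBIGUOUS))
        else:
            out.append(ReadAssignment(read_id, OUTCOME_UNMAPPED))
    return out


def quadratic_overlap_counts(probes, reads) -> list[int]:
    """All-pairs half-open overlap count; probes/reads: (chrom, start, end)."""
    out = []
    for pc, ps, pe in probes:
        n = 0
        for rc, rs, re in reads:
            if rc == pc and rs < pe and re > ps:
                n += 1
        out.append(n)
    return out


def rank_formula_spearman(x, y) -> float:
    """Pearson correlation of average ranks — the definitional Spearman."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        pos = 1
        while i < v.size:
            j = i
            while j < v.size and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (pos + pos + (j - i) - 1) / 2
            pos += j - i
            i = j
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
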