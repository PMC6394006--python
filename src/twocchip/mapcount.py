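"""Two-step read assignment, barcode demultiplexing, and count tables.

Reads are matched first against the full-product assembly and, if not uniquely
assigned there, against the unpaired assembly — mirroring the assay's two-pass
mapping with word sizes 50 and 22.  The aligner word size is reinterpreted as
a minimum aligned-length gate plus an identity gate on an infix alignment
contract: a reference hits a read iff its best infix (semi-global) edit
distance d satisfies identity = 1 - d/len(ref) >= min_identity, and the score
is len(ref) - d (aligned length x identity).  A read is product-assigned only
when the top score is attained by exactly one reference; ties are never broken
arbitrarily.

The barcode is inferred from the matched reference (references embed the
barcode), not from a separate demultiplexing pass, so barcode sequencing
errors are tolerated up to the identity gate.  Reads are matched in the given
orientation (the library is directional); ``search_revcomp`` enables a
reverse-complement pass for other platforms.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Iterable

import edlib
import pandas as pd
from Bio import SeqIO

from .design import reverse_complement
from .reference import (
    ProductReference,
    UNPAIRED_BARCODE_FORWARD,
    UNPAIRED_FORWARD,
    UNPAIRED_REVERSE,
)

logger = logging.getLogger("twocchip")

OUTCOME_PRODUCT = "product"
OUTCOME_AMBIGUOUS = "ambiguous"
OUTCOME_UNMAPPED = "unmapped"
# unpaired outcomes reuse the reference category names
UNPAIRED_OUTCOMES = (UNPAIRED_BARCODE_FORWARD, UNPAIRED_FORWARD, UNPAIRED_REVERSE)

RUN_LEVEL = "__run__"  # pseudo-library for reads that carry no barcode

CATEGORY_ROWS = ("off_diagonal", UNPAIRED_BARCODE_FORWARD, UNPAIRED_FORWARD,
                 UNPAIRED_REVERSE, OUTCOME_AMBIGUOUS, OUTCOME_UNMAPPED)


@dataclass(frozen=True)
class MatchParams:
    """Gates of the two mapping passes.

    ``min_match_full``/``min_match_unpaired`` default to 50 and 22 nt — the
    smallest expected product in each assembly; ``min_identity`` is the
    alignment identity gate (not a published value; exposed in config).
    """

    min_match_full: int = 50
    min_match_unpaired: int = 22
    min_identity: float = 0.95
    search_revcomp: bool = False

    def __post_init__(self) -> None:
        if self.min_match_unpaired > self.min_match_full:
            raise ValueError("min_match_unpaired must be <= min_match_full")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    outcome: str
    product_id: str | None = None
    barcode_id: str | None = None
    score: float = 0.0


def _max_dist(ref_len: int, min_identity: float) -> int:
    """Largest edit distance still meeting the identity gate."""
    return math.floor((1.0 - min_identity) * ref_len + 1e-9)


def _infix_distance(ref: str, read: str, k: int) -> int | None:
    """Best infix edit distance of ``ref`` within ``read``; None if > k."""
    d = edlib.align(ref, read, mode="HW", task="distance", k=k)["editDistance"]
    return None if d < 0 else d


def match_read(
    read: str,
    references: Iterable[tuple[str, str]],
    min_match: int,
    min_identity: float = 0.95,
) -> list[tuple[str, float]]:
    """All references hitting ``read`` under the length and identity gates.

    Returns (ref_id, score) sorted by descending score (ties by ref_id for
    determinism); score = aligned_length x identity = len(ref) - distance.
    """
    if not read:
        raise ValueError("read must be non-empty")
    hits: list[tuple[str, float]] = []
    if len(read) < min_match:
        return hits
    for ref_id, seq in references:
        if len(seq) < min_match:
            continue
        d = _infix_distance(seq, read, _max_dist(len(seq), min_identity))
        if d is not None:
            hits.append((ref_id, float(len(seq) - d)))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


class _FullIndex:
    """Full-product assembly grouped by shared (barcode, forward) prefix.

    Products with the same barcode and forward primer share the prefix
    barcode + forward_tail + forward_homology.  For any extension P+S of a
    prefix P, an infix alignment of P+S in a read contains an infix alignment
    of P at no greater cost, so d(read, P) <= d(read, P+S): a group whose
    prefix distance already exceeds every member's identity budget can be
    skipped without changing the hit set.
    """

    def __init__(self, reference: ProductReference, params: MatchParams):
        self.params = params
        by_prefix: dict[tuple[str, str], list] = {}
        for p in reference.full_products:
            by_prefix.setdefault((p.barcode_id, p.forward_probe_id), []).append(p)
        self.groups = []
        for prods in by_prefix.values():
            prefix = os.path.commonprefix([p.sequence for p in prods])
            k_max = max(_max_dist(len(p.sequence), params.min_identity) for p in prods)
            self.groups.append((prefix, k_max, prods))

    def hits(self, read: str) -> list[tuple[str, float]]:
        params = self.params
        out: list[tuple[str, float]] = []
        if len(read) < params.min_match_full:
            return out
        for prefix, k_max, prods in self.groups:
            dp = _infix_distance(prefix, read, k_max)
            if dp is None:
                continue
            for p in prods:
                if len(p.sequence) < params.min_match_full:
                    continue
                k = _max_dist(len(p.sequence), params.min_identity)
                if dp > k:
                    continue
                d = _infix_distance(p.sequence, read, k)
                if d is not None:
                    out.append((p.product_id, float(len(p.sequence) - d)))
        out.sort(key=lambda h: (-h[1], h[0]))
        return out


def _top_set(hits: list[tuple[str, float]]) -> list[tuple[str, float]]:
    if not hits:
        return []
    best = hits[0][1]
    return [h for h in hits if h[1] == best]


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    """Accept a FASTQ path, SeqRecords, or (id, seq) tuples."""
    if isinstance(reads, (str, os.PathLike)):
        import gzip

        path = str(reads)
        if path.endswith(".gz"):
            with gzip.open(path, "rt") as fh:
                yield from ((r.id, str(r.seq)) for r in SeqIO.parse(fh, "fastq"))
        else:
            yield from ((r.id, str(r.seq)) for r in SeqIO.parse(path, "fastq"))
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item
        else:  # SeqRecord
            yield item.id, str(item.seq)


def two_step_assign(
    reads,
    reference: ProductReference,
    params: MatchParams = MatchParams(),
) -> list[ReadAssignment]:
    """Assign every read by the two-pass strategy.

    Pass 1 matches the full-product assembly under ``min_match_full``: a read
    with exactly one top-scoring product is assigned to it; reads with tied
    top hits or no hit fall through to pass 2 against the unpaired assembly
    under ``min_match_unpaired``, where a unique best hit yields its unpaired
    category.  Remaining ties are ambiguous; a read with no hit in either
    assembly is unmapped.  Malformed records (empty sequence) are skipped with
    a warning.
    """
    full_index = _FullIndex(reference, params)
    unpaired_refs = [(u.ref_id, u.sequence) for u in reference.unpaired]
    unpaired_by_id = {u.ref_id: u for u in reference.unpaired}
    product_barcode = {p.product_id: p.barcode_id for p in reference.full_products}

    out: list[ReadAssignment] = []
    for read_id, seq in _iter_reads(reads):
        if not seq:
            logger.warning("skipping malformed read %s (empty sequence)", read_id)
            continue
        variants = [seq]
        if params.search_revcomp:
            variants.append(reverse_complement(seq))
        hits: list[tuple[str, float]] = []
        for v in variants:
            hits.extend(full_index.hits(v))
        hits.sort(key=lambda h: (-h[1], h[0]))
        top = _top_set(hits)
        if len(top) == 1:
            pid = top[0][0]
            out.append(ReadAssignment(read_id, OUTCOME_PRODUCT, pid,
                                      product_barcode[pid], top[0][1]))
            continue
        had_step1_tie = len(top) > 1
        uhits: list[tuple[str, float]] = []
        for v in variants:
            uhits.extend(match_read(v, unpaired_refs, params.min_match_unpaired,
                                    params.min_identity))
        uhits.sort(key=lambda h: (-h[1], h[0]))
        utop = _top_set(uhits)
        if len(utop) == 1:
            u = unpaired_by_id[utop[0][0]]
            out.append(ReadAssignment(read_id, u.category, None, u.barcode_id,
                                      utop[0][1]))
        elif utop or had_step1_tie:
            out.append(ReadAssignment(read_id, OUTCOME_AMBIGUOUS))
        else:
            out.append(ReadAssignment(read_id, OUTCOME_UNMAPPED))
    return out


def split_by_barcode(
    assignments: list[ReadAssignment],
    known_barcodes: list[str] | None = None,
) -> dict[str | None, list[ReadAssignment]]:
    """Partition assignments by inferred barcode.

    Assignments without a barcode (reverse-only, forward-only, ambiguous,
    unmapped) pool under the key ``None`` — the run-level residue.  With
    ``known_barcodes`` given, barcodes outside the table are logged and keyed
    ``"unexpected:<id>"``.
    """
    out: dict[str | None, list[ReadAssignment]] = {}
    for a in assignments:
        key: str | None = a.barcode_id
        if key is not None and known_barcodes is not None and key not in known_barcodes:
            logger.warning("read %s carries unexpected barcode %s", a.read_id, key)
            key = f"unexpected:{key}"
        out.setdefault(key, []).append(a)
    return out


@dataclass
class CountTable:
    """Per-library probe counts plus artifact/QC tallies.

    ``probe_counts``: on-diagonal product reads per (probe, library).
    ``categories``: off-diagonal, unpaired-by-category, ambiguous and unmapped
    tallies per library, with barcode-less reads under the ``__run__`` column.
    Category sums plus probe sums equal ``total_reads`` (conservation).
    """

    probe_counts: pd.DataFrame
    categories: pd.DataFrame
    total_reads: int

    @property
    def libraries(self) -> list[str]:
        return [c for c in self.probe_counts.columns]

    def library_product_total(self, library: str) -> int:
        return int(self.probe_counts[library].sum())

    def library_total(self, library: str) -> int:
        return int(self.probe_counts[library].sum() + self.categories[library].sum())

    def check_conservation(self) -> bool:
        total = int(self.probe_counts.to_numpy().sum() + self.categories.to_numpy().sum())
        return total == self.total_reads

    def to_tsv(self, path) -> None:
        long = pd.concat([
            self.probe_counts.reset_index().melt(
                id_vars="probe_id", var_name="library", value_name="count"
            ).assign(kind="probe").rename(columns={"probe_id": "key"}),
            self.categories.reset_index().melt(
                id_vars="category", var_name="library", value_name="count"
            ).assign(kind="category").rename(columns={"category": "key"}),
        ])
        long = long[["kind", "key", "library", "count"]]
        with open(path, "w") as fh:
            fh.write(f"# total_reads={self.total_reads}\n")
            long.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        with open(path) as fh:
            header = fh.readline()
        total = int(header.strip().split("=", 1)[1])
        long = pd.read_csv(path, sep="\t", comment="#")
        probes = long[long["kind"] == "probe"].pivot(index="key", columns="library",
                                                     values="count")
        cats = long[long["kind"] == "category"].pivot(index="key", columns="library",
                                                      values="count")
        probes.index.name = "probe_id"
        cats.index.name = "category"
        cats = cats.reindex(CATEGORY_ROWS)
        return cls(probes.astype(int), cats.astype(int), total)


def tabulate(
    split: dict[str | None, list[ReadAssignment]],
    reference: ProductReference,
) -> CountTable:
    """Tally per-probe on-diagonal counts and artifact categories per library."""
    product_info = {p.product_id: p for p in reference.full_products}
    probe_ids = reference.probe_ids
    libraries = [b.barcode_id for b in reference.barcodes]
    extra = [k for k in split if k is not None and k not in libraries]
    columns = libraries + sorted(extra)

    probes = pd.DataFrame(0, index=pd.Index(probe_ids, name="probe_id"),
                          columns=columns, dtype=int)
    cats = pd.DataFrame(0, index=pd.Index(CATEGORY_ROWS, name="category"),
                        columns=columns + [RUN_LEVEL], dtype=int)
    total = 0
    for key, assignments in split.items():
        for a in assignments:
            total += 1
            col = key if key is not None else RUN_LEVEL
            if a.outcome == OUTCOME_PRODUCT:
                p = product_info[a.product_id]
                if p.on_diagonal:
                    probes.loc[p.forward_probe_id, col] += 1
                else:
                    cats.loc["off_diagonal", col] += 1
            elif a.outcome in UNPAIRED_OUTCOMES:
                cats.loc[a.outcome, col] += 1
            elif a.outcome == OUTCOME_AMBIGUOUS:
                cats.loc[OUTCOME_AMBIGUOUS, col] += 1
            else:
                cats.loc[OUTCOME_UNMAPPED, col] += 1
    return CountTable(probe_counts=probes, categories=cats, total_reads=total)


def assignments_to_tsv(assignments: list[ReadAssignment], path) -> None:
    pd.DataFrame(
        [(a.read_id, a.outcome, a.product_id or "", a.barcode_id or "", a.score)
         for a in assignments],
        columns=["read_id", "outcome", "product_id", "barcode_id", "score"],
    ).to_csv(path, sep="\t", index=False)
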