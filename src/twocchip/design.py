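"""Primer-panel design for 2C-ChIP (carbon copy ChIP).

2C-ChIP quantifies ChIP signal over predefined regions by ligation-mediated
amplification (LMA): a forward and a reverse primer anneal contiguously on the
same strand of immunoprecipitated DNA and are joined by a nick-sealing ligase;
only correctly juxtaposed pairs yield amplifiable, sequenceable products.

This module designs such panels: it tiles one or more target intervals with
adjacent forward/reverse homology pairs under length, GC, uniqueness and
self-complementarity constraints, attaches the universal amplification tails,
and manages library barcodes.  Coordinates are 0-based half-open internally;
BED/bedGraph output follows the same convention.

Strand convention: both primers anneal to the antisense strand, so homologies
are stored in sequenced-read orientation — the sense strand of the emitted
ligation product.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("twocchip")

# Universal tails: T3-complement on forward primers (5' end), P1-key-complement
# on reverse primers (3' end).  Reverse primers are 5'-phosphorylated so the
# ligase can seal the nick.
T3C_TAIL = "TAATTGGGAGTGATTTCCCT"
P1_KEY_C_TAIL = "ATCACCGACTGCCCATAGAGAGG"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_BASES = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or sequences outside the A/C/G/T alphabet."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {bad}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class PrimerConstraints:
    """Constraints a primer homology must satisfy.

    Defaults follow the assay's design rules: homologies of 22-34 nt with
    ~40-60% GC, unique in the target genome, and no self-complementary run
    of ``max_selfcomp_run`` or more (a proxy for self-annealing / hairpins).
    """

    min_homology_len: int = 22
    max_homology_len: int = 34
    min_gc: float = 0.40
    max_gc: float = 0.60
    uniqueness_required: bool = True
    max_selfcomp_run: int = 6

    def __post_init__(self) -> None:
        if self.min_homology_len > self.max_homology_len:
            raise ValueError("min_homology_len must be <= max_homology_len")
        if not (0 <= self.min_gc <= self.max_gc <= 1):
            raise ValueError("require 0 <= min_gc <= max_gc <= 1")


@dataclass(frozen=True)
class ProbePair:
    """An adjacent forward/reverse homology pair.

    The two homologies abut at ``junction`` with no gap or overlap — the
    ligase contract: only contiguously annealed primers are joined.
    """

    probe_id: str
    junction: int
    forward_homology: str
    reverse_homology: str
    forward_interval: GenomicInterval
    reverse_interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.forward_interval.end != self.reverse_interval.start:
            raise ValueError(
                f"{self.probe_id}: forward and reverse homologies must abut "
                f"(forward ends {self.forward_interval.end}, reverse starts "
                f"{self.reverse_interval.start})"
            )
        if self.forward_interval.end != self.junction:
            raise ValueError(f"{self.probe_id}: junction must sit at the F/R boundary")

    @property
    def interval(self) -> GenomicInterval:
        """The probed interval: forward start to reverse end."""
        return GenomicInterval(
            self.forward_interval.chrom,
            self.forward_interval.start,
            self.reverse_interval.end,
            self.forward_interval.strand,
        )


@dataclass
class PrimerPanel:
    """An ordered panel of probe pairs plus the universal tails."""

    pairs: list[ProbePair]
    forward_tail: str = T3C_TAIL
    reverse_tail: str = P1_KEY_C_TAIL
    reverse_phosphorylated: bool = True

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("probe_ids must be unique")
        junctions = [p.junction for p in self.pairs]
        if junctions != sorted(junctions):
            raise ValueError("pairs must be sorted by junction coordinate")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.pairs]

    def intervals(self) -> dict[str, GenomicInterval]:
        return {p.probe_id: p.interval for p in self.pairs}

    def pair(self, probe_id: str) -> ProbePair:
        for p in self.pairs:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    # -- serialization ------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        return assemble_full_primers(self)

    def to_tsv(self, path) -> None:
        """Write the primer table; a header comment documents the orientation."""
        with open(path, "w") as fh:
            fh.write(
                "# 2C-ChIP primer panel. Homologies are stored in sequenced-read "
                "orientation (sense strand of the ligation product); both primers "
                "anneal to the antisense strand. Coordinates 0-based half-open.\n"
            )
            fh.write(f"# forward_tail={self.forward_tail}\treverse_tail={self.reverse_tail}\n")
            self.to_table().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PrimerPanel":
        tails = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line.lstrip("# ").strip().split("\t"):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        tails[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        pairs = []
        for probe_id, grp in df.groupby("probe_id", sort=False):
            rows = {r.role: r for r in grp.itertuples()}
            f, r = rows["forward"], rows["reverse"]
            pairs.append(
                ProbePair(
                    probe_id=str(probe_id),
                    junction=int(f.end),
                    forward_homology=f.homology,
                    reverse_homology=r.homology,
                    forward_interval=GenomicInterval(f.chrom, int(f.start), int(f.end), f.strand),
                    reverse_interval=GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                )
            )
        pairs.sort(key=lambda p: p.junction)
        return cls(
            pairs,
            forward_tail=tails.get("forward_tail", T3C_TAIL),
            reverse_tail=tails.get("reverse_tail", P1_KEY_C_TAIL),
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.pairs:
                iv = p.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.probe_id}\t0\t{iv.strand}\n")


@dataclass(frozen=True)
class Barcode:
    """A library-identifying sequence placed so it is read first."""

    barcode_id: str
    sequence: str
    library_label: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.sequence)


def validate_barcodes(barcodes: list[Barcode], min_hamming: int = 2) -> None:
    """All barcodes must share a length and be pairwise Hamming >= min_hamming."""
    if not barcodes:
        return
    lengths = {len(b.sequence) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must have equal length, got lengths {sorted(lengths)}")
    for a, b in itertools.combinations(barcodes, 2):
        d = sum(x != y for x, y in zip(a.sequence, b.sequence))
        if d < min_hamming:
            raise ValueError(
                f"barcodes {a.barcode_id} and {b.barcode_id} have Hamming distance "
                f"{d} < {min_hamming}"
            )


def make_barcodes(n: int, length: int = 8, seed: int = 0, min_hamming: int = 2) -> list[Barcode]:
    """Sample ``n`` random barcodes of ``length`` nt, pairwise Hamming >= 2."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("could not sample a compatible barcode set")
        cand = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        if all(sum(x != y for x, y in zip(cand, c)) >= min_hamming for c in chosen):
            chosen.append(cand)
    bcs = [Barcode(f"BC{i + 1:02d}", s, library_label=f"lib{i + 1}") for i, s in enumerate(chosen)]
    validate_barcodes(bcs, min_hamming)
    return bcs


def write_barcode_tsv(barcodes: list[Barcode], path) -> None:
    pd.DataFrame(
        [(b.barcode_id, b.sequence, b.library_label) for b in barcodes],
        columns=["barcode_id", "sequence", "library_label"],
    ).to_csv(path, sep="\t", index=False)


def read_barcode_tsv(path) -> list[Barcode]:
    df = pd.read_csv(path, sep="\t")
    bcs = [Barcode(r.barcode_id, r.sequence, getattr(r, "library_label", "") or "")
           for r in df.itertuples()]
    validate_barcodes(bcs)
    return bcs


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """Fraction of G/C bases in ``seq``; raises on empty or non-ACGT input."""
    _check_dna(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def count_occurrences(genome: str, sub: str) -> int:
    """Exact (possibly overlapping) occurrences of ``sub`` in ``genome``."""
    count = start = 0
    while True:
        start = genome.find(sub, start)
        if start < 0:
            return count
        count += 1
        start += 1


def _has_selfcomp_run(homology: str, run: int) -> bool:
    """True when a >=run-nt substring and its reverse complement both occur."""
    if run <= 0 or len(homology) < run:
        return False
    for i in range(len(homology) - run + 1):
        if reverse_complement(homology[i:i + run]) in homology:
            return True
    return False


@dataclass(frozen=True)
class PrimerCheck:
    passed: bool
    violations: tuple[str, ...]


def check_primer(homology: str, constraints: PrimerConstraints, genome: str) -> PrimerCheck:
    """Check one homology against the panel's design rules.

    Returns a verdict and the list of violated rules among ``length``, ``gc``,
    ``uniqueness`` (exact occurrence count in the supplied genome != 1, our
    self-contained stand-in for a genome-wide alignment uniqueness check) and
    ``self_complementarity``.
    """
    _check_dna(homology)
    violations: list[str] = []
    if not (constraints.min_homology_len <= len(homology) <= constraints.max_homology_len):
        violations.append("length")
    gc = gc_content(homology)
    if not (constraints.min_gc <= gc <= constraints.max_gc):
        violations.append("gc")
    if constraints.uniqueness_required and count_occurrences(genome, homology) != 1:
        violations.append("uniqueness")
    if _has_selfcomp_run(homology, constraints.max_selfcomp_run):
        violations.append("self_complementarity")
    return PrimerCheck(passed=not violations, violations=tuple(violations))


def _design_homology(
    genome: str,
    constraints: PrimerConstraints,
    anchor: int,
    direction: int,
    limit: int,
) -> str | None:
    """Grow a homology from ``anchor`` (junction) outward; shortest valid wins.

    direction=-1 grows the forward homology leftward (ends at anchor),
    direction=+1 grows the reverse homology rightward (starts at anchor).
    ``limit`` bounds how far growth may reach (previous pair end / interval end).
    """
    for length in range(constraints.min_homology_len, constraints.max_homology_len + 1):
        if direction < 0:
            start, end = anchor - length, anchor
            if start < limit:
                return None
        else:
            start, end = anchor, anchor + length
            if end > limit:
                return None
        homology = genome[start:end]
        if check_primer(homology, constraints, genome).passed:
            return homology
    return None


def tile_region(
    genome: str,
    interval: GenomicInterval,
    constraints: PrimerConstraints | None = None,
    target_spacing: int | str = "max-density",
    probe_prefix: str = "P",
) -> PrimerPanel:
    """Tile ``interval`` with adjacent forward/reverse probe pairs.

    Greedy left-to-right scan: at each candidate junction the forward homology
    grows leftward and the reverse rightward from the minimum to the maximum
    length, the shortest lengths passing :func:`check_primer` are accepted, and
    the scan advances so that junctions are at least ``target_spacing`` apart
    (``"max-density"`` = as dense as the constraints allow).  Pure function of
    its inputs: identical calls return identical panels.
    """
    constraints = constraints or PrimerConstraints()
    if interval.end > len(genome):
        raise ValueError("interval extends beyond genome")
    spacing = 0 if target_spacing == "max-density" else int(target_spacing)

    pairs: list[ProbePair] = []
    prev_end = interval.start          # first base a new forward may use
    prev_junction: int | None = None
    junction = interval.start + constraints.min_homology_len
    while junction + constraints.min_homology_len <= interval.end:
        if prev_junction is not None and junction - prev_junction < spacing:
            junction = prev_junction + spacing
            continue
        fwd = _design_homology(genome, constraints, junction, -1, prev_end)
        rev = _design_homology(genome, constraints, junction, +1, interval.end)
        if fwd is not None and rev is not None:
            n = len(pairs) + 1
            pair = ProbePair(
                probe_id=f"{probe_prefix}{n:04d}",
                junction=junction,
                forward_homology=fwd,
                reverse_homology=rev,
                forward_interval=GenomicInterval(
                    interval.chrom, junction - len(fwd), junction, interval.strand
                ),
                reverse_interval=GenomicInterval(
                    interval.chrom, junction, junction + len(rev), interval.strand
                ),
            )
            pairs.append(pair)
            prev_junction = junction
            prev_end = pair.reverse_interval.end
            junction = max(prev_end + constraints.min_homology_len,
                           junction + spacing)
        else:
            junction += 1
    if not pairs:
        logger.warning(
            "tile_region: no valid probe pair found in %s:%d-%d",
            interval.chrom, interval.start, interval.end,
        )
    return PrimerPanel(pairs)


def assemble_full_primers(panel: PrimerPanel) -> pd.DataFrame:
    """Full oligo table: forward = tail+homology, reverse = homology+tail.

    Reverse oligos carry a 5'-phosphorylation flag — required for ligation.
    """
    rows = []
    for p in panel.pairs:
        rows.append((
            p.probe_id, "forward", p.forward_interval.chrom,
            p.forward_interval.start, p.forward_interval.end, p.forward_interval.strand,
            p.forward_homology, panel.forward_tail + p.forward_homology, False,
        ))
        rows.append((
            p.probe_id, "reverse", p.reverse_interval.chrom,
            p.reverse_interval.start, p.reverse_interval.end, p.reverse_interval.strand,
            p.reverse_homology, p.reverse_homology + panel.reverse_tail,
            panel.reverse_phosphorylated,
        ))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "role", "chrom", "start", "end", "strand",
                 "homology", "full_oligo", "phospho"],
    )


def reaction_molarity(amount_fmol: float, volume_ul: float) -> float:
    """Concentration in pM of ``amount_fmol`` in ``volume_ul``.

    1 fmol/ul = 1 nM = 1000 pM, so e.g. 0.34 fmol in a 10 ul annealing
    reaction gives the assay's standard 34 pM per-primer concentration.
    """
    if volume_ul <= 0:
        raise ValueError("volume must be > 0")
    if amount_fmol < 0:
        raise ValueError("amount must be >= 0")
    return amount_fmol / volume_ul * 1000.0


def count_primer_pairs(path) -> int:
    """Count forward/reverse primer pairs in a published primer table.

    Accepts a TSV/CSV/xlsx table and pairs rows either via forward/reverse
    sequence columns (one pair per row) or via a role column (one primer per
    row).  Returns the number of complete pairs.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    fwd_cols = [c for lc, c in cols.items() if "forward" in lc or lc.startswith("fwd")]
    rev_cols = [c for lc, c in cols.items() if "reverse" in lc or lc.startswith("rev")]
    if fwd_cols and rev_cols:
        return int((df[fwd_cols[0]].notna() & df[rev_cols[0]].notna()).sum())
    role_cols = [c for lc, c in cols.items() if lc in {"role", "type", "orientation"}]
    if role_cols:
        roles = df[role_cols[0]].astype(str).str.lower()
        return int(min(roles.str.contains("f").sum(), roles.str.contains("r").sum()))
    raise ValueError("could not identify forward/reverse primer columns in table")
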