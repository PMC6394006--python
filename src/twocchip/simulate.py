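"""Ground-truth simulator: genomes, enrichment profiles, and sequencing reads.

The generator stands in for everything upstream of the FASTQ file: chromatin
occupancy (an enrichment profile over the designed probes), the LMA reaction
(reads drawn per product, with a controlled rate of off-diagonal ligation and
of truncated unligated fragments), and the sequencer (per-base substitution
errors, reads starting at the barcode).  Every read's origin is recorded, so
the mapping and quantification stages can be checked against exact truth.

Reads are emitted adapter-trimmed: the instrument key ahead of the barcode is
consumed upstream and the constant reverse tail behind the reverse homology is
trimmed, so a noiseless read equals its reference product byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import PrimerPanel
from .reference import ProductReference, UNPAIRED_BARCODE_FORWARD

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ORIGIN_ON = "on_diagonal"
ORIGIN_OFF = "off_diagonal"
ORIGIN_TRUNCATED = "truncated"


@dataclass
class EnrichmentProfile:
    """Relative occupancy per probe, consumed as multinomial weights."""

    occupancy: pd.Series  # index probe_id, values >= 0

    def __post_init__(self) -> None:
        if (self.occupancy < 0).any():
            raise ValueError("occupancy values must be non-negative")
        if not (self.occupancy > 0).any():
            raise ValueError("profile needs at least one positive value")

    def weights(self, probe_ids: list[str]) -> np.ndarray:
        missing = set(probe_ids) - set(self.occupancy.index)
        if missing:
            raise ValueError(f"profile missing probes: {sorted(missing)[:5]}")
        return self.occupancy.loc[probe_ids].to_numpy(dtype=float)


@dataclass
class SimulationTruth:
    """Exact bookkeeping of what was emitted, keyed by read id."""

    reads: pd.DataFrame  # columns: read_id, origin, ref_id
    off_diagonal_rate: float
    truncation_rate: float
    error_rate: float
    seed: int
    n_reads: int

    def product_counts(self) -> pd.Series:
        """Reads per full product (on- and off-diagonal)."""
        mask = self.reads["origin"].isin([ORIGIN_ON, ORIGIN_OFF])
        return self.reads.loc[mask, "ref_id"].value_counts()

    def on_diagonal_probe_counts(self, reference: ProductReference) -> pd.Series:
        """Reads per probe, on-diagonal products only, zero-filled."""
        on = self.reads["origin"] == ORIGIN_ON
        by_product = self.reads.loc[on, "ref_id"].value_counts()
        probe_of = {p.product_id: p.forward_probe_id
                    for p in reference.full_products if p.on_diagonal}
        counts = pd.Series(0, index=pd.Index(reference.probe_ids, name="probe_id"))
        for pid, n in by_product.items():
            counts[probe_of[pid]] += n
        return counts


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome with i.i.d. bases, P(G)+P(C)=gc; deterministic per seed."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def flat_profile(panel: PrimerPanel, background: float = 1.0) -> EnrichmentProfile:
    """The input library's profile: uniform background occupancy."""
    return EnrichmentProfile(pd.Series(background, index=pd.Index(panel.probe_ids, name="probe_id")))


def simulate_profile(
    panel: PrimerPanel,
    n_peaks: int,
    peak_height: float = 8.0,
    background: float = 1.0,
    min_peak_width: int = 2,
    max_peak_width: int = 6,
    jitter: float = 0.0,
    seed: int = 0,
) -> EnrichmentProfile:
    """Piecewise ChIP-like profile: background plus contiguous peak runs.

    ``n_peaks`` runs of width uniform in [min_peak_width, max_peak_width] are
    placed at random probe positions (overlaps merge) and set to
    ``peak_height``.  ``jitter`` > 0 multiplies every probe by an independent
    log-normal factor exp(N(0, jitter)) — real occupancy varies continuously
    between probes, and rank-based recovery checks need that variation; the
    default 0 keeps the profile exactly two-valued.
    """
    if background <= 0:
        raise ValueError("background must be > 0")
    n = len(panel.pairs)
    if n_peaks > n:
        raise ValueError(f"n_peaks={n_peaks} exceeds probe count {n}")
    rng = np.random.default_rng(seed)
    values = np.full(n, float(background))
    for _ in range(n_peaks):
        width = int(rng.integers(min_peak_width, max_peak_width + 1))
        start = int(rng.integers(0, max(1, n - width + 1)))
        values[start:start + width] = peak_height
    if jitter > 0:
        values = values * np.exp(rng.normal(0.0, jitter, size=n))
    return EnrichmentProfile(pd.Series(values, index=pd.Index(panel.probe_ids, name="probe_id")))


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution; an erroneous base is replaced by a different one."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    n = int(hit.sum())
    if n:
        # offset 1..3 from the current base index guarantees a real change
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_library(
    reference: ProductReference,
    profile: EnrichmentProfile,
    barcode_id: str,
    n_reads: int,
    off_diagonal_rate: float = 0.0,
    truncation_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    quality_char: str = "I",
    min_read_len: int | None = None,
    max_read_len: int | None = None,
) -> tuple[list[SeqRecord], SimulationTruth]:
    """Draw reads for one barcoded library.

    Each read is, with probability 1 - off_diagonal_rate - truncation_rate, an
    on-diagonal product of probe i drawn proportionally to the profile; with
    probability off_diagonal_rate a uniformly random off-diagonal product; and
    with probability truncation_rate an unpaired barcode-forward fragment
    (uniform over probes).  Substitutions are applied per base at
    ``error_rate``; the quality string is constant.  ``min_read_len`` /
    ``max_read_len`` model size selection as an optional read-length filter.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    for name, r in [("off_diagonal_rate", off_diagonal_rate),
                    ("truncation_rate", truncation_rate),
                    ("error_rate", error_rate)]:
        if not (0 <= r <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if off_diagonal_rate + truncation_rate > 1:
        raise ValueError("off_diagonal_rate + truncation_rate must be <= 1")

    rng = np.random.default_rng(seed)
    on = [p for p in reference.full_products if p.on_diagonal and p.barcode_id == barcode_id]
    off = [p for p in reference.full_products if not p.on_diagonal and p.barcode_id == barcode_id]
    trunc = [u for u in reference.unpaired
             if u.category == UNPAIRED_BARCODE_FORWARD and u.barcode_id == barcode_id]
    if not on:
        raise ValueError(f"reference has no on-diagonal products for barcode {barcode_id}")

    probe_order = [p.forward_probe_id for p in on]
    w = profile.weights(probe_order)
    if not w.sum() > 0:
        raise ValueError("profile weights sum to zero over panel probes")
    w = w / w.sum()

    origins = rng.choice(
        3, size=n_reads,
        p=[1 - off_diagonal_rate - truncation_rate, off_diagonal_rate, truncation_rate],
    )
    on_idx = rng.choice(len(on), size=n_reads, p=w)
    off_idx = rng.integers(0, max(1, len(off)), size=n_reads)
    tr_idx = rng.integers(0, len(trunc), size=n_reads)

    records: list[SeqRecord] = []
    rows: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        if origins[i] == 0:
            prod = on[on_idx[i]]
            origin, rid, seq = ORIGIN_ON, prod.product_id, prod.sequence
        elif origins[i] == 1:
            if not off:
                raise ValueError("off_diagonal_rate > 0 but panel has a single pair")
            prod = off[off_idx[i]]
            origin, rid, seq = ORIGIN_OFF, prod.product_id, prod.sequence
        else:
            u = trunc[tr_idx[i]]
            origin, rid, seq = ORIGIN_TRUNCATED, u.ref_id, u.sequence
        if error_rate > 0:
            seq = _mutate(seq, error_rate, rng)
        if min_read_len is not None and len(seq) < min_read_len:
            continue
        if max_read_len is not None and len(seq) > max_read_len:
            continue
        read_id = f"{barcode_id}:{i:07d}"
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality_char) - 33] * len(seq)
        records.append(rec)
        rows.append((read_id, origin, rid))

    truth = SimulationTruth(
        reads=pd.DataFrame(rows, columns=["read_id", "origin", "ref_id"]),
        off_diagonal_rate=off_diagonal_rate,
        truncation_rate=truncation_rate,
        error_rate=error_rate,
        seed=seed,
        n_reads=n_reads,
    )
    return records, truth


def write_fastq(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_truth(truth: SimulationTruth, path) -> None:
    truth.reads.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Titration: template mass -> library behaviour
# ---------------------------------------------------------------------------

def titration_response(
    amount_ng: float,
    reads_per_ng: float = 50000.0,
    saturation_ng: float = 1.6,
    off_diagonal_base: float = 0.02,
    off_diagonal_halfpoint_ng: float = 0.05,
    max_off_diagonal: float = 0.6,
) -> tuple[int, float, float]:
    """Phenomenological map from template mass to (n_reads, off rate, yield).

    Library yield rises linearly with template and saturates hard at
    ``saturation_ng`` (the upper edge of the assay's linear detection range);
    the off-diagonal rate is lowest at high template and grows as
    base * (1 + halfpoint/amount) when template becomes scarce, reflecting
    non-specific primer-primer ligation dominating sparse reactions.  This is
    a documented stand-in for the reaction chemistry, not a kinetic model.
    """
    if amount_ng <= 0:
        raise ValueError("amount_ng must be > 0")
    eff = min(amount_ng, saturation_ng)
    yield_rel = eff
    n_reads = max(1, int(round(reads_per_ng * eff)))
    off = min(max_off_diagonal,
              off_diagonal_base * (1 + off_diagonal_halfpoint_ng / amount_ng))
    return n_reads, off, yield_rel


def simulate_titration(
    amounts_ng: list[float],
    seed: int = 0,
    noise_sigma: float = 0.05,
    **response_kwargs,
) -> pd.DataFrame:
    """Yield/read metrics over a template titration, with log-normal noise.

    Returns a table (amount_ng, yield, n_reads, off_diagonal_rate) suitable
    for :func:`twocchip.qc.assess_linearity`.
    """
    if sorted(amounts_ng) != list(amounts_ng) or len(set(amounts_ng)) != len(amounts_ng):
        raise ValueError("amounts must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for a in amounts_ng:
        n_reads, off, y = titration_response(a, **response_kwargs)
        y *= math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
        rows.append((a, y, n_reads, off))
    return pd.DataFrame(rows, columns=["amount_ng", "yield", "n_reads", "off_diagonal_rate"])
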