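"""Normalization chain and input-normalized signal tracks.

Per-probe signal is expressed relative to input through a multiplicative
factor chain: reads-per-million over the library's mapped on-diagonal product
reads, times the sequencing dilution factor (TaqMan-style quantitation), times
the linearity dilution factor, and — on the ChIP side — times the fraction of
input material actually processed (default 10%).  The final track is the
ratio of normalized ChIP to normalized input per probe, serialized as
bedGraph (0-based half-open).

All steps are multiplicative, so their order is immaterial; the per-million
base is the mapped on-diagonal product reads by default (off-diagonal and
unpaired reads are artifacts), switchable to the library total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PrimerPanel
from .mapcount import CountTable

logger = logging.getLogger("twocchip")


@dataclass(frozen=True)
class LibraryFactors:
    """Per-library scaling factors of the normalization chain."""

    library_label: str
    seq_dilution: float = 1.0
    linearity_dilution: float = 1.0
    is_input: bool = False
    input_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.seq_dilution <= 0 or self.linearity_dilution <= 0:
            raise ValueError("dilution factors must be > 0")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")


def read_factors_tsv(path) -> dict[str, LibraryFactors]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples():
        out[r.library_label] = LibraryFactors(
            library_label=r.library_label,
            seq_dilution=float(getattr(r, "seq_dilution", 1.0)),
            linearity_dilution=float(getattr(r, "linearity_dilution", 1.0)),
            is_input=bool(getattr(r, "is_input", False)),
            input_fraction=float(getattr(r, "input_fraction", 0.10)),
        )
    return out


@dataclass
class NormalizedTrack:
    """Per-probe input-normalized signal with genomic intervals."""

    data: pd.DataFrame  # index probe_id; columns chrom, start, end, value
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data["value"]
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError("track values must be finite")

    @property
    def values(self) -> pd.Series:
        return self.data["value"]

    def __len__(self) -> int:
        return len(self.data)


def normalize_counts(
    table: CountTable,
    factors: LibraryFactors,
    library: str | None = None,
    norm_base: str = "product",
) -> pd.Series:
    """One library's normalized per-probe values.

    value_i = count_i / base * 1e6 * seq_dilution * linearity_dilution, with
    ChIP libraries (``is_input=False``) additionally multiplied by
    ``input_fraction`` — the adjustment for only a fraction of the input
    having been processed.  ``norm_base`` picks the per-million denominator:
    mapped on-diagonal product reads (default) or the library total.
    """
    library = library or factors.library_label
    if library not in table.probe_counts.columns:
        raise KeyError(f"library {library!r} not in count table")
    counts = table.probe_counts[library].astype(float)
    if norm_base == "product":
        base = table.library_product_total(library)
    elif norm_base == "total":
        base = table.library_total(library)
    else:
        raise ValueError("norm_base must be 'product' or 'total'")
    if base <= 0:
        raise ValueError(f"library {library!r} has zero mapped reads")
    values = counts / base * 1e6 * factors.seq_dilution * factors.linearity_dilution
    if not factors.is_input:
        values = values * factors.input_fraction
    return values


def chip_input_ratio(
    chip: pd.Series,
    input_: pd.Series,
    panel: PrimerPanel,
    pseudocount: float = 0.0,
    provenance: dict | None = None,
) -> NormalizedTrack:
    """Ratio of normalized ChIP to normalized input per probe.

    Probes with zero input signal are dropped from the track (logged), unless
    a ``pseudocount`` is added to both sides.  Probe order and intervals come
    from the panel.
    """
    if not chip.index.equals(input_.index):
        if set(chip.index) != set(input_.index):
            raise ValueError("ChIP and input cover different probe sets")
        input_ = input_.loc[chip.index]
    intervals = panel.intervals()
    missing = [p for p in chip.index if p not in intervals]
    if missing:
        raise ValueError(f"panel lacks probes: {missing[:5]}")
    rows = []
    dropped = []
    for probe_id in chip.index:
        c = chip[probe_id] + pseudocount
        i = input_[probe_id] + pseudocount
        if i == 0:
            dropped.append(probe_id)
            continue
        iv = intervals[probe_id]
        rows.append((probe_id, iv.chrom, iv.start, iv.end, c / i))
    if dropped:
        logger.info("chip_input_ratio: dropped %d zero-input probes: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end", "value"])
    df = df.set_index("probe_id")
    return NormalizedTrack(df, provenance=dict(provenance or {}, dropped_probes=dropped))


def write_bedgraph(track: NormalizedTrack, path) -> None:
    """Standard bedGraph, 0-based half-open, 6 significant digits.

    Intervals must be sorted and non-overlapping within each chromosome.
    """
    df = track.data
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if not (starts[1:] >= ends[:-1]).all() or not (starts < ends).all():
            raise ValueError(f"intervals on {chrom} unsorted or overlapping")
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:.6g}\n")


def read_bedgraph(path) -> NormalizedTrack:
    """Read a bedGraph written by :func:`write_bedgraph`.

    Probe identities are not part of the format; rows get synthetic ids in
    file order.  Round-trip preserves intervals exactly and values to the
    6-significant-digit formatting.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df.index = pd.Index([f"row{i:05d}" for i in range(len(df))], name="probe_id")
    return NormalizedTrack(df)
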