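"""Quality control and validation statistics.

Covers the assay's run-level QC (mapping composition and the off-diagonal
fraction — the share of non-specific primer-primer ligation products, a
library-quality signal), titration linearity (the template-mass window where
yield scales proportionally), and the validation comparisons: 1-kb window
averaging against qPCR amplicons, per-probe read summation against ChIP-seq,
Spearman rank correlation (optionally excluding zeros), and replicate R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapcount import CountTable
from .quantify import NormalizedTrack

logger = logging.getLogger("twocchip")


@dataclass
class RunQC:
    total_reads: int
    product_fraction: float            # on-diagonal product reads / all reads
    off_diagonal_fraction_all: float   # off-diagonal reads / all reads
    off_diagonal_fraction_unexpected: float  # among reads not on-diagonal
    unpaired_fractions: dict[str, float]
    ambiguous_fraction: float
    unmapped_fraction: float
    per_library_share: dict[str, float]


def run_qc(table: CountTable) -> RunQC:
    """Composition of a run: what fraction of reads went where.

    The off-diagonal fraction is reported both over all reads and over the
    "unexpected" reads (everything that is not an on-diagonal product), the
    latter being the assay's usual artifact-composition statistic.
    """
    total = table.total_reads
    if total <= 0:
        raise ValueError("count table has no reads")
    on = int(table.probe_counts.to_numpy().sum())
    cat = table.categories.sum(axis=1)
    off = int(cat["off_diagonal"])
    unexpected = total - on
    shares = {}
    for lib in table.probe_counts.columns:
        shares[lib] = table.library_total(lib) / total
    return RunQC(
        total_reads=total,
        product_fraction=on / total,
        off_diagonal_fraction_all=off / total,
        off_diagonal_fraction_unexpected=(off / unexpected) if unexpected else 0.0,
        unpaired_fractions={k: int(cat[k]) / total
                            for k in ("barcode-forward", "forward", "reverse")},
        ambiguous_fraction=int(cat["ambiguous"]) / total,
        unmapped_fraction=int(cat["unmapped"]) / total,
        per_library_share=shares,
    )


def window_average(
    track: NormalizedTrack,
    center: int,
    width: int = 1000,
    chrom: str | None = None,
    membership: str = "midpoint",
) -> float | None:
    """Mean probe value in a window centered at ``center``.

    A probe belongs to the window when its interval midpoint lies in
    [center - width/2, center + width/2) (``membership="midpoint"``, the
    default) or when its interval overlaps the window at all
    (``membership="overlap"``).  Returns None when no probe qualifies —
    the qPCR-comparison convention for amplicons outside probed territory.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    df = track.data
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    lo, hi = center - width / 2, center + width / 2
    if membership == "midpoint":
        mid = (df["start"] + df["end"]) / 2
        sel = (mid >= lo) & (mid < hi)
    elif membership == "overlap":
        sel = (df["start"] < hi) & (df["end"] > lo)
    else:
        raise ValueError("membership must be 'midpoint' or 'overlap'")
    if not sel.any():
        return None
    return float(df.loc[sel, "value"].mean())


def spearman(x, y, drop_zeros: bool = False) -> float:
    """Spearman rank correlation with average ranks for ties.

    With ``drop_zeros`` (the validation-comparison convention) pairs where
    either value equals zero are excluded first; the number dropped is
    logged.  Requires at least 3 retained pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if drop_zeros:
        keep = (x != 0) & (y != 0)
        ndrop = int((~keep).sum())
        if ndrop:
            logger.info("spearman: dropped %d zero pairs of %d", ndrop, x.size)
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 retained pairs, have {x.size}")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def chipseq_overlap_score(
    track: NormalizedTrack,
    reads: pd.DataFrame,
) -> pd.Series:
    """Reads overlapping each probed interval (half-open overlap).

    ``reads`` is a BED-like table with columns chrom, start, end.  A read
    overlaps a probe iff read.start < probe.end and read.end > probe.start on
    the same chromosome; abutting intervals do not overlap.  The result feeds
    :func:`spearman` with ``drop_zeros=True`` for the ChIP-seq comparison.
    """
    counts = pd.Series(0, index=track.data.index, dtype=int)
    for chrom, probes in track.data.groupby("chrom", sort=False):
        r = reads[reads["chrom"] == chrom]
        if r.empty:
            continue
        starts = np.sort(r["start"].to_numpy())
        ends = np.sort(r["end"].to_numpy())
        # overlap count = (#reads starting before probe end)
        #                 - (#reads ending at/before probe start)
        begun = np.searchsorted(starts, probes["end"].to_numpy(), side="left")
        done = np.searchsorted(ends, probes["start"].to_numpy(), side="right")
        counts.loc[probes.index] = (begun - done).astype(int)
    return counts


@dataclass
class TitrationSeries:
    """Template amounts (ng, strictly increasing) and the yield per amount."""

    amounts_ng: list[float]
    yields: list[float]

    def __post_init__(self) -> None:
        a = self.amounts_ng
        if len(a) != len(self.yields):
            raise ValueError("amounts and yields must have equal length")
        if any(x <= 0 for x in a) or any(nxt <= prev for prev, nxt in zip(a, a[1:])):
            raise ValueError("amounts must be strictly increasing and > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   amount_col: str = "amount_ng", yield_col: str = "yield"):
        return cls(list(df[amount_col]), list(df[yield_col]))


@dataclass
class LinearityResult:
    lo_ng: float | None
    hi_ng: float | None
    slope: float | None
    r2: float | None
    n_points: int

    @property
    def has_linear_range(self) -> bool:
        return self.lo_ng is not None


def assess_linearity(
    series: TitrationSeries,
    r2_threshold: float = 0.98,
    slope_range: tuple[float, float] = (0.8, 1.2),
) -> LinearityResult:
    """Find the widest contiguous titration window with proportional yield.

    Every contiguous sub-series of >= 3 points is fit by least squares in
    log(yield) vs log(amount); the widest one with r^2 >= ``r2_threshold``
    and slope within ``slope_range`` wins (ties: larger log-span, then
    leftmost).  Saturated high points (flat yield, slope -> 0) and
    background-dominated low points fall outside the window.  Returns a
    no-linear-range result rather than raising when nothing qualifies.
    """
    a = np.asarray(series.amounts_ng, dtype=float)
    y = np.asarray(series.yields, dtype=float)
    if a.size < 3:
        raise ValueError("need >= 3 titration points")
    best: tuple[int, float, int] | None = None  # (n_points, logspan, -start)
    best_fit = None
    for i in range(a.size):
        for j in range(i + 3, a.size + 1):
            ya = y[i:j]
            if (ya <= 0).any():
                continue
            la, ly = np.log10(a[i:j]), np.log10(ya)
            fit = stats.linregress(la, ly)
            r2 = fit.rvalue ** 2
            if r2 < r2_threshold or not (slope_range[0] <= fit.slope <= slope_range[1]):
                continue
            key = (j - i, la[-1] - la[0], -i)
            if best is None or key > best:
                best = key
                best_fit = (a[i], a[j - 1], fit.slope, r2, j - i)
    if best_fit is None:
        logger.info("assess_linearity: no qualifying linear range")
        return LinearityResult(None, None, None, None, 0)
    lo, hi, slope, r2, n = best_fit
    return LinearityResult(float(lo), float(hi), float(slope), float(r2), int(n))


def replicate_correlation(track_a: NormalizedTrack, track_b: NormalizedTrack) -> float:
    """Squared Pearson correlation (R^2) over probes present in both tracks."""
    shared = track_a.data.index.intersection(track_b.data.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared probes, have {len(shared)}")
    x = track_a.data.loc[shared, "value"].to_numpy(dtype=float)
    y = track_b.data.loc[shared, "value"].to_numpy(dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


def qc_report(qc: RunQC) -> str:
    """Human-readable one-run summary."""
    lines = [
        f"total reads            {qc.total_reads}",
        f"on-diagonal products   {qc.product_fraction:.4f}",
        f"off-diagonal (all)     {qc.off_diagonal_fraction_all:.4f}",
        f"off-diagonal (unexp.)  {qc.off_diagonal_fraction_unexpected:.4f}",
        f"ambiguous              {qc.ambiguous_fraction:.4f}",
        f"unmapped               {qc.unmapped_fraction:.4f}",
    ]
    for k, v in qc.unpaired_fractions.items():
        lines.append(f"unpaired {k:<14}{v:.4f}")
    for lib, share in qc.per_library_share.items():
        lines.append(f"library {lib:<15}{share:.4f}")
    return "\n".join(lines) + "\n"
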