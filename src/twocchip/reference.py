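"""Expected-product reference assemblies for read assignment.

Two assemblies are built from a primer panel and a barcode set:

1. the *full-product* assembly — every barcode x forward x reverse ligation
   product, labelled on-diagonal (forward and reverse from the same designed
   probe pair) or off-diagonal (a non-specific ligation between non-adjacent
   primers, the assay's main artifact class);
2. the *unpaired* assembly — barcode-forward, forward-only and reverse-only
   primer sequences, which catch truncated or unligated material.

Sequences are stored in sequenced-read orientation, beginning at the barcode.
The constant reverse universal tail is excluded by default: reads are decided
before reaching it and it adds no discriminative power.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Barcode, PrimerPanel, validate_barcodes

logger = logging.getLogger("twocchip")

UNPAIRED_BARCODE_FORWARD = "barcode-forward"
UNPAIRED_FORWARD = "forward"
UNPAIRED_REVERSE = "reverse"


@dataclass(frozen=True)
class ExpectedProduct:
    product_id: str
    barcode_id: str | None
    forward_probe_id: str
    reverse_probe_id: str
    sequence: str
    on_diagonal: bool
    sequence_is_duplicate: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UnpairedSequence:
    category: str  # one of the UNPAIRED_* constants
    ref_id: str
    barcode_id: str | None
    probe_id: str
    sequence: str


@dataclass
class ProductReference:
    """Both assemblies plus the metadata read assignment and simulation need."""

    full_products: list[ExpectedProduct]
    unpaired: list[UnpairedSequence]
    barcodes: list[Barcode]
    forward_tail: str
    reverse_tail: str
    include_reverse_tail: bool

    @property
    def min_full_product_len(self) -> int:
        return min(p.length for p in self.full_products)

    @property
    def min_unpaired_len(self) -> int:
        return min(len(u.sequence) for u in self.unpaired)

    @property
    def on_diagonal_products(self) -> list[ExpectedProduct]:
        return [p for p in self.full_products if p.on_diagonal]

    @property
    def probe_ids(self) -> list[str]:
        seen: list[str] = []
        for p in self.full_products:
            if p.on_diagonal and p.forward_probe_id not in seen:
                seen.append(p.forward_probe_id)
        return seen

    def product(self, product_id: str) -> ExpectedProduct:
        for p in self.full_products:
            if p.product_id == product_id:
                return p
        raise KeyError(product_id)

    def index_table(self) -> pd.DataFrame:
        rows = [
            ("product", p.product_id, p.barcode_id, p.forward_probe_id,
             p.reverse_probe_id, "on" if p.on_diagonal else "off", p.length)
            for p in self.full_products
        ] + [
            ("unpaired:" + u.category, u.ref_id, u.barcode_id, u.probe_id,
             "", "", len(u.sequence))
            for u in self.unpaired
        ]
        return pd.DataFrame(
            rows, columns=["kind", "ref_id", "barcode_id", "forward_probe_id",
                           "reverse_probe_id", "diagonal", "length"])


def product_id(barcode_id: str, forward_probe_id: str, reverse_probe_id: str) -> str:
    return f"{barcode_id}|{forward_probe_id}|{reverse_probe_id}"


def build_full_reference(
    panel: PrimerPanel,
    barcodes: list[Barcode],
    include_reverse_tail: bool = False,
    max_full_products: int | None = None,
    off_diagonal_sample: int | None = None,
    seed: int = 0,
) -> list[ExpectedProduct]:
    """Enumerate every barcode x forward x reverse product.

    ``on_diagonal`` marks products whose forward and reverse primers belong to
    the same designed pair.  For pathological panel sizes the n^2 enumeration
    can be capped (``max_full_products``) with on-diagonal products kept and a
    seeded sample of ``off_diagonal_sample`` off-diagonal ones.  Duplicate
    product sequences (identical homologies in the panel) are kept but flagged
    and logged.
    """
    if not panel.pairs:
        raise ValueError("panel is empty")
    if not barcodes:
        raise ValueError("need at least one barcode")
    validate_barcodes(barcodes)

    n_full = len(barcodes) * len(panel.pairs) ** 2
    combos: list[tuple[int, int]]
    all_combos = [(i, j) for i in range(len(panel.pairs)) for j in range(len(panel.pairs))]
    if max_full_products is not None and n_full > max_full_products:
        if off_diagonal_sample is None:
            raise ValueError(
                f"{n_full} products exceed cap {max_full_products}; set "
                "off_diagonal_sample to enumerate on-diagonal plus a sampled subset"
            )
        off = [(i, j) for i, j in all_combos if i != j]
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(off), size=min(off_diagonal_sample, len(off)), replace=False)
        combos = [(i, i) for i in range(len(panel.pairs))] + [off[k] for k in sorted(keep)]
    else:
        combos = all_combos

    products: list[ExpectedProduct] = []
    seen: dict[str, str] = {}
    for bc in barcodes:
        for i, j in combos:
            fp, rp = panel.pairs[i], panel.pairs[j]
            seq = bc.sequence + panel.forward_tail + fp.forward_homology + rp.reverse_homology
            if include_reverse_tail:
                seq += panel.reverse_tail
            pid = product_id(bc.barcode_id, fp.probe_id, rp.probe_id)
            dup = seq in seen
            if dup:
                logger.warning("duplicate product sequence: %s == %s", pid, seen[seq])
            else:
                seen[seq] = pid
            products.append(ExpectedProduct(
                product_id=pid,
                barcode_id=bc.barcode_id,
                forward_probe_id=fp.probe_id,
                reverse_probe_id=rp.probe_id,
                sequence=seq,
                on_diagonal=(i == j),
                sequence_is_duplicate=dup,
            ))
    return products


def build_unpaired_reference(panel: PrimerPanel, barcodes: list[Barcode]) -> list[UnpairedSequence]:
    """Enumerate unpaired barcode-forward, forward and reverse sequences."""
    if not panel.pairs:
        raise ValueError("panel is empty")
    out: list[UnpairedSequence] = []
    for bc in barcodes:
        for p in panel.pairs:
            out.append(UnpairedSequence(
                UNPAIRED_BARCODE_FORWARD,
                f"{bc.barcode_id}|{p.probe_id}",
                bc.barcode_id, p.probe_id,
                bc.sequence + panel.forward_tail + p.forward_homology,
            ))
    for p in panel.pairs:
        out.append(UnpairedSequence(
            UNPAIRED_FORWARD, f"F|{p.probe_id}", None, p.probe_id,
            panel.forward_tail + p.forward_homology,
        ))
    for p in panel.pairs:
        out.append(UnpairedSequence(
            UNPAIRED_REVERSE, f"R|{p.probe_id}", None, p.probe_id,
            p.reverse_homology + panel.reverse_tail,
        ))
    return out


def build_reference(
    panel: PrimerPanel,
    barcodes: list[Barcode],
    include_reverse_tail: bool = False,
    **kwargs,
) -> ProductReference:
    """Build both assemblies in one call."""
    return ProductReference(
        full_products=build_full_reference(panel, barcodes, include_reverse_tail, **kwargs),
        unpaired=build_unpaired_reference(panel, barcodes),
        barcodes=list(barcodes),
        forward_tail=panel.forward_tail,
        reverse_tail=panel.reverse_tail,
        include_reverse_tail=include_reverse_tail,
    )


# -- serialization ----------------------------------------------------------

def write_reference(ref: ProductReference, outdir) -> None:
    """FASTA for each assembly plus a TSV index with labels and lengths.

    Full-product headers are structured ``product|<barcode>|<F>|<R>|<on/off>``
    so any external aligner can consume the assemblies directly.
    """
    os.makedirs(outdir, exist_ok=True)
    full = [
        SeqRecord(Seq(p.sequence),
                  id=f"product|{p.barcode_id}|{p.forward_probe_id}|{p.reverse_probe_id}|"
                     f"{'on' if p.on_diagonal else 'off'}",
                  description="")
        for p in ref.full_products
    ]
    SeqIO.write(full, os.path.join(outdir, "full_products.fa"), "fasta")
    unpaired = [
        SeqRecord(Seq(u.sequence),
                  id=f"unpaired|{u.category}|{u.barcode_id or '-'}|{u.probe_id}",
                  description="")
        for u in ref.unpaired
    ]
    SeqIO.write(unpaired, os.path.join(outdir, "unpaired.fa"), "fasta")
    ref.index_table().to_csv(os.path.join(outdir, "index.tsv"), sep="\t", index=False)
    meta = pd.DataFrame(
        [(b.barcode_id, b.sequence, b.library_label) for b in ref.barcodes],
        columns=["barcode_id", "sequence", "library_label"])
    meta.to_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "tails.tsv"), "w") as fh:
        fh.write(f"forward_tail\t{ref.forward_tail}\n")
        fh.write(f"reverse_tail\t{ref.reverse_tail}\n")
        fh.write(f"include_reverse_tail\t{int(ref.include_reverse_tail)}\n")


def load_reference(outdir) -> ProductReference:
    tails = dict(
        line.strip().split("\t")
        for line in open(os.path.join(outdir, "tails.tsv"))
    )
    bdf = pd.read_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t")
    barcodes = [Barcode(r.barcode_id, r.sequence, r.library_label if isinstance(r.library_label, str) else "")
                for r in bdf.itertuples()]
    full: list[ExpectedProduct] = []
    for rec in SeqIO.parse(os.path.join(outdir, "full_products.fa"), "fasta"):
        _, bc, f, r, diag = rec.id.split("|")
        full.append(ExpectedProduct(product_id(bc, f, r), bc, f, r,
                                    str(rec.seq), diag == "on"))
    unpaired: list[UnpairedSequence] = []
    for rec in SeqIO.parse(os.path.join(outdir, "unpaired.fa"), "fasta"):
        _, cat, bc, probe = rec.id.split("|")
        bc_id = None if bc == "-" else bc
        if cat == UNPAIRED_BARCODE_FORWARD:
            rid = f"{bc_id}|{probe}"
        elif cat == UNPAIRED_FORWARD:
            rid = f"F|{probe}"
        else:
            rid = f"R|{probe}"
        unpaired.append(UnpairedSequence(cat, rid, bc_id, probe, str(rec.seq)))
    return ProductReference(
        full_products=full,
        unpaired=unpaired,
        barcodes=barcodes,
        forward_tail=tails["forward_tail"],
        reverse_tail=tails["reverse_tail"],
        include_reverse_tail=bool(int(tails["include_reverse_tail"])),
    )
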