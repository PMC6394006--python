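# twocchip

Design, simulation, read assignment, and quantification for **2C-ChIP**
(carbon copy ChIP) — a targeted, multiplexed assay that quantifies ChIP
signal over predefined genomic regions by ligation-mediated amplification
(LMA).

## Who this is for

Labs running (or evaluating) targeted ChIP quantification over regions of
interest — e.g. a developmental gene cluster across a differentiation time
course — who need the computational arm of the assay: a primer panel tiling
the target, the expected-product references, demultiplexing and counting of
the sequenced ligation products, input normalization, and genome-browser
tracks, plus a ground-truth simulator so the whole pipeline is testable
without sequencing data.

## The method in brief

For each probed position a forward and a reverse primer anneal contiguously
on the same template strand; a nick-sealing ligase joins only correctly
juxtaposed pairs, so each ligation product's read count reports local
template abundance. Primers carry universal tails (T3-complement forward,
P1-key-complement reverse) for one-step amplification, and an 8-nt barcode
read first for multiplexing. Reads are assigned in two passes — first
against all barcode × F_i × R_j products (minimum aligned length 50 nt),
then leftovers against unpaired barcode-F / F / R sequences (minimum 22 nt);
only uniquely top-scoring reads are assigned. Products with i ≠ j
("off-diagonal") are non-specific ligation artifacts tracked as a library
quality metric. Per-probe enrichment is

```
value_i = count_i / N_product × 10⁶ × seq_dilution × linearity_dilution   (× input_fraction for ChIP)
signal_i = value_i(ChIP) / value_i(input)
```

written as a bedGraph track. See `docs/methods.md` for the full model,
defaults, and limitations.

## Worked example

```python
import twocchip as tc

genome = tc.simulate_genome(30_000, gc=0.5, seed=11)
panel = tc.tile_region(genome, tc.GenomicInterval("chrS", 0, 30_000),
                       target_spacing=1400)
panel = tc.PrimerPanel(panel.pairs[:20])

barcodes = tc.make_barcodes(2, seed=5)           # BC01 = ChIP, BC02 = input
ref = tc.build_reference(panel, barcodes)
print(len(ref.full_products), ref.min_full_product_len)
# 800 expected products (2 barcodes x 20 x 20), min length 72 nt

profile = tc.simulate_profile(panel, n_peaks=2, peak_height=8.0,
                              jitter=0.5, seed=4)
chip_reads, truth = tc.simulate_library(ref, profile, "BC01", 20_000,
                                        off_diagonal_rate=0.05,
                                        error_rate=0.005, seed=9)
input_reads, _ = tc.simulate_library(ref, tc.flat_profile(panel), "BC02",
                                     20_000, off_diagonal_rate=0.05,
                                     error_rate=0.005, seed=10)

assignments = tc.two_step_assign(chip_reads + input_reads, ref)
table = tc.tabulate(tc.split_by_barcode(assignments), ref)
q = tc.run_qc(table)
print(f"mapped on-diagonal: {q.product_fraction:.1%}, "
      f"off-diagonal: {q.off_diagonal_fraction_all:.1%}")
# mapped on-diagonal: 95.1%, off-diagonal: 4.8%

chip = tc.normalize_counts(table, tc.LibraryFactors("BC01"), "BC01")
inp = tc.normalize_counts(table, tc.LibraryFactors("BC02", is_input=True), "BC02")
track = tc.chip_input_ratio(chip, inp, panel)
rho = tc.spearman(profile.occupancy.loc[track.data.index], track.values)
print(f"Spearman(true occupancy, recovered ChIP/input): {rho:.3f}")
# Spearman(true occupancy, recovered ChIP/input): 0.991

tc.write_bedgraph(track, "chip_over_input.bedGraph")
```

The recovered track ranks probes almost identically to the simulated
occupancy (ρ = 0.991 at this depth), the off-diagonal estimate matches the
simulated 5% artifact rate, and the bedGraph starts:

```
track type=bedGraph
chrS	0	44	0.0416844
chrS	1400	1444	0.0267582
```

(values are ChIP/input ratios scaled by the 0.10 input fraction, so a
background probe sits near 0.02–0.04 here and peak probes ~8× higher).

The same pipeline is available as a CLI —
`twocchip design | build-ref | simulate | map | quantify | qc` — each
subcommand a thin wrapper over the functions above.

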