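import pytest

import twocchip as tc


@pytest.fixture(scope="session")
def genome():
    return tc.simulate_genome(30000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def panel(genome):
    full = tc.tile_region(genome, tc.GenomicInterval("chrS", 0, 30000),
                          target_spacing=1400)
    return tc.PrimerPanel(full.pairs[:20])


@pytest.fixture(scope="session")
def barcodes():
    return tc.make_barcodes(2, seed=5)


@pytest.fixture(scope="session")
def reference(panel, barcodes):
    return tc.build_reference(panel, barcodes)


@pytest.fixture()
def tiny_panel():
    """Hand-built two-pair panel with 22-nt homologies (no design constraints)."""
    seqs = [
        ("GATTACAGATTACAGATTACAG", "CTTGAGGACTTGAGGACTTGAG"),
        ("ACCGTTACCGTTACCGTTACCG", "TGGCATTGGCATTGGCATTGGC"),
    ]
    pairs = []
    pos = 100
    for i, (f, r) in enumerate(seqs):
        j = pos + len(f)
        pairs.append(tc.ProbePair(
            probe_id=f"T{i + 1:02d}",
            junction=j,
            forward_homology=f,
            reverse_homology=r,
            forward_interval=tc.GenomicInterval("chrT", pos, j),
            reverse_interval=tc.GenomicInterval("chrT", j, j + len(r)),
        ))
        pos = j + len(r) + 50
    return tc.PrimerPanel(pairs)


@pytest.fixture()
def tiny_barcodes():
    return [tc.Barcode("BC01", "AACCGGTT", "chip"),
            tc.Barcode("BC02", "TTGGCCAA", "input")]
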