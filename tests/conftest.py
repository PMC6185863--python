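"""Shared fixtures: small deterministic panels and simulated runs."""

import numpy as np
import pytest

from snpselect.assay import AlleleProbe, AssayPanel, LocusProbe, SNPLocusAssay


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_locus(locus_id, bc4a, bc4b, la1, la2, ll, bc8, rng, sym=("A", "G")):
    """Crafted locus with explicit barcodes and target lengths."""
    return SNPLocusAssay(
        locus_id=locus_id,
        allele_probes=(
            AlleleProbe(sym[0], bc4a, _dna(rng, la1)),
            AlleleProbe(sym[1], bc4b, _dna(rng, la2)),
        ),
        locus_probe=LocusProbe(_dna(rng, ll), bc8),
    )


@pytest.fixture
def toy_panel():
    """4-locus valid panel spanning the target-length extremes."""
    rng = np.random.default_rng(42)
    return AssayPanel(
        [
            make_locus("M1", "AACC", "GGTT", 20, 20, 20, "AAGGTTCC", rng),
            make_locus("M2", "ACAC", "TGTG", 29, 28, 28, "CCAATTGG", rng),
            make_locus("M3", "AAAA", "CCCC", 24, 25, 22, "ACGTACGT", rng),
            make_locus("M4", "GGGG", "TTTT", 21, 23, 26, "TTTTAAAA", rng),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
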