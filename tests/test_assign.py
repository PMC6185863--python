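"""Read assignment: barcode lookup, gap filter, rejections, demultiplexing."""

import numpy as np
import pytest

from snpselect._util import revcomp
from snpselect.assay import AssayPanel, assemble_ligation_product, expected_gap
from snpselect.assign import (
    AssignmentPolicy,
    CountTable,
    PanelIndex,
    assign_read,
    count_reads,
    demultiplex,
)
from snpselect.simulate import (
    SimulationConfig,
    make_sample_indexes,
    random_panel,
    simulate_population,
    simulate_reads,
)

from conftest import make_locus


def brute_force_assign(read, panel):
    """Independent oracle: direct string comparison of every (locus, allele,
    offset) triple against the read; the unique match is the assignment."""
    matches = set()
    for locus in panel:
        for ai in (1, 2):
            bc4 = locus.allele_probe(ai).barcode4
            g = expected_gap(locus, ai)
            if len(read) >= 12 + g and read[0:4] == bc4 and read[4 + g: 12 + g] == locus.barcode8:
                matches.add((locus.locus_id, ai))
    return matches


def clean_read(locus, ai, length=126):
    prod = assemble_ligation_product(locus, ai)
    core = prod[29:]
    return (core + "G" * length)[:length]


def test_roundtrip_assignment(toy_panel):
    for locus in toy_panel:
        for ai in (1, 2):
            a = assign_read(clean_read(locus, ai), toy_panel)
            assert (a.locus_id, a.allele_index, a.reason) == (locus.locus_id, ai, None)


def test_unknown_locus_barcode(toy_panel, rng):
    read = "".join(rng.choice(list("ACGT"), size=126))
    a = assign_read(read, toy_panel)
    assert a.reason == "unknown_locus_barcode"


def test_too_short(toy_panel):
    a = assign_read("ACGT" * 10, toy_panel)  # 40 nt < 12 + min gap
    assert a.reason == "too_short"


def test_chimera_gap_mismatch(rng):
    """A chimera joining the allele half of X (La=20) to the locus half of Y
    (allele targets 25/27 nt) shows Y's barcode at an offset matching no
    design gap of Y — rejected as gap_mismatch."""
    x = make_locus("X", "AACC", "GGTT", 20, 20, 24, "AAGGTTCC", rng)
    y = make_locus("Y", "AACC", "GGTT", 25, 27, 24, "CCAATTGG", rng)
    panel = AssayPanel([x, y])
    chimera = x.allele_probe(1).sequence + y.locus_probe.sequence
    read = (chimera[29:] + "G" * 126)[:126]
    # Y's barcode sits at the observed gap 20 + 24 = 44 (a design gap of X,
    # so it is scanned); Y's own design gaps are 49 and 51
    assert read[4 + 44: 12 + 44] == "CCAATTGG"
    a = assign_read(read, panel)
    assert a.reason == "gap_mismatch"


def test_unknown_allele_barcode(rng):
    x = make_locus("X", "AACC", "GGTT", 20, 20, 22, "AAGGTTCC", rng)
    panel = AssayPanel([x])
    read = clean_read(x, 1)
    read = "TTTT" + read[4:]  # corrupt the allele barcode
    a = assign_read(read, panel)
    assert a.reason == "unknown_allele_barcode"


def test_gap_check_optional(rng):
    """Disabling require_gap_match accepts a wrong-distance product."""
    x = make_locus("X", "AACC", "GGTT", 20, 20, 24, "AAGGTTCC", rng)
    y = make_locus("Y", "AACC", "GGTT", 25, 27, 24, "CCAATTGG", rng)
    panel = AssayPanel([x, y])
    chimera = x.allele_probe(1).sequence + y.locus_probe.sequence
    read = (chimera[29:] + "G" * 126)[:126]
    a = assign_read(read, panel, AssignmentPolicy(require_gap_match=False))
    assert a.assigned and a.locus_id == "Y"


def test_one_mismatch_mode_recovers_barcode_errors(toy_panel):
    locus = toy_panel["M1"]
    read = clean_read(locus, 1)
    g = expected_gap(locus, 1)
    pos = 4 + g + 3  # inside the 8-nt locus barcode
    bad = read[:pos] + ("A" if read[pos] != "A" else "C") + read[pos + 1:]
    assert assign_read(bad, toy_panel).reason == "unknown_locus_barcode"
    a = assign_read(bad, toy_panel, AssignmentPolicy(max_barcode_mismatches=1))
    assert a.assigned and a.locus_id == "M1"


def test_verify_targets_mode(toy_panel):
    locus = toy_panel["M1"]
    read = clean_read(locus, 1)
    policy = AssignmentPolicy(verify_targets=True)
    assert assign_read(read, toy_panel, policy).assigned
    # scramble the target region (keep both barcodes and the gap intact)
    scrambled = read[:10] + revcomp(read[10:40]) + read[40:]
    a = assign_read(scrambled, toy_panel, policy)
    assert a.reason in ("target_mismatch", "unknown_locus_barcode")


def test_oracle_equivalence_on_random_reads(rng):
    """assign_read agrees with the brute-force all-triples oracle on valid,
    mutated and random reads over random panels."""
    for seed in (0, 1):
        panel = random_panel(30, seed)
        index = PanelIndex(panel, AssignmentPolicy())
        loci = panel.loci
        for _ in range(150):
            kind = rng.integers(3)
            if kind == 0:
                read = "".join(rng.choice(list("ACGT"), size=126))
            else:
                locus = loci[rng.integers(len(loci))]
                read = clean_read(locus, int(rng.integers(1, 3)))
                if kind == 2:
                    for p in rng.choice(100, size=3, replace=False):
                        read = read[:p] + "ACGT"[rng.integers(4)] + read[p + 1:]
            expected = brute_force_assign(read, panel)
            a = assign_read(read, panel, index=index)
            if len(expected) == 1:
                assert (a.locus_id, a.allele_index) == next(iter(expected))
            else:
                assert not a.assigned


def test_counts_match_truth_exactly(toy_panel, tmp_path):
    """Error-free, chimera-free simulation: counts equal the truth table."""
    g = simulate_population("F2", 8, toy_panel, rng=70)
    samples = make_sample_indexes(g.sample_ids, "F2", 71)
    cfg = SimulationConfig(depth_mean=25, base_error_rate=0.0, chimera_rate=0.0, seed=72)
    res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / "reads")
    table = count_reads(samples, toy_panel)
    assert table.rejected_total() == 0
    tc = res.truth_counts()
    for row in tc.itertuples():
        assert table.counts[(row.sample, row.locus)][row.allele - 1] == row.count
    assert table.assigned_total() == len(res.truth)


def test_conservation_under_noise(toy_panel, tmp_path):
    g = simulate_population("F2", 6, toy_panel, rng=80)
    samples = make_sample_indexes(g.sample_ids, "F2", 81)
    cfg = SimulationConfig(depth_mean=25, base_error_rate=0.01, chimera_rate=0.05, seed=82)
    res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / "reads")
    table = count_reads(samples, toy_panel)
    assert table.assigned_total() + table.rejected_total() == len(res.truth)
    for s in samples:
        n = (res.truth["sample"] == s.sample_id).sum()
        assert table.assigned_total(s.sample_id) + table.rejected_total(s.sample_id) == n


def test_assignment_rate_matches_barcode_survival(tmp_path):
    """With substitution rate e and exact matching, the assignment rate is
    close to (1-e)^12 — the chance the 12 barcode bases survive."""
    panel = random_panel(12, 3)
    g = simulate_population("F2", 10, panel, rng=90)
    samples = make_sample_indexes(g.sample_ids, "F2", 91)
    cfg = SimulationConfig(depth_mean=60, base_error_rate=0.01, chimera_rate=0.0, seed=92)
    res = simulate_reads(g, panel, samples, cfg, tmp_path / "reads")
    table = count_reads(samples, panel)
    rate = table.assigned_total() / len(res.truth)
    assert abs(rate - 0.99**12) < 0.02


def test_empty_fastq(toy_panel, tmp_path):
    samples = make_sample_indexes(["s1"], "F2", 95)
    path = tmp_path / "s1.fastq"
    path.write_text("")
    table = count_reads(samples, toy_panel, fastq_paths={"s1": str(path)})
    assert table.assigned_total() == 0 and table.rejected_total() == 0
    assert all(sum(v) == 0 for v in table.counts.values())


def test_count_table_tsv_dialect_and_roundtrip(toy_panel, tmp_path):
    samples = make_sample_indexes(["s1", "s2"], "F2", 96)
    table = CountTable([s.sample_id for s in samples], toy_panel.locus_ids,
                       allele_symbols={l.locus_id: (l.allele_probes[0].allele_symbol,
                                                    l.allele_probes[1].allele_symbol)
                                       for l in toy_panel})
    table.add("s1", "M1", 1)
    table.add("s1", "M1", 2)
    text = table.to_tsv()
    lines = text.splitlines()
    assert lines[0] == "sample\tlocus\tallele1\tcount1\tallele2\tcount2"
    assert len(lines) == 1 + 2 * 4  # full sample x locus grid
    assert lines[1].startswith("s1\tM1\t")
    back = CountTable.from_tsv(text)
    assert back.counts == table.counts
    assert back.to_tsv() == text


def test_demultiplex_routes_by_index_pair(tmp_path):
    samples = make_sample_indexes(["s1", "s2"], "F2", 97)
    recs = []
    for i, s in enumerate(samples):
        for j in range(3):
            recs.append(f"@r{i}_{j} 1:N:0:{s.i5}+{s.i7}\nACGTACGT\n+\nIIIIIIII\n")
    recs.append("@novel 1:N:0:AAAAAA+CCCCC\nACGTACGT\n+\nIIIIIIII\n")
    mux = tmp_path / "mux.fastq"
    mux.write_text("".join(recs))
    paths = demultiplex(mux, samples, tmp_path / "demux")
    def n_reads(p):
        return len(open(p).read().splitlines()) // 4
    assert n_reads(paths["s1"]) == 3 and n_reads(paths["s2"]) == 3
    assert n_reads(paths["Undetermined"]) == 1
    assert sum(n_reads(p) for p in paths.values()) == 7


def test_demultiplex_collision_goes_undetermined(tmp_path):
    """Two samples within the mismatch radius: the read is never
    double-assigned, it goes to Undetermined."""
    samples = make_sample_indexes(["s1", "s2"], "F2", 98)
    s1, s2 = samples
    s2.i5 = s1.i5
    i7 = list(s1.i7)
    i7[0] = "A" if i7[0] != "A" else "C"
    s2.i7 = "".join(i7)  # Hamming distance 1 from s1.i7
    mux = tmp_path / "mux.fastq"
    mux.write_text(f"@r1 1:N:0:{s1.i5}+{s1.i7}\nACGT\n+\nIIII\n")
    paths = demultiplex(mux, samples, tmp_path / "demux", max_index_mismatches=1)
    assert len(open(paths["Undetermined"]).read().splitlines()) // 4 == 1
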