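"""Population and read simulation: distributions, layout, determinism."""

import hashlib
import math

import numpy as np
import pytest
from scipy import stats

from snpselect.assay import expected_gap
from snpselect.assign import AssignmentPolicy, count_reads
from snpselect.samples import read_sample_sheet, write_sample_sheet
from snpselect.simulate import (
    SimulationConfig,
    make_sample_indexes,
    random_panel,
    simulate_population,
    simulate_reads,
)

from conftest import make_locus
from snpselect.assay import AssayPanel


def test_f2_genotype_frequencies_converge():
    """F2 draws follow 1:2:1; chi-square GOF at n=10,000 and the 4-sd bound."""
    g = simulate_population("F2", 10_000, ["L1"], rng=0)
    counts = g.calls["L1"].value_counts()
    obs = [counts.get(k, 0) for k in "AHB"]
    _, p = stats.chisquare(obs, f_exp=[2500, 5000, 2500])
    assert p > 1e-6
    for o, e in zip(obs, [2500, 5000, 2500]):
        sd = math.sqrt(10_000 * (e / 10_000) * (1 - e / 10_000))
        assert abs(o - e) < 4 * sd


def test_ril_residual_heterozygosity():
    g0 = simulate_population("RIL", 500, ["L1", "L2"], residual_het=0.0, rng=1)
    assert not (g0.calls == "H").to_numpy().any()
    g2 = simulate_population("RIL", 2000, ["L1"], residual_het=0.1, rng=2)
    h_frac = (g2.calls == "H").to_numpy().mean()
    assert 0.05 < h_frac < 0.15


def test_germplasm_is_homozygous():
    g = simulate_population("germplasm", 200, ["L1", "L2", "L3"], rng=3)
    assert set(np.unique(g.calls.to_numpy())) <= {"A", "B"}


def test_unknown_population_kind():
    with pytest.raises(ValueError, match="unknown population kind"):
        simulate_population("BC1", 10, ["L1"], rng=0)


@pytest.fixture
def small_run(toy_panel, tmp_path):
    g = simulate_population("F2", 6, toy_panel, rng=10)
    samples = make_sample_indexes(g.sample_ids, "F2", 11)
    cfg = SimulationConfig(depth_mean=15, base_error_rate=0.0, chimera_rate=0.0, seed=12)
    res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / "reads")
    return g, samples, cfg, res


def test_clean_reads_have_design_layout(toy_panel, small_run):
    """With no errors/chimeras every read starts with a valid allele barcode
    for its truth locus and shows the locus barcode at offset 4 + gap."""
    g, samples, cfg, res = small_run
    reads = {}
    for sid, path in res.fastq_paths.items():
        with open(path) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            reads[lines[i][1:].split()[0]] = lines[i + 1]
    assert len(reads) == len(res.truth)
    for row in res.truth.itertuples():
        seq = reads[row.read_id]
        locus = toy_panel[row.locus]
        probe = locus.allele_probe(row.allele)
        assert seq[0:4] == probe.barcode4
        gap = expected_gap(locus, row.allele)
        assert seq[4 + gap: 12 + gap] == locus.barcode8
        assert len(seq) == cfg.read_length


def test_read_count_conservation(small_run):
    g, samples, cfg, res = small_run
    n_fastq = 0
    for path in res.fastq_paths.values():
        with open(path) as fh:
            n_fastq += sum(1 for _ in fh) // 4
    assert n_fastq == len(res.truth)
    tc = res.truth_counts()
    assert tc["count"].sum() == len(res.truth)


def test_simulation_determinism(toy_panel, tmp_path):
    """Identical (config, seed) produce byte-identical FASTQ files."""
    g = simulate_population("F2", 4, toy_panel, rng=20)
    samples = make_sample_indexes(g.sample_ids, "F2", 21)
    cfg = SimulationConfig(depth_mean=20, seed=22)
    hashes = []
    for d in ("a", "b"):
        res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / d)
        digest = hashlib.sha256()
        for sid in sorted(res.fastq_paths):
            digest.update(open(res.fastq_paths[sid], "rb").read())
        hashes.append(digest.hexdigest())
    assert hashes[0] == hashes[1]


def test_all_chimeras_rejected_with_pairwise_distinct_allele_lengths(rng, tmp_path):
    """On a panel whose allele-target lengths differ pairwise between loci,
    a chimeric read's observed barcode distance never equals a design
    distance, so the gap filter rejects every chimera downstream."""
    panel = AssayPanel(
        [
            make_locus("X1", "AACC", "GGTT", 20, 20, 22, "AAGGTTCC", rng),
            make_locus("X2", "ACAC", "TGTG", 24, 24, 22, "CCAATTGG", rng),
            make_locus("X3", "AAAA", "CCCC", 28, 28, 22, "ACGTACGT", rng),
        ]
    )
    g = simulate_population("F2", 4, panel, rng=30)
    samples = make_sample_indexes(g.sample_ids, "F2", 31)
    cfg = SimulationConfig(depth_mean=20, base_error_rate=0.0, chimera_rate=1.0, seed=32)
    simulate_reads(g, panel, samples, cfg, tmp_path / "reads")
    table = count_reads(samples, panel)
    assert table.assigned_total() == 0
    reasons = set()
    for sid in table.sample_ids:
        reasons |= set(table.rejections[sid])
    assert reasons <= {"gap_mismatch", "unknown_allele_barcode", "unknown_locus_barcode"}


def test_locus_first_layout_roundtrip(toy_panel, tmp_path):
    """Opposite-strand reads assign correctly under the matching policy."""
    g = simulate_population("F2", 4, toy_panel, rng=40)
    samples = make_sample_indexes(g.sample_ids, "F2", 41)
    cfg = SimulationConfig(depth_mean=15, base_error_rate=0.0, chimera_rate=0.0,
                           layout="locus-first", seed=42)
    res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / "reads")
    table = count_reads(samples, toy_panel, AssignmentPolicy(layout="locus-first"))
    assert table.assigned_total() == len(res.truth)
    assert table.rejected_total() == 0


def test_dropout_zeroes_loci(toy_panel, tmp_path):
    g = simulate_population("F2", 30, toy_panel, rng=50)
    samples = make_sample_indexes(g.sample_ids, "F2", 51)
    cfg = SimulationConfig(depth_mean=20, dropout_rate=1.0, seed=52)
    res = simulate_reads(g, toy_panel, samples, cfg, tmp_path / "reads")
    assert len(res.truth) == 0


def test_sample_sheet_roundtrip(tmp_path):
    samples = make_sample_indexes([f"s{i}" for i in range(5)], "RIL", 60,
                                  duplicate_groups={"s0": "dupA", "s1": "dupA"})
    path = tmp_path / "sheet.tsv"
    write_sample_sheet(samples, path)
    back = read_sample_sheet(path)
    assert [s.sample_id for s in back] == [s.sample_id for s in samples]
    assert back[0].duplicate_group == "dupA" and back[2].duplicate_group is None
    assert write_sample_sheet(back) == write_sample_sheet(samples)


def test_sample_sheet_rejects_duplicate_index_pair():
    samples = make_sample_indexes(["s1", "s2"], "F2", 61)
    samples[1].i5, samples[1].i7 = samples[0].i5, samples[0].i7
    with pytest.raises(ValueError, match="duplicate index pair"):
        write_sample_sheet(samples)


def test_config_yaml_roundtrip():
    cfg = SimulationConfig(depth_mean=33.5, depth_dispersion=math.inf,
                           base_error_rate=0.01, seed=7)
    back = SimulationConfig.from_yaml(cfg.to_yaml())
    assert back == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(base_error_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(read_length=50)
    with pytest.raises(ValueError):
        SimulationConfig(layout="sideways")
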