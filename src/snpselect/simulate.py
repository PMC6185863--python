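"""Synthetic data: population genotypes and amplicon reads for an OLA panel.

The generator produces the inputs the downstream pipeline expects:

* genotype matrices for the three study designs — an F2 population
  (1:2:1 segregation), recombinant inbred lines (1:1 with residual
  heterozygosity) and an inbred germplasm collection (homozygous calls at
  locus-specific allele frequencies);
* per-sample single-end FASTQ files whose reads have the exact ligated-probe
  layout (allele barcode, allele target, locus target, locus barcode, probe
  tail, then amplicon flank), with i.i.d. substitution errors, negative-
  binomial depth dispersion, chimeric ligation products that join probe
  halves of different loci, and whole-locus dropout;
* a truth table recording each read's source (sample, locus, allele,
  chimera status) for downstream accuracy measurement.

Identical configuration and seed give byte-identical output files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp
from .assay import (
    TAIL3P,
    TAIL5P,
    ALLELE_TARGET_RANGE,
    LOCUS_TARGET_RANGE,
    MIN_PRIMER_OVERLAP,
    AlleleProbe,
    AssayPanel,
    LocusProbe,
    PrimerConstants,
    SampleIndex,
    SNPLocusAssay,
    _suffix_prefix_overlap,
    assemble_ligation_product,
)
from .genotypes import GenotypeMatrix
from .samples import check_unique_indexes

BASES = np.frombuffer(b"ACGT", dtype="S1")

LAYOUTS = ("allele-first", "locus-first")


@dataclass
class SimulationConfig:
    """Parameters of the read simulator.

    depth_mean
        Expected reads per (sample, locus) before dropout.
    depth_dispersion
        Negative-binomial size parameter; ``inf`` gives Poisson depth.
    base_error_rate
        Per-base substitution probability, i.i.d. over the read.
    chimera_rate
        Fraction of reads whose locus-probe half (locus target + locus
        barcode) is swapped for that of a different, uniformly chosen locus —
        emulating incorrect ligation products.
    het_balance
        Expected allele-1 fraction in heterozygotes.
    het_split
        ``"binomial"`` draws the allele-1 count from Binomial(depth, q);
        ``"exact"`` uses round(depth * q) — a fully noise-free control.
    dropout_rate
        Probability that a (sample, locus) yields zero reads, emulating loci
        absent from a germplasm accession.
    read_length
        Single-read length in nt; must cover the widest barcode span
        (4 + 57 + 8 = 69 nt).
    layout
        ``"allele-first"`` reads start at the allele barcode;
        ``"locus-first"`` reads come from the opposite strand and start at
        the (reverse-complemented) locus barcode.
    """

    depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    base_error_rate: float = 0.002
    chimera_rate: float = 0.01
    het_balance: float = 0.5
    het_split: str = "binomial"
    dropout_rate: float = 0.0
    read_length: int = 126
    layout: str = "allele-first"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "chimera_rate", "het_balance", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not (self.depth_dispersion > 0):
            raise ValueError("depth_dispersion must be > 0 (inf for Poisson)")
        if self.read_length < 69:
            raise ValueError("read_length must be >= 69 (maximum barcode span)")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.het_split not in ("binomial", "exact"):
            raise ValueError("het_split must be 'binomial' or 'exact'")

    def to_yaml(self, path=None):
        d = asdict(self)
        if math.isinf(d["depth_dispersion"]):
            d["depth_dispersion"] = "inf"
        text = yaml.safe_dump(d, sort_keys=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path_or_text) -> "SimulationConfig":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            d = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                d = yaml.safe_load(fh)
        if str(d.get("depth_dispersion", "")).lower() in ("inf", ".inf"):
            d["depth_dispersion"] = math.inf
        return cls(**d)


# ------------------------------------------------------------ random designs


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length).astype("U1"))


def random_panel(
    n_loci: int,
    rng: np.random.Generator | int = 0,
    allele_target_lengths: tuple[int, int] = ALLELE_TARGET_RANGE,
    locus_target_lengths: tuple[int, int] = LOCUS_TARGET_RANGE,
    prefix: str = "L",
) -> AssayPanel:
    """Generate a valid random panel (unique locus barcodes, valid lengths)."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    seen8: set[str] = set()
    loci = []
    for i in range(n_loci):
        while True:
            bc8 = _random_dna(rng, 8)
            if bc8 not in seen8:
                seen8.add(bc8)
                break
        while True:
            bc4a, bc4b = _random_dna(rng, 4), _random_dna(rng, 4)
            if bc4a != bc4b:
                break
        sym1, sym2 = rng.choice(np.array(list("ACGT")), size=2, replace=False)
        la1 = int(rng.integers(allele_target_lengths[0], allele_target_lengths[1] + 1))
        la2 = int(rng.integers(allele_target_lengths[0], allele_target_lengths[1] + 1))
        ll = int(rng.integers(locus_target_lengths[0], locus_target_lengths[1] + 1))
        loci.append(
            SNPLocusAssay(
                locus_id=f"{prefix}{i + 1:04d}",
                allele_probes=(
                    AlleleProbe(str(sym1), bc4a, _random_dna(rng, la1)),
                    AlleleProbe(str(sym2), bc4b, _random_dna(rng, la2)),
                ),
                locus_probe=LocusProbe(_random_dna(rng, ll), bc8),
            )
        )
    return AssayPanel(loci)


def make_sample_indexes(
    sample_ids: list[str],
    dataset: str = "other",
    rng: np.random.Generator | int = 0,
    duplicate_groups: dict[str, str] | None = None,
) -> list[SampleIndex]:
    """Assign unique (i5, i7) dual indexes to the given sample ids."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    seen: set[tuple[str, str]] = set()
    out = []
    for sid in sample_ids:
        while True:
            pair = (_random_dna(rng, 6), _random_dna(rng, 5))
            if pair not in seen:
                seen.add(pair)
                break
        out.append(
            SampleIndex(
                sample_id=sid,
                i5=pair[0],
                i7=pair[1],
                dataset=dataset,
                duplicate_group=(duplicate_groups or {}).get(sid),
            )
        )
    check_unique_indexes(out)
    return out


# -------------------------------------------------------------- populations


def simulate_population(
    kind: str,
    n_samples: int,
    panel: AssayPanel | list[str],
    residual_het: float = 0.02,
    freq_range: tuple[float, float] = (0.05, 0.95),
    rng: np.random.Generator | int = 0,
    sample_prefix: str | None = None,
) -> GenotypeMatrix:
    """Draw a genotype matrix for one of the three study designs.

    F2: independent 1:2:1 draws per locus.  RIL: A and B each with
    probability (1 - h)/2 where h is the residual heterozygosity.
    Germplasm: inbred lines, homozygous A/B at a per-locus allele frequency
    drawn uniformly from ``freq_range``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    locus_ids = panel.locus_ids if isinstance(panel, AssayPanel) else list(panel)
    n_loci = len(locus_ids)
    if kind == "F2":
        probs = [0.25, 0.5, 0.25]
        symbols = np.array(["A", "H", "B"])
    elif kind == "RIL":
        h = residual_het
        probs = [(1 - h) / 2, h, (1 - h) / 2]
        symbols = np.array(["A", "H", "B"])
    elif kind == "germplasm":
        p = rng.uniform(freq_range[0], freq_range[1], size=n_loci)
        draws = rng.random((n_samples, n_loci)) < p[None, :]
        calls_arr = np.where(draws, "A", "B")
        symbols = None
    else:
        raise ValueError(f"unknown population kind {kind!r}; expected F2, RIL or germplasm")
    if symbols is not None:
        idx = rng.choice(3, size=(n_samples, n_loci), p=probs)
        calls_arr = symbols[idx]
    prefix = sample_prefix if sample_prefix is not None else kind
    sample_ids = [f"{prefix}_{i + 1:04d}" for i in range(n_samples)]
    calls = pd.DataFrame(calls_arr, index=sample_ids, columns=locus_ids)
    return GenotypeMatrix(calls, pd.Series(kind, index=sample_ids))


# -------------------------------------------------------------------- reads

_GENOTYPE_Q = {"A": 1.0, "B": 0.0}


@dataclass
class SimulationResult:
    """Simulator outputs: FASTQ paths per sample and the read truth table."""

    fastq_paths: dict[str, str]
    truth: pd.DataFrame  # read_id, sample, locus, allele, is_chimera
    config: SimulationConfig
    multiplexed_path: str | None = None

    def truth_counts(self) -> pd.DataFrame:
        """Per (sample, locus, allele) read counts from the truth table."""
        return (
            self.truth.groupby(["sample", "locus", "allele"], sort=False)
            .size()
            .rename("count")
            .reset_index()
        )


def _read_from_product(
    product: str,
    suffix3p: str,
    prefix_rc: str,
    layout: str,
    read_length: int,
) -> str:
    """Error-free read for a ligation product in the chosen orientation.

    allele-first: bases from the end of the allele-probe tail onwards, i.e.
    ``barcode4 | targets | barcode8 | tail3p | <amplicon 3' flank>``.
    locus-first: the opposite strand from the locus-probe side, i.e.
    ``revcomp(barcode8) | revcomp(targets) | revcomp(barcode4) |
    revcomp(tail5p) | <flank>``.  Reads shorter than the amplicon remainder
    are padded with G (the no-signal base of two-channel instruments).
    """
    if layout == "allele-first":
        core = product[len(TAIL5P):] + suffix3p
    else:
        core = revcomp(product[: len(product) - len(TAIL3P)]) + prefix_rc
    if len(core) >= read_length:
        return core[:read_length]
    return core + "G" * (read_length - len(core))


def simulate_reads(
    genotypes: GenotypeMatrix,
    panel: AssayPanel,
    samples: list[SampleIndex],
    config: SimulationConfig,
    out_dir,
    constants: PrimerConstants = PrimerConstants(),
    multiplexed: bool = False,
) -> SimulationResult:
    """Write per-sample FASTQ files (plus truth table) for a genotype matrix.

    Per (sample, locus): depth ~ NB(depth_mean, dispersion) (Poisson in the
    dispersion -> inf limit), zeroed on dropout or a U genotype; the allele-1
    read count is Binomial(depth, q) with q = 1 / het_balance / 0 for
    A / H / B.  Each read then independently becomes a chimera (its locus
    half swapped for another locus') and accumulates substitution errors.
    """
    os.makedirs(out_dir, exist_ok=True)
    check_unique_indexes(samples)
    by_id = {s.sample_id: s for s in samples}
    missing = [sid for sid in genotypes.sample_ids if sid not in by_id]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing[:5]}")
    for lid in genotypes.locus_ids:
        if lid not in panel:
            raise ValueError(f"locus {lid} not in panel")

    rng = np.random.default_rng(config.seed)
    L = config.read_length
    e = config.base_error_rate
    k7 = _suffix_prefix_overlap(constants.p7_primer("A" * constants.i7_len), TAIL5P, MIN_PRIMER_OVERLAP)
    k5 = _suffix_prefix_overlap(constants.p5_primer("A" * constants.i5_len), revcomp(TAIL3P), MIN_PRIMER_OVERLAP)
    if not k7 or not k5:
        raise ValueError("amplification primers do not anneal to the probe tails")

    loci = [panel[lid] for lid in genotypes.locus_ids]
    n_loci = len(loci)
    # per-locus probe halves used for chimera construction
    locus_halves = [locus.locus_probe.sequence for locus in loci]

    qual = "I" * L
    truth_rows: list[tuple[str, str, str, int, bool]] = []
    fastq_paths: dict[str, str] = {}
    mux_chunks: list[str] = []
    mux_path = os.path.join(out_dir, "multiplexed.fastq") if multiplexed else None

    for sid in genotypes.sample_ids:
        sample = by_id[sid]
        # sample-specific amplicon flanks that pad the read past the probes
        suffix3p = revcomp(constants.p5_primer(sample.i5)[:-k5])
        prefix_rc = revcomp(constants.p7_primer(sample.i7)[:-k7])
        # error-free base reads per (locus index, allele index)
        base_reads: dict[tuple[int, int], str] = {}
        chunks: list[str] = []
        n_read = 0
        for li, locus in enumerate(loci):
            g = str(genotypes.calls.at[sid, locus.locus_id])
            if g == "U":
                continue
            if g not in _GENOTYPE_Q and g != "H":
                raise ValueError(f"cannot simulate reads for genotype {g!r}")
            if config.dropout_rate and rng.random() < config.dropout_rate:
                continue
            if math.isinf(config.depth_dispersion):
                d = int(rng.poisson(config.depth_mean))
            else:
                k = config.depth_dispersion
                d = int(rng.negative_binomial(k, k / (k + config.depth_mean)))
            if d == 0:
                continue
            q = _GENOTYPE_Q.get(g, config.het_balance)
            if config.het_split == "exact":
                n1 = int(round(d * q))
            else:
                n1 = int(rng.binomial(d, q))
            alleles = np.repeat([1, 2], [n1, d - n1])
            chim = rng.random(d) < config.chimera_rate if config.chimera_rate else np.zeros(d, bool)
            nerr = rng.binomial(L, e, size=d) if e else np.zeros(d, np.int64)
            for j in range(d):
                ai = int(alleles[j])
                if chim[j]:
                    partner = int(rng.integers(n_loci - 1))
                    if partner >= li:
                        partner += 1
                    product = loci[li].allele_probe(ai).sequence + locus_halves[partner]
                    seq = _read_from_product(product, suffix3p, prefix_rc, config.layout, L)
                else:
                    key = (li, ai)
                    seq = base_reads.get(key)
                    if seq is None:
                        product = assemble_ligation_product(locus, ai)
                        seq = _read_from_product(product, suffix3p, prefix_rc, config.layout, L)
                        base_reads[key] = seq
                if nerr[j]:
                    pos = rng.choice(L, size=int(nerr[j]), replace=False)
                    arr = list(seq)
                    for p in pos:
                        alt = "ACGT".replace(arr[p], "")
                        arr[p] = alt[int(rng.integers(len(alt)))]
                    seq = "".join(arr)
                rid = f"{sid}:{n_read + 1:07d}"
                n_read += 1
                truth_rows.append((rid, sid, locus.locus_id, ai, bool(chim[j])))
                if multiplexed:
                    mux_chunks.append(f"@{rid} 1:N:0:{sample.i5}+{sample.i7}\n{seq}\n+\n{qual}\n")
                else:
                    chunks.append(f"@{rid}\n{seq}\n+\n{qual}\n")
        if not multiplexed:
            path = os.path.join(out_dir, f"{sid}.fastq")
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("".join(chunks))
            fastq_paths[sid] = path
            sample.fastq_path = path
    if multiplexed:
        with open(mux_path, "w", encoding="utf-8") as fh:
            fh.write("".join(mux_chunks))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample", "locus", "allele", "is_chimera"]
    )
    return SimulationResult(fastq_paths, truth, config, multiplexed_path=mux_path)


def write_truth_table(result: SimulationResult, path) -> None:
    result.truth.to_csv(path, sep="\t", index=False)
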