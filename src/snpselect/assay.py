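"""Probe/primer architecture of a multiplexed oligonucleotide-ligation (OLA) assay.

Each bi-allelic SNP locus is interrogated by three ligation probes:

* two **allele probes** ``5'-<tail5p><4-nt allele barcode><allele target>-3'``,
  whose 3' end covers the SNP base itself, and
* one **locus probe** ``5'-<locus target><8-nt locus barcode><tail3p>-3'``
  (5'-phosphorylated so it can be ligated), annealing immediately downstream.

Allele-specific ligation joins one allele probe to the locus probe; the
resulting ligation product is amplified with two universal primers that carry
sample indexes and the flow-cell grafting sequences (P5/P7).  A sequence read
therefore encodes the genotype purely in the two embedded barcodes and in the
*distance* between them — the SNP base is never inspected directly.

This module holds the domain types, assembles ligation products and amplicons,
and validates panels (barcode uniqueness, target-length ranges, amplicon size
window).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from ._util import is_dna, revcomp

# Universal probe tails (amplification-primer binding sites); shared by every
# locus in a panel.
TAIL5P = "TGGAGTTCAGACGTGTGCTCTTCCGATCT"  # 29 nt, 5' tail of allele probes
TAIL3P = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGT"  # 31 nt, 3' tail of locus probes

ALLELE_SYMBOLS = frozenset("ACGT+-")

#: allele target length range (nt)
ALLELE_TARGET_RANGE = (20, 29)
#: locus target length range (nt)
LOCUS_TARGET_RANGE = (20, 28)

#: size-selection window applied to amplicons (bp)
AMPLICON_SIZE_WINDOW = (170, 230)

#: minimum exact 3'-end overlap required for primer annealing
MIN_PRIMER_OVERLAP = 10


@dataclass(frozen=True)
class PrimerConstants:
    """Universal amplification-primer segments.

    The P5-side primer is ``p5_prefix + i5 + p5_suffix`` (grafting sequence,
    6-nt sample index, sequencing-primer part); the P7-side primer is
    ``p7_prefix + i7 + p7_suffix`` with a 5-nt index.
    """

    p5_prefix: str = "AATGATACGGCGACCACCGAGATCTACAC"
    p5_suffix: str = "ACACTCTTTCCCTACACGAC"
    p7_prefix: str = "CAAGCAGAAGACGGCATACGAGAT"
    p7_suffix: str = "GTGACTGGAGTTCAGACGTGT"
    i5_len: int = 6
    i7_len: int = 5

    def p5_primer(self, i5: str) -> str:
        if len(i5) != self.i5_len or not is_dna(i5):
            raise ValueError(f"i5 index must be {self.i5_len} nt A/C/G/T, got {i5!r}")
        return self.p5_prefix + i5 + self.p5_suffix

    def p7_primer(self, i7: str) -> str:
        if len(i7) != self.i7_len or not is_dna(i7):
            raise ValueError(f"i7 index must be {self.i7_len} nt A/C/G/T, got {i7!r}")
        return self.p7_prefix + i7 + self.p7_suffix


@dataclass(frozen=True)
class AlleleProbe:
    """Allele-specific ligation probe: ``tail5p | barcode4 | target``."""

    allele_symbol: str
    barcode4: str
    target: str
    tail5p: str = TAIL5P

    def __post_init__(self) -> None:
        if self.allele_symbol not in ALLELE_SYMBOLS:
            raise ValueError(f"allele symbol must be one of ACGT+-, got {self.allele_symbol!r}")
        if len(self.barcode4) != 4 or not is_dna(self.barcode4):
            raise ValueError(f"allele barcode must be 4 nt A/C/G/T, got {self.barcode4!r}")
        if not is_dna(self.target):
            raise ValueError(f"allele target must be A/C/G/T, got {self.target!r}")
        # target length range is a panel-level QC check (validate_panel), so
        # out-of-spec probes can still be parsed and reported
        if self.tail5p != TAIL5P:
            raise ValueError("allele-probe 5' tail does not equal the universal constant")

    @property
    def sequence(self) -> str:
        return self.tail5p + self.barcode4 + self.target


@dataclass(frozen=True)
class LocusProbe:
    """Locus-specific (common) probe: ``target | barcode8 | tail3p``.

    Must be 5'-phosphorylated to serve as the acceptor in ligation.
    """

    target: str
    barcode8: str
    tail3p: str = TAIL3P
    phosphorylated_5p: bool = True

    def __post_init__(self) -> None:
        if len(self.barcode8) != 8 or not is_dna(self.barcode8):
            raise ValueError(f"locus barcode must be 8 nt A/C/G/T, got {self.barcode8!r}")
        if not is_dna(self.target):
            raise ValueError(f"locus target must be A/C/G/T, got {self.target!r}")
        if self.tail3p != TAIL3P:
            raise ValueError("locus-probe 3' tail does not equal the universal constant")

    @property
    def sequence(self) -> str:
        return self.target + self.barcode8 + self.tail3p


@dataclass(frozen=True)
class SNPLocusAssay:
    """One SNP locus: two allele probes plus the common locus probe."""

    locus_id: str
    allele_probes: tuple[AlleleProbe, AlleleProbe]
    locus_probe: LocusProbe

    def __post_init__(self) -> None:
        a1, a2 = self.allele_probes
        if a1.allele_symbol == a2.allele_symbol:
            raise ValueError(f"{self.locus_id}: the two allele symbols must differ")
        # identical allele barcodes are reported by validate_panel rather than
        # rejected here, so a parsed panel can be QC'd as a whole

    def allele_probe(self, allele_index: int) -> AlleleProbe:
        if allele_index not in (1, 2):
            raise ValueError(f"allele_index must be 1 or 2, got {allele_index}")
        return self.allele_probes[allele_index - 1]

    @property
    def barcode8(self) -> str:
        return self.locus_probe.barcode8


@dataclass
class SampleIndex:
    """One sample's combinatorial dual index (6-nt i5 + 5-nt i7)."""

    sample_id: str
    i5: str
    i7: str
    dataset: str = "other"
    duplicate_group: str | None = None
    fastq_path: str | None = None

    def __post_init__(self) -> None:
        if len(self.i5) != 6 or not is_dna(self.i5):
            raise ValueError(f"{self.sample_id}: i5 must be 6 nt A/C/G/T, got {self.i5!r}")
        if len(self.i7) != 5 or not is_dna(self.i7):
            raise ValueError(f"{self.sample_id}: i7 must be 5 nt A/C/G/T, got {self.i7!r}")


class AssayPanel:
    """An ordered multiplex of :class:`SNPLocusAssay`.

    The locus barcode (8-mer) is unique across the panel, so the pair
    (locus barcode, allele barcode) resolves to at most one allele.  4-nt
    allele barcodes may repeat between loci (only 256 exist); they need only
    distinguish the two alleles *within* a locus.
    """

    def __init__(self, loci: list[SNPLocusAssay]):
        self.loci = list(loci)
        self._by_id = {locus.locus_id: locus for locus in self.loci}
        if len(self._by_id) != len(self.loci):
            raise ValueError("duplicate locus_id in panel")
        self.locus_barcode_index: dict[str, SNPLocusAssay] = {}
        for locus in self.loci:
            if locus.barcode8 in self.locus_barcode_index:
                raise ValueError(
                    f"duplicate locus barcode {locus.barcode8} "
                    f"({self.locus_barcode_index[locus.barcode8].locus_id} vs {locus.locus_id})"
                )
            self.locus_barcode_index[locus.barcode8] = locus

    @property
    def plex(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> SNPLocusAssay:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def gap_set(self) -> list[int]:
        """Sorted distinct inter-barcode gaps present in the panel."""
        gaps = {
            expected_gap(locus, ai) for locus in self.loci for ai in (1, 2)
        }
        return sorted(gaps)

    # ------------------------------------------------------------------ I/O

    TSV_COLUMNS = (
        "locus_id",
        "allele1_symbol",
        "allele1_barcode",
        "allele1_target",
        "allele2_symbol",
        "allele2_barcode",
        "allele2_target",
        "locus_target",
        "locus_barcode",
    )

    def to_tsv(self, path=None) -> str | None:
        """Serialize to the one-row-per-locus panel table dialect."""
        buf = io.StringIO()
        buf.write("\t".join(self.TSV_COLUMNS) + "\n")
        for locus in self.loci:
            a1, a2 = locus.allele_probes
            buf.write(
                "\t".join(
                    (
                        locus.locus_id,
                        a1.allele_symbol,
                        a1.barcode4,
                        a1.target,
                        a2.allele_symbol,
                        a2.barcode4,
                        a2.target,
                        locus.locus_probe.target,
                        locus.barcode8,
                    )
                )
                + "\n"
            )
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, path_or_text) -> "AssayPanel":
        """Parse a panel table (UTF-8 TSV, header row, ``#`` comments ignored)."""
        if isinstance(path_or_text, str) and "\t" in path_or_text:
            lines = path_or_text.splitlines()
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        rows = [ln for ln in lines if ln and not ln.startswith("#")]
        if not rows:
            raise ValueError("empty panel table")
        header = tuple(rows[0].split("\t"))
        if header != cls.TSV_COLUMNS:
            raise ValueError(f"unexpected panel header {header}")
        loci = []
        for ln in rows[1:]:
            f = dict(zip(cls.TSV_COLUMNS, ln.split("\t")))
            loci.append(
                SNPLocusAssay(
                    locus_id=f["locus_id"],
                    allele_probes=(
                        AlleleProbe(f["allele1_symbol"], f["allele1_barcode"], f["allele1_target"]),
                        AlleleProbe(f["allele2_symbol"], f["allele2_barcode"], f["allele2_target"]),
                    ),
                    locus_probe=LocusProbe(f["locus_target"], f["locus_barcode"]),
                )
            )
        return cls(loci)


# --------------------------------------------------------------- assembly ops


def assemble_ligation_product(locus: SNPLocusAssay, allele_index: int) -> str:
    """Sequence of the ligated allele-probe + locus-probe molecule.

    Layout: ``tail5p | barcode4 | allele_target | locus_target | barcode8 |
    tail3p``; length is 72 + len(allele_target) + len(locus_target).
    """
    probe = locus.allele_probe(allele_index)
    return probe.sequence + locus.locus_probe.sequence


def expected_gap(locus: SNPLocusAssay, allele_index: int) -> int:
    """Read-space distance between the allele and locus barcodes.

    Number of bases between the end of the 4-nt allele barcode and the start
    of the 8-nt locus barcode: ``len(allele_target) + len(locus_target)``.
    This design distance is what separates genuine ligation products from
    chimeric ones during read assignment.
    """
    return len(locus.allele_probe(allele_index).target) + len(locus.locus_probe.target)


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with a[-k:] == b[:k]; 0 if none."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a.endswith(b[:k]):
            return k
    return 0


def assemble_amplicon(
    product: str,
    sample: SampleIndex,
    constants: PrimerConstants = PrimerConstants(),
) -> str:
    """PCR amplicon from a ligation product, by exact-match primer annealing.

    The P7-side primer's 3' end overlaps the 5' tail of the product (16 nt);
    the P5-side primer's 3' end overlaps the reverse complement of the 3'
    tail (18 nt).  Both overlaps are located by exact string search; a missing
    site signals corrupted constants.  The returned strand reads
    ``P7 flank | product | revcomp(P5 flank)`` — the orientation in which the
    single-read sequencing primer sits immediately 5' of the allele barcode.
    """
    p7 = constants.p7_primer(sample.i7)
    p5 = constants.p5_primer(sample.i5)
    k7 = _suffix_prefix_overlap(p7, product, MIN_PRIMER_OVERLAP)
    if k7 == 0:
        raise ValueError("P7 primer has no exact annealing site on the ligation product")
    bottom = revcomp(product)
    k5 = _suffix_prefix_overlap(p5, bottom, MIN_PRIMER_OVERLAP)
    if k5 == 0:
        raise ValueError("P5 primer has no exact annealing site on the ligation product")
    return p7[:-k7] + product + revcomp(p5[:-k5])


# --------------------------------------------------------------- validation


@dataclass(frozen=True)
class Violation:
    code: str
    locus_id: str
    detail: str = ""


def validate_panel(
    loci: list[SNPLocusAssay] | AssayPanel,
    constants: PrimerConstants = PrimerConstants(),
) -> list[Violation]:
    """QC report for a panel; an empty list means the panel is valid.

    Checks duplicate locus barcodes, identical allele barcodes within a
    locus, target lengths out of range, and amplicon lengths outside the
    size-selection window.  Works on a raw locus list so broken panels can
    be reported rather than rejected at construction.
    """
    if isinstance(loci, AssayPanel):
        loci = loci.loci
    report: list[Violation] = []
    seen8: dict[str, str] = {}
    dummy = SampleIndex("__qc__", "A" * constants.i5_len, "A" * constants.i7_len)
    for locus in loci:
        bc8 = locus.barcode8
        if bc8 in seen8:
            report.append(
                Violation("duplicate_locus_barcode", locus.locus_id,
                          f"{bc8} also used by {seen8[bc8]}")
            )
        else:
            seen8[bc8] = locus.locus_id
        a1, a2 = locus.allele_probes
        if a1.barcode4 == a2.barcode4:
            report.append(Violation("duplicate_allele_barcode", locus.locus_id, a1.barcode4))
        for ai, probe in ((1, a1), (2, a2)):
            lo, hi = ALLELE_TARGET_RANGE
            if not lo <= len(probe.target) <= hi:
                report.append(
                    Violation("target_length", locus.locus_id,
                              f"allele{ai} target {len(probe.target)} nt")
                )
        lo, hi = LOCUS_TARGET_RANGE
        if not lo <= len(locus.locus_probe.target) <= hi:
            report.append(
                Violation("target_length", locus.locus_id,
                          f"locus target {len(locus.locus_probe.target)} nt")
            )
        for ai in (1, 2):
            amp = assemble_amplicon(assemble_ligation_product(locus, ai), dummy, constants)
            wlo, whi = AMPLICON_SIZE_WINDOW
            if not wlo <= len(amp) <= whi:
                report.append(
                    Violation("amplicon_size", locus.locus_id,
                              f"allele{ai} amplicon {len(amp)} bp outside [{wlo}, {whi}]")
                )
    return report
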