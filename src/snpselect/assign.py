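"""Assign reads to (locus, allele) by barcode pair and inter-barcode distance.

A read is assigned without ever inspecting the SNP base: the 4-nt allele
barcode and 8-nt locus barcode are located in the read, and the observed
distance between them must equal the panel's design distance for that
(locus, allele).  Reads from incorrect (chimeric) ligation products carry a
distance that mismatches the design and are excluded; every rejection is
tallied by reason so that assigned + rejected always equals the total.
"""

from __future__ import annotations

import io
import itertools
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import pysam

from ._util import hamming, revcomp
from .assay import AssayPanel, SampleIndex, SNPLocusAssay, expected_gap
from .samples import check_unique_indexes

REJECTION_REASONS = (
    "unknown_locus_barcode",
    "unknown_allele_barcode",
    "gap_mismatch",
    "ambiguous",
    "too_short",
    "target_mismatch",
)


@dataclass(frozen=True)
class AssignmentPolicy:
    """How strictly barcodes are matched.

    max_barcode_mismatches (0 or 1) applies independently to the allele and
    locus barcodes; the default 0 is exact matching — a 4-nt allele barcode
    has no error-correction headroom, and strictness favors specificity.
    With require_gap_match the observed inter-barcode distance must equal the
    design distance (the chimera filter).  verify_targets additionally
    requires >= min_target_identity over the target region.
    """

    max_barcode_mismatches: int = 0
    require_gap_match: bool = True
    layout: str = "allele-first"
    verify_targets: bool = False
    min_target_identity: float = 0.9

    def __post_init__(self) -> None:
        if self.max_barcode_mismatches not in (0, 1):
            raise ValueError("max_barcode_mismatches must be 0 or 1")
        if self.layout not in ("allele-first", "locus-first"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class Assignment:
    """Outcome for one read: a (locus, allele) or a rejection reason."""

    locus_id: str | None
    allele_index: int | None
    reason: str | None

    @property
    def assigned(self) -> bool:
        return self.reason is None


class PanelIndex:
    """Precomputed lookup structures for a panel under one policy."""

    def __init__(self, panel: AssayPanel, policy: AssignmentPolicy):
        self.panel = panel
        self.policy = policy
        self.gaps = panel.gap_set()
        self.min_gap = self.gaps[0]
        self.bc8_exact: dict[str, SNPLocusAssay] = dict(panel.locus_barcode_index)
        self.bc8_fuzzy: dict[str, list[SNPLocusAssay]] | None = None
        if policy.max_barcode_mismatches == 1:
            fuzzy: dict[str, list[SNPLocusAssay]] = {}
            for bc8, locus in self.bc8_exact.items():
                for word in _hamming_ball(bc8):
                    fuzzy.setdefault(word, []).append(locus)
            self.bc8_fuzzy = fuzzy

    def lookup_bc8(self, word: str) -> list[SNPLocusAssay]:
        """Loci whose locus barcode matches *word* within the policy radius.

        In 1-mismatch mode a word within distance 1 of two different locus
        barcodes is ambiguous and matches neither.
        """
        if self.policy.max_barcode_mismatches == 0:
            locus = self.bc8_exact.get(word)
            return [locus] if locus is not None else []
        hits = self.bc8_fuzzy.get(word, [])
        return hits if len(hits) == 1 else []


def _hamming_ball(word: str) -> list[str]:
    out = [word]
    for i, ch in enumerate(word):
        for b in "ACGT":
            if b != ch:
                out.append(word[:i] + b + word[i + 1:])
    return out


def _bc_match(observed: str, designed: str, max_mm: int) -> bool:
    if max_mm == 0:
        return observed == designed
    return hamming(observed, designed) <= max_mm


def assign_read(
    read: str,
    panel: AssayPanel,
    policy: AssignmentPolicy = AssignmentPolicy(),
    index: PanelIndex | None = None,
) -> Assignment:
    """Assign one read, or reject it with the most specific reason.

    Allele-first layout: the candidate allele barcode is ``read[0:4]``; for
    every distinct design gap g the 8-mer at ``read[4+g : 12+g]`` is looked
    up among the locus barcodes; a (locus, allele) survives only when the
    allele barcode matches one of the locus' two allele barcodes and g
    equals that allele's design gap.  Exactly one survivor is an assignment;
    several are "ambiguous"; none yields the most specific rejection
    observed (gap_mismatch > unknown_allele_barcode > unknown_locus_barcode).
    The locus-first layout applies the same algorithm to the opposite-strand
    read (barcodes appear reverse-complemented, locus barcode first).
    """
    if index is None:
        index = PanelIndex(panel, policy)
    if len(read) < 12 + index.min_gap:
        return Assignment(None, None, "too_short")

    locus_first = policy.layout == "locus-first"
    if locus_first:
        bc8_obs_fixed = revcomp(read[0:8])
    else:
        bc4_obs = read[0:4]

    hits: set[tuple[str, int]] = set()
    hit_loci: dict[str, SNPLocusAssay] = {}
    saw_locus = False
    saw_allele = False
    for g in index.gaps:
        if 12 + g > len(read):
            continue
        if locus_first:
            bc8_obs = bc8_obs_fixed
            bc4_obs = revcomp(read[8 + g: 12 + g])
            candidates = index.lookup_bc8(bc8_obs)
        else:
            bc8_obs = read[4 + g: 12 + g]
            candidates = index.lookup_bc8(bc8_obs)
        for locus in candidates:
            saw_locus = True
            for ai in (1, 2):
                if _bc_match(bc4_obs, locus.allele_probe(ai).barcode4,
                             policy.max_barcode_mismatches):
                    saw_allele = True
                    if not policy.require_gap_match or g == expected_gap(locus, ai):
                        hits.add((locus.locus_id, ai))
                        hit_loci[locus.locus_id] = locus
    if len(hits) == 1:
        locus_id, ai = next(iter(hits))
        if policy.verify_targets:
            locus = hit_loci[locus_id]
            probe = locus.allele_probe(ai)
            designed = probe.target + locus.locus_probe.target
            if locus_first:
                observed = revcomp(read[8: 8 + len(designed)])
            else:
                observed = read[4: 4 + len(designed)]
            ident = sum(a == b for a, b in zip(observed, designed)) / len(designed)
            if ident < policy.min_target_identity:
                return Assignment(None, None, "target_mismatch")
        return Assignment(locus_id, ai, None)
    if len(hits) > 1:
        return Assignment(None, None, "ambiguous")
    if saw_allele:
        return Assignment(None, None, "gap_mismatch")
    if saw_locus:
        return Assignment(None, None, "unknown_allele_barcode")
    return Assignment(None, None, "unknown_locus_barcode")


# --------------------------------------------------------------- count table


@dataclass
class CountTable:
    """Per (sample, locus) allele read counts plus per-sample rejections."""

    sample_ids: list[str]
    locus_ids: list[str]
    counts: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    rejections: dict[str, Counter] = field(default_factory=dict)
    allele_symbols: dict[str, tuple[str, str]] = field(default_factory=dict)
    datasets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.sample_ids:
            self.rejections.setdefault(sid, Counter())
            for lid in self.locus_ids:
                self.counts.setdefault((sid, lid), [0, 0])

    def add(self, sample_id: str, locus_id: str, allele_index: int) -> None:
        self.counts[(sample_id, locus_id)][allele_index - 1] += 1

    def reject(self, sample_id: str, reason: str) -> None:
        self.rejections[sample_id][reason] += 1

    def assigned_total(self, sample_id: str | None = None) -> int:
        keys = self.counts if sample_id is None else (
            (sample_id, lid) for lid in self.locus_ids)
        return sum(sum(self.counts[k]) for k in keys)

    def rejected_total(self, sample_id: str | None = None) -> int:
        if sample_id is None:
            return sum(sum(c.values()) for c in self.rejections.values())
        return sum(self.rejections[sample_id].values())

    def depth(self, sample_id: str, locus_id: str) -> int:
        c = self.counts[(sample_id, locus_id)]
        return c[0] + c[1]

    # ------------------------------------------------------------------ I/O

    HEADER = "sample\tlocus\tallele1\tcount1\tallele2\tcount2"

    def to_tsv(self, path=None, provenance: str | None = None):
        """Tab-delimited count table, samples then loci in declared order."""
        buf = io.StringIO()
        if provenance:
            buf.write(f"# {provenance}\n")
        buf.write(self.HEADER + "\n")
        for sid in self.sample_ids:
            for lid in self.locus_ids:
                c1, c2 = self.counts[(sid, lid)]
                a1, a2 = self.allele_symbols.get(lid, ("A", "B"))
                buf.write(f"{sid}\t{lid}\t{a1}\t{c1}\t{a2}\t{c2}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, path_or_text) -> "CountTable":
        if isinstance(path_or_text, str) and "\t" in path_or_text:
            lines = path_or_text.splitlines()
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        rows = [ln for ln in lines if ln and not ln.startswith("#")]
        if rows[0] != cls.HEADER:
            raise ValueError(f"unexpected count-table header {rows[0]!r}")
        sample_ids: list[str] = []
        locus_ids: list[str] = []
        counts: dict[tuple[str, str], list[int]] = {}
        symbols: dict[str, tuple[str, str]] = {}
        for ln in rows[1:]:
            sid, lid, a1, c1, a2, c2 = ln.split("\t")
            if sid not in sample_ids:
                sample_ids.append(sid)
            if lid not in locus_ids:
                locus_ids.append(lid)
            counts[(sid, lid)] = [int(c1), int(c2)]
            symbols[lid] = (a1, a2)
        table = cls(sample_ids, locus_ids, allele_symbols=symbols)
        for k, v in counts.items():
            table.counts[k] = v
        return table

    def rejections_to_tsv(self, path=None, provenance: str | None = None):
        buf = io.StringIO()
        if provenance:
            buf.write(f"# {provenance}\n")
        cols = ["sample", "assigned"] + list(REJECTION_REASONS) + ["total"]
        buf.write("\t".join(cols) + "\n")
        for sid in self.sample_ids:
            a = self.assigned_total(sid)
            rej = [self.rejections[sid].get(r, 0) for r in REJECTION_REASONS]
            buf.write("\t".join([sid, str(a)] + [str(x) for x in rej]
                               + [str(a + sum(rej))]) + "\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None


def count_reads(
    samples: list[SampleIndex],
    panel: AssayPanel,
    policy: AssignmentPolicy = AssignmentPolicy(),
    fastq_paths: dict[str, str] | None = None,
) -> CountTable:
    """Run :func:`assign_read` over every read of every sample's FASTQ.

    FASTQ paths come from the sample sheet (``fastq_path`` column) unless
    given explicitly.  The resulting table covers the full sample x locus
    grid; conservation (assigned + rejected == total) holds per sample.
    """
    check_unique_indexes(samples)
    index = PanelIndex(panel, policy)
    table = CountTable(
        sample_ids=[s.sample_id for s in samples],
        locus_ids=panel.locus_ids,
        allele_symbols={
            locus.locus_id: (locus.allele_probes[0].allele_symbol,
                             locus.allele_probes[1].allele_symbol)
            for locus in panel
        },
        datasets={s.sample_id: s.dataset for s in samples},
    )
    for sample in samples:
        path = (fastq_paths or {}).get(sample.sample_id) or sample.fastq_path
        if not path:
            raise ValueError(f"no FASTQ path for sample {sample.sample_id}")
        if not os.path.exists(path):
            raise FileNotFoundError(f"FASTQ file not found: {path}")
        n = 0
        try:
            with pysam.FastxFile(path) as fh:
                for rec in fh:
                    n += 1
                    a = assign_read(rec.sequence.upper(), panel, policy, index)
                    if a.assigned:
                        table.add(sample.sample_id, a.locus_id, a.allele_index)
                    else:
                        table.reject(sample.sample_id, a.reason)
        except (OSError, ValueError) as exc:
            raise ValueError(
                f"FASTQ parse failure in {path} near record {n + 1}: {exc}"
            ) from exc
    return table


# --------------------------------------------------------------- demultiplex


def demultiplex(
    fastq_path,
    samples: list[SampleIndex],
    out_dir,
    max_index_mismatches: int = 0,
) -> dict[str, str]:
    """Route a multiplexed FASTQ to per-sample files by the header index pair.

    Read headers carry an ``i5+i7`` token (bcl2fastq convention).  A read is
    routed to the unique sample within the mismatch radius; reads matching
    no sample, or more than one, go to ``Undetermined.fastq``.
    """
    check_unique_indexes(samples)
    os.makedirs(out_dir, exist_ok=True)
    handles: dict[str, object] = {}
    paths: dict[str, str] = {}
    try:
        for s in samples:
            paths[s.sample_id] = os.path.join(out_dir, f"{s.sample_id}.fastq")
            handles[s.sample_id] = open(paths[s.sample_id], "w", encoding="utf-8")
        paths["Undetermined"] = os.path.join(out_dir, "Undetermined.fastq")
        handles["Undetermined"] = open(paths["Undetermined"], "w", encoding="utf-8")
        with pysam.FastxFile(str(fastq_path)) as fh:
            for rec in fh:
                token = (rec.comment or "").split(":")[-1]
                dest = "Undetermined"
                if "+" in token:
                    i5, i7 = token.split("+", 1)
                    matches = [
                        s.sample_id
                        for s in samples
                        if len(i5) == len(s.i5) and len(i7) == len(s.i7)
                        and hamming(i5, s.i5) <= max_index_mismatches
                        and hamming(i7, s.i7) <= max_index_mismatches
                    ]
                    if len(matches) == 1:
                        dest = matches[0]
                qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
                comment = f" {rec.comment}" if rec.comment else ""
                handles[dest].write(f"@{rec.name}{comment}\n{rec.sequence}\n+\n{qual}\n")
    finally:
        for h in handles.values():
            h.close()
    return paths
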