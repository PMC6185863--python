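"""Ratio-score genotype calling from allele read counts.

For each (sample, locus) the ratio score is r = count1 / (count1 + count2).
Adjustable boundaries partition [0, 1] into the homozygous classes A
(r >= hom1_min) and B (r <= hom2_max), the heterozygous class H
(het_low <= r <= het_high), and two intermediate bands: C ("B or H",
hom2_max < r < het_low) and D ("A or H", het_high < r < hom1_min).
Intermediates are emitted only on request; by default they become U, as does
anything below the minimum depth.  Boundaries can be adjusted per locus —
useful for sample collections with skewed allele frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .assign import CountTable
from .genotypes import GenotypeMatrix


@dataclass(frozen=True)
class CallBoundaries:
    """Ratio-class thresholds and minimum depth for genotype assignment.

    The defaults (0.90 / 0.70 / 0.30 / 0.10, depth >= 10) are configuration,
    not a published standard; every QC report should state the boundary set
    used.
    """

    min_depth: int = 10
    hom1_min: float = 0.90
    hom2_max: float = 0.10
    het_low: float = 0.30
    het_high: float = 0.70
    emit_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0 <= self.hom2_max < self.het_low <= self.het_high < self.hom1_min <= 1):
            raise ValueError(
                "boundaries must satisfy 0 <= hom2_max < het_low <= het_high < hom1_min <= 1"
            )

    def to_yaml(self, path=None):
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path_or_text) -> "CallBoundaries":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            d = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                d = yaml.safe_load(fh)
        return cls(**d)


def call_genotype(count1: int, count2: int, boundaries: CallBoundaries = CallBoundaries()) -> str:
    """Single-character call for one (sample, locus) count pair."""
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be >= 0")
    depth = count1 + count2
    if depth < boundaries.min_depth:
        return "U"
    r = count1 / depth
    if r >= boundaries.hom1_min:
        return "A"
    if r <= boundaries.hom2_max:
        return "B"
    if boundaries.het_low <= r <= boundaries.het_high:
        return "H"
    if r < boundaries.het_low:
        return "C" if boundaries.emit_intermediates else "U"
    return "D" if boundaries.emit_intermediates else "U"


def call_matrix(
    counts: CountTable,
    boundaries: CallBoundaries = CallBoundaries(),
    per_locus_overrides: dict[str, CallBoundaries] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Call every (sample, locus); returns the matrix and a per-locus summary.

    Per-locus boundary overrides replace the global set for the listed loci
    (the manual-adjustment mechanism).  (sample, locus) combinations absent
    from the table are called U.  The summary holds per-locus class counts,
    mean depth, and the mean/sd of the defined ratio scores.
    """
    overrides = per_locus_overrides or {}
    unknown = set(overrides) - set(counts.locus_ids)
    if unknown:
        raise ValueError(f"boundary overrides for unknown loci: {sorted(unknown)}")
    calls = pd.DataFrame(
        "U", index=counts.sample_ids, columns=counts.locus_ids, dtype=object
    )
    summary_rows = []
    for lid in counts.locus_ids:
        b = overrides.get(lid, boundaries)
        depths, ratios = [], []
        cls: dict[str, int] = {k: 0 for k in "ABHUCD"}
        for sid in counts.sample_ids:
            c1, c2 = counts.counts.get((sid, lid), (0, 0))
            g = call_genotype(c1, c2, b)
            calls.at[sid, lid] = g
            cls[g] += 1
            d = c1 + c2
            depths.append(d)
            if d > 0:
                ratios.append(c1 / d)
        summary_rows.append(
            {
                "locus": lid,
                **{f"n_{k}": cls[k] for k in "ABHUCD"},
                "mean_depth": float(np.mean(depths)) if depths else 0.0,
                "r_mean": float(np.mean(ratios)) if ratios else np.nan,
                "r_sd": float(np.std(ratios)) if ratios else np.nan,
            }
        )
    datasets = pd.Series(
        [counts.datasets.get(sid, "other") for sid in counts.sample_ids],
        index=counts.sample_ids,
    )
    return GenotypeMatrix(calls, datasets), pd.DataFrame(summary_rows).set_index("locus")


# ------------------------------------------------------------------ .loc I/O

_LOC_POPT = {"F2": "F2", "RIL": "RIL"}


def export_loc(matrix: GenotypeMatrix, population_type: str, name: str, path=None):
    """Export a mapping population's calls as a JoinMap-style .loc file.

    Header lines give the dataset name, population type, locus and
    individual counts; each marker record lists lower-case codes
    a/b/h/c/d/u (one per individual).  Germplasm panels are not mapping
    populations and are rejected.
    """
    if population_type not in _LOC_POPT:
        raise ValueError(
            f"population_type must be F2 or RIL (a mapping population), got {population_type!r}"
        )
    buf = io.StringIO()
    buf.write(f"name = {name}\n")
    buf.write(f"popt = {_LOC_POPT[population_type]}\n")
    buf.write(f"nloc = {len(matrix.locus_ids)}\n")
    buf.write(f"nind = {len(matrix.sample_ids)}\n")
    for lid in matrix.locus_ids:
        codes = [str(matrix.calls.at[sid, lid]).lower() for sid in matrix.sample_ids]
        buf.write(f"{lid} {' '.join(codes)}\n")
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return None


def read_loc(path_or_text) -> tuple[GenotypeMatrix, str, str]:
    """Parse a .loc file back into (matrix, population_type, name)."""
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    header: dict[str, str] = {}
    records: list[tuple[str, list[str]]] = []
    for ln in lines:
        if not ln.strip():
            continue
        if "=" in ln and len(records) == 0:
            k, v = ln.split("=", 1)
            header[k.strip()] = v.strip()
        else:
            parts = ln.split()
            records.append((parts[0], [c.upper() for c in parts[1:]]))
    nind = int(header["nind"])
    sample_ids = [f"ind_{i + 1:04d}" for i in range(nind)]
    calls = pd.DataFrame(
        {lid: codes for lid, codes in records}, index=sample_ids
    )
    popt = header["popt"]
    return GenotypeMatrix(calls, pd.Series(popt, index=sample_ids)), popt, header["name"]


def plot_ratio_scores(counts: list[tuple[int, int]]) -> dict[str, list]:
    """Scatter data for raw allele frequencies and ratio scores.

    Returns ``raw`` (one (count1, count2) pair per sample) and ``ratio``
    ((depth, r) pairs; zero-depth samples are excluded because r is
    undefined there).  Pure deterministic transform; plotting is left to the
    caller.
    """
    raw = [(int(c1), int(c2)) for c1, c2 in counts]
    ratio = [
        (c1 + c2, c1 / (c1 + c2)) for c1, c2 in raw if c1 + c2 > 0
    ]
    return {"raw": raw, "ratio": ratio}
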