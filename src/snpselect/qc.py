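"""Validation metrics: call rate, concordance, reproducibility, read totals.

All metrics see the 4-symbol alphabet {A, B, H, U}: the intermediate C/D
classes are collapsed to U first, so "called" always means A, B or H.
Percentages are reported to one decimal, rounded half-up.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import percent
from .genotypes import GenotypeMatrix

QC_ALPHABET = ("A", "B", "H", "U")

#: unordered genotype-pair categories, e.g. ("A", "B") covers A-B and B-A
PAIR_CATEGORIES = tuple(
    tuple(sorted(p)) for p in itertools.combinations_with_replacement(QC_ALPHABET, 2)
)


def _collapse(matrix: GenotypeMatrix) -> pd.DataFrame:
    return matrix.collapse_intermediates().calls


def call_rate(matrix: GenotypeMatrix, group_by: str = "all"):
    """Fraction of sample x locus slots with a non-U call.

    ``group_by="dataset"`` returns a dict of per-dataset rates plus
    ``"total"``; ``"all"`` returns the overall fraction.
    """
    calls = _collapse(matrix)
    if calls.size == 0:
        raise ValueError("empty genotype matrix")
    called = calls.isin(list("ABH"))
    if group_by == "all":
        return float(called.to_numpy().mean())
    if group_by == "dataset":
        out = {}
        for ds, idx in matrix.dataset.groupby(matrix.dataset).groups.items():
            out[str(ds)] = float(called.loc[idx].to_numpy().mean())
        out["total"] = float(called.to_numpy().mean())
        return out
    raise ValueError(f"group_by must be 'all' or 'dataset', got {group_by!r}")


def call_rate_from_counts(called: int, capacity: int) -> float:
    """Call rate (%) from summary counts, e.g. a published table row."""
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    return percent(called / capacity)


@dataclass
class ConcordanceReport:
    """Pairwise genotype comparison over shared (sample, locus) slots.

    ``contingency`` counts every unordered genotype-pair category over
    {A, B, H, U}; ``n_shared`` are the slots called (non-U) in both
    datasets, and the concordance rate is computed over those only.
    """

    contingency: dict[tuple[str, str], int]
    n_total: int
    n_shared: int
    n_concordant: int

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_total if self.n_total else float("nan")

    @property
    def concordance_rate(self) -> float:
        return self.n_concordant / self.n_shared if self.n_shared else float("nan")

    @property
    def shared_percent(self) -> float:
        return percent(self.shared_fraction)

    @property
    def concordance_percent(self) -> float:
        return percent(self.concordance_rate)

    @classmethod
    def from_contingency(cls, contingency: dict) -> "ConcordanceReport":
        """Build a report from pair-category counts (e.g. a published table)."""
        cont = {tuple(sorted(k)): int(v) for k, v in contingency.items()}
        bad = set(cont) - set(PAIR_CATEGORIES)
        if bad:
            raise ValueError(f"unknown pair categories {sorted(bad)}")
        n_total = sum(cont.values())
        n_shared = sum(v for k, v in cont.items() if "U" not in k)
        n_concordant = sum(v for k, v in cont.items() if "U" not in k and k[0] == k[1])
        return cls(cont, n_total, n_shared, n_concordant)

    def to_text(self) -> str:
        lines = ["pair\tcount"]
        for k in PAIR_CATEGORIES:
            lines.append(f"{k[0]}-{k[1]}\t{self.contingency.get(k, 0)}")
        lines += [
            f"total\t{self.n_total}",
            f"shared\t{self.n_shared}\t{self.shared_percent}%",
            f"concordant\t{self.n_concordant}\t{self.concordance_percent}%",
        ]
        return "\n".join(lines) + "\n"


def concordance(
    m1: GenotypeMatrix,
    m2: GenotypeMatrix,
    sample_map: dict[str, str] | None = None,
    locus_map: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Compare two genotype matrices on their shared (sample, locus) slots.

    Intersection is by id string equality; explicit id maps (m1 id -> m2 id)
    support cross-assay comparisons where names differ.  Symmetric in its
    arguments since pair categories are unordered.
    """
    c1, c2 = _collapse(m1), _collapse(m2)
    if sample_map:
        c1 = c1.rename(index=sample_map)
    if locus_map:
        c1 = c1.rename(columns=locus_map)
    samples = [s for s in c1.index if s in set(c2.index)]
    loci = [l for l in c1.columns if l in set(c2.columns)]
    if not samples or not loci:
        raise ValueError("no shared (sample, locus) slots between the matrices")
    a = c1.loc[samples, loci].to_numpy(dtype=str)
    b = c2.loc[samples, loci].to_numpy(dtype=str)
    cont: Counter = Counter()
    for x, y in zip(a.ravel(), b.ravel()):
        cont[tuple(sorted((x, y)))] += 1
    return ConcordanceReport.from_contingency(dict(cont))


def reproducibility(
    matrix: GenotypeMatrix, duplicate_groups: dict[str, list[str]]
) -> tuple[pd.DataFrame, float]:
    """Per duplicate-pair concordance and the unweighted average over pairs.

    Each group of replicated samples contributes all its unordered pairs;
    a pair's rate is identical calls / slots called in both replicates.
    """
    calls = _collapse(matrix)
    rows = []
    for group, members in sorted(duplicate_groups.items()):
        members = [m for m in members if m in calls.index]
        for s1, s2 in itertools.combinations(members, 2):
            a = calls.loc[s1].to_numpy(dtype=str)
            b = calls.loc[s2].to_numpy(dtype=str)
            both = (a != "U") & (b != "U")
            shared = int(both.sum())
            ident = int(((a == b) & both).sum())
            rows.append(
                {
                    "group": group,
                    "sample1": s1,
                    "sample2": s2,
                    "shared": shared,
                    "identical": ident,
                    "rate": ident / shared if shared else float("nan"),
                }
            )
    if not rows:
        raise ValueError("no duplicate group of size >= 2")
    df = pd.DataFrame(rows)
    avg = float(np.nanmean(df["rate"].to_numpy()))
    return df, avg


def duplicate_groups_from_samples(samples) -> dict[str, list[str]]:
    """Collect duplicate groups declared in a sample sheet."""
    groups: dict[str, list[str]] = {}
    for s in samples:
        if s.duplicate_group:
            groups.setdefault(s.duplicate_group, []).append(s.sample_id)
    return {g: m for g, m in groups.items() if len(m) >= 2}


def read_distribution(per_sample_totals: dict[str, int] | pd.Series) -> dict:
    """Summary of per-sample read totals: mean, median, CV and histogram data."""
    totals = pd.Series(per_sample_totals, dtype=float)
    if totals.empty:
        raise ValueError("at least one sample required")
    mean = float(totals.mean())
    return {
        "per_sample": {str(k): int(v) for k, v in totals.items()},
        "total": int(totals.sum()),
        "mean": mean,
        "median": float(totals.median()),
        "cv": float(totals.std(ddof=0) / mean) if mean else float("nan"),
    }
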