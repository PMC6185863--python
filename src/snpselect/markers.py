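"""Marker-quality filtering for linkage mapping and informative-subset selection.

The filter chain for a mapping population runs in a fixed order:

1. **missingness** — drop markers whose U fraction over all samples exceeds
   a population-specific threshold (F2: 25%, RIL: 5%);
2. **overrepresentation** — drop markers whose most frequent called genotype
   makes up >= 90% of called genotypes (non-segregating / near-monomorphic);
3. **segregation distortion** — drop markers whose chi-square test against
   the Mendelian expectation (F2 1:2:1, df=2; RIL 1:1 on the A/B margin,
   df=1) gives p below 1e-6.

Subset selection for reduced-plex assays ranks loci by the number of
datasets in which they segregate and fills the target plex tier by tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

POPULATION_EXPECTATIONS = {
    "F2": {"classes": ("A", "H", "B"), "probs": (0.25, 0.5, 0.25), "df": 2},
    "RIL": {"classes": ("A", "B"), "probs": (0.5, 0.5), "df": 1},
}


@dataclass(frozen=True)
class FilterSettings:
    """Thresholds of the three-step marker filter."""

    max_missing_fraction: float = 0.25
    max_genotype_fraction: float = 0.90
    segregation_p_threshold: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "max_genotype_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0 < self.segregation_p_threshold < 1:
            raise ValueError("segregation_p_threshold must be in (0, 1)")

    @classmethod
    def for_population(cls, population_type: str) -> "FilterSettings":
        """Population defaults: F2 tolerates 25% missing, RIL only 5%."""
        if population_type == "F2":
            return cls(max_missing_fraction=0.25)
        if population_type == "RIL":
            return cls(max_missing_fraction=0.05)
        raise ValueError(f"unknown population type {population_type!r}")


@dataclass
class FilterTrace:
    """Ordered (step name, markers remaining) record of a filter run."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, name: str, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][1]:
            raise ValueError("marker counts must be non-increasing along the chain")
        self.steps.append((name, remaining))

    def counts(self) -> list[int]:
        return [n for _, n in self.steps]

    def to_tsv(self, path=None, population: str = ""):
        lines = ["population\tstep\tmarkers_remaining"]
        for name, n in self.steps:
            lines.append(f"{population}\t{name}\t{n}")
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None


def chi_square_pvalue(x: float, df: int) -> float:
    """Upper-tail chi-square p-value for df 1 or 2.

    df=2 has the closed form exp(-x/2); the scipy survival function is used
    for both and agrees with it to full precision.
    """
    if df not in (1, 2):
        raise ValueError(f"df must be 1 or 2, got {df}")
    if x < 0:
        raise ValueError("chi-square statistic must be >= 0")
    return float(stats.chi2.sf(x, df))


def segregation_test(calls, population_type: str) -> tuple[float, float]:
    """Chi-square test of observed vs expected Mendelian segregation.

    ``calls`` is an iterable of single-character genotypes for one marker.
    F2 tests (nA, nH, nB) against n*(1/4, 1/2, 1/4); RIL tests the A/B
    margin against 1:1, excluding residual H calls.  Returns (chi2, p);
    (nan, nan) when no genotype informs the test.
    """
    if population_type not in POPULATION_EXPECTATIONS:
        raise ValueError(f"unknown population type {population_type!r}")
    exp = POPULATION_EXPECTATIONS[population_type]
    counts = pd.Series(list(calls)).value_counts()
    obs = np.array([counts.get(c, 0) for c in exp["classes"]], dtype=float)
    n = obs.sum()
    if n == 0:
        return float("nan"), float("nan")
    expected = n * np.array(exp["probs"])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, chi_square_pvalue(chi2, exp["df"])


def filter_markers(
    matrix: GenotypeMatrix,
    population_type: str,
    settings: FilterSettings | None = None,
) -> tuple[list[str], FilterTrace]:
    """Apply the three-step filter chain; returns kept loci and the trace.

    Step 1 removes markers with a U fraction strictly greater than
    ``max_missing_fraction`` (denominator: all samples).  Step 2 removes
    markers whose most frequent called class reaches >=
    ``max_genotype_fraction`` of called genotypes (markers with no called
    genotype at all are also non-informative and removed here).  Step 3
    removes markers with segregation-distortion p below the threshold (or
    an undefined test).
    """
    if population_type not in POPULATION_EXPECTATIONS:
        raise ValueError(f"unknown population type {population_type!r}")
    settings = settings or FilterSettings.for_population(population_type)
    calls = matrix.collapse_intermediates().calls
    n_samples = len(calls.index)
    trace = FilterTrace()
    kept = list(calls.columns)
    trace.record("start", len(kept))

    u_frac = (calls == "U").sum(axis=0) / n_samples
    kept = [l for l in kept if u_frac[l] <= settings.max_missing_fraction]
    trace.record(f"missing<= {settings.max_missing_fraction:.0%}", len(kept))

    def _top_fraction(locus: str) -> float:
        col = calls[locus]
        called = col[col.isin(list("ABH"))]
        if called.empty:
            return 1.0
        return called.value_counts().iloc[0] / len(called)

    kept = [l for l in kept if _top_fraction(l) < settings.max_genotype_fraction]
    trace.record(f"top_genotype< {settings.max_genotype_fraction:.0%}", len(kept))

    def _passes_segregation(locus: str) -> bool:
        col = calls[locus]
        _, p = segregation_test(col[col.isin(list("ABH"))], population_type)
        return not math.isnan(p) and p >= settings.segregation_p_threshold

    kept = [l for l in kept if _passes_segregation(l)]
    trace.record(f"segregation_p>= {settings.segregation_p_threshold:g}", len(kept))
    return kept, trace


# ------------------------------------------------------------ subset choice


def segregates(calls: pd.Series, min_class_fraction: float = 0.05) -> bool:
    """A locus segregates in a dataset if >= 2 called classes each reach
    ``min_class_fraction`` of its called genotypes (robust to stray
    miscalls)."""
    called = calls[calls.isin(list("ABH"))]
    if called.empty:
        return False
    frac = called.value_counts() / len(called)
    return int((frac >= min_class_fraction).sum()) >= 2


@dataclass
class SubsetSelection:
    """Outcome of informative-subset selection."""

    loci: list[str]
    tiers: dict[str, list[str]]  # multi / single / none, eligible loci per tier
    composition: dict[str, int]  # how many of each tier were selected


def select_subset(
    matrices: dict[str, GenotypeMatrix],
    target_plex: int,
    u_threshold: float = 0.25,
    min_class_fraction: float = 0.05,
    locus_order: list[str] | None = None,
) -> SubsetSelection:
    """Select the most informative loci for a reduced-plex assay.

    Eligibility: U fraction below ``u_threshold`` in at least one dataset.
    Eligible loci are tiered by the number of datasets in which they
    segregate (>= 2 datasets, exactly 1, none) and the target plex is filled
    tier by tier, deterministically in locus order within a tier.  Raises if
    the eligible loci cannot fill the target.
    """
    if not matrices:
        raise ValueError("at least one dataset matrix required")
    mats = {name: m.collapse_intermediates().calls for name, m in matrices.items()}
    if locus_order is None:
        locus_order = []
        for calls in mats.values():
            for l in calls.columns:
                if l not in locus_order:
                    locus_order.append(l)
    eligible = []
    n_segregating: dict[str, int] = {}
    for locus in locus_order:
        u_ok = False
        nseg = 0
        for calls in mats.values():
            if locus not in calls.columns:
                continue
            col = calls[locus]
            if (col == "U").mean() < u_threshold:
                u_ok = True
            if segregates(col, min_class_fraction):
                nseg += 1
        if u_ok:
            eligible.append(locus)
            n_segregating[locus] = nseg
    tiers = {
        "multi": [l for l in eligible if n_segregating[l] >= 2],
        "single": [l for l in eligible if n_segregating[l] == 1],
        "none": [l for l in eligible if n_segregating[l] == 0],
    }
    if len(eligible) < target_plex:
        raise ValueError(
            f"only {len(eligible)} eligible loci for a target plex of "
            f"{target_plex} (short by {target_plex - len(eligible)})"
        )
    chosen: list[str] = []
    composition = {"multi": 0, "single": 0, "none": 0}
    for tier in ("multi", "single", "none"):
        for locus in tiers[tier]:
            if len(chosen) == target_plex:
                break
            chosen.append(locus)
            composition[tier] += 1
    return SubsetSelection(chosen, tiers, composition)
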