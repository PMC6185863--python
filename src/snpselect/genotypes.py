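"""Genotype matrices: samples x loci single-character calls.

The call alphabet is ``A`` / ``B`` (the two homozygotes), ``H``
(heterozygote), ``U`` (unknown / no call) and the two intermediate classes
``C`` (B or H) and ``D`` (A or H) that a caller may emit when a ratio score
falls between class boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_ALPHABET = frozenset("ABHUCD")
#: classes counted as "called" by QC metrics
CALLED = frozenset("ABH")


@dataclass
class GenotypeMatrix:
    """Samples x loci call matrix with a per-sample dataset label.

    ``calls`` is a pandas DataFrame (index: sample ids, columns: locus ids,
    values: single characters from the 6-symbol alphabet).
    """

    calls: pd.DataFrame
    dataset: pd.Series | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy(dtype=str))) - CALL_ALPHABET
        if bad:
            raise ValueError(f"invalid genotype symbols {sorted(bad)}")
        if self.dataset is None:
            self.dataset = pd.Series("other", index=self.calls.index)
        else:
            self.dataset = self.dataset.reindex(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def collapse_intermediates(self) -> "GenotypeMatrix":
        """Map the intermediate C/D classes to U (4-symbol view for QC)."""
        return GenotypeMatrix(self.calls.replace({"C": "U", "D": "U"}), self.dataset)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path=None, provenance: str | None = None):
        buf = io.StringIO()
        if provenance:
            buf.write(f"# {provenance}\n")
        buf.write("\t".join(["sample", "dataset"] + self.locus_ids) + "\n")
        for sid in self.sample_ids:
            row = self.calls.loc[sid]
            buf.write("\t".join([sid, str(self.dataset.loc[sid])] + list(row)) + "\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_tsv(cls, path_or_text) -> "GenotypeMatrix":
        if isinstance(path_or_text, str) and "\t" in path_or_text:
            lines = path_or_text.splitlines()
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        rows = [ln for ln in lines if ln and not ln.startswith("#")]
        header = rows[0].split("\t")
        if header[:2] != ["sample", "dataset"]:
            raise ValueError("unexpected genotype-matrix header")
        loci = header[2:]
        sids, datasets, data = [], [], []
        for ln in rows[1:]:
            f = ln.split("\t")
            sids.append(f[0])
            datasets.append(f[1])
            data.append(f[2:])
        calls = pd.DataFrame(data, index=sids, columns=loci)
        return cls(calls, pd.Series(datasets, index=sids))
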