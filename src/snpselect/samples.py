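"""Sample-sheet I/O: one row per sample with its dual index and metadata."""

from __future__ import annotations

import io

from .assay import SampleIndex

SHEET_COLUMNS = ("sample_id", "dataset", "i5", "i7", "duplicate_group", "fastq_path")


def check_unique_indexes(samples: list[SampleIndex]) -> None:
    """Every sample must carry a unique (i5, i7) combination."""
    seen: dict[tuple[str, str], str] = {}
    for s in samples:
        key = (s.i5, s.i7)
        if key in seen:
            raise ValueError(
                f"duplicate index pair {s.i5}+{s.i7} for samples "
                f"{seen[key]!r} and {s.sample_id!r}"
            )
        seen[key] = s.sample_id
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample sheet")


def write_sample_sheet(samples: list[SampleIndex], path=None, provenance: str | None = None):
    """Serialize samples to TSV; raises on duplicate (i5, i7) pairs."""
    check_unique_indexes(samples)
    buf = io.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    buf.write("\t".join(SHEET_COLUMNS) + "\n")
    for s in samples:
        buf.write(
            "\t".join(
                (s.sample_id, s.dataset, s.i5, s.i7,
                 s.duplicate_group or "", s.fastq_path or "")
            )
            + "\n"
        )
    text = buf.getvalue()
    if path is None:
        return text
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return None


def read_sample_sheet(path_or_text) -> list[SampleIndex]:
    if isinstance(path_or_text, str) and "\t" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    if not rows:
        raise ValueError("empty sample sheet")
    header = tuple(rows[0].split("\t"))
    if header != SHEET_COLUMNS:
        raise ValueError(f"unexpected sample-sheet header {header}")
    samples = []
    for ln in rows[1:]:
        f = dict(zip(SHEET_COLUMNS, ln.split("\t")))
        samples.append(
            SampleIndex(
                sample_id=f["sample_id"],
                i5=f["i5"],
                i7=f["i7"],
                dataset=f["dataset"],
                duplicate_group=f["duplicate_group"] or None,
                fastq_path=f["fastq_path"] or None,
            )
        )
    check_unique_indexes(samples)
    return samples
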