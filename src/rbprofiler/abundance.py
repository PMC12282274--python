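"""Read-filtering virome abundance: relative abundance per phage category and
RPKM per reference.

A mapped read is kept when its percent identity over the aligned region and
its aligned fraction of the read both meet inclusive thresholds.  Two filter
presets mirror the profiling workflow: *genome mode* (identity ≥ 80, aligned
≥ 50) for relative abundance of phage genera, and *contig mode* (identity ≥
86, aligned ≥ 95, covered fraction ≥ 55) for RPKM of representative RBP
group sequences.

Relative abundance uses a length-normalised read-count estimator: each
category's weight is the sum over its references of kept reads divided by
reference length, category percentages are rescaled by the mapped-and-kept
fraction, and reads that are unmapped or fail a filter appear as an
"unmapped" row so the table always sums to 100.

RPKM_r = kept_reads_r / ((length_bp_r / 1000) · (total_kept_reads / 10^6)),
with references whose covered fraction falls below the floor reported as 0
and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

UNMAPPED = "unmapped"

GENOME_MODE = None  # set below, after FilterParams is defined
CONTIG_MODE = None


class InvalidRecordError(ValueError):
    """Raised for malformed alignment records."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference mapping (or an unmapped read)."""

    read_id: str
    ref_id: str | None  # None when unmapped
    ref_start: int = 0  # 1-based
    aligned_length: int = 0  # read residues aligned (CIGAR M/=/X/I)
    read_length: int = 0
    percent_identity: float = 0.0
    ref_aligned_length: int = 0  # reference bases spanned (M/=/X/D)

    def __post_init__(self) -> None:
        if self.ref_id is not None:
            if self.ref_start < 1:
                raise InvalidRecordError(f"read {self.read_id!r}: ref_start must be >= 1")
            if not (0 < self.aligned_length <= self.read_length):
                raise InvalidRecordError(
                    f"read {self.read_id!r}: aligned_length must be in (0, read_length]"
                )
            if not (0 <= self.percent_identity <= 100):
                raise InvalidRecordError(
                    f"read {self.read_id!r}: percent_identity out of [0, 100]"
                )

    @property
    def mapped(self) -> bool:
        return self.ref_id is not None

    @property
    def aligned_pct(self) -> float:
        return 100.0 * self.aligned_length / self.read_length if self.read_length else 0.0


@dataclass(frozen=True)
class FilterParams:
    """Inclusive read-filter thresholds, all on the 0–100 percent scale."""

    min_identity: float
    min_aligned_pct: float
    min_covered_fraction: float | None = None

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_aligned_pct):
            if not (0 <= v <= 100):
                raise ValueError("filter thresholds must be in [0, 100]")
        if self.min_covered_fraction is not None and not (0 <= self.min_covered_fraction <= 100):
            raise ValueError("min_covered_fraction must be in [0, 100]")

    def keeps(self, rec: AlignmentRecord) -> bool:
        return (
            rec.mapped
            and rec.percent_identity >= self.min_identity
            and rec.aligned_pct >= self.min_aligned_pct
        )


GENOME_MODE = FilterParams(min_identity=80.0, min_aligned_pct=50.0)
CONTIG_MODE = FilterParams(min_identity=86.0, min_aligned_pct=95.0, min_covered_fraction=55.0)


@dataclass
class ReferenceSet:
    """Reference lengths plus a category label (phage genus or RBP group)."""

    lengths: dict[str, int]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.lengths) != set(self.categories):
            raise ValueError("lengths and categories must cover the same ids")
        for ref, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"reference {ref!r} has nonpositive length")

    @property
    def category_names(self) -> list[str]:
        return sorted(set(self.categories.values()))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSet":
        df = pd.read_csv(path, sep="\t", dtype={"ref_id": str, "category": str})
        required = {"ref_id", "length_bp", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"reference TSV must have columns {sorted(required)}")
        return cls(
            lengths=dict(zip(df.ref_id, df.length_bp.astype(int))),
            categories=dict(zip(df.ref_id, df.category)),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "ref_id": list(self.lengths),
                "length_bp": [self.lengths[r] for r in self.lengths],
                "category": [self.categories[r] for r in self.lengths],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AbundanceTable:
    """Per-category relative abundance (plus unmapped) and per-reference stats."""

    categories: pd.DataFrame  # index category (+ 'unmapped'); column relative_abundance_pct
    references: pd.DataFrame  # index ref_id; filtered_read_count, covered_fraction_pct, rpkm, below_covered_threshold


def filter_records(
    records: list[AlignmentRecord], p: FilterParams
) -> tuple[list[AlignmentRecord], int, int]:
    """Split records into (kept, n_filtered_out, n_unmapped).

    Thresholds are inclusive: a read at exactly the identity or
    aligned-fraction floor is kept.
    """
    kept: list[AlignmentRecord] = []
    n_filtered = 0
    n_unmapped = 0
    for rec in records:
        if not rec.mapped:
            n_unmapped += 1
        elif p.keeps(rec):
            kept.append(rec)
        else:
            n_filtered += 1
    return kept, n_filtered, n_unmapped


def covered_fraction(
    records: list[AlignmentRecord], ref_id: str, refset: ReferenceSet
) -> float:
    """Percent of reference positions overlapped by ≥1 kept record (interval union)."""
    if ref_id not in refset.lengths:
        raise ValueError(f"unknown reference {ref_id!r}")
    length = refset.lengths[ref_id]
    intervals = sorted(
        (r.ref_start, min(r.ref_start + (r.ref_aligned_length or r.aligned_length) - 1, length))
        for r in records
        if r.ref_id == ref_id
    )
    covered = 0
    cur_start, cur_end = None, None
    for start, end in intervals:
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return 100.0 * covered / length


def _per_reference_counts(
    kept: list[AlignmentRecord], refset: ReferenceSet
) -> dict[str, int]:
    counts = {ref: 0 for ref in refset.lengths}
    for rec in kept:
        if rec.ref_id not in counts:
            raise ValueError(f"record {rec.read_id!r} maps to unknown reference {rec.ref_id!r}")
        counts[rec.ref_id] += 1
    return counts


def relative_abundance(
    records: list[AlignmentRecord],
    refset: ReferenceSet,
    p: FilterParams = GENOME_MODE,
) -> AbundanceTable:
    """Genome-mode relative abundance per category, summing to 100 with unmapped."""
    kept, n_filtered, n_unmapped = filter_records(records, p)
    total = len(records)
    counts = _per_reference_counts(kept, refset)
    weights = {c: 0.0 for c in refset.category_names}
    for ref, n in counts.items():
        weights[refset.categories[ref]] += n / refset.lengths[ref]
    total_weight = sum(weights.values())
    mapped_kept_fraction = len(kept) / total if total else 0.0
    rows = {}
    for c in refset.category_names:
        share = weights[c] / total_weight if total_weight else 0.0
        rows[c] = 100.0 * share * mapped_kept_fraction
    rows[UNMAPPED] = 100.0 * (n_filtered + n_unmapped) / total if total else 100.0
    if total and not kept:
        rows[UNMAPPED] = 100.0
    categories = pd.DataFrame(
        {"relative_abundance_pct": pd.Series(rows)}
    ).rename_axis("category")
    refs = pd.DataFrame(
        {
            "filtered_read_count": pd.Series(counts),
            "covered_fraction_pct": pd.Series(
                {ref: covered_fraction(kept, ref, refset) for ref in refset.lengths}
            ),
        }
    ).rename_axis("ref_id")
    return AbundanceTable(categories=categories, references=refs)


def rpkm(
    records: list[AlignmentRecord],
    refset: ReferenceSet,
    p: FilterParams = CONTIG_MODE,
) -> pd.DataFrame:
    """Contig-mode RPKM per reference, with the covered-fraction floor applied."""
    kept, _, _ = filter_records(records, p)
    counts = _per_reference_counts(kept, refset)
    total_kept = sum(counts.values())
    if total_kept == 0:
        warnings.warn("no reads passed the filters; all RPKM values are 0", stacklevel=2)
    rows = []
    for ref in refset.lengths:
        cov = covered_fraction(kept, ref, refset)
        below = (
            p.min_covered_fraction is not None and cov < p.min_covered_fraction
        )
        if total_kept and not below:
            value = counts[ref] / ((refset.lengths[ref] / 1000.0) * (total_kept / 1e6))
        else:
            value = 0.0
        rows.append(
            {
                "ref_id": ref,
                "filtered_read_count": counts[ref],
                "covered_fraction_pct": cov,
                "rpkm": value,
                "below_covered_threshold": bool(below),
            }
        )
    return pd.DataFrame(rows).set_index("ref_id")


# ---------------------------------------------------------------------------
# SAM input

_QUERY_ALIGNED_OPS = {0, 1, 7, 8}  # M, I, =, X consume query and are aligned
_REF_ALIGNED_OPS = {0, 2, 7, 8}  # M, D, =, X consume reference


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a plain headerful SAM file into alignment records.

    Secondary and supplementary alignments are skipped (one primary
    alignment per read).  Percent identity is derived from the standard
    edit-distance tag as 100·(aligned − NM)/aligned; mapped records lacking
    the tag are rejected.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_secondary or seg.is_supplementary:
                continue
            if seg.is_unmapped:
                records.append(AlignmentRecord(read_id=seg.query_name, ref_id=None))
                continue
            aligned = sum(n for op, n in seg.cigartuples if op in _QUERY_ALIGNED_OPS)
            ref_aligned = sum(n for op, n in seg.cigartuples if op in _REF_ALIGNED_OPS)
            read_len = seg.infer_read_length() or seg.query_length
            if not seg.has_tag("NM"):
                raise InvalidRecordError(
                    f"mapped record {seg.query_name!r} lacks the NM edit-distance tag"
                )
            nm = int(seg.get_tag("NM"))
            identity = 100.0 * (aligned - nm) / aligned if aligned else 0.0
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    ref_start=seg.reference_start + 1,
                    aligned_length=aligned,
                    read_length=read_len,
                    percent_identity=identity,
                    ref_aligned_length=ref_aligned,
                )
            )
    return records
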