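"""Data-set construction and filtering.

Three data sets are built from a whole-plastome alignment with per-column
provenance: coding (CDS exons + tRNA + rRNA columns), noncoding (introns +
intergenic spacers) and complete, all with the second IR copy removed.
Three filtering levels apply: unfiltered, light (Gblocks-style gappy/
ambiguous column trimming, deterministic) and strict (no column with any
gap survives). Subsets for partitioned phylogenetics are one per
gene/intron/spacer, with small or invariant subsets pooled by functional
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentMatrix
from .divergence import classify_sites

MIN_SUBSET = 200

CODING_PREFIXES = ("cds:", "trna:", "rrna:")
NONCODING_PREFIXES = ("intron:", "spacer:")


@dataclass
class DataSetBundle:
    complete: AlignmentMatrix
    coding: AlignmentMatrix
    noncoding: AlignmentMatrix


@dataclass
class PartitionScheme:
    subsets: list[tuple[str, np.ndarray, str]]  # (name, column indices, category)
    merged_small: list[str]

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.subsets]


def _category(label: str) -> str:
    for prefix, cat in (
        ("cds:", "CDS"),
        ("trna:", "tRNA"),
        ("rrna:", "rRNA"),
        ("intron:", "intron"),
        ("spacer:", "spacer"),
    ):
        if label.startswith(prefix):
            return cat
    raise ValueError(f"unrecognized provenance label {label!r}")


def build_datasets(aln: AlignmentMatrix, drop_second_ir: bool = True) -> DataSetBundle:
    """Split a labeled alignment into complete / coding / noncoding sets.

    Columns labeled as CDS/tRNA/rRNA are coding; intron and spacer columns
    are noncoding (overlap-ambiguous columns were already resolved to
    coding when the labels were assigned). With ``drop_second_ir`` the IRa
    columns are removed from all three sets first.
    """
    if aln.column_labels is None:
        raise ValueError("alignment has no per-column provenance labels")
    keep = np.ones(aln.n_columns, dtype=bool)
    if drop_second_ir:
        if aln.region_labels is None:
            raise ValueError("drop_second_ir requires region labels")
        keep = np.asarray(aln.region_labels) != "IRa"
    base = aln.take_columns(np.nonzero(keep)[0])
    labels = base.column_labels
    is_coding = np.array([str(x).startswith(CODING_PREFIXES) for x in labels])
    is_noncoding = np.array([str(x).startswith(NONCODING_PREFIXES) for x in labels])
    if not (is_coding | is_noncoding).all():
        bad = labels[~(is_coding | is_noncoding)][0]
        raise ValueError(f"unrecognized provenance label {bad!r}")
    return DataSetBundle(
        complete=base,
        coding=base.take_columns(np.nonzero(is_coding)[0]),
        noncoding=base.take_columns(np.nonzero(is_noncoding)[0]),
    )


def filter_strict(aln: AlignmentMatrix) -> AlignmentMatrix:
    """Keep exactly the columns with zero gap characters, order preserved."""
    keep = ~aln.gap_mask().any(axis=0)
    return aln.take_columns(np.nonzero(keep)[0])


def filter_light(
    aln: AlignmentMatrix,
    max_gap_fraction: float = 0.5,
    min_conserved_block: int = 10,
    min_conservation: float = 0.5,
) -> AlignmentMatrix:
    """Deterministic Gblocks-style light filter.

    Removes (1) columns whose gap fraction exceeds ``max_gap_fraction``,
    (2) remaining gap-containing columns whose majority-state frequency
    (over non-gap characters) falls below ``min_conservation``, and (3)
    retained islands shorter than ``min_conserved_block`` whose columns all
    contain a gap. Only gap-containing columns are ever removed, so the
    light output always contains the strict output.
    """
    gaps = aln.gap_mask()
    n_gap = gaps.sum(axis=0)
    has_gap = n_gap > 0
    gap_frac = n_gap / aln.n_taxa
    counts = aln.state_counts()
    non_gap = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        majority = np.where(non_gap > 0, counts.max(axis=0) / np.maximum(non_gap, 1), 0.0)
    remove = (gap_frac > max_gap_fraction) | (has_gap & (majority < min_conservation))
    # rag-end trimming: short retained islands made purely of gapped columns
    keep = ~remove
    j = 0
    L = aln.n_columns
    while j < L:
        if keep[j]:
            k = j
            while k < L and keep[k]:
                k += 1
            island = np.arange(j, k)
            if (k - j) < min_conserved_block and has_gap[island].all():
                keep[island] = False
            j = k
        else:
            j += 1
    return aln.take_columns(np.nonzero(keep)[0])


def build_partitions(aln: AlignmentMatrix, min_subset: int = MIN_SUBSET) -> PartitionScheme:
    """One subset per gene/intron/spacer; small or invariant subsets are
    pooled into their functional category's merged subset."""
    if aln.column_labels is None:
        raise ValueError("alignment has no per-column provenance labels")
    labels = [str(x) for x in aln.column_labels]
    order: dict[str, list[int]] = {}
    for j, lab in enumerate(labels):
        order.setdefault(lab, []).append(j)
    subsets: list[tuple[str, np.ndarray, str]] = []
    pooled: dict[str, list[int]] = {}
    merged_names: list[str] = []
    for lab, cols in order.items():
        cat = _category(lab)
        cols_arr = np.array(cols)
        sub = aln.take_columns(cols_arr)
        variable = classify_sites(sub).variable if sub.n_taxa >= 2 else 0
        if len(cols) < min_subset or variable == 0:
            pooled.setdefault(cat, []).extend(cols)
            merged_names.append(lab)
        else:
            subsets.append((lab, cols_arr, cat))
    for cat, cols in pooled.items():
        subsets.append((f"pooled-{cat}", np.array(sorted(cols)), cat))
    # machine-check: a set partition of the columns
    allcols = np.concatenate([c for _, c, _ in subsets]) if subsets else np.array([], dtype=int)
    assert len(allcols) == aln.n_columns and len(np.unique(allcols)) == aln.n_columns
    return PartitionScheme(subsets=subsets, merged_small=merged_names)


def _ranges(cols: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous 0-based half-open runs of a sorted column index set."""
    cols = np.sort(cols)
    breaks = np.nonzero(np.diff(cols) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(cols) - 1]])
    return [(int(cols[s]), int(cols[e]) + 1) for s, e in zip(starts, ends)]


def raxml_partition_text(scheme: PartitionScheme) -> str:
    """RAxML-style partition definitions (1-based inclusive ranges)."""
    lines = []
    for name, cols, _ in scheme.subsets:
        spans = ", ".join(f"{s + 1}-{e}" for s, e in _ranges(cols))
        lines.append(f"DNA, {name} = {spans}")
    return "\n".join(lines) + "\n"


def nexus_sets_block(scheme: PartitionScheme) -> str:
    lines = ["#NEXUS", "begin sets;"]
    for name, cols, _ in scheme.subsets:
        spans = " ".join(f"{s + 1}-{e}" for s, e in _ranges(cols))
        safe = name.replace(":", "_").replace("-", "_").replace(".", "_")
        lines.append(f"    charset {safe} = {spans};")
    lines.append("end;")
    return "\n".join(lines) + "\n"
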