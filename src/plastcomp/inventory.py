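"""Per-genome and cross-genome summary features: gene censuses, region
length dispersions, coding/noncoding split and GC."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import PlastomeRecord
from .quadripartite import QuadripartitePartition


@dataclass(frozen=True)
class GeneCensus:
    unique_genes: int
    total_genes: int
    duplicated_in_ir: int
    cds: int
    trna: int
    rrna: int
    one_intron: int
    two_intron: int


@dataclass(frozen=True)
class RegionSummary:
    region_class: str
    lengths: tuple[int, ...]
    mean: int
    sd: int


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gene_census(record: PlastomeRecord, partition: QuadripartitePartition | None = None) -> GeneCensus:
    """Gene counts per the study's conventions.

    Unique genes are distinct annotated names; a gene is IR-duplicated when
    it has two copies, one inside each IR (when no partition is given, any
    multi-copy name counts as duplicated). Intron counts come from
    multi-part (join) features, taking the maximum over copies of a name.
    """
    by_name: dict[str, list] = {}
    for f in record.features:
        by_name.setdefault(f.name, []).append(f)
    unique = len(by_name)
    total = len(record.features)
    dup = 0
    n = len(record.sequence)
    for name, copies in by_name.items():
        if len(copies) < 2:
            continue
        if partition is None:
            dup += 1
            continue
        in_irb = any(partition.irb.contains(f.start, n) for f in copies)
        in_ira = any(partition.ira.contains(f.start, n) for f in copies)
        if in_irb and in_ira:
            dup += 1
    kinds = {k: sum(1 for name, copies in by_name.items() if copies[0].kind == k) for k in ("CDS", "tRNA", "rRNA")}
    one_intron = sum(1 for copies in by_name.values() if max(f.intron_count for f in copies) == 1)
    two_intron = sum(1 for copies in by_name.values() if max(f.intron_count for f in copies) == 2)
    return GeneCensus(
        unique_genes=unique,
        total_genes=total,
        duplicated_in_ir=dup,
        cds=kinds["CDS"],
        trna=kinds["tRNA"],
        rrna=kinds["rRNA"],
        one_intron=one_intron,
        two_intron=two_intron,
    )


def coding_noncoding_lengths(record: PlastomeRecord) -> tuple[int, int, float]:
    """(coding bp, noncoding bp, coding percent) using exon-interval union.

    Overlapping exons are counted once, so coding + noncoding always equals
    the genome length.
    """
    n = len(record.sequence)
    ivs = []
    for f in record.features:
        for p in f.parts:
            if p.wraps_origin:
                ivs.append((p.start, n))
                ivs.append((0, p.end))
            else:
                ivs.append((p.start, p.end))
    coding = 0
    for s, e in _merge(ivs):
        coding += e - s
    pct = 100.0 * coding / n
    return coding, n - coding, pct


def _merge(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def region_length_summary(lengths, region_class: str) -> RegionSummary:
    """Mean and sample (n-1) standard deviation, rounded half away from
    zero to the nearest bp — the convention that reproduces the study's
    printed dispersions (e.g. IR: 146.54 -> 147)."""
    lengths = [int(x) for x in lengths]
    if len(lengths) < 2:
        raise ValueError("need >= 2 samples for a dispersion summary")
    mean = float(np.mean(lengths))
    sd = float(np.std(lengths, ddof=1))
    return RegionSummary(
        region_class=region_class,
        lengths=tuple(lengths),
        mean=_round_half_away(mean),
        sd=_round_half_away(sd),
    )


def summary_table(summaries: list[RegionSummary]) -> str:
    lines = ["region_class\tn\tmean_bp\tsd_bp"]
    for s in summaries:
        lines.append(f"{s.region_class}\t{len(s.lengths)}\t{s.mean}\t{s.sd}")
    return "\n".join(lines) + "\n"
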