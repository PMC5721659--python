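"""Divergence statistics: site classification, the sliding-window
mutation-event proportion, hotspot calling, and windowed pairwise identity.

The window statistic is the proportion of mutation events
``100 * (NS + ID) / L`` where NS counts substitution columns, ID counts
indel events (a maximal run of columns sharing one gap presence/absence
pattern is one event, however long), and L is the aligned window length
including gap columns. Hotspots are merged runs of windows whose
proportion strictly exceeds the threshold (default 20%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentMatrix

WINDOW_LEN = 600
STEP = 200
HOTSPOT_THRESHOLD = 20.0


@dataclass(frozen=True)
class SiteClassCounts:
    total: int
    constant: int
    variable: int
    parsimony_informative: int
    singleton: int

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total or 1
        return {
            "variable": 100.0 * self.variable / t,
            "parsimony_informative": 100.0 * self.parsimony_informative / t,
        }


@dataclass(frozen=True)
class WindowStat:
    start: int
    end: int
    NS: int
    ID: int

    @property
    def L(self) -> int:
        return self.end - self.start

    @property
    def proportion(self) -> float:
        return 100.0 * (self.NS + self.ID) / self.L


@dataclass(frozen=True)
class HotspotRegion:
    start: int
    end: int
    peak_proportion: float
    overlapping_features: tuple[str, ...] = field(default_factory=tuple)


def _column_classes(aln: AlignmentMatrix):
    """Vectorized per-column state bookkeeping.

    Returns (n_states, n_taxa_with_each_state>=2 count, classifiable mask)
    where states are unambiguous non-gap characters only.
    """
    counts = aln.state_counts()  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_recurrent = (counts >= 2).sum(axis=0)
    return n_states, n_recurrent


def classify_sites(aln: AlignmentMatrix) -> SiteClassCounts:
    """Constant / variable / parsimony-informative / singleton columns.

    Columns with no unambiguous non-gap state are unclassifiable and count
    only toward ``total``.
    """
    if aln.n_taxa < 2:
        raise ValueError("site classification needs >= 2 taxa")
    n_states, n_recurrent = _column_classes(aln)
    constant = int((n_states == 1).sum())
    variable = int((n_states >= 2).sum())
    pi = int(((n_states >= 2) & (n_recurrent >= 2)).sum())
    return SiteClassCounts(
        total=aln.n_columns,
        constant=constant,
        variable=variable,
        parsimony_informative=pi,
        singleton=variable - pi,
    )


def _substitution_columns(aln: AlignmentMatrix) -> np.ndarray:
    """Boolean mask of columns counted as substitution sites (NS)."""
    n_states, _ = _column_classes(aln)
    return n_states >= 2


def _indel_events(aln: AlignmentMatrix) -> list[tuple[int, int]]:
    """Indel events as (start, end) column runs.

    An event is a maximal run of consecutive columns sharing an identical
    gap pattern across taxa, where that pattern has at least one gap.
    """
    mask = aln.gap_mask()
    any_gap = mask.any(axis=0)
    if not any_gap.any():
        return []
    # run-length encode pattern identity between neighbors
    same_as_prev = np.zeros(aln.n_columns, dtype=bool)
    if aln.n_columns > 1:
        same_as_prev[1:] = (mask[:, 1:] == mask[:, :-1]).all(axis=0)
    events = []
    start = None
    for j in range(aln.n_columns):
        if any_gap[j]:
            if start is None or not same_as_prev[j]:
                if start is not None:
                    events.append((start, j))
                start = j
        else:
            if start is not None:
                events.append((start, j))
                start = None
    if start is not None:
        events.append((start, aln.n_columns))
    return events


def count_window_events(aln: AlignmentMatrix, start: int, end: int) -> tuple[int, int]:
    """(NS, ID) within alignment columns [start, end).

    An indel event straddling the window boundary counts in every window
    it touches.
    """
    if not (0 <= start < end <= aln.n_columns):
        raise ValueError(f"bad window [{start}, {end}) for {aln.n_columns} columns")
    sub = _substitution_columns(aln)
    ns = int(sub[start:end].sum())
    ide = sum(1 for s, e in _indel_events(aln) if s < end and e > start)
    return ns, ide


def window_scan(aln: AlignmentMatrix, window_len: int = WINDOW_LEN, step: int = STEP) -> list[WindowStat]:
    """Sliding-window mutation-event proportions (defaults 600/200).

    Windows start at 0, step, 2*step, ... while a full window fits; a final
    truncated window covers any remaining tail. An alignment shorter than
    one window yields a single full-length window with a warning.
    """
    L = aln.n_columns
    if L < window_len:
        warnings.warn(f"alignment ({L} columns) shorter than window ({window_len}); single window")
        starts_ends = [(0, L)]
    else:
        starts_ends = []
        start = 0
        while start + window_len <= L:
            starts_ends.append((start, start + window_len))
            start += step
        if starts_ends[-1][1] < L:
            starts_ends.append((start, L))
    sub = _substitution_columns(aln)
    events = _indel_events(aln)
    out = []
    for s, e in starts_ends:
        ns = int(sub[s:e].sum())
        ide = sum(1 for a, b in events if a < e and b > s)
        out.append(WindowStat(start=s, end=e, NS=ns, ID=ide))
    return out


def call_hotspots(
    windows: list[WindowStat],
    threshold: float = HOTSPOT_THRESHOLD,
    column_labels: np.ndarray | None = None,
) -> list[HotspotRegion]:
    """Merge qualifying windows (proportion strictly > threshold) that
    overlap or are adjacent into hotspot regions."""
    hot = [w for w in windows if w.proportion > threshold]
    if not hot:
        return []
    hot.sort(key=lambda w: w.start)
    merged: list[list] = []
    for w in hot:
        if merged and w.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], w.end)
            merged[-1][2] = max(merged[-1][2], w.proportion)
        else:
            merged.append([w.start, w.end, w.proportion])
    out = []
    for s, e, peak in merged:
        feats: tuple[str, ...] = ()
        if column_labels is not None:
            seen = dict.fromkeys(str(x) for x in column_labels[s:e])
            feats = tuple(seen)
        out.append(HotspotRegion(start=s, end=e, peak_proportion=peak, overlapping_features=feats))
    return out


def pairwise_identity(
    aln: AlignmentMatrix,
    ref_taxon: str,
    window_len: int = WINDOW_LEN,
    step: int = STEP,
) -> dict[str, list[tuple[int, int, float]]]:
    """mVISTA-style windowed percent identity of every taxon to a reference.

    Identity = matches / (matches + mismatches) over columns where both
    sequences have unambiguous non-gap characters; windows with no
    comparable column report ``nan``.
    """
    if ref_taxon not in aln.taxa:
        raise ValueError(f"unknown reference taxon {ref_taxon!r}")
    ref = aln.row(ref_taxon)
    ok = np.isin(aln.data, [b"A", b"C", b"G", b"T"])
    ref_ok = np.isin(ref, [b"A", b"C", b"G", b"T"])
    L = aln.n_columns
    if L < window_len:
        bounds = [(0, L)]
    else:
        bounds = []
        start = 0
        while start + window_len <= L:
            bounds.append((start, start + window_len))
            start += step
        if bounds[-1][1] < L:
            bounds.append((start, L))
    out: dict[str, list[tuple[int, int, float]]] = {}
    for t in aln.taxa:
        if t == ref_taxon:
            continue
        row = aln.row(t)
        comparable = ok[aln.taxa.index(t)] & ref_ok
        match = comparable & (row == ref)
        res = []
        for s, e in bounds:
            denom = int(comparable[s:e].sum())
            ident = float("nan") if denom == 0 else 100.0 * int(match[s:e].sum()) / denom
            res.append((s, e, ident))
        out[t] = res
    return out


def window_table(windows: list[WindowStat]) -> str:
    lines = ["start\tend\tNS\tID\tL\tproportion"]
    for w in windows:
        lines.append(f"{w.start}\t{w.end}\t{w.NS}\t{w.ID}\t{w.L}\t{w.proportion:.2f}")
    return "\n".join(lines) + "\n"


def hotspots_bed(sample: str, regions: list[HotspotRegion]) -> str:
    rows = []
    for r in regions:
        name = ";".join(r.overlapping_features) or "."
        rows.append(f"{sample}\t{r.start}\t{r.end}\t{name}\t{r.peak_proportion:.2f}")
    return "\n".join(rows) + ("\n" if rows else "")
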