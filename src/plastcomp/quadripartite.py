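"""Inverted-repeat detection and quadripartite partitioning.

The detector finds the maximal pair of disjoint intervals where one is the
reverse complement of the other (seed-and-extend on k-mer anchors between
the sequence and its reverse complement, k = 21), searched on the doubled
sequence so repeats wrapping the origin are found. A quadratic brute-force
reference (:func:`brute_force_inverted_repeat`) exists for small sequences
and is the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import PlastomeRecord, SequenceInterval, reverse_complement

DEFAULT_MIN_LEN = 10_000
SEED_K = 21


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / IRb / SSC / IRa intervals tiling one circular genome."""

    lsc: SequenceInterval
    irb: SequenceInterval
    ssc: SequenceInterval
    ira: SequenceInterval
    seq_len: int

    @property
    def lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc.length(self.seq_len),
            "IRb": self.irb.length(self.seq_len),
            "SSC": self.ssc.length(self.seq_len),
            "IRa": self.ira.length(self.seq_len),
        }

    @property
    def ir_len(self) -> int:
        return self.irb.length(self.seq_len)


@dataclass(frozen=True)
class JunctionEvent:
    junction: str  # LSC/IRb | IRb/SSC | SSC/IRa | IRa/LSC
    feature: str
    overlap_bp: int
    location_class: str  # spans_junction | within_spacer | abuts


def brute_force_inverted_repeat(seq: str, min_len: int):
    """O(n^2)-ish exhaustive search for the longest disjoint revcomp pair.

    Only intended for test sequences (<= a few kb). Returns the same
    normalized interval pair as :func:`find_inverted_repeat` or None.
    """
    n = len(seq)
    best = None
    rc = reverse_complement(seq)
    # longest common substring between seq and rc via dynamic programming
    import numpy as np

    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    prev = np.zeros(n + 1, dtype=np.int32)
    hits = []
    for i in range(1, n + 1):
        cur = np.zeros(n + 1, dtype=np.int32)
        eq = a[i - 1] == b
        cur[1:][eq] = prev[:-1][eq] + 1
        for j in np.nonzero(cur >= min_len)[0]:
            L = int(cur[j])
            s1, e1 = i - L, i
            # rc[j-L:j] corresponds to seq[n-j : n-j+L]
            s2, e2 = n - j, n - j + L
            hits.append((L, s1, e1, s2, e2))
        prev = cur
    for L, s1, e1, s2, e2 in sorted(hits, reverse=True):
        if e1 <= s2 or e2 <= s1:  # disjoint
            first, second = sorted([(s1, e1), (s2, e2)])
            if best is None or L > best[0]:
                best = (L, first, second)
    if best is None:
        return None
    _, (s1, e1), (s2, e2) = best
    return SequenceInterval(s1, e1), SequenceInterval(s2, e2)


def find_inverted_repeat(
    record: PlastomeRecord | str,
    min_len: int = DEFAULT_MIN_LEN,
    max_mismatch_frac: float = 0.0,
):
    """Locate the IR pair; returns ``(irb, ira)`` intervals or ``None``.

    With ``max_mismatch_frac > 0`` the seed extension tolerates mismatches
    as long as their running fraction stays within the budget (flanks must
    match exactly). Coordinates are normalized modulo the genome length;
    a pair wrapping the origin is reported with ``wraps_origin``.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_len:
        raise ValueError(f"sequence length {n} < 2 x min_len {min_len}")
    circular = record.circular if isinstance(record, PlastomeRecord) else True
    search = seq + seq if circular else seq
    m = len(search)
    rc = reverse_complement(search)

    k = min(SEED_K, min_len)
    index: dict[str, list[int]] = {}
    for i in range(0, m - k + 1):
        index.setdefault(search[i : i + k], []).append(i)

    # seeds grouped by diagonal in (search, rc) space
    seen_on_diag: dict[int, list[tuple[int, int]]] = {}
    best: tuple[int, int, int, int, int] | None = None  # (len, s1, e1, s2, e2) on `search`

    def extend(i: int, p: int):
        """Maximally extend a match search[i:i+k] == rc[p:p+k]."""
        nonlocal best
        lo_i, lo_p = i, p
        hi_i, hi_p = i + k, p + k
        mismatches = 0
        # greedy right extension
        while hi_i < m and hi_p < m:
            if search[hi_i] == rc[hi_p]:
                hi_i += 1
                hi_p += 1
            elif max_mismatch_frac > 0 and (mismatches + 1) / (hi_i - lo_i + 1) <= max_mismatch_frac:
                mismatches += 1
                hi_i += 1
                hi_p += 1
            else:
                break
        while lo_i > 0 and lo_p > 0:
            if search[lo_i - 1] == rc[lo_p - 1]:
                lo_i -= 1
                lo_p -= 1
            elif max_mismatch_frac > 0 and (mismatches + 1) / (hi_i - lo_i + 1) <= max_mismatch_frac:
                mismatches += 1
                lo_i -= 1
                lo_p -= 1
            else:
                break
        # trim mismatching flanks
        while lo_i < hi_i and search[lo_i] != rc[lo_p]:
            lo_i += 1
            lo_p += 1
        while hi_i > lo_i and search[hi_i - 1] != rc[hi_p - 1]:
            hi_i -= 1
            hi_p -= 1
        L = hi_i - lo_i
        if L >= min_len:
            s1, e1 = lo_i, hi_i
            s2, e2 = m - hi_p, m - lo_p  # rc[lo_p:hi_p] == revcomp(search[m-hi_p : m-lo_p])
            # compare on normalized (mod n) coordinates so a pair split across
            # the doubled copies still counts as disjoint
            a = sorted([((s1 % n), (s1 % n) + (e1 - s1)), ((s2 % n), (s2 % n) + (e2 - s2))])
            (as1, ae1), (as2, ae2) = a
            if ae1 <= as2 and ae2 <= as1 + n:
                (s1, e1), (s2, e2) = sorted([(s1, e1), (s2, e2)])
                cand = (L, s1, e1, s2, e2)
                if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand < best):
                    best = cand
        return lo_i, hi_i

    for p in range(0, m - k + 1, k):  # non-overlapping probe k-mers of rc
        kmer = rc[p : p + k]
        for i in index.get(kmer, ()):
            d = p - i
            spans = seen_on_diag.setdefault(d, [])
            if any(lo <= i < hi for lo, hi in spans):
                continue
            spans.append(extend(i, p))

    if best is None:
        return None
    _, s1, e1, s2, e2 = best
    if not circular:
        return SequenceInterval(s1, e1), SequenceInterval(s2, e2)
    ivs = []
    for s, e in ((s1, e1), (s2, e2)):
        length = min(e - s, n)
        s_ = s % n
        e_ = s_ + length
        if e_ <= n:
            ivs.append(SequenceInterval(s_, e_))
        else:
            ivs.append(SequenceInterval(s_, e_ - n, wraps_origin=True))
    a, b = ivs
    # dedupe the doubled-sequence mirror: normalize so first interval start < second
    if (a.start, a.end) > (b.start, b.end):
        a, b = b, a
    return a, b


def partition_regions(record: PlastomeRecord | str, ir_pair) -> QuadripartitePartition:
    """Label the two single-copy gaps between the IRs (longer = LSC).

    The returned partition keeps original record coordinates; region order
    around the circle is canonical LSC -> IRb -> SSC -> IRa starting from
    whichever single-copy gap is larger.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    n = len(seq)
    r1, r2 = ir_pair

    def as_pairs(iv: SequenceInterval):
        if iv.wraps_origin:
            return iv.start, iv.end + n
        return iv.start, iv.end

    s1, e1 = as_pairs(r1)
    s2, e2 = as_pairs(r2)
    if s2 < s1:
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
    if e1 > s2 or e2 > s1 + n:
        raise ValueError("overlapping IR pair")
    # gaps on the circle: [e1, s2) and [e2, s1 + n)
    gap1 = (e1 % n, s2 % n, s2 - e1)
    gap2 = (e2 % n, s1 % n, s1 + n - e2)
    if gap1[2] == 0 or gap2[2] == 0:
        raise ValueError("IR pair leaves an empty single-copy gap")
    if gap1[2] == gap2[2]:
        raise ValueError("single-copy gaps have equal length; LSC/SSC labels ambiguous, override required")
    big, small = (gap1, gap2) if gap1[2] > gap2[2] else (gap2, gap1)

    def mk(start: int, end: int) -> SequenceInterval:
        if start < end:
            return SequenceInterval(start, end)
        return SequenceInterval(start, end, wraps_origin=True)

    lsc = mk(big[0], big[1])
    ssc = mk(small[0], small[1])
    # IRb is the IR immediately following LSC on the circle
    if big is gap1:  # lsc = [e1, s2)  -> following IR starts at s2
        irb = mk(s2 % n, e2 % n)
        ira = mk(s1 % n, e1 % n)
    else:  # lsc = [e2, s1+n) -> following IR starts at s1
        irb = mk(s1 % n, e1 % n)
        ira = mk(s2 % n, e2 % n)
    part = QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, seq_len=n)
    assert sum(part.lengths.values()) == n, "regions do not tile the genome"
    return part


def _junction_positions(part: QuadripartitePartition) -> list[tuple[str, int]]:
    """(junction name, first base of downstream region) going around the circle."""
    return [
        ("LSC/IRb", part.irb.start),
        ("IRb/SSC", part.ssc.start),
        ("SSC/IRa", part.ira.start),
        ("IRa/LSC", part.lsc.start),
    ]


def junction_report(record: PlastomeRecord, partition: QuadripartitePartition) -> list[JunctionEvent]:
    """Gene-junction relationships for the four region boundaries.

    A feature whose whole-gene span contains both flanking bases of a
    boundary spans the junction; its ``overlap_bp`` is the number of its
    bases on the minority side. A feature ending exactly at the boundary
    abuts it; otherwise the boundary lies in the spacer between the two
    nearest features.
    """
    n = partition.seq_len
    events = []
    spans = [(f, f.span()) for f in record.features]
    for name, b in _junction_positions(partition):
        upstream = (b - 1) % n
        hit = None
        for f, sp in spans:
            if sp.contains(upstream, n) and sp.contains(b, n):
                hit = (f, sp)
                break
        if hit is not None:
            f, sp = hit
            s, e = sp.start, sp.end if not sp.wraps_origin else sp.end + n
            bb = b if b >= s else b + n
            left = bb - s  # bases upstream of the junction
            right = e - bb
            events.append(
                JunctionEvent(junction=name, feature=f.name, overlap_bp=min(left, right), location_class="spans_junction")
            )
            continue
        abutting = [f for f, sp in spans if sp.end % n == b % n or sp.start % n == b % n]
        if abutting:
            events.append(
                JunctionEvent(junction=name, feature=abutting[0].name, overlap_bp=0, location_class="abuts")
            )
            continue
        # nearest features on each side (circular distance)
        def dist_before(sp):
            return (b - sp.end) % n

        def dist_after(sp):
            return (sp.start - b) % n

        label = "intergenic"
        if spans:
            prev_f = min(spans, key=lambda t: dist_before(t[1]))[0]
            next_f = min(spans, key=lambda t: dist_after(t[1]))[0]
            label = f"{prev_f.name}-{next_f.name}"
        events.append(JunctionEvent(junction=name, feature=label, overlap_bp=0, location_class="within_spacer"))
    return events


def junction_table(sample: str, events: list[JunctionEvent]) -> str:
    """Tab-separated junction report (sample, junction, feature, overlap_bp, class)."""
    lines = ["sample\tjunction\tfeature\toverlap_bp\tlocation_class"]
    for e in events:
        lines.append(f"{sample}\t{e.junction}\t{e.feature}\t{e.overlap_bp}\t{e.location_class}")
    return "\n".join(lines) + "\n"


def regions_bed(sample: str, part: QuadripartitePartition) -> str:
    rows = []
    for label, iv in (("LSC", part.lsc), ("IRb", part.irb), ("SSC", part.ssc), ("IRa", part.ira)):
        if iv.wraps_origin:
            rows.append(f"{sample}\t{iv.start}\t{part.seq_len}\t{label}")
            rows.append(f"{sample}\t0\t{iv.end}\t{label}")
        else:
            rows.append(f"{sample}\t{iv.start}\t{iv.end}\t{label}")
    return "\n".join(rows) + "\n"
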