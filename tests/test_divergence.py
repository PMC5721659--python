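"""Site classification, window event counting, hotspot calling and
pairwise identity — each against a brute-force oracle or planted truth."""

import numpy as np
import pytest

from plastcomp.alignment import AlignmentMatrix
from plastcomp.divergence import (
    WindowStat,
    call_hotspots,
    classify_sites,
    count_window_events,
    pairwise_identity,
    window_scan,
)


def aln_of(*rows, **kw):
    return AlignmentMatrix.from_dict({f"t{i}": s for i, s in enumerate(rows)}, **kw)


# ---------------------------------------------------------------- oracles


def brute_classify(aln):
    """Exhaustive per-column classifier (independent of the vectorized path)."""
    constant = variable = pi = singleton = 0
    for j in range(aln.n_columns):
        col = [aln.data[i, j] for i in range(aln.n_taxa)]
        states = [c for c in col if c in (b"A", b"C", b"G", b"T")]
        uniq = set(states)
        if not uniq:
            continue
        if len(uniq) == 1:
            constant += 1
        else:
            variable += 1
            if sum(1 for u in uniq if states.count(u) >= 2) >= 2:
                pi += 1
            else:
                singleton += 1
    return constant, variable, pi, singleton


def brute_indel_events(aln):
    """Enumerate indel events as maximal same-gap-pattern runs."""
    events = []
    prev_pattern = None
    start = None
    for j in range(aln.n_columns):
        pattern = tuple(aln.data[i, j] == b"-" for i in range(aln.n_taxa))
        if any(pattern):
            if start is None or pattern != prev_pattern:
                if start is not None:
                    events.append((start, j))
                start = j
        else:
            if start is not None:
                events.append((start, j))
                start = None
        prev_pattern = pattern
    if start is not None:
        events.append((start, aln.n_columns))
    return events


# ------------------------------------------------------------ site classes


def test_site_class_definitions():
    a = aln_of("AG", "AG", "GA", "GA")  # both columns PI
    sc = classify_sites(a)
    assert (sc.variable, sc.parsimony_informative, sc.singleton) == (2, 2, 0)
    b = aln_of("A", "A", "A", "G")
    sc = classify_sites(b)
    assert (sc.variable, sc.parsimony_informative, sc.singleton) == (1, 0, 1)


def test_single_taxon_errors():
    with pytest.raises(ValueError):
        classify_sites(aln_of("ACGT"))


def test_classify_matches_bruteforce(rng):
    chars = np.array(list("ACGT-N"), dtype="S1")
    data = chars[rng.integers(0, 6, size=(4, 1000))]
    aln = AlignmentMatrix([f"t{i}" for i in range(4)], data)
    sc = classify_sites(aln)
    assert (sc.constant, sc.variable, sc.parsimony_informative, sc.singleton) == brute_classify(aln)


# ------------------------------------------------------------- window events


def test_identical_pair_no_events():
    a = aln_of("ACGTACGT", "ACGTACGT")
    assert count_window_events(a, 0, 8) == (0, 0)


def test_hand_case_one_gap_one_substitution():
    a = aln_of("ACGT", "A-GA")
    assert count_window_events(a, 0, 4) == (1, 1)


def test_multicolumn_gap_is_one_event():
    a = aln_of("AAAAAAAA", "AA---AAA")
    assert count_window_events(a, 0, 8) == (0, 1)


def test_event_counts_match_bruteforce(rng):
    """Window event counts equal exhaustive enumeration on small alignments."""
    chars = np.array(list("ACGT-"), dtype="S1")
    for _ in range(25):
        data = chars[rng.integers(0, 5, size=(5, 50))]
        aln = AlignmentMatrix([f"t{i}" for i in range(5)], data)
        events = brute_indel_events(aln)
        for s, e in [(0, 50), (10, 30), (25, 26)]:
            ns, ide = count_window_events(aln, s, e)
            assert ide == sum(1 for a, b in events if a < e and b > s)
            brute_ns = 0
            for j in range(s, e):
                col = [c for c in aln.data[:, j] if c in (b"A", b"C", b"G", b"T")]
                if len(set(col)) >= 2:
                    brute_ns += 1
            assert ns == brute_ns


def test_boundary_straddling_event_counts_in_both_windows():
    a = aln_of("AAAAAAAAAA", "AAAA--AAAA")
    assert count_window_events(a, 0, 5)[1] == 1
    assert count_window_events(a, 5, 10)[1] == 1


# --------------------------------------------------------------- window scan


def test_proportion_formula():
    w = WindowStat(start=0, end=600, NS=100, ID=30)
    assert w.proportion == pytest.approx(21.6666, abs=1e-3)
    assert w.L == 600


def test_scan_layout_and_tail():
    a = aln_of("A" * 1500, "A" * 1500)
    ws = window_scan(a, window_len=600, step=200)
    assert [(w.start, w.end) for w in ws] == [(0, 600), (200, 800), (400, 1000), (600, 1200), (800, 1400), (1000, 1500)]
    assert all(w.proportion == 0.0 for w in ws)


def test_short_alignment_single_window_warns():
    a = aln_of("ACGT" * 50, "ACGT" * 50)
    with pytest.warns(UserWarning):
        ws = window_scan(a, window_len=600, step=200)
    assert [(w.start, w.end) for w in ws] == [(0, 200)]


def test_proportion_identity_invariant(rng):
    chars = np.array(list("ACGT-"), dtype="S1")
    data = chars[rng.integers(0, 5, size=(6, 2000))]
    aln = AlignmentMatrix([f"t{i}" for i in range(6)], data)
    for w in window_scan(aln):
        assert w.proportion == pytest.approx(100.0 * (w.NS + w.ID) / w.L, abs=1e-9)


# ----------------------------------------------------------------- hotspots


def test_no_hotspots_below_threshold():
    ws = [WindowStat(0, 600, 60, 60), WindowStat(200, 800, 0, 0)]
    assert ws[0].proportion == 20.0  # exactly 20 does not qualify (strict >)
    assert call_hotspots(ws) == []


def test_two_planted_hotspots_merge_and_separate():
    ws = [
        WindowStat(0, 600, 200, 0),
        WindowStat(200, 800, 180, 0),
        WindowStat(800, 1400, 0, 0),
        WindowStat(1400, 2000, 300, 0),
    ]
    regions = call_hotspots(ws)
    assert [(r.start, r.end) for r in regions] == [(0, 800), (1400, 2000)]
    assert regions[0].peak_proportion == pytest.approx(100 * 200 / 600)


def test_hotspot_feature_annotation():
    labels = np.array(["spacer:a-b"] * 600 + ["cds:g1"] * 600, dtype=object)
    ws = [WindowStat(300, 900, 500, 0)]
    (r,) = call_hotspots(ws, column_labels=labels)
    assert r.overlapping_features == ("spacer:a-b", "cds:g1")


def test_simulated_hotspot_is_argmax(toy_truth):
    """The max-proportion window overlaps a planted elevated-rate region."""
    _, truth = toy_truth
    aln = truth.alignment
    ws = window_scan(aln)
    top = max(ws, key=lambda w: w.proportion)
    assert any(s < top.end and e > top.start for s, e in truth.hotspot_columns)


# ----------------------------------------------------------- identity plot


def test_identity_trivial_cases():
    a = aln_of("A" * 100, "A" * 100)
    out = pairwise_identity(a, "t0", window_len=100, step=100)
    assert out["t1"][0][2] == 100.0
    b = aln_of("A" * 100, "A" * 99 + "G")
    out = pairwise_identity(b, "t0", window_len=100, step=100)
    assert out["t1"][0][2] == pytest.approx(99.0)


def test_identity_unknown_taxon():
    with pytest.raises(ValueError):
        pairwise_identity(aln_of("AC", "AC"), "nope")


def test_identity_tracks_divergence(rng):
    """Mean identity ~= 100(1-p) for a pair at mismatch fraction p."""
    n, p = 20_000, 0.07
    s1 = rng.choice(list("ACGT"), size=n)
    s2 = s1.copy()
    flip = rng.random(n) < p
    alt = rng.choice(list("ACGT"), size=n)
    s2[flip] = alt[flip]
    realized = (s1 != s2).mean()
    aln = aln_of("".join(s1), "".join(s2))
    vals = [v for _, _, v in pairwise_identity(aln, "t0")["t1"]]
    assert np.mean(vals) == pytest.approx(100 * (1 - realized), abs=0.5)
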