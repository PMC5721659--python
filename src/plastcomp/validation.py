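"""End-to-end validation experiments: planted-truth recovery rates and
calibration checks run at the study's conditions.

Each function simulates its own inputs from a seed, runs the relevant
pipeline stage, and returns a measured rate or estimate. They back both
the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .alignment import AlignmentMatrix
from .divergence import call_hotspots, count_window_events, window_scan
from .matrices import build_datasets, filter_light, filter_strict
from .model import reverse_complement
from .orf import clade_omega_contrast, ng86_dnds, simulate_codon_pair, translate_codon
from .plan import TOY_HOTSPOT_LABELS, toy_plan
from .quadripartite import find_inverted_repeat
from .sim import SimConfig, evolve
from .trees import DistanceMatrix, jc_distance, neighbor_joining, parse_newick, robinson_foulds

_ACGT = np.array(list("ACGT"))


def _random_seq(n: int, rng) -> str:
    return "".join(_ACGT[rng.integers(0, 4, size=n)])


# ------------------------------------------------------------- IR recovery


def ir_recovery_rate(n_genomes: int = 100, seed: int = 0,
                     sc_lens: tuple[int, int] = (20_000, 6_000),
                     ir_range: tuple[int, int] = (20_000, 30_000)) -> float:
    """Fraction of planted-IR genomes whose IR pair is recovered exactly.

    Each genome is LSC + IRb + SSC + revcomp(IRb) with the IR length drawn
    uniformly from ``ir_range`` and the four junction-flanking bases pinned
    so the planted pair is maximal on the circle.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    lsc_n, ssc_n = sc_lens
    for _ in range(n_genomes):
        ir_n = int(rng.integers(ir_range[0], ir_range[1] + 1))
        lsc = list(_random_seq(lsc_n, rng))
        ir = _random_seq(ir_n, rng)
        ssc = list(_random_seq(ssc_n, rng))
        comp = dict(zip("ACGT", "TGCA"))
        while lsc[-1] == comp[lsc[0]]:
            lsc[-1] = str(_ACGT[rng.integers(0, 4)])
        while ssc[0] == comp[ssc[-1]]:
            ssc[0] = str(_ACGT[rng.integers(0, 4)])
        g = "".join(lsc) + ir + "".join(ssc) + reverse_complement(ir)
        pair = find_inverted_repeat(g, min_len=10_000)
        if pair is None:
            continue
        got = sorted((iv.start, iv.end) for iv in pair)
        want = sorted([(lsc_n, lsc_n + ir_n), (lsc_n + ir_n + ssc_n, len(g))])
        hits += got == want
    return hits / n_genomes


# ------------------------------------------------ window event count oracle


def _brute_window_events(aln: AlignmentMatrix, start: int, end: int) -> tuple[int, int]:
    ns = 0
    for j in range(start, end):
        col = [c for c in aln.data[:, j] if c in (b"A", b"C", b"G", b"T")]
        if len(set(col)) >= 2:
            ns += 1
    events = []
    prev = None
    run_start = None
    for j in range(aln.n_columns):
        pattern = tuple(bool(aln.data[i, j] == b"-") for i in range(aln.n_taxa))
        if any(pattern):
            if run_start is None or pattern != prev:
                if run_start is not None:
                    events.append((run_start, j))
                run_start = j
        elif run_start is not None:
            events.append((run_start, j))
            run_start = None
        prev = pattern
    if run_start is not None:
        events.append((run_start, aln.n_columns))
    ide = sum(1 for a, b in events if a < end and b > start)
    return ns, ide


def window_event_oracle_agreement(n_reps: int = 50, seed: int = 0) -> float:
    """Fraction of random <=50-column alignments where (NS, ID) equals
    exhaustive enumeration, over several windows each."""
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT-N"), dtype="S1")
    ok = 0
    for _ in range(n_reps):
        n_taxa = int(rng.integers(2, 8))
        n_cols = int(rng.integers(5, 51))
        data = chars[rng.integers(0, 6, size=(n_taxa, n_cols))]
        aln = AlignmentMatrix([f"t{i}" for i in range(n_taxa)], data)
        windows = [(0, n_cols), (0, max(1, n_cols // 2)), (n_cols // 3, n_cols)]
        if all(count_window_events(aln, s, e) == _brute_window_events(aln, s, e) for s, e in windows):
            ok += 1
    return ok / n_reps


# ------------------------------------------------------ strict filter oracle


def strict_filter_oracle_agreement(n_reps: int = 50, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT-"), dtype="S1")
    ok = 0
    for _ in range(n_reps):
        n_taxa = int(rng.integers(2, 10))
        n_cols = int(rng.integers(10, 300))
        data = chars[rng.integers(0, 5, size=(n_taxa, n_cols))]
        aln = AlignmentMatrix([f"t{i}" for i in range(n_taxa)], data)
        out = filter_strict(aln)
        keep = [j for j in range(n_cols) if not any(data[i, j] == b"-" for i in range(n_taxa))]
        good = out.n_columns == len(keep) and np.array_equal(out.data, data[:, keep])
        good = good and not (out.data == b"-").any()
        ok += good
    return ok / n_reps


# -------------------------------------------------------- NJ additive trees


def _random_additive_tree(n_leaves: int, rng):
    subtrees = [f"L{i}" for i in range(n_leaves)]
    groups = [(f"L{i}",) for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        la, lb = 0.1 + rng.random(), 0.1 + rng.random()
        merged = f"({subtrees[i]}:{la:.5f},{subtrees[j]}:{lb:.5f})"
        mg = groups[i] + groups[j]
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [mg]
    return subtrees[0] + ";", sorted(groups[0])


def _patristic(newick: str, taxa: list[str]) -> np.ndarray:
    tree = parse_newick(newick)
    # leaf-to-leaf distances by accumulating root paths
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    mat = np.zeros((len(taxa), len(taxa)))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i < j:
                px, py = paths[x], paths[y]
                k = 0
                while k < min(len(px), len(py)) and px[k] is py[k]:
                    k += 1
                d = sum(n.length for n in px[k:]) + sum(n.length for n in py[k:])
                mat[i, j] = mat[j, i] = d
    return mat


def nj_additive_recovery_rate(n_reps: int = 50, seed: int = 0, max_leaves: int = 10) -> float:
    """Fraction of random additive distance matrices (4..max_leaves taxa)
    from which NJ reconstructs the generating topology exactly."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        n_leaves = int(rng.integers(4, max_leaves + 1))
        newick, taxa = _random_additive_tree(n_leaves, rng)
        mat = _patristic(newick, taxa)
        est = neighbor_joining(DistanceMatrix(taxa, mat))
        hits += robinson_foulds(est, parse_newick(newick)) == 0
    return hits / n_reps


# ---------------------------------------------------- topology invariance


def topology_invariance_rate(n_reps: int = 50, seed: int = 0) -> float:
    """The study's headline claim as a property: fraction of replicates in
    which the NJ topology from all of {complete, coding, noncoding} x
    {unfiltered, light, strict} matrices equals the true tree (RF = 0).

    Replicates use the scaled-down quadripartite plan at Cornales-like
    per-site divergence (the default 15-taxon tree).
    """
    filters = (lambda a: a, filter_light, filter_strict)
    hits = 0
    for r in range(n_reps):
        cfg = SimConfig(
            plan=toy_plan(),
            hotspot_labels={lab: 10.0 for lab in TOY_HOTSPOT_LABELS},
            seed=seed * 100_003 + r,
        )
        _, truth = evolve(cfg)
        true_tree = parse_newick(truth.tree)
        b = build_datasets(truth.alignment)
        all_zero = True
        for aln in (b.complete, b.coding, b.noncoding):
            for flt in filters:
                est = neighbor_joining(jc_distance(flt(aln)))
                if robinson_foulds(est, true_tree) != 0:
                    all_zero = False
        hits += all_zero
    return hits / n_reps


# ------------------------------------------------------- hotspot recovery


def hotspot_recovery(n_reps: int = 50, seed: int = 0, multiplier: float = 10.0):
    """(recall, null_clean_rate): recall of planted elevated-rate regions
    by the >20% sliding-window rule, and the fraction of rate-homogeneous
    null replicates with no hotspot call at all."""
    found = total = 0
    null_clean = 0
    for r in range(n_reps):
        cfg = SimConfig(
            plan=toy_plan(),
            hotspot_labels={lab: multiplier for lab in TOY_HOTSPOT_LABELS},
            seed=seed * 7_919 + r,
        )
        _, truth = evolve(cfg)
        regions = call_hotspots(window_scan(truth.alignment))
        for s, e in truth.hotspot_columns:
            total += 1
            found += any(h.start < e and h.end > s for h in regions)
        null_cfg = SimConfig(plan=toy_plan(), hotspot_labels={}, seed=seed * 7_919 + r)
        _, null_truth = evolve(null_cfg)
        null_regions = call_hotspots(window_scan(null_truth.alignment))
        null_clean += len(null_regions) == 0
    return found / total, null_clean / n_reps


# ----------------------------------------------------------- NG86 recovery


def ng86_recovery(n_reps: int = 50, seed: int = 0, omega: float = 0.35,
                  n_codons: int = 300, subs_per_site: float = 0.08) -> float:
    """Mean NG86 omega over simulated codon pairs with true ratio ``omega``."""
    rng = np.random.default_rng(seed)
    oms = []
    for _ in range(n_reps):
        a, b = simulate_codon_pair(n_codons, omega, subs_per_site, rng)
        est = ng86_dnds(a, b)
        if est.omega is not None:
            oms.append(est.omega)
    return float(np.mean(oms))


def _diverge_cds(seq: str, omega: float, subs_per_site: float, rng) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for _ in range(rng.poisson(subs_per_site * len(seq))):
        site = int(rng.integers(0, len(seq)))
        ci, off = divmod(site, 3)
        cur = codons[ci]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == cur[off]:
            continue
        mut = cur[:off] + alt + cur[off + 1 :]
        if translate_codon(mut) == "*":
            continue
        if translate_codon(mut) != translate_codon(cur) and rng.random() >= omega:
            continue
        codons[ci] = mut
    return "".join(codons)


def permutation_null_rejection_rate(n_reps: int = 200, seed: int = 0,
                                    omega: float = 0.35, n_codons: int = 300,
                                    n_each: int = 4, alpha: float = 0.05) -> float:
    """Type-I error of the clade contrast: two groups simulated under the
    same omega; fraction of replicates with p <= alpha (999 permutations)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for r in range(n_reps):
        anc, _ = simulate_codon_pair(n_codons, omega, 0.0, rng)
        seqs = {"outgroup": anc}
        groups = {"outgroup": "outgroup"}
        for g in ("A", "B"):
            for i in range(n_each):
                t = f"{g}{i}"
                seqs[t] = _diverge_cds(anc, omega, 0.08, rng)
                groups[t] = g
        res = clade_omega_contrast(seqs, groups, "outgroup", n_permutations=999, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return rejections / n_reps
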