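"""ORF scanning, disruption characterization, NG86 dN/dS and the
permutation clade contrast."""

import numpy as np
import pytest

from plastcomp.alignment import AlignmentMatrix
from plastcomp.io import extract_feature_sequence
from plastcomp.orf import (
    characterize_disruption,
    clade_omega_contrast,
    ng86_dnds,
    scan_orf,
    simulate_codon_pair,
)


# ----------------------------------------------------------------- scan_orf


def test_scan_orf_clean():
    rep = scan_orf("ATGAAATAA")
    assert rep.internal_stops == ()
    assert rep.terminal_stop_present
    assert rep.translatable


def test_scan_orf_internal_stop():
    rep = scan_orf("ATGTAAAAATAA")
    assert rep.internal_stops == (1,)
    assert not rep.translatable


def test_scan_orf_frame_length():
    rep = scan_orf("ATGAAAT")  # 7 bp, trailing partial codon
    assert rep.cds_length % 3 != 0
    assert not rep.translatable


def test_scan_orf_rejects_garbage():
    with pytest.raises(ValueError):
        scan_orf("ATG@@@")


# ---------------------------------------------------- disruption description


def test_frameshift_deletion_phase():
    aln = AlignmentMatrix.from_dict({"ref": "ATGAAAGGG", "q": "ATGA-AGGG"})
    (rep,) = characterize_disruption(aln, "ref")
    assert rep.frameshifts == ((4, -1, 1),)


def test_point_nonsense_reported():
    # codon 1 TGG -> TGA
    aln = AlignmentMatrix.from_dict({"ref": "ATGTGGAAATAA", "q": "ATGTGAAAATAA"})
    (rep,) = characterize_disruption(aln, "ref")
    assert rep.point_nonsense == ((1, "TGG", "TGA"),)
    assert rep.frameshifts == ()
    assert rep.has_internal_stop


def test_reference_with_stop_rejected():
    aln = AlignmentMatrix.from_dict({"ref": "ATGTAAAAATAA", "q": "ATGAAAAAATAA"})
    with pytest.raises(ValueError):
        characterize_disruption(aln, "ref")


def test_injected_insertion_recovered():
    ins = "ACGTACGTACGTACGTACG"  # 19 bp
    ref = "ATG" + "GAA" * 30 + "TAA"
    q = ref[:45] + ins + ref[45:]
    aln = AlignmentMatrix.from_dict({"ref": ref[:45] + "-" * 19 + ref[45:], "q": q})
    (rep,) = characterize_disruption(aln, "ref")
    assert rep.indels == ((45, 19, 1),)
    assert rep.frameshifts == ((45, 19, 1),)


# --------------------------------------------------------------------- NG86


def test_ng86_identical():
    est = ng86_dnds("ATGGAAAAA", "ATGGAAAAA")
    assert est.dN == est.dS == 0.0
    assert est.omega is None


def test_ng86_single_synonymous_change():
    est = ng86_dnds("ATGGAAAAA", "ATGGAGAAA")
    assert (est.Nd, est.Sd) == (0.0, 1.0)
    assert est.omega == 0.0


def test_ng86_single_nonsynonymous_change():
    # AAA (Lys) -> GAA (Glu): nonsynonymous only
    est = ng86_dnds("ATGAAAGAA", "ATGGAAGAA")
    assert (est.Nd, est.Sd) == (1.0, 0.0)
    assert est.dS == 0.0 and est.omega is None


def test_ng86_symmetry():
    a, b = "ATGGATACCGGA", "ATGGACATTGGC"
    e1, e2 = ng86_dnds(a, b), ng86_dnds(b, a)
    assert (e1.N, e1.S, e1.Nd, e1.Sd) == (e2.N, e2.S, e2.Nd, e2.Sd)


def test_ng86_site_counts_hand_case():
    """Hand-enumerated case: ATG has 0 synonymous sites, TTT (Phe) has 1/3
    (third-position T->C only), so N + S = 3 x codons."""
    est = ng86_dnds("ATGTTT", "ATGTTT")
    assert est.S == pytest.approx(1 / 3)
    assert est.N + est.S == pytest.approx(6.0)


def test_ng86_two_hit_codon_path_averaging():
    """TTT -> GTA: both orders of the two changes give 2 nonsynonymous
    steps (F->V->V? no: F->V, V->V is impossible; enumerate: via GTT
    (F->V then V->V? GTT=V, GTA=V: second step synonymous) or via TTA
    (F->L then L->V): averaged Sd = 0.5, Nd = 1.5."""
    est = ng86_dnds("TTTAAA", "GTAAAA")
    assert est.Sd == pytest.approx(0.5)
    assert est.Nd == pytest.approx(1.5)


def test_ng86_rejects_internal_stop():
    with pytest.raises(ValueError):
        ng86_dnds("ATGTAAAAA", "ATGTAAAAA")


def test_ng86_simulation_recovery(rng):
    """Mean NG86 omega over replicates recovers the simulated ratio 0.35."""
    oms = []
    for _ in range(30):
        a, b = simulate_codon_pair(300, 0.35, 0.08, rng)
        oms.append(ng86_dnds(a, b).omega)
    assert 0.25 <= float(np.mean(oms)) <= 0.45


# --------------------------------------------------------- clade contrast


def _group_data(rng, omega_by_group, n_codons=300, n_each=3):
    seqs, groups = {}, {}
    out_a, out_b = simulate_codon_pair(n_codons, 0.5, 0.02, rng)
    seqs["outgroup"] = out_a
    groups["outgroup"] = "outgroup"
    for g, om in omega_by_group.items():
        for i in range(n_each):
            _, child = simulate_codon_pair(n_codons, om, 0.08, rng)
            # diverge each taxon from the outgroup under the group's omega
            seqs[f"{g}{i}"] = _diverge(out_a, om, 0.08, rng)
            groups[f"{g}{i}"] = g
    return seqs, groups


def _diverge(seq, omega, subs, rng):
    from plastcomp.orf import NONSTOP_CODONS, translate_codon

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    n_prop = rng.poisson(subs * len(seq))
    for _ in range(n_prop):
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


def test_single_group_p_is_one(rng):
    seqs, groups = _group_data(rng, {"A": 0.35})
    res = clade_omega_contrast(seqs, groups, "outgroup", n_permutations=99, seed=0)
    assert res.p_value == 1.0
    assert res.statistic == 0.0


def test_contrast_power_under_strong_difference(rng):
    """omega 0.1 vs 0.9 groups: the permutation test usually rejects."""
    hits = 0
    reps = 20
    for r in range(reps):
        seqs, groups = _group_data(rng, {"lo": 0.08, "hi": 0.9}, n_each=4)
        res = clade_omega_contrast(seqs, groups, "outgroup", n_permutations=199, seed=r)
        hits += res.p_value <= 0.05
    assert hits >= 0.8 * reps


def test_contrast_groups_report(rng):
    seqs, groups = _group_data(rng, {"A": 0.3, "B": 0.3})
    res = clade_omega_contrast(seqs, groups, "outgroup", n_permutations=99, seed=3)
    assert set(res.group_omega) == {"A", "B"}
    assert 0 < res.p_value <= 1.0


# -------------------------------------------------- simulator ORF invariant


def test_simulator_orf_sensitivity_and_specificity(toy_truth):
    """Every injected disruption is flagged; no background gene is."""
    from plastcomp.plan import toy_plan
    from plastcomp.sim import Disruption, SimConfig, evolve

    cfg = SimConfig(
        plan=toy_plan(),
        hotspot_labels={},
        disruptions=(
            Disruption(taxon="Curtisia_dentata", gene="rpl22", kind="frameshift", length=1),
            Disruption(taxon="Mastixia_caudatilimba", gene="rpl22", kind="nonsense"),
            Disruption(taxon="Cornus_capitata_1", gene="rpl22", kind="frameshift", length=19),
        ),
        seed=77,
    )
    records, truth = evolve(cfg)
    disrupted = {(d.taxon, d.gene) for d in truth.disruptions}
    flagged = set()
    for taxon, rec in records.items():
        for f in rec.features_of_kind("CDS"):
            rep = scan_orf(extract_feature_sequence(rec, f), sample=taxon, gene=f.name)
            frame_broken = rep.cds_length % 3 != 0
            if rep.internal_stops or frame_broken:
                flagged.add((taxon, f.name))
    assert flagged == disrupted
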