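"""Data-set construction, strict/light filtering and partition subsets."""

import numpy as np
import pytest

from plastcomp.alignment import AlignmentMatrix
from plastcomp.matrices import (
    build_datasets,
    build_partitions,
    filter_light,
    filter_strict,
    nexus_sets_block,
    raxml_partition_text,
)


def labeled_aln(rows, labels, regions=None):
    aln = AlignmentMatrix.from_dict(
        {f"t{i}": s for i, s in enumerate(rows)},
        column_labels=np.array(labels, dtype=object),
        region_labels=None if regions is None else np.array(regions, dtype=object),
    )
    return aln


def test_build_datasets_toy_split():
    rows = ["ACGTACGT", "ACGTACGT"]
    labels = ["cds:g1"] * 3 + ["spacer:g1-g2"] * 2 + ["cds:g2"] * 3
    b = build_datasets(labeled_aln(rows, labels, ["LSC"] * 8), drop_second_ir=True)
    assert b.coding.n_columns == 6
    assert b.noncoding.n_columns == 2
    assert b.coding.n_columns + b.noncoding.n_columns == b.complete.n_columns


def test_build_datasets_drops_ira():
    rows = ["ACGTAC", "ACGTAC"]
    labels = ["cds:g1"] * 6
    regions = ["LSC", "LSC", "IRa", "IRa", "SSC", "SSC"]
    b = build_datasets(labeled_aln(rows, labels, regions))
    assert b.complete.n_columns == 4


def test_build_datasets_requires_labels():
    aln = AlignmentMatrix.from_dict({"a": "ACG", "b": "ACG"})
    with pytest.raises(ValueError):
        build_datasets(aln)


def test_datasets_from_simulator_truth(toy_truth):
    """Coding/noncoding column counts equal the simulator's truth labels."""
    _, truth = toy_truth
    aln = truth.alignment
    b = build_datasets(aln)
    keep = np.asarray(aln.region_labels) != "IRa"
    labels = np.asarray(aln.column_labels)[keep]
    want_coding = sum(str(x).startswith(("cds:", "trna:", "rrna:")) for x in labels)
    assert b.coding.n_columns == want_coding
    assert b.noncoding.n_columns == len(labels) - want_coding


def test_filter_strict_bruteforce(rng):
    chars = np.array(list("ACGT-"), dtype="S1")
    data = chars[rng.integers(0, 5, size=(6, 400))]
    aln = AlignmentMatrix([f"t{i}" for i in range(6)], data)
    out = filter_strict(aln)
    keep = [j for j in range(400) if all(aln.data[i, j] != b"-" for i in range(6))]
    assert out.n_columns == len(keep)
    assert np.array_equal(out.data, aln.data[:, keep])
    assert not (out.data == b"-").any()


def test_filter_strict_identity_on_gapless():
    aln = AlignmentMatrix.from_dict({"a": "ACGT", "b": "ACGT"})
    assert filter_strict(aln).n_columns == 4


def test_filter_light_gap_majority_column_removed():
    aln = AlignmentMatrix.from_dict({"a": "A-", "b": "A-", "c": "A-", "d": "AG"})
    out = filter_light(aln)
    assert out.n_columns == 1


def test_filter_light_identity_on_clean():
    aln = AlignmentMatrix.from_dict({"a": "ACGT" * 5, "b": "ACGT" * 5})
    assert filter_light(aln).n_columns == 20


def test_filter_light_removes_planted_gappy_block(rng):
    """A hypervariable, gap-riddled block disappears; clean flanks stay."""
    n_taxa = 8
    flank = np.array(list("ACGT" * 25), dtype="S1")
    left = np.tile(flank, (n_taxa, 1))
    right = np.tile(flank, (n_taxa, 1))
    chars = np.array(list("ACGT----"), dtype="S1")  # 50% gaps, rest scattered
    block = chars[rng.integers(0, 8, size=(n_taxa, 50))]
    data = np.hstack([left, block, right])
    aln = AlignmentMatrix([f"t{i}" for i in range(n_taxa)], data)
    out = filter_light(aln)
    assert out.n_columns >= 200  # flanks intact
    assert out.n_columns <= 210  # block essentially gone
    assert filter_strict(aln).n_columns <= out.n_columns


def test_light_contains_strict(toy_truth):
    """filter_light output is a superset of filter_strict output."""
    _, truth = toy_truth
    aln = truth.alignment
    light = filter_light(aln)
    strict = filter_strict(aln)
    assert strict.n_columns <= light.n_columns
    assert not (strict.data == b"-").any()
    # every strict (gap-free) column survives the light filter
    light_cols = set(map(tuple, light.data.T.tolist()))
    for col in strict.data.T.tolist():
        assert tuple(col) in light_cols


def test_partition_rule_trace():
    """Genes of 250/150/300 bp and spacers of 500/100 bp: the short gene
    and spacer merge into their categories' pooled subsets."""
    rng = np.random.default_rng(0)
    chars = np.array(list("ACGT"), dtype="S1")
    data = chars[rng.integers(0, 4, size=(4, 1300))]
    labels = (
        ["cds:g1"] * 250 + ["spacer:s1"] * 500 + ["cds:g2"] * 150
        + ["spacer:s2"] * 100 + ["cds:g3"] * 300
    )
    aln = AlignmentMatrix([f"t{i}" for i in range(4)], data, column_labels=np.array(labels, dtype=object))
    scheme = build_partitions(aln, min_subset=200)
    assert set(scheme.names) == {"cds:g1", "cds:g3", "spacer:s1", "pooled-CDS", "pooled-spacer"}
    assert set(scheme.merged_small) == {"cds:g2", "spacer:s2"}
    # disjoint + exhaustive
    cols = np.concatenate([c for _, c, _ in scheme.subsets])
    assert sorted(cols.tolist()) == list(range(1300))


def test_partition_no_merging_when_all_large(rng):
    chars = np.array(list("ACGT"), dtype="S1")
    data = chars[rng.integers(0, 4, size=(4, 600))]
    labels = ["cds:a"] * 300 + ["spacer:x"] * 300
    aln = AlignmentMatrix([f"t{i}" for i in range(4)], data, column_labels=np.array(labels, dtype=object))
    scheme = build_partitions(aln)
    assert len(scheme.subsets) == 2
    assert scheme.merged_small == []


def test_invariant_subsets_are_pooled():
    data = np.array([list("AAAACCCC"), list("AAAACCCC"), list("AAAACCCC")], dtype="S1")
    labels = ["cds:a"] * 4 + ["cds:b"] * 4
    aln = AlignmentMatrix(["x", "y", "z"], data, column_labels=np.array(labels, dtype=object))
    scheme = build_partitions(aln, min_subset=2)
    assert scheme.names == ["pooled-CDS"]


def test_partition_text_formats():
    rng = np.random.default_rng(0)
    chars = np.array(list("ACGT"), dtype="S1")
    data = chars[rng.integers(0, 4, size=(4, 500))]
    labels = ["cds:a"] * 250 + ["spacer:x"] * 250
    aln = AlignmentMatrix([f"t{i}" for i in range(4)], data, column_labels=np.array(labels, dtype=object))
    scheme = build_partitions(aln)
    txt = raxml_partition_text(scheme)
    assert "DNA, cds:a = 1-250" in txt
    assert "DNA, spacer:x = 251-500" in txt
    nex = nexus_sets_block(scheme)
    assert nex.startswith("#NEXUS")
    assert "charset" in nex


def test_partition_determinism(toy_truth):
    _, truth = toy_truth
    from plastcomp.matrices import build_datasets

    b = build_datasets(truth.alignment)
    s1 = build_partitions(b.complete)
    s2 = build_partitions(b.complete)
    assert s1.names == s2.names
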