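"""Synthetic quadripartite plastomes evolved along a known tree, with
ground truth for every downstream stage.

Model
-----
Substitutions follow a Jukes-Cantor kernel per branch: each site changes
with probability 3/4 (1 - exp(-4 d/3)) where d = branch length x the
site's rate multiplier (region x coding x hotspot), and a changed site
picks one of the other three bases uniformly. The two IR copies evolve as
one locus: mutations are drawn on IRb only and mirrored to IRa, so the
pair stays an exact reverse-complement (IR co-conversion). Background
substitutions that would create an in-frame stop codon in a CDS are
vetoed, and background indels (geometric lengths) fall only in single-copy
noncoding sites, so reading-frame disruptions arise exclusively from the
explicit disruption spec. The true multiple alignment is maintained
exactly through per-site keys: every ancestral site carries a sortable
key, insertions create fresh keys ordered after their anchor, and the
leaf-wise union of keys defines the alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import AlignmentMatrix
from .model import FeatureAnnotation, PlastomeRecord, SequenceInterval
from .plan import DEFAULT_HOTSPOT_LABELS, CORNALES_TREE, GenomePlan, cornales_like_plan

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA as base codes

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")


@dataclass(frozen=True)
class Disruption:
    taxon: str
    gene: str
    kind: str  # nonsense | frameshift
    length: int = 1  # frameshift indel length (negative = deletion)
    codon_index: int | None = None  # nonsense target; default mid-gene


@dataclass
class SimConfig:
    tree: str = CORNALES_TREE
    plan: GenomePlan = field(default_factory=cornales_like_plan)
    rate_ir: float = 0.3
    rate_coding: float = 0.5
    rate_noncoding: float = 1.0
    indel_rate: float = 0.1  # events per eligible site per unit branch length
    indel_mean_len: float = 4.0  # geometric mean length
    hotspot_labels: dict = field(default_factory=lambda: {lab: 10.0 for lab in DEFAULT_HOTSPOT_LABELS})
    disruptions: tuple[Disruption, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for v in (self.rate_ir, self.rate_coding, self.rate_noncoding):
            if v <= 0:
                raise ValueError("rate multipliers must be > 0")


@dataclass
class _FeatMeta:
    fid: int
    name: str
    kind: str
    strand: str
    region: str


@dataclass
class _State:
    """Mutable per-node genome state (parallel arrays + alignment keys)."""

    seq: np.ndarray  # uint8 base codes 0..3
    region: np.ndarray  # uint8: index into REGION_NAMES
    label: np.ndarray  # int32 index into label table
    exon: np.ndarray  # bool: coding column (CDS/tRNA/rRNA exon)
    feat: np.ndarray  # int32 feature instance id or -1 (gene span incl introns)
    cds: np.ndarray  # int32 CDS instance id or -1 (exon sites only)
    cds_pos: np.ndarray  # int32 position within the coding sequence
    rate: np.ndarray  # float32 site rate multiplier
    keys: list  # sortable per-site alignment keys

    def copy(self) -> "_State":
        return _State(
            self.seq.copy(), self.region.copy(), self.label.copy(), self.exon.copy(),
            self.feat.copy(), self.cds.copy(), self.cds_pos.copy(), self.rate.copy(),
            list(self.keys),
        )

    def __len__(self):
        return len(self.seq)


@dataclass
class TruthBundle:
    tree: str
    alignment: AlignmentMatrix
    ir_intervals: dict  # taxon -> (irb, ira) SequenceIntervals
    hotspot_columns: list  # (start, end) alignment-column intervals
    hotspot_labels: dict
    disruptions: tuple
    branch_substitutions: dict  # (parent, child) or leaf label -> count
    records: dict  # taxon -> PlastomeRecord
    plan: GenomePlan


def _rand_bases(n: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _rand_codons(n_codons: int, gc: float, rng) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    out = np.empty(3 * n_codons, dtype=np.uint8)
    i = 0
    while i < n_codons:
        c = tuple(rng.choice(4, size=3, p=p))
        if c in _STOP_CODES:
            continue
        out[3 * i : 3 * i + 3] = c
        i += 1
    return out


def _complement(codes: np.ndarray) -> np.ndarray:
    return (3 - codes).astype(np.uint8)


class _Builder:
    def __init__(self, config: SimConfig, rng):
        self.cfg = config
        self.rng = rng
        self.labels: list[str] = []
        self.label_idx: dict[str, int] = {}
        self.meta: list[_FeatMeta] = []

    def _lab(self, s: str) -> int:
        if s not in self.label_idx:
            self.label_idx[s] = len(self.labels)
            self.labels.append(s)
        return self.label_idx[s]

    def build_ancestor(self) -> _State:
        cfg, rng = self.cfg, self.rng
        plan = cfg.plan
        cols = {k: [] for k in ("seq", "region", "label", "exon", "feat", "cds", "cds_pos")}

        def emit(seq, region, label, exon, feat, cds, cds_pos):
            cols["seq"].append(seq)
            n = len(seq)
            cols["region"].append(np.full(n, region, np.uint8))
            cols["label"].append(np.full(n, label, np.int32))
            cols["exon"].append(np.full(n, exon, bool) if np.isscalar(exon) else exon)
            cols["feat"].append(np.full(n, feat, np.int32))
            cols["cds"].append(cds if not np.isscalar(cds) else np.full(n, cds, np.int32))
            cols["cds_pos"].append(cds_pos if not np.isscalar(cds_pos) else np.full(n, cds_pos, np.int32))

        def build_feature(f, region_code, region_name):
            fid = len(self.meta)
            self.meta.append(_FeatMeta(fid, f.name, f.kind, f.strand, region_name))
            prefix = {"CDS": "cds", "tRNA": "trna", "rRNA": "rrna"}[f.kind]
            lab = self._lab(f"{prefix}:{f.name}")
            total_exon = sum(f.exons)
            if f.kind == "CDS":
                coding = np.empty(total_exon, dtype=np.uint8)
                coding[:3] = (0, 3, 2)  # ATG
                coding[3:-3] = _rand_codons(total_exon // 3 - 2, plan.gc_coding, rng)
                coding[-3:] = (3, 0, 0)  # TAA
                genomic = coding if f.strand == "+" else _complement(coding)[::-1]
                pos = np.arange(total_exon) if f.strand == "+" else np.arange(total_exon)[::-1]
                cid = fid
            else:
                genomic = _rand_bases(total_exon, plan.gc_coding, rng)
                pos = np.full(total_exon, -1, np.int32)
                cid = -1
            off = 0
            for i, ex in enumerate(f.exons):
                emit(genomic[off : off + ex], region_code, lab, True, fid,
                     np.full(ex, cid, np.int32), pos[off : off + ex].astype(np.int32))
                off += ex
                if i < len(f.introns):
                    ilab = self._lab(f"intron:{f.name}.{i + 1}")
                    emit(_rand_bases(f.introns[i], plan.gc_noncoding, rng), region_code, ilab, False, fid, -1, -1)

        for region_name, region_code, feats in (("LSC", 0, plan.lsc), ("IRb", 1, plan.irb), ("SSC", 2, plan.ssc)):
            spacers = plan.region_spacers(region_name)
            names = [f.name for f in feats]
            for i, gap in enumerate(spacers):
                left = names[i - 1] if i > 0 else (names[-1] if names else "start")
                right = names[i] if i < len(names) else names[0]
                slab = self._lab(f"spacer:{left}-{right}")
                emit(_rand_bases(gap, plan.gc_noncoding, rng), region_code, slab, False, -1, -1, -1)
                if i < len(feats):
                    build_feature(feats[i], region_code, region_name)

        state = _State(
            seq=np.concatenate(cols["seq"]).astype(np.uint8),
            region=np.concatenate(cols["region"]),
            label=np.concatenate(cols["label"]),
            exon=np.concatenate(cols["exon"]),
            feat=np.concatenate(cols["feat"]),
            cds=np.concatenate(cols["cds"]),
            cds_pos=np.concatenate(cols["cds_pos"]),
            rate=np.empty(0, np.float32),
            keys=[],
        )
        # IRa = mirrored IRb with fresh feature ids (duplicate gene copies)
        irb_mask = state.region == 1
        idx = np.nonzero(irb_mask)[0]
        mirror_fid = np.full(len(self.meta), -1, np.int32)
        for m in list(self.meta):
            if m.region == "IRb":
                fid = len(self.meta)
                self.meta.append(_FeatMeta(fid, m.name, m.kind, "-" if m.strand == "+" else "+", "IRa"))
                mirror_fid[m.fid] = fid
        feat_m = state.feat[idx][::-1].copy()
        remap = feat_m >= 0
        feat_m[remap] = mirror_fid[feat_m[remap]]
        ira = _State(
            seq=_complement(state.seq[idx])[::-1],
            region=np.full(len(idx), 3, np.uint8),
            label=state.label[idx][::-1].copy(),
            exon=state.exon[idx][::-1].copy(),
            feat=feat_m,
            cds=np.full(len(idx), -1, np.int32),
            cds_pos=np.full(len(idx), -1, np.int32),
            rate=np.empty(0, np.float32),
            keys=[],
        )
        for name in ("seq", "region", "label", "exon", "feat", "cds", "cds_pos"):
            setattr(state, name, np.concatenate([getattr(state, name), getattr(ira, name)]))
        # site rate multipliers
        cfg_rate = np.where(state.exon, self.cfg.rate_coding, self.cfg.rate_noncoding)
        ir = (state.region == 1) | (state.region == 3)
        cfg_rate = cfg_rate * np.where(ir, self.cfg.rate_ir, 1.0)
        hot = np.ones(len(state.seq))
        for lab, mult in self.cfg.hotspot_labels.items():
            if lab in self.label_idx:
                hot[state.label == self.label_idx[lab]] = mult
        state.rate = (cfg_rate * hot).astype(np.float32)
        state.keys = [(i,) for i in range(len(state.seq))]
        _fix_ir_flanks(state, self.rng)
        assert len(state.seq) == self.cfg.plan.genome_len
        return state


def _fix_ir_flanks(state: _State, rng) -> None:
    """Make the planted IR maximal: the bases flanking the pair must not
    extend the reverse-complement match on the circle."""
    n = len(state.seq)
    b = np.nonzero(state.region == 1)[0]
    a = np.nonzero(state.region == 3)[0]
    b0, b1 = b[0], b[-1] + 1
    a0, a1 = a[0], a[-1] + 1
    pairs = [((b0 - 1) % n, a1 % n), (b1 % n, (a0 - 1) % n)]
    for i, j in pairs:
        while state.seq[i] == 3 - state.seq[j]:
            state.seq[i] = rng.integers(0, 4)


def _mirror_ir(state: _State) -> None:
    idx_b = np.nonzero(state.region == 1)[0]
    idx_a = np.nonzero(state.region == 3)[0]
    state.seq[idx_a] = _complement(state.seq[idx_b])[::-1]


def _veto_cds_stops(state: _State, hits: np.ndarray) -> np.ndarray:
    """Revert substitutions that created an in-frame stop. Returns the
    surviving hit index array."""
    hit_set = hits[state.cds[hits] >= 0]
    if len(hit_set) == 0:
        return hits
    reverted = []
    for g in np.unique(state.cds[hit_set]):
        sites = np.nonzero(state.cds == g)[0]
        order = np.argsort(state.cds_pos[sites], kind="stable")
        sites = sites[order]  # genomic indices in coding order
        coding = state.seq[sites]
        if sites[0] > sites[-1]:  # minus strand: genomic order reversed
            coding = _complement(coding)
        n_codons = len(coding) // 3
        codons = coding[: 3 * n_codons].reshape(-1, 3)
        stops = np.nonzero(
            (codons[:, 0] == 3)
            & (
                ((codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 2)))
                | ((codons[:, 1] == 2) & (codons[:, 2] == 0))
            )
        )[0]
        bad = set(stops[stops < n_codons - 1].tolist())  # new internal stops
        if n_codons - 1 not in stops:  # terminal stop lost
            bad.add(n_codons - 1)
        if tuple(codons[0]) != (0, 3, 2):  # start codon lost
            bad.add(0)
        for ci in bad:
            reverted.extend(sites[3 * ci : 3 * ci + 3])
    if not reverted:
        return hits
    reverted = np.array(sorted(set(reverted) & set(hit_set.tolist())), dtype=hits.dtype)
    return np.setdiff1d(hits, reverted)


def _evolve_branch(parent: _State, t: float, cfg: SimConfig, rng, counter: list) -> tuple[_State, int]:
    state = parent.copy()
    n = len(state)
    eligible = state.region != 3  # IRa mirrors IRb
    d = t * state.rate
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    u = rng.random(n)
    hits = np.nonzero(eligible & (u < p))[0]
    old = state.seq[hits].copy()
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits)).astype(np.uint8)
        state.seq[hits] = (state.seq[hits] + shift) % 4
        survivors = _veto_cds_stops(state, hits)
        dropped = np.setdiff1d(hits, survivors)
        if len(dropped):
            # restore vetoed sites to their parental base
            pos_in_hits = np.searchsorted(hits, dropped)
            state.seq[dropped] = old[pos_in_hits]
        hits = survivors
    n_sub = len(hits)

    # background indels: single-copy noncoding sites only
    elig_mask = (~state.exon) & ((state.region == 0) | (state.region == 2))
    n_elig = int(elig_mask.sum())
    lam = cfg.indel_rate * t * n_elig
    n_events = rng.poisson(lam)
    for _ in range(n_events):
        elig_idx = np.nonzero(elig_mask)[0]
        if len(elig_idx) == 0:
            break
        pos = int(elig_idx[rng.integers(0, len(elig_idx))])
        length = int(rng.geometric(1.0 / cfg.indel_mean_len))
        if rng.random() < 0.5:  # deletion
            end = pos
            while end < len(state) and end - pos < length and elig_mask[end]:
                end += 1
            if end == pos:
                continue
            sel = np.arange(pos, end)
            for name in ("seq", "region", "label", "exon", "feat", "cds", "cds_pos", "rate"):
                setattr(state, name, np.delete(getattr(state, name), sel))
            del state.keys[pos:end]
            elig_mask = np.delete(elig_mask, sel)
        else:  # insertion after pos
            counter[0] += 1
            newkeys = [state.keys[pos] + (counter[0], j) for j in range(length)]
            gc = cfg.plan.gc_noncoding
            ins_seq = rng.choice(4, size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]).astype(np.uint8)
            at = pos + 1
            state.seq = np.insert(state.seq, at, ins_seq)
            state.region = np.insert(state.region, at, np.full(length, state.region[pos]))
            state.label = np.insert(state.label, at, np.full(length, state.label[pos]))
            state.exon = np.insert(state.exon, at, np.zeros(length, bool))
            state.feat = np.insert(state.feat, at, np.full(length, state.feat[pos]))
            state.cds = np.insert(state.cds, at, np.full(length, -1))
            state.cds_pos = np.insert(state.cds_pos, at, np.full(length, -1))
            state.rate = np.insert(state.rate, at, np.full(length, state.rate[pos]))
            state.keys[at:at] = newkeys
            elig_mask = np.insert(elig_mask, at, np.ones(length, bool))

    _mirror_ir(state)
    _fix_ir_flanks(state, rng)
    return state, n_sub


def _apply_disruption(state: _State, disr: Disruption, meta: list[_FeatMeta], rng, counter: list) -> None:
    cand = [m for m in meta if m.name == disr.gene and m.kind == "CDS" and m.region in ("LSC", "SSC")]
    if not cand:
        raise ValueError(f"disruption target {disr.gene!r} is not a single-copy CDS in the plan")
    g = cand[0].fid
    sites = np.nonzero(state.cds == g)[0]
    order = np.argsort(state.cds_pos[sites], kind="stable")
    sites = sites[order]  # coding-order genomic indices
    minus = cand[0].strand == "-"
    n_codons = len(sites) // 3
    if disr.kind == "nonsense":
        ci = disr.codon_index if disr.codon_index is not None else n_codons // 2
        if not 0 < ci < n_codons - 1:
            raise ValueError("nonsense codon index must be internal")
        target = (3, 0, 0)  # TAA
        for k in range(3):
            base = target[k]
            state.seq[sites[3 * ci + k]] = 3 - base if minus else base
    elif disr.kind == "frameshift":
        if disr.length % 3 == 0:
            raise ValueError("frameshift length must not be a multiple of 3")
        mid = sites[(n_codons // 2) * 3]
        if disr.length > 0:
            length = disr.length
            counter[0] += 1
            newkeys = [state.keys[int(mid)] + (counter[0], j) for j in range(length)]
            at = int(mid) + 1
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            state.seq = np.insert(state.seq, at, ins)
            for name, fillval in (
                ("region", state.region[mid]), ("label", state.label[mid]), ("exon", True),
                ("feat", state.feat[mid]), ("cds", -1), ("cds_pos", -1), ("rate", state.rate[mid]),
            ):
                setattr(state, name, np.insert(getattr(state, name), at, np.full(length, fillval)))
            state.keys[at:at] = newkeys
        else:
            length = -disr.length
            at = int(mid)
            sel = np.arange(at, at + length)
            for name in ("seq", "region", "label", "exon", "feat", "cds", "cds_pos", "rate"):
                setattr(state, name, np.delete(getattr(state, name), sel))
            del state.keys[at : at + length]
    else:
        raise ValueError(f"unknown disruption kind {disr.kind!r}")


def _leaf_record(taxon: str, state: _State, meta: list[_FeatMeta]) -> PlastomeRecord:
    seq = _BASES[state.seq].tobytes().decode()
    features = []
    for m in meta:
        pos = np.nonzero(state.feat == m.fid)[0]
        if len(pos) == 0:
            continue
        ex = state.exon[pos]
        parts = []
        runs = np.nonzero(np.diff(np.concatenate([[0], ex.astype(int), [0]])))[0].reshape(-1, 2)
        for s, e in runs:
            parts.append(SequenceInterval(int(pos[s]), int(pos[e - 1]) + 1, m.strand))
        features.append(FeatureAnnotation(name=m.name, kind=m.kind, parts=parts, strand=m.strand))
    rec = PlastomeRecord(id=taxon, sequence=seq, circular=True, features=features)
    rec.validate()
    return rec


def build_ancestor(config: SimConfig) -> PlastomeRecord:
    """Build just the ancestral genome of a configuration (no evolution)."""
    rng = np.random.default_rng(config.seed)
    builder = _Builder(config, rng)
    state = builder.build_ancestor()
    return _leaf_record("ancestor", state, builder.meta)


def evolve(config: SimConfig) -> tuple[dict, TruthBundle]:
    """Evolve the planned ancestor along the configured tree.

    Returns (records by taxon, TruthBundle). Fully deterministic for a
    given config + seed.
    """
    rng = np.random.default_rng(config.seed)
    builder = _Builder(config, rng)
    anc = builder.build_ancestor()
    tree = dendropy.Tree.get(data=config.tree, schema="newick", preserve_underscores=True)
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("tree must have >= 3 leaves")
    counter = [0]
    leaf_states: dict[str, _State] = {}
    branch_subs: dict[str, int] = {}

    node_counter = [0]

    def label_of(node):
        if node.taxon is not None:
            return node.taxon.label
        node_counter[0] += 1
        return f"node{node_counter[0]}"

    def walk(node, state: _State):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_state, nsub = _evolve_branch(state, t, config, rng, counter)
            branch_subs[label_of(child)] = nsub
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    walk(tree.seed_node, anc)

    for disr in config.disruptions:
        if disr.taxon not in leaf_states:
            raise ValueError(f"disruption taxon {disr.taxon!r} not a tree leaf")
        _apply_disruption(leaf_states[disr.taxon], disr, builder.meta, rng, counter)

    # assemble the true alignment from the union of per-leaf site keys
    taxa = [lf.taxon.label for lf in leaves]
    all_keys = sorted(set().union(*(set(s.keys) for s in leaf_states.values())))
    col_of = {k: i for i, k in enumerate(all_keys)}
    L = len(all_keys)
    data = np.full((len(taxa), L), b"-", dtype="S1")
    col_label = np.empty(L, dtype=object)
    col_region = np.empty(L, dtype=object)
    for ti, taxon in enumerate(taxa):
        st = leaf_states[taxon]
        cols = np.fromiter((col_of[k] for k in st.keys), dtype=np.int64, count=len(st.keys))
        data[ti, cols] = _BASES[st.seq]
        col_label[cols] = [builder.labels[i] for i in st.label]
        col_region[cols] = [REGION_NAMES[i] for i in st.region]
    aln = AlignmentMatrix(taxa, data, column_labels=col_label, region_labels=col_region)

    hot_cols = []
    hot_ids = {builder.label_idx[lab] for lab in config.hotspot_labels if lab in builder.label_idx}
    if hot_ids:
        is_hot = np.array([lab is not None and lab in {builder.labels[i] for i in hot_ids} for lab in col_label])
        runs = np.nonzero(np.diff(np.concatenate([[0], is_hot.astype(int), [0]])))[0].reshape(-1, 2)
        hot_cols = [(int(s), int(e)) for s, e in runs]

    records = {t: _leaf_record(t, leaf_states[t], builder.meta) for t in taxa}
    ir_intervals = {}
    for t in taxa:
        st = leaf_states[t]
        b = np.nonzero(st.region == 1)[0]
        a = np.nonzero(st.region == 3)[0]
        ir_intervals[t] = (
            SequenceInterval(int(b[0]), int(b[-1]) + 1),
            SequenceInterval(int(a[0]), int(a[-1]) + 1),
        )
    truth = TruthBundle(
        tree=config.tree,
        alignment=aln,
        ir_intervals=ir_intervals,
        hotspot_columns=hot_cols,
        hotspot_labels=dict(config.hotspot_labels),
        disruptions=tuple(config.disruptions),
        branch_substitutions=branch_subs,
        records=records,
        plan=config.plan,
    )
    return records, truth
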