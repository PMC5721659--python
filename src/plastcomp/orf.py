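"""Premature-stop-codon scanning, indel/frameshift characterization, and
Nei-Gojobori (1986) dN/dS with a permutation clade contrast.

The NG86 counting method substitutes for likelihood branch models when the
question is whether stop-containing lineages evolve at an elevated
nonsynonymous rate: site and difference counts use the plastid/bacterial
genetic code (translation table 11), multi-hit codons average over all
minimal substitution paths with equal weights (paths through stop codons
excluded when any stop-free path exists), and proportions receive the
Jukes-Cantor correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from math import log

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .alignment import AlignmentMatrix

_T11 = unambiguous_dna_by_id[11]
STOPS = frozenset(_T11.stop_codons)  # TAA, TAG, TGA
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in STOPS:
        return "*"
    return _T11.forward_table.get(codon, "X")


@dataclass(frozen=True)
class OrfReport:
    sample: str
    gene: str
    cds_length: int
    internal_stops: tuple[int, ...]
    frameshift_events: tuple[tuple[int, int, int], ...]  # (position, indel length, phase)
    terminal_stop_present: bool

    @property
    def translatable(self) -> bool:
        return not self.internal_stops and self.cds_length % 3 == 0


@dataclass(frozen=True)
class DnDsEstimate:
    N: float
    S: float
    Nd: float
    Sd: float
    dN: float
    dS: float

    @property
    def omega(self) -> float | None:
        """dN/dS; None (undefined, not infinite) when dS = 0."""
        if self.dS == 0.0:
            return None
        if self.dS == float("inf") and self.dN == float("inf"):
            return None  # both classes saturated; ratio uninformative
        return self.dN / self.dS


def scan_orf(cds_sequence: str, sample: str = "", gene: str = "") -> OrfReport:
    """Scan an annotated-frame CDS for internal stop codons.

    Internal stop = TAA/TAG/TGA at any codon before the final one; a
    trailing partial codon (length not divisible by 3) is never a stop.
    """
    seq = cds_sequence.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    allowed = set("ACGTNRYSWKMBDHV")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    n_codons = len(seq) // 3
    stops = []
    for i in range(n_codons):
        if seq[3 * i : 3 * i + 3] in STOPS:
            stops.append(i)
    terminal = False
    if len(seq) % 3 == 0 and stops and stops[-1] == n_codons - 1:
        terminal = True
        stops = stops[:-1]
    return OrfReport(
        sample=sample,
        gene=gene,
        cds_length=len(seq),
        internal_stops=tuple(stops),
        frameshift_events=(),
        terminal_stop_present=terminal,
    )


@dataclass(frozen=True)
class DisruptionReport:
    taxon: str
    indels: tuple[tuple[int, int, int], ...]  # (alignment column, signed length, phase)
    frameshifts: tuple[tuple[int, int, int], ...]  # the subset with phase != 0
    point_nonsense: tuple[tuple[int, str, str], ...]  # (codon index, ref codon, taxon codon)
    has_internal_stop: bool


def characterize_disruption(gene_alignment: AlignmentMatrix, reference_taxon: str) -> list[DisruptionReport]:
    """Per-taxon description of indels and nonsense changes relative to an
    intact reference.

    Insertions relative to the reference have positive length, deletions
    negative; phase = length mod 3, nonzero phase marks a frameshift.
    Point nonsense changes are reported for codons that align gap-free in
    both sequences (e.g. TGG -> TGA).
    """
    ref_row = gene_alignment.row(reference_taxon)
    ref_seq = ref_row[ref_row != b"-"].tobytes().decode()
    ref_scan = scan_orf(ref_seq)
    if ref_scan.internal_stops:
        raise ValueError(f"reference {reference_taxon} itself has internal stop codons")
    gaps = gene_alignment.gap_mask()
    ri = gene_alignment.taxa.index(reference_taxon)
    # reference codon index per alignment column (-1 where ref has a gap)
    ref_pos = np.cumsum(~gaps[ri]) - 1
    reports = []
    for ti, taxon in enumerate(gene_alignment.taxa):
        if taxon == reference_taxon:
            continue
        row = gene_alignment.data[ti]
        indels: list[tuple[int, int, int]] = []
        j = 0
        L = gene_alignment.n_columns
        while j < L:
            if gaps[ri, j] and not gaps[ti, j]:  # insertion in taxon
                k = j
                while k < L and gaps[ri, k] and not gaps[ti, k]:
                    k += 1
                indels.append((j, k - j, (k - j) % 3))
                j = k
            elif gaps[ti, j] and not gaps[ri, j]:  # deletion in taxon
                k = j
                while k < L and gaps[ti, k] and not gaps[ri, k]:
                    k += 1
                indels.append((j, -(k - j), (k - j) % 3))
                j = k
            else:
                j += 1
        nonsense = []
        n_codons = len(ref_seq) // 3
        cols_by_codon: dict[int, list[int]] = {}
        for j in range(L):
            if not gaps[ri, j]:
                cols_by_codon.setdefault(int(ref_pos[j]) // 3, []).append(j)
        for ci in range(n_codons):
            cols = cols_by_codon.get(ci, [])
            if len(cols) != 3:
                continue
            if any(gaps[ti, c] for c in cols):
                continue
            ref_codon = b"".join(ref_row[c] for c in cols).decode()
            tax_codon = b"".join(row[c] for c in cols).decode()
            if tax_codon in STOPS and ref_codon not in STOPS and ci < n_codons - 1:
                nonsense.append((ci, ref_codon, tax_codon))
        tax_seq = row[row != b"-"].tobytes().decode()
        has_stop = bool(scan_orf(tax_seq).internal_stops) if len(tax_seq) >= 3 else False
        reports.append(
            DisruptionReport(
                taxon=taxon,
                indels=tuple(indels),
                frameshifts=tuple(e for e in indels if e[2] != 0),
                point_nonsense=tuple(nonsense),
                has_internal_stop=has_stop,
            )
        )
    return reports


@lru_cache(maxsize=64)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon.

    Changes producing stop codons count as nonsynonymous, following the
    original counting scheme.
    """
    aa = translate_codon(codon)
    s = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if translate_codon(mut) == aa and mut not in STOPS:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=4096)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaging equal-weight minimal paths."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS and nxt != c2:
                through_stop = True
            if translate_codon(cur) == translate_codon(nxt) and nxt not in STOPS and cur not in STOPS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [(s, n) for t, s, n in paths if not t] or [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jc(p: float) -> float:
    """JC-corrected distance; saturation (p >= 3/4) maps to +inf."""
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return float("inf")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(cds_a: str, cds_b: str) -> DnDsEstimate:
    """Nei-Gojobori (1986) dN/dS for two aligned, stop-free CDSs."""
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    n_codons = len(a) // 3
    S = Sd = Nd = 0.0
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if i < n_codons - 1 and (ca in STOPS or cb in STOPS):
            raise ValueError(f"internal stop codon at codon {i}")
        sa, _ = _codon_sites(ca)
        sb, _ = _codon_sites(cb)
        S += 0.5 * (sa + sb)
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    return DnDsEstimate(N=N, S=S, Nd=Nd, Sd=Sd, dN=_jc(pN), dS=_jc(pS))


@dataclass
class OmegaContrast:
    group_omega: dict[str, float]
    per_taxon_omega: dict[str, float]
    statistic: float
    p_value: float


def clade_omega_contrast(
    sequences: dict[str, str],
    groups: dict[str, str],
    outgroup: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> OmegaContrast:
    """Group-wise NG86 omega (each taxon vs an outgroup reference) with a
    label-permutation test for a between-group difference.

    The statistic is the range (max - min) of group mean omegas; the
    p-value is the fraction of label permutations whose statistic is at
    least the observed one (add-one correction). With a single group the
    statistic is 0 and p = 1.
    """
    if outgroup not in sequences:
        raise ValueError(f"outgroup {outgroup!r} missing from sequences")
    taxa = [t for t in groups if t != outgroup]
    if not taxa:
        raise ValueError("no in-group taxa")
    ref = sequences[outgroup]
    omegas = {}
    for t in taxa:
        est = ng86_dnds(sequences[t], ref)
        if est.omega is None:
            continue  # dS = 0: this pair carries no rate-ratio information
        omegas[t] = est.omega
    labels = [groups[t] for t in omegas]
    values = np.array([omegas[t] for t in omegas])
    names = sorted(set(labels))
    for g in names:
        if labels.count(g) == 0:
            raise ValueError(f"group {g!r} has no valid pairs")

    def stat(lab) -> float:
        means = [values[[l == g for l in lab]].mean() for g in names]
        return max(means) - min(means)

    obs = stat(labels)
    group_means = {g: float(values[[l == g for l in labels]].mean()) for g in names}
    if len(names) < 2:
        return OmegaContrast(group_omega=group_means, per_taxon_omega=omegas, statistic=0.0, p_value=1.0)
    rng = np.random.default_rng(seed)
    hits = 0
    lab = list(labels)
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if stat(lab) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return OmegaContrast(group_omega=group_means, per_taxon_omega=omegas, statistic=obs, p_value=p)


NONSTOP_CODONS = sorted(set("".join(c) for c in __import__("itertools").product(_BASES, repeat=3)) - STOPS)


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    subs_per_site: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Simulate a CDS pair diverged under a simple codon model with a fixed
    nonsynonymous/synonymous acceptance ratio ``omega``.

    Mutations are proposed uniformly per nucleotide site at rate
    ``subs_per_site`` per lineage (two lineages diverge from a common
    ancestor); synonymous proposals are always accepted, nonsynonymous
    ones with probability ``omega`` and proposals creating stop codons are
    rejected, so the realized dN/dS equals ``omega`` in expectation.
    """
    anc = [NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), size=n_codons)]

    def evolve(codons: list[str]) -> list[str]:
        codons = list(codons)
        n_prop = rng.poisson(subs_per_site * 3 * n_codons)
        for _ in range(n_prop):
            site = int(rng.integers(0, 3 * n_codons))
            ci, off = divmod(site, 3)
            cur = codons[ci]
            alt = _BASES[int(rng.integers(0, 4))]
            if alt == cur[off]:
                continue
            mut = cur[:off] + alt + cur[off + 1 :]
            if mut in STOPS:
                continue
            if translate_codon(mut) != translate_codon(cur) and rng.random() >= omega:
                continue
            codons[ci] = mut
        return codons

    return "".join(evolve(anc)), "".join(evolve(anc))
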