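"""Genome plans for the synthetic plastome generator.

A plan fixes the quadripartite region lengths and an ordered feature table
(name, kind, strand, exon lengths, intron lengths) per region; spacer
lengths are derived deterministically so that each region hits its target
length. The default plan emulates a Cornales-like plastome: ~157 kb, 114
unique genes (79 CDS, 31 tRNA, 4 rRNA), 16 genes duplicated in the ~26 kb
IR, 17 one-intron and 2 two-intron genes, GC ~0.38. It is an emulation of
the gene complement, not a copy of any real record: lengths are typical
values and two of the one-intron genes (rps12, treated cis, and trnE-UUC)
are designated intron-bearing to match the census.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PlannedFeature:
    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str
    exons: tuple[int, ...]
    introns: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.introns) != max(len(self.exons) - 1, 0):
            raise ValueError(f"{self.name}: {len(self.exons)} exons need {len(self.exons)-1} introns")
        if self.kind == "CDS" and sum(self.exons) % 3:
            raise ValueError(f"{self.name}: CDS exon total {sum(self.exons)} not divisible by 3")

    @property
    def span(self) -> int:
        return sum(self.exons) + sum(self.introns)


@dataclass(frozen=True)
class GenomePlan:
    lsc_len: int
    ssc_len: int
    ir_len: int
    lsc: tuple[PlannedFeature, ...]
    irb: tuple[PlannedFeature, ...]  # IRa is the mirrored copy
    ssc: tuple[PlannedFeature, ...]
    gc_coding: float = 0.403
    gc_noncoding: float = 0.345

    @property
    def gc(self) -> float:
        """Approximate overall GC implied by the two compositional targets."""
        coding = sum(sum(f.exons) for f in self.features()) + sum(sum(f.exons) for f in self.irb)
        return (coding * self.gc_coding + (self.genome_len - coding) * self.gc_noncoding) / self.genome_len

    @property
    def genome_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def features(self):
        return list(self.lsc) + list(self.irb) + list(self.ssc)

    def region_spacers(self, region: str) -> list[int]:
        """Deterministic spacer lengths for a region: the slack left by the
        features is spread over the len(features)+1 inter-feature gaps,
        remainder going one bp at a time to the leftmost gaps."""
        feats = {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc}[region]
        target = {"LSC": self.lsc_len, "IRb": self.ir_len, "SSC": self.ssc_len}[region]
        slack = target - sum(f.span for f in feats)
        n_gaps = len(feats) + 1
        if slack < n_gaps:
            raise ValueError(f"{region}: features ({target - slack} bp) exceed region budget {target}")
        base, extra = divmod(slack, n_gaps)
        return [base + (1 if i < extra else 0) for i in range(n_gaps)]


def _cds(name, n, strand="+", exons=None, introns=()):
    return PlannedFeature(name, "CDS", strand, tuple(exons) if exons else (n,), tuple(introns))


def _trna(name, n=74, strand="+", exons=None, introns=()):
    return PlannedFeature(name, "tRNA", strand, tuple(exons) if exons else (n,), tuple(introns))


def _rrna(name, n, strand="+"):
    return PlannedFeature(name, "rRNA", strand, (n,))


_LSC = (
    _trna("trnH-GUG", 75, "-"),
    _cds("psbA", 1062, "-"),
    _trna("trnK-UUU", None, "-", exons=(35, 37), introns=(950,)),
    _cds("matK", 1530, "-"),
    _cds("rps16", None, "-", exons=(40, 221), introns=(850,)),
    _trna("trnQ-UUG", 72, "-"),
    _cds("psbK", 186),
    _cds("psbI", 111),
    _trna("trnS-GCU", 88, "-"),
    _trna("trnG-UCC", None, "+", exons=(23, 48), introns=(700,)),
    _trna("trnR-UCU", 72),
    _cds("atpA", 1524, "-"),
    _cds("atpF", None, "-", exons=(145, 410), introns=(700,)),
    _cds("atpH", 246, "-"),
    _cds("atpI", 744, "-"),
    _cds("rps2", 711, "-"),
    _cds("rpoC2", 4140, "-"),
    _cds("rpoC1", None, "-", exons=(432, 1611), introns=(750,)),
    _cds("rpoB", 3213, "-"),
    _trna("trnC-GCA", 71),
    _cds("petN", 90),
    _cds("psbM", 105, "-"),
    _trna("trnD-GUC", 74, "-"),
    _trna("trnY-GUA", 84, "-"),
    _trna("trnE-UUC", None, "-", exons=(24, 49), introns=(650,)),
    _trna("trnT-GGU", 72),
    _cds("psbD", 1062),
    _cds("psbC", 1386),
    _trna("trnS-UGA", 93, "-"),
    _cds("psbZ", 189),
    _trna("trnG-GCC", 71),
    _trna("trnfM-CAU", 73, "-"),
    _cds("rps14", 303, "-"),
    _cds("psaB", 2205, "-"),
    _cds("psaA", 2253, "-"),
    _cds("ycf3", None, "-", exons=(126, 228, 153), introns=(730, 740)),
    _trna("trnS-GGA", 87, "-"),
    _cds("rps4", 606, "-"),
    _trna("trnT-UGU", 73, "-"),
    _trna("trnL-UAA", None, "+", exons=(35, 50), introns=(500,)),
    _trna("trnF-GAA", 73),
    _cds("ndhJ", 477, "-"),
    _cds("ndhK", 678, "-"),
    _cds("ndhC", 363, "-"),
    _trna("trnV-UAC", None, "-", exons=(38, 34), introns=(600,)),
    _trna("trnM-CAU", 73),
    _cds("atpE", 402, "-"),
    _cds("atpB", 1497, "-"),
    _cds("rbcL", 1428),
    _cds("accD", 1467),
    _cds("psaI", 111),
    _cds("ycf4", 555),
    _cds("cemA", 690),
    _cds("petA", 963),
    _cds("psbJ", 123, "-"),
    _cds("psbL", 117, "-"),
    _cds("psbF", 120, "-"),
    _cds("psbE", 252, "-"),
    _cds("petL", 96),
    _cds("petG", 114),
    _trna("trnW-CCA", 74, "-"),
    _trna("trnP-UGG", 74, "-"),
    _trna("trnP-GGG", 74),
    _cds("psaJ", 135),
    _cds("rpl33", 201),
    _cds("rps18", 306),
    _cds("rpl20", 354, "-"),
    _cds("rps12", None, "-", exons=(114, 258), introns=(540,)),
    _cds("clpP", None, "-", exons=(69, 294, 228), introns=(800, 650)),
    _cds("psbB", 1527),
    _cds("psbT", 108),
    _cds("psbN", 132, "-"),
    _cds("psbH", 222),
    _cds("petB", None, "+", exons=(6, 642), introns=(750,)),
    _cds("petD", None, "+", exons=(8, 475), introns=(700,)),
    _cds("rpoA", 1014, "-"),
    _cds("rps11", 417, "-"),
    _cds("rpl36", 114, "-"),
    _cds("infA", 234, "-"),
    _cds("rps8", 405, "-"),
    _cds("rpl14", 369, "-"),
    _cds("rpl16", None, "-", exons=(9, 399), introns=(1000,)),
    _cds("rps3", 657, "-"),
    _cds("rpl22", 477, "-"),
    _cds("rps19", 279, "-"),
)

_IRB = (
    _cds("rpl2", None, "-", exons=(393, 429), introns=(660,)),
    _cds("rpl23", 282, "-"),
    _trna("trnI-CAU", 74, "-"),
    _cds("ycf2", 6837),
    _trna("trnL-CAA", 81, "-"),
    _cds("ndhB", None, "-", exons=(777, 756), introns=(680,)),
    _cds("rps7", 468, "-"),
    _trna("trnV-GAC", 72),
    _rrna("rrn16", 1491),
    _trna("trnI-GAU", None, "+", exons=(37, 35), introns=(940,)),
    _trna("trnA-UGC", None, "+", exons=(38, 35), introns=(800,)),
    _rrna("rrn23", 2810),
    _rrna("rrn4.5", 103),
    _rrna("rrn5", 121),
    _trna("trnR-ACG", 74),
    _trna("trnN-GUU", 72, "-"),
)

_SSC = (
    _cds("ndhF", 2241, "-"),
    _cds("rpl32", 174),
    _trna("trnL-UAG", 80),
    _cds("ccsA", 966),
    _cds("ndhD", 1503, "-"),
    _cds("psaC", 246, "-"),
    _cds("ndhE", 306, "-"),
    _cds("ndhG", 531, "-"),
    _cds("ndhI", 504, "-"),
    _cds("ndhA", None, "-", exons=(553, 539), introns=(1080,)),
    _cds("ndhH", 1182, "-"),
    _cds("rps15", 273, "-"),
    _cds("ycf1", 5577),
)


def cornales_like_plan() -> GenomePlan:
    """Full-scale default plan (~157 kb, 114 unique / 130 total genes)."""
    return GenomePlan(lsc_len=86_500, ssc_len=18_500, ir_len=26_000, lsc=_LSC, irb=_IRB, ssc=_SSC)


#: labels of the regions carrying elevated mutation rates by default,
#: emulating the nine reported hotspot regions (2 genes + 7 spacers; the
#: trnK-rps16 region maps to the matK-rps16 spacer here because the plan
#: places matK between trnK and rps16 rather than inside the trnK intron).
DEFAULT_HOTSPOT_LABELS = (
    "cds:matK",
    "cds:ndhF",
    "spacer:matK-rps16",
    "spacer:rpoB-trnC-GCA",
    "spacer:trnE-UUC-trnT-GGU",
    "spacer:petA-psbJ",
    "spacer:psbE-petL",
    "spacer:rpl32-trnL-UAG",
    "spacer:rps15-ycf1",
)


def toy_plan(lsc_len: int = 12_000, ssc_len: int = 4_000, ir_len: int = 3_200) -> GenomePlan:
    """Small quadripartite plan for replicate-heavy simulations and tests.

    Keeps the structural ingredients of the full plan (both strands, an
    intron gene, IR-duplicated genes of all three kinds) at ~1/9 scale.
    """
    lsc = (
        _cds("psbA", 1062, "-"),
        _trna("trnK-UUU", None, "-", exons=(35, 37), introns=(450,)),
        _cds("matK", 1530, "-"),
        _cds("rbcL", 1428),
        _cds("clpP", None, "-", exons=(69, 294, 228), introns=(400, 350)),
        _trna("trnW-CCA", 74, "-"),
        _cds("petA", 963),
        _cds("psbJ", 123, "-"),
        _cds("rpl22", 477, "-"),
        _cds("rps19", 279, "-"),
    )
    irb = (
        _cds("rpl2", None, "-", exons=(393, 429), introns=(360,)),
        _rrna("rrn5", 121),
        _trna("trnN-GUU", 72, "-"),
    )
    ssc = (
        _cds("ndhF", 966, "-"),
        _cds("rps15", 273, "-"),
        _cds("ycf1", 708),
    )
    return GenomePlan(lsc_len=lsc_len, ssc_len=ssc_len, ir_len=ir_len, lsc=lsc, irb=irb, ssc=ssc)


TOY_HOTSPOT_LABELS = ("cds:matK", "spacer:petA-psbJ", "spacer:rps15-ycf1")


#: 15-leaf tree emulating the recovered Cornales topology, branch lengths
#: in substitutions/site (noncoding scale).
CORNALES_TREE = (
    "((((((Cornus_capitata_1:0.0006,Cornus_capitata_2:0.0006):0.004,"
    "Cornus_controversa:0.005):0.006,(Alangium_alpinum:0.002,"
    "Alangium_chinense:0.002):0.008):0.003,Curtisia_dentata:0.010):0.004,"
    "((((Nyssa_wenshanensis:0.001,Nyssa_sinensis:0.001):0.004,"
    "Camptotheca_acuminata:0.006):0.003,Davidia_involucrata:0.007):0.002,"
    "(Mastixia_caudatilimba:0.005,Diplopanax_stachyanthus:0.005):0.004):0.002):0.003,"
    "((Hydrangea_heteromalla:0.004,Hydrangea_aspera:0.004):0.003,"
    "Deutzia_crassifolia:0.006):0.004);"
)
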