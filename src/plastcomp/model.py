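"""Core data model for annotated plastid genomes.

Coordinates are 0-based half-open everywhere inside the package; the
GenBank 1-based inclusive convention exists only at the I/O boundary
(:mod:`plastcomp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv-",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb-",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceInterval:
    """A span on a (possibly circular) sequence, 0-based half-open.

    ``wraps_origin`` marks spans that run off the end of the linearized
    sequence and continue from position 0; for those, ``end`` < ``start``
    and the length is ``seq_len - start + end``.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if not self.wraps_origin and self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def length(self, seq_len: int | None = None) -> int:
        if self.wraps_origin:
            if seq_len is None:
                raise ValueError("seq_len required for origin-wrapping interval")
            return seq_len - self.start + self.end
        return self.end - self.start

    def contains(self, pos: int, seq_len: int | None = None) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end


@dataclass
class FeatureAnnotation:
    """One annotated gene copy: exon parts in transcription-template order.

    ``parts`` are stored in ascending genomic order; minus-strand features
    are reverse-complemented on extraction. ``intron_count`` equals
    ``len(parts) - 1`` for features that do not wrap the origin.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    parts: list[SequenceInterval]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise ValueError("feature with no parts")

    @property
    def intron_count(self) -> int:
        return len(self.parts) - 1

    @property
    def start(self) -> int:
        return min(p.start for p in self.parts)

    @property
    def end(self) -> int:
        return max(p.end for p in self.parts)

    def span(self) -> SequenceInterval:
        """Whole gene span (first exon start to last exon end), introns included."""
        return SequenceInterval(self.start, self.end, self.strand)


@dataclass
class PlastomeRecord:
    """A linearized, annotated, (usually) circular plastid genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for p in f.parts:
                if p.wraps_origin:
                    if not self.circular:
                        raise ValueError(f"{f.name}: wrapping part on linear record")
                elif p.end > n:
                    raise ValueError(f"{f.name}: part [{p.start},{p.end}) outside [0,{n})")

    def features_of_kind(self, kind: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.kind == kind]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlastomeRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence.upper() == other.sequence.upper()
            and self.circular == other.circular
            and _feature_key_list(self.features) == _feature_key_list(other.features)
        )


def _feature_key_list(features):
    return sorted(
        (f.name, f.kind, f.strand, tuple((p.start, p.end, p.wraps_origin) for p in f.parts))
        for f in features
    )
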