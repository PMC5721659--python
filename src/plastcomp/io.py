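"""GenBank / FASTA reading and writing for the plastome data model.

Biopython does the flat-file parsing; this module only converts between
``SeqRecord``/``SeqFeature`` and :class:`~plastcomp.model.PlastomeRecord`,
keeping all coordinates 0-based half-open internally.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import FeatureAnnotation, PlastomeRecord, SequenceInterval, reverse_complement

_KINDS = ("CDS", "tRNA", "rRNA")


class GenBankParseError(ValueError):
    pass


def _interval_from_location(loc) -> list[SequenceInterval]:
    strand = "-" if loc.strand == -1 else "+"
    parts = []
    for p in sorted(loc.parts, key=lambda q: int(q.start)):
        parts.append(SequenceInterval(int(p.start), int(p.end), strand))
    return parts


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read a GenBank flat file into a :class:`PlastomeRecord`.

    Gene copies are taken from CDS/tRNA/rRNA features carrying a ``/gene``
    qualifier (bare ``gene`` features are containers and are skipped, so a
    gene + CDS pair yields one annotation). Raises
    :class:`GenBankParseError` on malformed records.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with line info
        raise GenBankParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise GenBankParseError(f"{path}: record has no sequence")
    circular = rec.annotations.get("topology", "circular") == "circular"
    features: list[FeatureAnnotation] = []
    for f in rec.features:
        if f.type not in _KINDS:
            continue
        name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if f.location.strand == -1 else "+"
        parts = _interval_from_location(f.location)
        features.append(FeatureAnnotation(name=name, kind=f.type, parts=parts, strand=strand))
    out = PlastomeRecord(id=rec.id or rec.name, sequence=seq, circular=circular, features=features)
    out.validate()
    return out


def _location_from_feature(f: FeatureAnnotation):
    locs = [SimpleLocation(p.start, p.end, strand=-1 if f.strand == "-" else 1) for p in f.parts]
    if len(locs) == 1:
        return locs[0]
    if f.strand == "-":
        locs = locs[::-1]  # GenBank lists minus-strand exons 5'->3'
    return CompoundLocation(locs)


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    record.validate()
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for f in record.features:
        loc = _location_from_feature(f)
        rec.features.append(SeqFeature(loc, type="gene", qualifiers={"gene": [f.name]}))
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]}))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read (multi-)FASTA into an ordered ``{id: sequence}`` dict."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_feature_sequence(record: PlastomeRecord, feature: FeatureAnnotation) -> str:
    """Concatenated exon sequence, reverse-complemented for minus strand."""
    n = len(record.sequence)
    chunks = []
    for p in feature.parts:
        if p.wraps_origin:
            chunks.append(record.sequence[p.start :] + record.sequence[: p.end])
        else:
            if p.end > n:
                raise ValueError(f"{feature.name}: interval [{p.start},{p.end}) out of range")
            chunks.append(record.sequence[p.start : p.end])
    seq = "".join(chunks)
    return reverse_complement(seq) if feature.strand == "-" else seq


def gc_content(sequence: str) -> float:
    """GC percent over unambiguous bases; N/IUPAC codes excluded entirely."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; GC content undefined")
    return 100.0 * gc / (gc + at)
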