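"""Taxa x columns character matrix with per-column provenance.

The matrix is stored as a 2-D numpy byte array (dtype ``S1``, upper-case);
``column_labels`` carries the feature/spacer label of each column (e.g.
``cds:rbcL``, ``intron:atpF.1``, ``spacer:psbA-trnK``) and
``region_labels`` the quadripartite region (``LSC``/``IRb``/``SSC``/``IRa``),
both optional.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

GAP = b"-"
UNAMBIG = (b"A", b"C", b"G", b"T")


class AlignmentMatrix:
    def __init__(
        self,
        taxa: list[str],
        data: np.ndarray,
        column_labels: np.ndarray | None = None,
        region_labels: np.ndarray | None = None,
        reference_map: np.ndarray | None = None,
    ):
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon ids")
        data = np.asarray(data, dtype="S1")
        if data.ndim != 2 or data.shape[0] != len(taxa):
            raise ValueError("data must be (n_taxa, n_columns)")
        self.taxa = list(taxa)
        self.data = np.char.upper(data)
        for name, arr in (("column_labels", column_labels), ("region_labels", region_labels), ("reference_map", reference_map)):
            if arr is not None and len(arr) != data.shape[1]:
                raise ValueError(f"{name} length != number of columns")
        self.column_labels = None if column_labels is None else np.asarray(column_labels, dtype=object)
        self.region_labels = None if region_labels is None else np.asarray(region_labels, dtype=object)
        self.reference_map = reference_map

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def sequence(self, taxon: str, degap: bool = False) -> str:
        row = self.row(taxon)
        s = row.tobytes().decode()
        return s.replace("-", "") if degap else s

    def take_columns(self, idx: np.ndarray) -> "AlignmentMatrix":
        idx = np.asarray(idx)
        return AlignmentMatrix(
            self.taxa,
            self.data[:, idx],
            None if self.column_labels is None else self.column_labels[idx],
            None if self.region_labels is None else self.region_labels[idx],
            None if self.reference_map is None else np.asarray(self.reference_map)[idx],
        )

    def gap_mask(self) -> np.ndarray:
        return self.data == GAP

    def state_counts(self) -> np.ndarray:
        """(4, n_columns) counts of A/C/G/T per column; gaps/ambiguity excluded."""
        return np.stack([(self.data == b).sum(axis=0) for b in UNAMBIG])

    @classmethod
    def from_dict(cls, seqs: dict[str, str], **kw) -> "AlignmentMatrix":
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            raise ValueError("rows differ in length")
        data = np.array([list(s.upper()) for s in seqs.values()], dtype="S1")
        return cls(list(seqs.keys()), data, **kw)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        from .io import read_fasta

        return cls.from_dict(read_fasta(path))

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        from .io import write_fasta

        write_fasta({t: self.sequence(t) for t in self.taxa}, path, width=width)
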