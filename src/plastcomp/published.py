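"""Published genome-feature table for the 15 Cornales plastomes + outgroup.

These are the per-accession summary values as printed in the source study's
genome-feature table (full length, GC%, region lengths, gene counts, coding
and noncoding lengths/GC, mean read coverage). They serve as reference
inputs for the dispersion and coding-percentage recomputations; note the
Camptotheca acuminata row is internally inconsistent as printed (coding +
noncoding = 157,850 while the full length column reads 157,811) and is kept
verbatim.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "taxon", "family", "accession", "full_len", "full_gc",
    "lsc_len", "ssc_len", "ir_len", "genes", "protein_coding", "rnas",
    "coding_len", "coding_gc", "noncoding_len", "noncoding_gc", "coverage",
]

_ROWS = [
    ("Nyssa wenshanensis",    "Nyssaceae",      "MG524995", 156598, 37.9, 86109, 18261, 26114, 114, 79, 35, 91073, 40.3, 65525, 34.6,  974),
    ("Nyssa sinensis",        "Nyssaceae",      "MG525000", 156567, 37.9, 86089, 18250, 26114, 114, 79, 35, 91073, 40.3, 65494, 34.6,  802),
    ("Camptotheca acuminata", "Nyssaceae",      "MG525005", 157811, 37.8, 87333, 18760, 25859, 114, 79, 35, 91078, 40.3, 66772, 34.4, 2757),
    ("Davidia involucrata",   "Davidiaceae",    "MG525002", 158131, 37.8, 87335, 18856, 25970, 114, 79, 35, 91037, 40.3, 67094, 34.4, 1026),
    ("Mastixia caudatilimba", "Mastixiaceae",   "MG525001", 158221, 37.8, 87418, 18797, 26003, 114, 79, 35, 90962, 40.3, 67259, 34.4, 1889),
    ("Diplopanax stachyanthus", "Mastixiaceae", "MG524991", 158715, 37.8, 87679, 18632, 26202, 114, 79, 35, 90944, 40.2, 67771, 34.6, 1758),
    ("Hydrangea heteromalla", "Hydrangeaceae",  "MG524994", 157889, 37.8, 86907, 18738, 26122, 114, 79, 35, 91138, 40.1, 66751, 34.7,  937),
    ("Hydrangea aspera",      "Hydrangeaceae",  "MG524992", 157637, 37.8, 86815, 18646, 26088, 114, 79, 35, 91189, 40.2, 66448, 34.5,  766),
    ("Deutzia crassifolia",   "Hydrangeaceae",  "MG524993", 157035, 37.6, 86583, 18714, 25869, 114, 79, 35, 91099, 40.1, 65936, 34.1,  549),
    ("Alangium alpinum",      "Alangiaceae",    "MG525003", 156673, 37.7, 86181, 18592, 25950, 114, 79, 35, 90842, 40.2, 65831, 34.2, 2121),
    ("Alangium chinense",     "Alangiaceae",    "MG524996", 156684, 37.7, 86185, 18603, 25948, 114, 79, 35, 90824, 40.2, 65860, 34.2,  383),
    ("Cornus capitata #1",    "Cornaceae",      "MG524990", 157200, 38.2, 86564, 18412, 26112, 114, 79, 35, 90928, 40.5, 66272, 35.0, 1068),
    ("Cornus capitata #2",    "Cornaceae",      "MG524998", 157200, 38.2, 86564, 18412, 26112, 114, 79, 35, 90928, 40.5, 66272, 35.0, 2523),
    ("Cornus controversa",    "Cornaceae",      "MG525004", 158668, 37.8, 87835, 18705, 26064, 114, 79, 35, 90823, 40.4, 67845, 34.3,  573),
    ("Curtisia dentata",      "Curtisiaceae",   "MG524999", 158548, 37.7, 87158, 18490, 26450, 114, 79, 35, 91018, 40.2, 67530, 34.3,  538),
    ("Fouquieria diguetii",   "Fouquieriaceae", "MG524997", 157895, 37.3, 87321, 18482, 26046, 114, 79, 35, 91244, 39.9, 66651, 33.7, 1195),
]

#: Nine mutational-hotspot regions reported for Cornales (2 genes, 7 spacers).
HOTSPOT_REGIONS = [
    "matK", "ndhF", "trnK-rps16", "rpoB-trnC", "trnT-trnE",
    "petA-psbJ", "psbE-petL", "rpl32-trnL", "rps15-ycf1",
]


def genome_feature_table(cornales_only: bool = True) -> pd.DataFrame:
    """The published per-plastome feature table.

    With ``cornales_only`` (default) the Ericales outgroup Fouquieria
    diguetii is excluded, as in the study's cross-genome summaries.
    """
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    if cornales_only:
        df = df[df.family != "Fouquieriaceae"].reset_index(drop=True)
    return df
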