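"""Shared configuration for the numbered analysis drivers.

One deterministic Cornales-scale simulation backs all stages: 15 taxa on
the recovered-topology tree, full-scale quadripartite plan, the nine
default elevated-rate regions, and rpl22 disruptions mirroring the study's
seven affected individuals (frameshift insertions of 19/19/5 bp in the
Cornus samples, 1 bp deletions in both Alangium samples, a 1 bp insertion
in Curtisia, and a point-nonsense change in Mastixia).
"""

from pathlib import Path

from plastcomp.sim import Disruption, SimConfig, evolve

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 2024

RPL22_DISRUPTIONS = (
    Disruption("Cornus_capitata_1", "rpl22", "frameshift", length=19),
    Disruption("Cornus_capitata_2", "rpl22", "frameshift", length=19),
    Disruption("Cornus_controversa", "rpl22", "frameshift", length=5),
    Disruption("Alangium_alpinum", "rpl22", "frameshift", length=-1),
    Disruption("Alangium_chinense", "rpl22", "frameshift", length=-1),
    Disruption("Curtisia_dentata", "rpl22", "frameshift", length=1),
    Disruption("Mastixia_caudatilimba", "rpl22", "nonsense"),
)


def default_config(seed: int = SEED) -> SimConfig:
    return SimConfig(disruptions=RPL22_DISRUPTIONS, seed=seed)


_cache = {}


def default_run(seed: int = SEED):
    """(records, truth) of the shared simulation, cached per process."""
    if seed not in _cache:
        _cache[seed] = evolve(default_config(seed))
    return _cache[seed]
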