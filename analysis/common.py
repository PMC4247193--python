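"""Shared setup for the numbered analysis scripts.

Each script can be run on its own: the synthetic dataset is regenerated
deterministically (seed 7) if `results/sim/` does not exist yet, so the
scripts don't depend on each other's outputs beyond this cache.
"""

from pathlib import Path

from drnatss import io
from drnatss.config import PipelineConfig
from drnatss.simulate import (SimulationParams, generate_genome, read_truth,
                              simulate_all_coverage, write_truth)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "sim"

PARAMS = SimulationParams(n_genes=200, seed=7)
CONFIG = PipelineConfig.default()


def simulate_and_write():
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_genome(PARAMS)
    tracks = simulate_all_coverage(annotation, truth, PARAMS)
    with open(SIM_DIR / "genome.fa", "w") as fh:
        for name, seq in annotation.sequences.items():
            fh.write(f">{name}\n{seq}\n")
    io.write_annotation(annotation, SIM_DIR / "annotation.gff")
    io.write_operons(annotation.operons, SIM_DIR / "operons.tsv")
    write_truth(truth, SIM_DIR / "truth.tsv")
    for (cond, treated), track in sorted(tracks.items()):
        tag = f"{cond}_{'TEX' if treated else 'noTEX'}"
        io.write_coverage(track, SIM_DIR / f"{tag}_fwd.wig",
                          SIM_DIR / f"{tag}_rev.wig")
    CONFIG.to_file(SIM_DIR / "pipeline.config")
    return annotation, truth, tracks


def load_dataset():
    """Read the simulated dataset back from disk (regenerating if absent),
    exercising the same file formats a real dataset would arrive in."""
    if not (SIM_DIR / "genome.fa").exists():
        return simulate_and_write()
    genome = io.read_genome(SIM_DIR / "genome.fa")
    genome.operons = io.read_operons(SIM_DIR / "operons.tsv")
    annotation = io.read_annotation(SIM_DIR / "annotation.gff", genome)
    truth = read_truth(SIM_DIR / "truth.tsv")
    tracks = {}
    for cond in truth.conditions:
        for treated in (True, False):
            tag = f"{cond}_{'TEX' if treated else 'noTEX'}"
            lib = cond if treated else f"{cond}_noTEX"
            tracks[(cond, treated)] = io.read_coverage(
                SIM_DIR / f"{tag}_fwd.wig", SIM_DIR / f"{tag}_rev.wig",
                annotation, lib, cond, treated)
    return annotation, truth, tracks
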