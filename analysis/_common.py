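"""Shared configuration for the numbered analysis scripts.

The analysis walks one read-level synthetic study through the whole
pipeline: 200 genes on 2 toy chromosomes, 3 histone marks, 2 patients vs
4 controls, 10 silenced + 10 active implanted genes at |log2 effect| = 2,
libraries of 20,000 reads per sample and mark. Heavy intermediates (BED
reads, count matrices, per-gene differential tables) live under scratch/;
the small summary tables each script reports go to results/.
"""

from pathlib import Path

from promdiff.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 42

CONFIG = SimulationConfig(
    n_genes=200,
    n_chroms=2,
    chrom_length=300_000,
    library_size=20_000,
    seed=SEED,
)

MARKS = list(CONFIG.marks)
SAMPLES = {s: CONFIG.group_of(s) for s in CONFIG.sample_ids()}


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
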