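"""Shared plumbing for the analysis drivers: where data and results live."""

from pathlib import Path

from barcodeval import read_marker_alignment, reference_config, simulate_dataset
from barcodeval import write_dataset

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

MARKERS = ["ITS", "ITS2", "rbcL", "matK", "psbA-trnH"]


def ensure_dataset():
    """Simulate the study dataset once; later drivers reuse the files."""
    if not (DATA_DIR / "metadata.tsv").exists():
        alignments, truth = simulate_dataset(reference_config(SEED))
        write_dataset(alignments, truth, DATA_DIR)
    return {
        name: read_marker_alignment(
            DATA_DIR / f"{name}.fasta", DATA_DIR / "metadata.tsv", name
        )
        for name in MARKERS
    }
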