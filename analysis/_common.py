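"""Shared plumbing for the numbered analysis scripts."""

from pathlib import Path
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results"
DATA_CSV = RESULTS / "data" / "met_simulated.csv"
SEED = 20180701
TRAIT = "FYLD"


def load_or_simulate():
    """The analysis dataset: one study-scale simulated uniform-yield-trial
    series (written by 01_simulate.py; regenerated deterministically if absent)."""
    from metgei import SimulationConfig, read_met_csv, simulate_met, write_met_csv

    if DATA_CSV.exists():
        return read_met_csv(DATA_CSV)
    DATA_CSV.parent.mkdir(parents=True, exist_ok=True)
    data, _ = simulate_met(SimulationConfig(seed=SEED))
    write_met_csv(data, DATA_CSV)
    return data


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
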