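"""Shared helper: generate the example dataset once and reuse it."""

from pathlib import Path

from chromage import SimulationConfig, write_fixture

DATA = Path(__file__).resolve().parent / "example_data"


def ensure_fixture(seed: int = 1) -> Path:
    """Write the synthetic dataset to examples/example_data once."""
    if not (DATA / "truth.json").exists():
        write_fixture(DATA, SimulationConfig(seed=seed), overwrite=True)
        print(f"generated synthetic dataset in {DATA}")
    return DATA
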