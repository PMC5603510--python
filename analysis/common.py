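"""Shared configuration for the numbered analysis drivers.

Every driver operates on the same run directory so that later stages pick
up the files written by earlier ones.  Run the scripts in order, or use
``kinotox run-all`` to execute the whole pipeline in one go.
"""

from pathlib import Path

from kinotox.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def screen_config(seed: int = 7) -> RunConfig:
    return RunConfig(seed=seed, out_dir=str(RESULTS / "screen"))
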