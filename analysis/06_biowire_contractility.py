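"""Stage 6: engineered-tissue contractility dose series.

Synthesizes paced force traces for replicate tissues over a dose series,
extracts active tension, beat duration and contraction/relaxation
slopes, and tests each metric across doses with one-way ANOVA followed
by protected Fisher LSD comparisons against the vehicle dose.
"""

import pandas as pd
from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    metrics = run_stage("biowire", cfg)
    print(f"tissues: {metrics['n_tissues']} over {metrics['n_doses']} doses")
    anova = pd.read_csv(f"{cfg.out_dir}/biowire_anova.csv")
    print(anova.to_string(index=False))


if __name__ == "__main__":
    main()
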