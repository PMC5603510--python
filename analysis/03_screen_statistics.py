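"""Stage 3: normalize endpoints against blanks and band the effects.

Computes per-well viability and live-cell counts, normalizes every
endpoint against the per-plate blank mean, and assigns each
compound x concentration cell a signed standard-deviation band (capped
at +/-3) for the heatmap view.
"""

import pandas as pd
from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    metrics = run_stage("screen", cfg)
    print(f"screen summary rows: {metrics['n_rows']}")
    heat = pd.read_csv(f"{cfg.out_dir}/heatmap.csv")
    band_cols = [c for c in heat.columns if c.endswith("uM")]
    strong = (heat[band_cols].abs() == 3).sum().sum()
    print(f"compound x concentration cells at the +/-3 SD band: {strong}")


if __name__ == "__main__":
    main()
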