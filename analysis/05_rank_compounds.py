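"""Stage 5: predict the design grid and rank the compounds.

Evaluates the selected network over the constrained design grid (13
log-spaced concentrations x 11 frequency levels x 11 viability levels
per compound; 125,840 rows for the full registry) and ranks compounds by
mean predicted normalized peak magnitude: the maximum is the least
detrimental compound, the minimum the most detrimental.
"""

import pandas as pd
from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    pm = run_stage("predict", cfg)
    print(f"grid predictions: {pm['n_rows']} rows ({pm['rows_per_compound']} per compound)")
    rm = run_stage("rank", cfg)
    print(f"least detrimental compound: #{rm['least_detrimental']}")
    print(f"most detrimental compound:  #{rm['most_detrimental']}")
    ranked = pd.read_csv(f"{cfg.out_dir}/ranking.csv")
    print(ranked.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
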