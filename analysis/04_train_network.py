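"""Stage 4: architecture search with Levenberg-Marquardt training.

Pivots the screen summary into one record per compound x concentration
(inputs: concentration, kinase target index, normalized frequency,
viability and live-cell count; output: normalized peak magnitude),
splits 90/10, trains every candidate architecture with multi-restart
Levenberg-Marquardt, and keeps the network with the best held-out R².
Also fits the three per-concentration control networks (live cells +
target -> viability).
"""

import pandas as pd
from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    metrics = run_stage("train", cfg)
    print(f"records: {metrics['n_records']}")
    print(f"selected architecture: {metrics['best_architecture']}")
    print(f"held-out R²: {metrics['test_r2']:.4f}  RMSE: {metrics['test_rmse']:.4f}")
    report = pd.read_csv(f"{cfg.out_dir}/search_report.csv")
    print("top candidates:")
    print(report.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
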