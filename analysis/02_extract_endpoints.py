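"""Stage 2: extract calcium endpoints from the raw traces.

Estimates the minimum-contraction noise floor from the non-beating
control wells, then detects transients in every well and records peak
count (beat frequency) and mean peak magnitude.
"""

from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    metrics = run_stage("traces", cfg)
    print(f"noise floor: {metrics['noise_floor']:.3f} fluorescence units")
    print(f"wells analyzed: {metrics['n_wells']}")


if __name__ == "__main__":
    main()
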