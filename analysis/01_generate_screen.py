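"""Stage 1: synthesize the kinase-inhibitor screen.

Builds the 80-compound / 23-target registry, lays out three 384-well
plates (0.1, 1, 10 uM in triplicate plus reference wells), and generates
calcium-flux traces and live/dead cell counts with a planted per-compound
effect model whose ground truth is written alongside the data.
"""

from common import screen_config

from kinotox.pipeline import run_stage


def main() -> None:
    cfg = screen_config()
    metrics = run_stage("generate", cfg)
    print(f"wrote screen fixture to {cfg.out_dir}")
    for k, v in sorted(metrics.items()):
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
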