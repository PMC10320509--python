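"""Shared argument parsing for the numbered analysis scripts.

Each script runs the deterministic pipeline up to its stage and writes that
stage's artifacts under results/ (stages are pure functions of config and
seed, so prefixes are recomputed rather than read from disk).
"""
import argparse
import logging
from pathlib import Path

from envdecode.pipeline import STAGES, load_config, run_experiment


def run_stage(last_stage: str, default_out: str, description: str,
              **kwargs) -> dict:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", type=Path, default=None,
                        help="YAML or JSON config file")
    parser.add_argument("--seed", type=int, default=0, help="master seed")
    parser.add_argument("--out", type=Path, default=Path(default_out),
                        help="output directory")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s: %(message)s")
    cfg = load_config(args.config) if args.config else None
    stages = STAGES[:STAGES.index(last_stage) + 1]
    report = run_experiment(config=cfg, seed=args.seed, outdir=args.out,
                            stages=stages, **kwargs)
    print(f"stages={list(stages)} seed={args.seed} "
          f"config_hash={report['config_hash']} -> {args.out}")
    return report
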