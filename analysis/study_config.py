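"""Shared run configuration for the numbered analysis scripts.

A desk-scale version of the study: 8 participants, 10 trials per emotion
condition, the generator's default injected effects (happy gamma burst and
left theta->low-gamma coupling, sad slow-power increase and contralateral
coupling, the shared RF alpha -> LP low-gamma path). Every script operates
on the same run directory so stages build on each other.
"""

import argparse
from pathlib import Path

from emopac.pipeline import RunConfig


def study_config(out_dir: str, seed: int) -> RunConfig:
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        simulate={"n_participants": 8, "n_trials_per_condition": 10},
        tf={"decim": 16},
        permutation={"n_permutations": 1000},
        pac={"n_surrogates": 200},
    )


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--out", default="results/study",
                        help="run directory shared by all analysis steps")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    Path(args.out).mkdir(parents=True, exist_ok=True)
    return args
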