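"""Fronto-parietal phase-amplitude coupling comodulograms.

Surrogate-normalised MVL over the fine (phase x amplitude) grid for the
four paths LF-LP / RF-RP / LF-RP / RF-LP and three conditions, as
activation-minus-reference contrast, with across-participant permutation
significance (k >= 12). Written to ``pac.h5``. The injected happy LF->LP
theta x low-gamma coupling and sad LF->RP theta x high-gamma coupling
should dominate their paths.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["pac"]
run_pipeline(config)
print(f"PAC comodulograms written to {args.out}/pac.h5")
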