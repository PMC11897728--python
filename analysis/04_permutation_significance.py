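"""Permutation/cluster significance of the activation-vs-reference TF
difference (1000 permutations, two-sided p < .001, clusters k >= 100).

Reads ``tf.h5``, writes per cluster/condition masks, z- and p-maps to
``permtest.h5``. Significant regions should coincide with the injected
band-power changes and be empty elsewhere.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["permtest"]
run_pipeline(config)
print(f"TF significance masks written to {args.out}/permtest.h5")
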