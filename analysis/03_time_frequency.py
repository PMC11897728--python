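"""Morlet time-frequency maps per electrode cluster and emotion condition.

Baseline-normalised (log change vs -3..0 s) maps for LF/RF/LP/RP x
neutral/happy/sad, at participant level and grand average; written to
``tf.h5``. The happy condition should show the injected 2-4 s gamma
enhancement, the sad condition the sustained left-frontal slow increase.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["tf"]
run_pipeline(config)
print(f"time-frequency maps written to {args.out}/tf.h5")
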