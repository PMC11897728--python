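"""Generate the synthetic study: EEG epochs and behavioral ratings.

Writes ``eeg_raw.h5`` (trials x channels x time per participant) and
``behavior.csv`` into the run directory. The injected effect structure is
the generator default: condition-specific gamma/slow-power changes and
fronto-parietal couplings, plus the originality/arousal/pleasure rating
means whose ordering the group statistics should recover.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["simulate"]
run_pipeline(config)
print(f"simulated study written to {args.out} (eeg_raw.h5, behavior.csv)")
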