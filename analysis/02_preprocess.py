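"""Offline preprocessing: average reference, downsample to 256 Hz,
notch (47-53 Hz) + band-pass (0.1-100 Hz) zero-phase filtering.

Reads ``eeg_raw.h5`` from the run directory, writes
``eeg_preprocessed.h5``.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["preprocess"]
run_pipeline(config)
print(f"preprocessed EEG written to {args.out}/eeg_preprocessed.h5")
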