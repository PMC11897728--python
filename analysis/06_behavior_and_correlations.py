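"""Group statistics: behavioral ANOVAs and PAC band-feature correlations.

Within-subject one-way ANOVAs (emotion condition) with Tukey post hocs
for arousal, pleasure and originality -> ``behavior_anova.csv``; Pearson
correlations among PAC band features within/across conditions per path,
with gender subgroups where group sizes permit -> ``correlations.csv``.
Expected pattern: originality happy > neutral and sad > neutral, happy
vs sad not separable.
"""

import logging

from emopac.pipeline import run_pipeline
from study_config import parse_args, study_config

logging.basicConfig(level=logging.INFO)

args = parse_args(__doc__)
config = study_config(args.out, args.seed)
config.stages = ["behavior", "correlate"]
run_pipeline(config)
print(f"group statistics written to {args.out}/behavior_anova.csv and correlations.csv")
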