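"""Render the summary report for the study run directory: behavioral
table, TF heatmap panels per cluster x condition, PAC comodulograms per
path x condition, and the starred correlation table."""

from emopac.pipeline import render_report
from study_config import parse_args

args = parse_args(__doc__)
path = render_report(args.out)
print(f"report written to {path}")
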