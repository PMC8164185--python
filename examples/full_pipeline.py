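"""Run the whole analysis end to end and render the report.

Simulate -> descriptives -> prevalence (direct + double-list) -> scales ->
disclosure gradient -> imputation-pooled risk models -> profile predictions,
written to scratch/report/ as JSON, text and CSV tables.
"""

from pathlib import Path

from violence_survey import default_config, render_report_text, run_pipeline

report = run_pipeline(
    default_config(n_respondents=3818, seed=2),
    m=10,
    full_model=True,
    risk_outcomes=["physical_conflict", "corporal_punishment"],
    outdir=Path("scratch/report"),
)
print(render_report_text(report))
print("files written to scratch/report/: report.json, report.txt, prevalence.csv, ...")
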