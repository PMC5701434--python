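"""Reproduce the full simulation grid and its summary diagnostics.

Runs all nine study conditions (latent rate 1 with threshold SD 1-4,
rates 2 and 3 with SD 1-2, and uniform(0,5) thresholds at rate 1), each
with 10,000 respondents, writing per-condition totals, histograms,
tail fits and plots under scratch/grid/ plus one summary row per
condition.  Read the summary down the rows: skewness falls and right-tail
R-squared rises as threshold noise (or the latent rate) grows, and the
uniform condition has its mode at 0 with a log-linear full range —
the conditions under which total scores inherit the latent trait's
exponential shape.
"""

from exptrait import study_grid, run_grid

summary = run_grid(study_grid(master_seed=0), "scratch/grid")
cols = ["condition", "lambda", "threshold_sd", "skewness",
        "tail_slope", "tail_r_squared", "modal_score"]
print(summary[cols].to_string(index=False))
print("\nArtifacts (CSVs, tail-fit JSON, plots) written under scratch/grid/")
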