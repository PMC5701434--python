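"""Calibrate question thresholds to symptom prevalence.

Loads the committed 57-question prevalence fixture and maps each rate to
its threshold-distribution mean under an exponential latent trait with
rate 1: the upper-tail quantile t with P(X > t) = prevalence.  The first
row is the one published survey value, 5.49%, whose percentile point is
2.90 — the worked example the calibration is anchored to.
"""

from exptrait import LatentModel, calibration_table, fixture_prevalence_table

prevalence = fixture_prevalence_table()
table = calibration_table(prevalence, LatentModel(rate=1.0))

print(table.head(5).to_string(index=False))
print("...")
row0 = table.iloc[0]
print(
    f"\n'{row0['item']}' question {row0['question']}: prevalence "
    f"{row0['prevalence']:.4f} -> threshold mean {row0['threshold_mean']:.2f}"
)
print(
    "A rarer symptom sits higher on the latent severity scale: only the "
    "most severe 5.49% of respondents exceed a mean threshold of 2.90."
)
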