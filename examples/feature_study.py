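"""Balanced posed-vs-spontaneous feature comparison on a small synthetic cohort.

Runs the complete chain (conditioning, ICA, envelope, features) on six
producers, balances the classes, and prints the Bonferroni-corrected
pooled-variance t-test for each of the six smile features.  The signs are
the substance: spontaneous smiles are longer, larger in onset magnitude,
more negative in offset magnitude, and faster in both directions, so the
posed − spontaneous differences come out negative for onset features and
positive for offset magnitude/speed.
"""

from emgsmile import PipelineConfig
from emgsmile.pipeline import run_cohort
from emgsmile.smile_discrimination import run_feature_study
from emgsmile.synthetic_data import GeneratorConfig

gen = GeneratorConfig.well_separated(seed=42, n_producers=6, events_per_block=8)
cfg = PipelineConfig(seed=42)
features = run_cohort(gen, cfg)
table = run_feature_study(features, cfg)

print(f"{len(features)} feature rows from {gen.n_producers} producers\n")
print(table[["feature", "mean_difference", "t", "df", "cohens_d", "p_bonferroni"]]
      .to_string(index=False, float_format=lambda x: f"{x:0.4f}"))
print("\nmean_difference is posed - spontaneous; a negative onset duration /")
print("magnitude and positive offset magnitude reproduce the published direction.")
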