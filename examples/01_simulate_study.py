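"""Generate a synthetic three-genotype study and inspect the ground truth.

The generator emulates the transgene dose design (NTg / TgL / TgH): negative
binomial counts with a 1/mean dispersion trend, planted transgene-only /
transgene-dose / dose-only effects, promoter ARE sites for the designated
reductomiRs, and seed-complementary sites in the UTRs of suppressed targets.
"""

from reductomir.synthetic_data import (
    SimulationConfig,
    simulate_counts,
    simulate_sequences,
    synthetic_are_pwm,
)

cfg = SimulationConfig(seed=7)
cm_mirna, cm_mrna, manifest = simulate_counts(cfg)
sequences = simulate_sequences(cfg, manifest, synthetic_are_pwm())

print(f"miRNA counts: {cm_mirna.counts.shape[0]} features x {cm_mirna.counts.shape[1]} samples")
print(f"mRNA  counts: {cm_mrna.counts.shape[0]} features x {cm_mrna.counts.shape[1]} samples")
print("\ntrue class composition (miRNA):")
print(manifest.mirnas()["true_class"].value_counts().to_string())
print(f"\nplanted ARE sites: {len(manifest.are_sites)} in "
      f"{manifest.are_sites['mirna_id'].nunique()} promoters")
print(f"planted seed sites: {len(manifest.seed_sites)} "
      f"({manifest.seed_sites['site_type'].value_counts().to_dict()})")
print(f"true effector reductomiRs: {len(manifest.true_effectors())}")
# Counts per class are the study conditions; the manifest is what downstream
# recovery is measured against.
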