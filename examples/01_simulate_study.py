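"""Simulate the full synthetic study: a stem/differentiated reference
compendium, a drug-treated tumor cohort, and pathway-like gene sets.

The cohort's latent stemness (uniform on [0,1]) drives drug response and
survival; four panel genes follow a planted regulatory chain.
"""

from hccstem import (
    SimulationConfig,
    generate_gene_sets,
    generate_reference_compendium,
    generate_tumor_cohort,
)

cfg = SimulationConfig(seed=1)
X_ref, labels, truth = generate_reference_compendium(cfg)
X_cohort, clinical, truth = generate_tumor_cohort(cfg, truth)
gene_sets = generate_gene_sets(cfg, truth)

print(f"reference compendium: {X_ref.shape[0]} genes x {X_ref.shape[1]} samples "
      f"({(labels == 'stem').sum()} stem, {(labels == 'differentiated').sum()} differentiated)")
print(f"planted stemness program: {len(truth.stemness_gene_ids)} genes "
      f"({int((truth.program_signs > 0).sum())} up, {int((truth.program_signs < 0).sum())} down in stem)")
print(f"tumor cohort: {X_cohort.shape[1]} samples; "
      f"{(clinical['response'] == 'non_responder').sum()} non-responders, "
      f"{(clinical['response'] == 'responder').sum()} responders")
print(f"panel chain: {' -> '.join(g for g, _ in truth.true_chain_edges)} -> {truth.true_chain_edges[-1][1]}")
print(f"gene sets: {len(gene_sets)} (including the planted PPAR-like pathway)")
# The response split mirrors a ~2/3 non-response rate; every downstream
# example reuses exactly these objects via the same seed.
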