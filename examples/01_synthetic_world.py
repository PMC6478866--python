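"""Generate a synthetic world and inspect its ground truth.

Builds a 60x60 equal-area landscape (5-km cells) with 27 autocorrelated
environmental layers, 12 species with known logistic niches, occurrence
records with injected QC defects, protected-area blobs and 5 future
climate realizations.
"""

import cwrplan as cp

config = cp.LandscapeConfig(grid=cp.GridSpec(60, 60, 5.0), seed=1, n_future_realizations=5)
world = cp.generate_world(config, n_species=12, n_occurrences=300)

print(f"layers: {len(world.env.layers)} "
      f"(climatic: {len(world.env.variables_in_set('climatic'))})")
print(f"protected fraction: {world.pa_mask.mean():.3f} (target 0.15)")
print(f"occurrence records: {len(world.occurrences)} "
      f"({(world.occurrences['qc_truth'] != 'clean').sum()} injected defects)")
print(world.truth[["species_id", "true_current_cells", "true_loss"]].to_string(index=False))

# true_loss is the fraction of each species' true current range that
# disappears under the mean future climate -- the number the modelling
# pipeline later has to recover without seeing the niches.
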