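"""Clean occurrences and fit one species' distribution model.

Shows the full modelling chain for a single species: QC, VIF screening,
cross-validated maximum-entropy fit, MAXTRSS binarization, future
ensemble and the climate-stable range.
"""

import cwrplan as cp
from cwrplan import occurrence_qc as qc
from cwrplan.pipeline import PipelineConfig, model_species

config = cp.LandscapeConfig(grid=cp.GridSpec(60, 60, 5.0), seed=1, n_future_realizations=5)
world = cp.generate_world(config, n_species=12, n_occurrences=300)

clean_df, report = qc.clean(world.occurrences, world.native_range, world.env.grid)
rep = report.iloc[0]
sid = rep["species_id"]
print(f"{sid}: {rep['raw']} raw -> {rep['final_unique']} unique records "
      f"({rep['duplicates_removed']} duplicates, {rep['removed_uncertain']} uncertain, "
      f"{rep['removed_out_of_range']} outside range) -> pathway {rep['pathway']}")

occ = clean_df.loc[clean_df["species_id"] == sid, ["x_km", "y_km"]].to_numpy()
res = model_species(sid, occ, world, PipelineConfig(seed=1), rep["pathway"])

true_loss = world.truth.set_index("species_id").loc[sid, "true_loss"]
print(f"fold AUCs: {[round(a, 3) for a in res.fold_aucs]}")
print(f"MAXTRSS threshold: {res.threshold:.3f}")
print(f"current range: {res.current.n_cells} cells; stable: {res.stable.n_cells} cells")
print(f"estimated range loss {res.loss:.3f} vs true loss {true_loss:.3f}")

# The estimated loss comes solely from occurrence points and the layers;
# closeness to the true loss is the pipeline's recovery diagnostic.
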