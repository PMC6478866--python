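"""Ecogeographic zonation and protected-area gap analysis.

Builds an ELC map (composite edaphic/geophysical/climatic clusters) for
one species, overlays it with the range and the protected-area mask, and
prints the species' conservation status plus the crop-type summary table.
"""

import cwrplan as cp
from cwrplan import gap_analysis as gap
from cwrplan import occurrence_qc as qc
from cwrplan.elc import build_elc, scenarios_in_range
from cwrplan.pipeline import PipelineConfig, model_species

config = cp.LandscapeConfig(grid=cp.GridSpec(60, 60, 5.0), seed=1, n_future_realizations=5)
world = cp.generate_world(config, n_species=12, n_occurrences=300)
clean_df, report = qc.clean(world.occurrences, world.native_range, world.env.grid)

records = []
for _, rep in report.iterrows():
    sid = rep["species_id"]
    occ = clean_df.loc[clean_df["species_id"] == sid, ["x_km", "y_km"]].to_numpy()
    res = model_species(sid, occ, world, PipelineConfig(seed=1), rep["pathway"])
    if res.current is None:
        continue
    by_set = {s: world.env.variables_in_set(s) for s in ("edaphic", "geophysical", "climatic")}
    elc = build_elc(world.env, by_set, k_per_set=3, native_range=world.native_range[sid],
                    seed=1, species_id=sid)
    records.append(
        gap.species_gap_record(
            sid, [], rep["final_unique"], res.pathway, res.current.mask, world.pa_mask,
            elc=elc, stable_mask=res.stable.mask if res.stable else None, range_loss=res.loss,
        )
    )
    if sid == report.iloc[0]["species_id"]:
        scen = scenarios_in_range(elc, res.current.mask)
        print(f"{sid}: {len(scen)} adaptive scenarios in current range; "
              f"{records[-1].pct_range_in_pa_current:.1f}% of range protected; "
              f"under-conserved: {records[-1].under_conserved}")

summary = gap.summarize_by_crop_type(records, world.crop_map)
print(summary.to_string(index=False))

# Each adaptive scenario is one composite environmental category -- the
# proxy unit of genetic diversity; a species with <50% of its scenarios
# in protected areas is flagged under-conserved.
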