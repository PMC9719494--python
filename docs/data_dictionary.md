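# Analysis-table data dictionary

One row per species-year maximum out-of-range record (output of
`poleward.predictors.assemble_design_table`, written as `design.csv` by
`poleward run`).

| column | units | description |
| --- | --- | --- |
| `species_id` | — | species identifier; grouping factor of the random intercept |
| `year` | — | calendar year of the maximum annual observation |
| `latitudinal_km` | km | meridional distance from the historical poleward limit (response 1) |
| `coastal_km` | km | along-coast least-cost distance from the limit point (response 2) |
| `climate_velocity` | km yr⁻¹ | buffer mean of climate velocity over the fixed long-term window |
| `kinetic_energy` | m² s⁻² | buffer mean of 0.5·(u²+v²) of currents averaged over the 10 years before `year` |
| `directional_agreement` | — (∈[−1,1]) | buffer mean of cos(current bearing − velocity bearing), same 10-year window |
| `mhw_displacement` | km | median thermal displacement over heatwave months at range-edge cells in the 10-year window (0 when none) |
| `mcs_cumulative_intensity` | °C·day | buffer mean of per-cell cold-spell cumulative intensity in the 10-year window |
| `trophic_category` | — | herbivore \| omnivore \| carnivore |
| `reproductive_mode` | — | planktonic \| non-planktonic \| live-bearing |
| `adult_mobility` | — | high \| low |
| `habitat` | — | inshore/sandy \| rocky \| reef \| oceanic |
| `water_column` | — | benthic \| demersal/benthic \| pelagic |
| `range_size` | ° latitude | latitudinal extent of the species' historical range |

Buffers are all ocean cells within 25 km of the least-cost path between
the limit point and the observation; range-edge cells are coastal-strip
cells within 25 km of the limit point. Undefined (land/flagged) cells are
excluded from every mean; rows with a fully-missing predictor are dropped
with a log entry.
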