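"""End-to-end orchestration of the synthetic-world analysis.

Wires the stages together: world generation -> climate velocity ->
climatology/extremes -> coast geometry -> cohort -> screening ->
predictor assembly -> GLMM fitting/selection.  Used by the CLI and by
the reproducibility tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import pandas as pd

from poleward.coastal_geometry import build_coast_geometry
from poleward.extremes import build_climatology
from poleward.glmm import GlmmFit, ModelSpec, backward_select, fit_pql, marginal_r2
from poleward.predictors import PredictorContext, assemble_design_table
from poleward.screening import filter_to_extensions, historical_limit
from poleward.synthetic_data import SynthConfig, World, make_cohort, make_world
from poleward.thermal_change import velocity_from_monthly


@dataclass
class PipelineResult:
    world: World
    geometry: object
    context: PredictorContext
    species: pd.DataFrame
    observations: pd.DataFrame
    records: list
    design: pd.DataFrame
    truth: dict
    fits: dict[str, GlmmFit]
    marginal_r2: dict[str, float]

    def design_hash(self) -> str:
        """Byte-level fingerprint of the analysis table (reproducibility)."""
        csv = self.design.to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(csv.encode()).hexdigest()


def run_pipeline(config: SynthConfig, select: bool = False, fit: bool = True) -> PipelineResult:
    """Run every stage on one seeded configuration.

    ``fit=False`` stops after predictor assembly (useful for small worlds
    whose cohorts cannot support the full fixed-effect structure).
    """
    world = make_world(config)
    velocity = velocity_from_monthly(world.sst_monthly, config.velocity_window)
    clim = build_climatology(world.sst_daily, config.baseline)
    geometry = build_coast_geometry(world.landmask)
    period = (config.obs_years[0] - 10, config.obs_years[1] - 1)
    context = PredictorContext(
        geometry,
        velocity,
        world.u_series,
        world.v_series,
        world.sst_monthly,
        world.sst_daily,
        clim,
        period,
    )
    species, occurrences, observations, truth = make_cohort(config, world, geometry, context)

    # re-derive limits from the fabricated occurrence tables (they must match)
    limits = {
        sp: historical_limit(occurrences[occurrences["species_id"] == sp], config.coast)
        for sp in species["species_id"]
    }
    screen_table = species.copy()
    screen_table["historical_limit_lat"] = [limits[sp] for sp in screen_table["species_id"]]

    records = filter_to_extensions(observations, screen_table, geometry)
    design = assemble_design_table(records, context, species)

    fits: dict[str, GlmmFit] = {}
    r2: dict[str, float] = {}
    if not fit:
        pass
    elif select:
        for response in ("coastal_km", "latitudinal_km"):
            spec = ModelSpec(response=response)
            final_spec, fit, _ = backward_select(spec, design)
            fits[response] = fit
            r2[response] = marginal_r2(fit)
    else:
        for response in ("coastal_km", "latitudinal_km"):
            fit = fit_pql(ModelSpec(response=response), design)
            fits[response] = fit
            r2[response] = marginal_r2(fit)

    return PipelineResult(
        world=world,
        geometry=geometry,
        context=context,
        species=species,
        observations=observations,
        records=records,
        design=design,
        truth=truth,
        fits=fits,
        marginal_r2=r2,
    )
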