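"""Shared fixtures: the default synthetic study system and fitted models.

Session-scoped so the expensive pieces (raster generation, model fits,
the full pipeline run) happen once and are reused across test modules.
"""

import numpy as np
import pytest

from maxhab.maxent import (
    MaxentParams,
    build_features,
    fit,
    sample_background,
)
from maxhab.raster_io import extract_at_points
from maxhab.synthetic import (
    GeneratorConfig,
    end_to_end_fixture,
    sample_presences,
    truth_bundle,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study system (seed 1): scenario stacks, truth
    bundle, presence and background value tables."""
    cfg = GeneratorConfig(seed=1)
    stacks, bundle = truth_bundle(cfg)
    current = stacks["current"]
    occ = sample_presences(bundle.suitability["current"], cfg.n_presences, cfg.seed + 1)
    coords = occ.coords()
    pres_table = extract_at_points(current, coords[:, 0], coords[:, 1])
    bg_table = sample_background(current, 10_000, seed=3)
    return {
        "cfg": cfg,
        "stacks": stacks,
        "bundle": bundle,
        "occ": occ,
        "pres_table": pres_table,
        "bg_table": bg_table,
    }


@pytest.fixture(scope="session")
def fitted_model(study):
    """Full-data model on all six candidate variables, default settings."""
    params = MaxentParams(seed=4)
    names = study["stacks"]["current"].names
    Fp, Fb, expansion = build_features(
        study["pres_table"][names], study["bg_table"], params
    )
    model = fit(Fp, Fb, expansion, params)
    return {"model": model, "Fp": Fp, "Fb": Fb, "params": params}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default fixture (seed 1)."""
    from maxhab.pipeline import load_config, run_full

    root = tmp_path_factory.mktemp("e2e")
    fx = end_to_end_fixture(GeneratorConfig(seed=1), root)
    out = run_full(load_config(fx["config"]))
    return {"fixture": fx, "config": fx["config"], "out": out, "root": root}


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
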