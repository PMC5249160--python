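"""Shared fixtures: scenario models and one fully processed random fixture."""

from __future__ import annotations

import logging

import pytest

from fluxcost.costs import compute_cost_table
from fluxcost.fixtures import (FixtureSpec, make_synthetic_rates,
                               random_fixture)
from fluxcost.media import enumerate_minimal_media
from fluxcost.workflow import prepare_catalog

logging.getLogger("fluxcost").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_bundle():
    """A modest random fixture processed end to end: model, media set,
    blocked reactions, gene catalog, cost table and synthetic rates.

    Smaller than the full study conditions (60 genes, 4 x 3 sources) so the
    many tests sharing it stay fast; the acceptance suite runs the full-size
    conditions itself.
    """
    spec = FixtureSpec(seed=7, n_genes=60, n_carbon_sources=4,
                       n_nitrogen_sources=3)
    fix = random_fixture(spec)
    ms = enumerate_minimal_media(fix.model, fix.reference,
                                 fix.carbon_exchange, fix.nitrogen_exchange)
    blocked, catalog = prepare_catalog(fix.model, ms.media)
    costs = compute_cost_table(fix.model, ms.media, blocked=blocked,
                               catalog=catalog)
    burden = costs.groupby("gene")["flc"].mean()
    rates = make_synthetic_rates(burden, seed=7)
    return {
        "spec": spec,
        "fixture": fix,
        "model": fix.model,
        "media_set": ms,
        "media": ms.media,
        "blocked": blocked,
        "catalog": catalog,
        "costs": costs,
        "rates": rates,
    }
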