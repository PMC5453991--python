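"""Shared fixtures: synthetic structures, maps, templates and detections.

Everything heavy (template construction, SSE detection) is session-scoped so
the expensive objects are built once and reused across test modules.
"""

import numpy as np
import pytest

from emtracer import fixtures, ss_engine, template_builder
from emtracer.cli import PipelineConfig, detect_sses


@pytest.fixture(scope="session")
def toy_model():
    return fixtures.toy_protein()


@pytest.fixture(scope="session")
def toy_map(toy_model):
    return fixtures.simulate_map(fixtures.SimulationSpec(model=toy_model))


@pytest.fixture(scope="session")
def training_model():
    return fixtures.training_protein()


@pytest.fixture(scope="session")
def training_map(training_model):
    return fixtures.simulate_map(fixtures.SimulationSpec(model=training_model))


@pytest.fixture(scope="session")
def template_source():
    model = fixtures.template_training_structure()
    gmap = fixtures.simulate_map(fixtures.SimulationSpec(model=model))
    return model, gmap


@pytest.fixture(scope="session")
def templates(template_source):
    model, gmap = template_source
    return {
        kind: template_builder.build_template(gmap, model, kind)
        for kind in ("helix", "strand")
    }


@pytest.fixture(scope="session")
def helix_template(templates):
    return templates["helix"]


@pytest.fixture(scope="session")
def toy_placements(toy_map, templates):
    """Cross-kind-filtered SSE placements detected in the toy map."""
    return detect_sses(toy_map, templates, PipelineConfig())


def sse_window_coms(model, kind):
    """Cα COMs of every sliding template-length window of each true SSE."""
    length = template_builder.SEGMENT_LENGTH[kind]
    coms = []
    for ch in model.chains:
        if ch.residues[0].ss != kind:
            continue
        ca = np.array([r.ca.pos for r in ch.residues])
        for i in range(len(ca) - length + 1):
            coms.append(ca[i : i + length].mean(axis=0))
    return np.array(coms)


@pytest.fixture(scope="session")
def isolated_helix_map():
    """A single ideal 6-residue helix in otherwise empty density."""
    model = fixtures.AtomModel(
        [fixtures._place(fixtures.make_ideal_helix(6), np.eye(3), np.zeros(3), chain="A")]
    )
    gmap = fixtures.simulate_map(fixtures.SimulationSpec(model=model, margin=9.0))
    return model, gmap
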