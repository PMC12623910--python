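import numpy as np
import pytest
from hypothesis import settings

import mesokit as mk
from mesokit.reduction import (
    coherence_length,
    default_r_grid,
    normalize_high_q,
    pdf_transform,
    to_structure_factor,
)
from mesokit.synthetic import diffraction_preset, generate_pattern

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def itz():
    return mk.itz_composition()


@pytest.fixture(scope="session")
def reduced_presets(itz):
    """Full reduction of the calibrated presets, shared across tests.

    name -> dict with the pattern, S(Q), G(r) and coherence estimate,
    produced by the same chain the pipeline runs (noise off).
    """
    out = {}
    for name in ("V-ITZ", "SE-ITZ-20"):
        sim = generate_pattern(diffraction_preset(name), comp=itz)
        pattern_eu, scale = normalize_high_q(sim.pattern, itz)
        sf = to_structure_factor(pattern_eu, itz, incoherent="subtract", qmax=20.0)
        pdf = pdf_transform(sf, r=default_r_grid(), window=True, qmax=20.0)
        out[name] = {
            "sim": sim,
            "scale": scale,
            "sf": sf,
            "pdf": pdf,
            "coherence": coherence_length(pdf),
        }
    return out
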