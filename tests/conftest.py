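import math

import numpy as np
import pytest

from pcarbor.morphology import MorphPoint, NeuronMorphology, Section
from pcarbor.synthetic import HUMAN, MOUSE, generate_morphology


def straight_points(start, end, diameter, n=2):
    """Points along a straight segment with constant diameter."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    return [
        MorphPoint(*(start + t * (end - start)), diameter)
        for t in np.linspace(0.0, 1.0, n)
    ]


def make_morphology(sections_spec, soma_diameter=20.0):
    """Build a morphology from (parent_id, stype, points) specs.

    Section ids are 1-based in spec order; the soma (id 0) is a single point
    at the origin.
    """
    sections = {0: Section(0, None, "soma", [MorphPoint(0, 0, 0, soma_diameter)])}
    for i, (parent, stype, points) in enumerate(sections_spec, start=1):
        sections[i] = Section(i, parent, stype, points)
    return NeuronMorphology(sections, 0)


def y_tree(stem_len=100.0, child_len=100.0, stem_diam=2.0, child_diam=0.8):
    """Soma -> stem -> two children; the hand-enumerated DCI toy tree."""
    tip = stem_len
    h = child_len / math.sqrt(2.0)
    return make_morphology(
        [
            (0, "dendrite", straight_points((0, 0, 0), (0, tip, 0), stem_diam)),
            (1, "dendrite",
             straight_points((0, tip, 0), (h, tip + h, 0), child_diam)),
            (1, "dendrite",
             straight_points((0, tip, 0), (-h, tip + h, 0), child_diam)),
        ]
    )


@pytest.fixture(scope="session")
def mouse_morph():
    return generate_morphology(MOUSE, 7)


@pytest.fixture(scope="session")
def human_morph():
    return generate_morphology(HUMAN, 42)


@pytest.fixture(scope="session")
def mouse_model(mouse_morph):
    from pcarbor.passive import PassiveParams, assign_passive, discretize

    return assign_passive(discretize(mouse_morph, 5.0), PassiveParams())
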