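import numpy as np
import pytest

import fibrogrid as fg


@pytest.fixture(scope="session")
def ref_spec():
    return fg.build_reference_network()


@pytest.fixture()
def toy_chain_spec():
    """A -> B -> C: one external input driving a two-step cascade."""
    return fg.NetworkSpec(
        species=[
            fg.Species("A", module="input"),
            fg.Species("B"),
            fg.Species("C"),
        ],
        edges=[
            fg.RegulatoryEdge("B", ("A",)),
            fg.RegulatoryEdge("C", ("B",)),
        ],
        inputs=["A"],
        name="chain",
    )


@pytest.fixture()
def diffusion_only_spec():
    """One inert species plus one feedback field with zero clearance: with
    the species held at zero the field evolves by pure diffusion."""
    return fg.NetworkSpec(
        species=[fg.Species("X")],
        edges=[],
        inputs=[],
        feedback_fields=[
            fg.FeedbackField(name="F", precursor="X", clearance=0.0),
        ],
        name="diffusion-only",
    )


def make_state(spec, N, intra=None, feedback=None, ecm=None):
    S = len(spec.species)
    K = len(spec.feedback_fields)
    M = len(spec.ecm_fields)
    return fg.GridState(
        intracellular=np.zeros((N, N, S)) if intra is None else intra,
        feedback=np.zeros((K, N, N)) if feedback is None else feedback,
        ecm=np.zeros((M, N, N)) if ecm is None else ecm,
        species_names=spec.species_names(),
        feedback_names=tuple(f.name for f in spec.feedback_fields),
        ecm_names=tuple(f.name for f in spec.ecm_fields),
    )
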