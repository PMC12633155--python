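"""Packaged reference cardiac-fibroblast network.

The curated network ships as ``data/reference_network.yaml``: 132 species and
200+ regulatory edges spanning ten inputs (TGFB, AngII, IL6, IL1, TNFa, NE,
PDGF, ET1, NP, E2), ten receptor classes, eight second messengers, fifteen
kinases/phosphatases, twelve MAPK components, eight transcription-factor
families, eighteen mechanotransduction components and twenty ECM outputs,
plus four secreted feedback precursors whose fields (TGFBfb, AngIIfb, IL6fb,
ET1fb) diffuse between cells.  Each edge in the file carries a one-line
mechanistic justification, so the topology is transparent and replaceable.
"""

from importlib import resources
from pathlib import Path

import yaml

from .network import NetworkSpec, network_from_dict

_DATA_PACKAGE = "fibrogrid.data"
_FILENAME = "reference_network.yaml"


def reference_network_path() -> Path:
    """Filesystem path of the packaged reference network file."""
    return Path(resources.files(_DATA_PACKAGE) / _FILENAME)


def build_reference_network() -> NetworkSpec:
    """Load and validate the packaged reference NetworkSpec."""
    with resources.files(_DATA_PACKAGE).joinpath(_FILENAME).open() as fh:
        doc = yaml.safe_load(fh)
    return network_from_dict(doc, name="reference")
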