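"""Access to the versioned protocol constants shipped with the package.

``protocol.yaml`` registers every analysis constant (prior registry, ROPE
and decision thresholds, subgroup cut-offs, elicited survey inputs) in one
diffable document; :func:`load_protocol` returns it as a dict, and the
test suite asserts it stays consistent with the constants the code
actually uses.
"""

from __future__ import annotations

from importlib import resources

import yaml


def load_protocol() -> dict:
    text = resources.files("peepbayes").joinpath("protocol.yaml").read_text()
    return yaml.safe_load(text)
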