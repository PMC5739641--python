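"""Packaged demo fixtures.

``demo_pathways.gmt`` and ``demo_targets.tsv`` are small illustrative
(synthetic) stand-ins for curated pathway and validated-target databases:
pathway names common in pancreatic-cancer signalling with a handful of
member genes each, and a miRNA → target map covering the same symbols.
They demonstrate the enrichment interface and make examples runnable
offline; they claim no database fidelity.
"""

from importlib import resources
from pathlib import Path


def demo_gmt_path() -> Path:
    return Path(resources.files(__package__) / "demo_pathways.gmt")


def demo_target_map_path() -> Path:
    return Path(resources.files(__package__) / "demo_targets.tsv")
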