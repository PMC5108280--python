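"""Accessors for the small packaged data fixtures.

``table1_ponto_caspian.csv`` transcribes the published list of Ponto-Caspian
species established in the North Sea, Baltic Sea, Great Lakes and St. Lawrence
River (54 species with per-subregion presence marks). ``table2.csv`` carries
the published donor/recipient inputs of the expected-versus-observed
comparison: average donor richness, region-pair invasion probability, and
observed NIS counts for the ten donor-recipient pairs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .checklist import Checklist, load_checklist

#: subregion ids of the two recipient systems in the Ponto-Caspian table
NORTH_BALTIC_SUBREGIONS = ("north_sea", "baltic_sea")
GREAT_LAKES_SUBREGIONS = ("great_lakes", "st_lawrence_river")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("invexpect").joinpath("data", name)))


def table1_path() -> Path:
    return _data_path("table1_ponto_caspian.csv")


def table2_path() -> Path:
    return _data_path("table2.csv")


def demo_checklist_path() -> Path:
    return _data_path("demo_north_baltic.csv")


def demo_pipeline_config_path() -> Path:
    return _data_path("demo_pipeline.yaml")


def load_table1() -> Checklist:
    """The Ponto-Caspian cross-system checklist (recipient_region None: spans both)."""
    return load_checklist(table1_path(), recipient_region=None)


def load_table2() -> pd.DataFrame:
    return pd.read_csv(table2_path())


def load_demo_checklist() -> Checklist:
    return load_checklist(demo_checklist_path(), recipient_region="north_baltic")
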