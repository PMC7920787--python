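"""Bundled reference data: the default 14-species catalog and the study's
reported per-stratum network-attribute summaries (used as the input for the
regime x habitat comparison and as a cross-check fixture)."""

from __future__ import annotations

from importlib import resources

from .event_store import SpeciesCatalog, read_catalog
from .network_metrics import NetworkSummary, read_summary_table

_DATA = resources.files("sbanet") / "data"


def load_default_catalog() -> SpeciesCatalog:
    """The packaged 14-species, 5-guild wintering-waterbird catalog."""
    with resources.as_file(_DATA / "default_catalog.csv") as path:
        return read_catalog(path)


def load_reference_summaries() -> list[NetworkSummary]:
    """The 10 published (regime, habitat) network-attribute rows."""
    with resources.as_file(_DATA / "reference_network_summaries.csv") as path:
        return read_summary_table(path)
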