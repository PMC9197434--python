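"""Bundled reference data: outlet sizes and flow fractions of a
full-complexity (48-outlet) hepatic arterial tree."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def reference_outlet_table() -> pd.DataFrame:
    """48-outlet reference table: outlet_id, diameter_mm, flow_fraction_pct."""
    with resources.files("hepatrunc.data").joinpath("reference_outlets.csv").open() as fh:
        return pd.read_csv(fh)
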