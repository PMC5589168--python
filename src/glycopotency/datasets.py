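"""Bundled fixture tables: the published batch list, the Asn52 class
distributions, and the site-specific Z/A metric table, transcribed to CSV so
metric computations can be exercised offline."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_batch_table",
    "load_asn52_classes",
    "load_site_metrics_table",
    "asn52_class_block",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("glycopotency.data").joinpath(name).open() as handle:
        return pd.read_csv(handle)


def load_batch_table() -> pd.DataFrame:
    """Batch list with nominal IU, protein mass (µg) and specific activity."""
    return _read("table1_batches.csv")


def load_asn52_classes() -> pd.DataFrame:
    """Long-format antennarity/fucosylation/sialylation class percentages at
    alpha-Asn52 for each analysed batch."""
    return _read("table2_asn52_classes.csv")


def load_site_metrics_table() -> pd.DataFrame:
    """Published per-site Z-number / A-index values plus the release-simulation
    averages for each analysed batch."""
    return _read("table3_site_metrics.csv")


def asn52_class_block(batch: str, block: str) -> dict[str, float]:
    """One class block (e.g. 'sialylation') for one batch as class → percent."""
    df = load_asn52_classes()
    sub = df[(df["batch"] == batch) & (df["block"] == block)]
    if sub.empty:
        raise KeyError(f"no {block!r} block for batch {batch!r}")
    return dict(zip(sub["class"], sub["percent"]))
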