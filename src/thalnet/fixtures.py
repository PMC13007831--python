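"""Packaged per-patient tables of the 12-patient thalamic RNS cohort."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2", "cohort_from_tables"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("thalnet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_table1() -> pd.DataFrame:
    """Clinical/demographic table (one row per patient)."""
    return _read("table1.csv")


def load_table2() -> pd.DataFrame:
    """Imaging-analysis table: streamline counts, stimulation settings,
    VTA volumes, seizure frequencies."""
    return _read("table2.csv")


def cohort_from_tables() -> pd.DataFrame:
    """Join of the two tables keyed by case, with the activation ratio
    (activated/total streamline counts) as ``proportion``."""
    t1 = load_table1()
    t2 = load_table2()
    merged = t1.merge(t2, on="case")
    merged["proportion"] = merged["n_streamlines_activated"] / merged["n_streamlines_total"]
    return merged
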