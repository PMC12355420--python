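"""Shared fixtures: tiny event frames and a synthetic FCS writer.

All fixture data are generated programmatically; nothing binary ships in the
repository.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from defac.cytometry import GateConfig
from defac.io import EventTable


def write_fcs(path, df: pd.DataFrame, datatype: str = "F", little: bool = True) -> None:
    """Serialize a DataFrame as a minimal list-mode FCS 3.1 file (test helper)."""
    names = list(df.columns)
    npar, tot = len(names), len(df)
    delim = "/"
    bits = {"F": "32", "D": "64"}[datatype]
    nbytes = {"F": 4, "D": 8}[datatype]
    kv = {
        "$DATATYPE": datatype,
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4" if little else "4,3,2,1",
        "$PAR": str(npar),
        "$TOT": str(tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, 1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = bits
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    text_start = 256
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + tot * npar * nbytes - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}{0:8d}{0:8d}".encode()
    )
    order = "<" if little else ">"
    dtype = f"{order}f{nbytes}"
    blob = (
        header
        + b" " * (text_start - len(header))
        + text.encode()
        + np.ascontiguousarray(df.to_numpy(), dtype=dtype).tobytes()
    )
    with open(path, "wb") as fh:
        fh.write(blob)


@pytest.fixture
def fcs_writer():
    return write_fcs


@pytest.fixture
def tiny_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gfp": [10.0, 500.0, 3000.0, 60000.0, 150.0],
            "lc3": [200.0, 400.0, 800.0, 1600.0, 300.0],
            "viability": [50.0, 60.0, 70.0, 80.0, 90.0],
        }
    )


@pytest.fixture
def gate() -> GateConfig:
    return GateConfig(
        viability_threshold=1000.0,
        gfp_boundaries=(200.0, 1000.0, 5000.0, 25000.0),
        min_events_per_level=1,
    )


def make_table(df: pd.DataFrame, **kw) -> EventTable:
    defaults = dict(sample_id="s", construct="WT", treatment="untreated", replicate=1)
    defaults.update(kw)
    return EventTable(events=df, **defaults)


@pytest.fixture
def table_factory():
    return make_table
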