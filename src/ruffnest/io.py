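"""Delimited-text IO for nest tables and fit outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import NestDistances, NestRecord

NEST_CSV_COLUMNS = ("nest_id", "year", "x", "y", "lay_day", "end_day", "fate",
                    "clutch_size", "protected_cause", "intervention_day",
                    "artificially_incubated", "female_id", "fate_seed")


def nests_to_frame(nests) -> pd.DataFrame:
    rows = []
    for n in nests:
        rows.append({c: getattr(n, c) for c in NEST_CSV_COLUMNS})
    return pd.DataFrame(rows, columns=list(NEST_CSV_COLUMNS))


def nests_to_csv(nests, path) -> None:
    nests_to_frame(nests).to_csv(path, index=False)


def nests_from_csv(path) -> list[NestRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(NestRecord(
            nest_id=str(r["nest_id"]), year=int(r["year"]),
            x=float(r["x"]), y=float(r["y"]),
            lay_day=int(r["lay_day"]), end_day=int(r["end_day"]),
            fate=str(r["fate"]), clutch_size=int(r["clutch_size"]),
            protected_cause=str(r.get("protected_cause", "none")),
            intervention_day=None if pd.isna(r.get("intervention_day"))
            else int(r["intervention_day"]),
            artificially_incubated=bool(r.get("artificially_incubated", False)),
            female_id=None if pd.isna(r.get("female_id")) else str(r["female_id"]),
            fate_seed=None if pd.isna(r.get("fate_seed")) else int(r["fate_seed"]),
            distances=NestDistances(),
        ))
    return out


def draws_to_frame(draws) -> pd.DataFrame:
    """Columnar draws table with chain and iteration indices."""
    m, n, d = draws.array.shape
    df = pd.DataFrame(draws.array.reshape(m * n, d), columns=list(draws.names))
    df.insert(0, "chain", np.repeat(np.arange(m), n))
    df.insert(1, "iteration", np.tile(np.arange(n), m))
    return df
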