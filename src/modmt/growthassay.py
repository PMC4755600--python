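"""Percent-of-control normalization of Cu-tolerance growth assays.

The complementation assay grows an MT-expressing strain in liquid
culture across a Cu dose series (triplicates per dose), reads endpoint
OD600, and plots each dose as a percentage of the OD600 reached by the
same strain without Cu. This module does that bookkeeping on a tidy
table: one row per replicate with columns strain, cu_conc, unit, od600.

Percent SD is propagated from the replicate spread of the treated
condition against the control mean (the usual error-bar convention),
not via a ratio-distribution correction. Concentration units are
carried through verbatim — no silent uM/mM conversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ModmtError, NoControlError

REQUIRED_COLUMNS = ("strain", "cu_conc", "unit", "od600")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ModmtError(f"growth table missing columns: {missing}")
    if (table["od600"] < 0).any():
        raise ModmtError("OD600 readings must be >= 0")
    return table


def normalize_growth(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize replicates and normalize growth to the zero-Cu control.

    Returns one row per (strain, cu_conc) with mean OD, OD SD,
    percent_of_control (ratio of means, x100) and percent_sd. The
    control row of each strain is exactly 100%. Raises
    :class:`NoControlError` for a strain without a positive-mean
    zero-Cu control.
    """
    table = _validate_table(table)
    rows = []
    for strain, group in table.groupby("strain", sort=True):
        control = group[group["cu_conc"] == 0]
        if control.empty:
            raise NoControlError(f"strain {strain!r} has no zero-Cu control")
        control_mean = control["od600"].mean()
        if control_mean <= 0:
            raise NoControlError(
                f"strain {strain!r} control mean OD is not positive"
            )
        for (conc, unit), cond in group.groupby(["cu_conc", "unit"], sort=True):
            od = cond["od600"].to_numpy(dtype=float)
            mean = float(np.mean(od))
            sd = float(np.std(od, ddof=1)) if len(od) > 1 else 0.0
            rows.append({
                "strain": strain,
                "cu_conc": conc,
                "unit": unit,
                "n_replicates": len(od),
                "mean_od600": mean,
                "sd_od600": sd,
                "percent_of_control": 100.0 * mean / control_mean,
                "percent_sd": 100.0 * sd / control_mean,
            })
    return pd.DataFrame(rows)


def read_growth_csv(path) -> pd.DataFrame:
    """Read a replicate-level growth table from CSV."""
    return _validate_table(pd.read_csv(path))
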