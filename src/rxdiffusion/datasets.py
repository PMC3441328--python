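"""Packaged reference data.

``load_adoption_table`` returns the published per-drug adoption table for
103 medicines subsidised in Australia between 1992 and 2009: anatomical
main group, month of first subsidised prescription, maximum monthly
prescriptions per 100,000, fitted p/q ratio, model fit R^2, and the
modelled adoption time in years.  The external/internal classification is
derived from the p/q ratio and cross-checked against the published
external-dominant flag at load time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .bass import EXTERNAL_DOMINANT, INTERNAL_DOMINANT

__all__ = ["load_adoption_table", "load_table1"]


def load_adoption_table() -> pd.DataFrame:
    """Load the published 103-drug adoption table.

    Returns a DataFrame with columns ``drug``, ``atc_main_group``,
    ``first_month`` (monthly Period), ``max_monthly_per_100k``,
    ``pq_ratio``, ``r2``, ``adoption_time_years``, ``external_dominant``
    (bool) and ``classification``.
    """
    with resources.files("rxdiffusion.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["first_month"] = (
        pd.to_datetime(df["first_month"], format="%b %Y").dt.to_period("M")
    )
    df["external_dominant"] = df["external_dominant"].astype(bool)
    derived = df["pq_ratio"] > 1
    if not (derived == df["external_dominant"]).all():
        bad = df.loc[derived != df["external_dominant"], "drug"].tolist()
        raise ValueError(f"inconsistent external-dominant flags for: {bad}")
    df["classification"] = derived.map(
        {True: EXTERNAL_DOMINANT, False: INTERNAL_DOMINANT}
    )
    return df


# alias kept for discoverability next to the published table numbering
load_table1 = load_adoption_table
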