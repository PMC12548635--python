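"""Packaged reference data: the published prediction-interval table.

The bundled CSV carries, for the 20 validation specimens of the baboon-skull
CT collection, the published 99% prediction-interval limits of each
measurement modality together with the single Microscribe digitizer value
per specimen and the published inclusion verdict.  It contains interval
*limits* only — the underlying replicate measurements are not redistributed
here — so it supports audit-only reproduction (membership and exceedance),
not re-estimation of the intervals themselves.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .validation_stats import InclusionAudit, PredictionInterval, inclusion_audit

_FIXTURE = "published_prediction_intervals.csv"


def load_published_intervals() -> pd.DataFrame:
    """The published interval table: one row per specimen x modality with
    columns group, specimen_id, microscribe_mm, modality, lower_mm,
    upper_mm, included."""
    with resources.files("ctspacing.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh)
    df["included"] = df["included"].astype(str).str.upper() == "TRUE"
    return df


def audit_published_intervals(df: pd.DataFrame | None = None) -> list[InclusionAudit]:
    """Re-run the inclusion audit from the published limits and probes.

    Each row's Microscribe value is probed against the row's interval; the
    returned audits can be compared with the published TRUE/FALSE column and
    summarized with :func:`ctspacing.validation_stats.summarize_audits`.
    """
    if df is None:
        df = load_published_intervals()
    audits = []
    for row in df.itertuples(index=False):
        interval = PredictionInterval(
            mean_mm=(row.lower_mm + row.upper_mm) / 2.0,
            sd_mm=float("nan"),
            n=10,
            confidence=0.99,
            lower_mm=row.lower_mm,
            upper_mm=row.upper_mm,
            specimen_id=row.specimen_id,
            modality=row.modality,
        )
        audits.append(
            inclusion_audit(row.microscribe_mm, interval, row.specimen_id, row.group)
        )
    return audits
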