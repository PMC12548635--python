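"""Repeated-measures validation statistics for measurement-modality agreement.

The design: each specimen's landmark distance (prosthion-basion, a cranial
length proxy) is measured repeatedly under several modalities — physical
calipers ("Original"), CT reconstructions under candidate slice spacings
("CT_0.58", "CT_0.60", "CT_0.75") — plus one articulated-arm digitizer value
per specimen ("Microscribe") that serves as an external probe.

Three statistical pieces decide which candidate spacing is the true one:

* paired t-tests between every within-specimen modality pair (replicates
  paired by replicate index), with Bonferroni adjustment over all
  comparisons in the run;
* per specimen x modality, the 99% prediction interval for a single future
  observation, mean +/- t_{(1+c)/2, n-1} * sd * sqrt(1 + 1/n) — the interval
  an intercept-only regression's predict() would give;
* an inclusion audit: does the Microscribe probe fall inside each interval
  (closed membership), and by how much does it miss when it does not.

A modality measured under the correct spacing agrees with the physical
measurements (non-significant t, probe included); a misassigned spacing
shifts the CT distances by its relative spacing error and fails both checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePairingError

MICROSCRIBE = "Microscribe"
MODALITIES = ("Original", "CT_0.58", "CT_0.60", "CT_0.75", MICROSCRIBE)
GROUPS = ("G1", "G2", "G3")

TABLE_COLUMNS = ["specimen_id", "group", "modality", "replicate", "distance_mm"]

#: significance ladder applied to adjusted p-values (most extreme label wins)
_SIGNIFICANCE_LADDER = [
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
]


class MeasurementTable:
    """Long-format table of repeated distances per specimen x modality.

    Wraps a pandas DataFrame with columns specimen_id, group, modality,
    replicate, distance_mm.  (specimen, modality, replicate) must be unique;
    the Microscribe modality carries exactly one replicate per specimen and
    every other modality at least two.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        df = df[TABLE_COLUMNS].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["distance_mm"] = df["distance_mm"].astype(float)
        if (df["distance_mm"] <= 0).any():
            raise ValueError("distance_mm must be positive")
        key = ["specimen_id", "modality", "replicate"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (specimen, modality, replicate) rows")
        counts = df.groupby(["specimen_id", "modality"])["replicate"].count()
        for (spec, mod), n in counts.items():
            if mod == MICROSCRIBE and n != 1:
                raise ValueError(f"{spec}: Microscribe must have exactly 1 replicate")
            if mod != MICROSCRIBE and n < 2:
                raise ValueError(f"{spec}/{mod}: needs at least 2 replicates")
        self.df = df.sort_values(key).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def specimens(self) -> list[str]:
        return list(dict.fromkeys(self.df["specimen_id"]))

    def group_of(self, specimen_id: str) -> str:
        return str(self.df.loc[self.df.specimen_id == specimen_id, "group"].iloc[0])

    def replicates(self, specimen_id: str, modality: str) -> np.ndarray:
        sel = self.df[
            (self.df.specimen_id == specimen_id) & (self.df.modality == modality)
        ].sort_values("replicate")
        return sel["distance_mm"].to_numpy()

    def modalities(self, specimen_id: str, include_probe: bool = False) -> list[str]:
        mods = list(
            dict.fromkeys(self.df.loc[self.df.specimen_id == specimen_id, "modality"])
        )
        if not include_probe:
            mods = [m for m in mods if m != MICROSCRIBE]
        # canonical report order: CT modalities ascending, Original last
        order = {m: i for i, m in enumerate(sorted(mods))}
        return sorted(mods, key=lambda m: order[m])


@dataclass
class ComparisonResult:
    specimen_id: str
    modality_1: str
    modality_2: str
    n1: int
    n2: int
    statistic: float
    df: int
    p: float
    p_adj: float = math.nan
    significance: str = ""


@dataclass
class PredictionInterval:
    mean_mm: float
    sd_mm: float
    n: int
    confidence: float
    lower_mm: float
    upper_mm: float
    degenerate: bool = False
    specimen_id: str = ""
    modality: str = ""


@dataclass
class InclusionAudit:
    specimen_id: str
    reference_modality: str
    probe_value_mm: float
    included: bool
    signed_exceedance_mm: float
    group: str = ""


def paired_t(
    sample_1: Sequence[float], sample_2: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t-test on replicate-ordered samples: t, df, two-sided p.

    Differences with zero variance but nonzero mean give a signed infinite
    statistic with p = 0; identical samples have no defined statistic and
    raise :class:`DegeneratePairingError`.
    """
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired samples must be equal-length 1-D, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            raise DegeneratePairingError("degenerate pairing: identical samples")
        return math.copysign(math.inf, mean), n - 1, 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def adjust_p(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p), m defaulting to len(p_values)."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p) or len(p) < 1:
        raise ValueError("m must be at least the number of p-values (>= 1)")
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"invalid probability: {v}")
    return [min(1.0, m * v) for v in p]


def significance_label(p_adj: float) -> str:
    """Star ladder: ns above 0.05, then * / ** / *** / **** at the usual
    thresholds (most extreme applicable label)."""
    if not (0.0 <= p_adj <= 1.0):
        raise ValueError(f"invalid probability: {p_adj}")
    for threshold, label in _SIGNIFICANCE_LADDER:
        if p_adj <= threshold:
            return label
    return "ns"


def prediction_interval(
    sample: Sequence[float], confidence: float = 0.99
) -> PredictionInterval:
    """Interval expected to contain a single future observation.

    mean +/- t_{(1+confidence)/2, n-1} * sd * sqrt(1 + 1/n), the prediction
    interval of an intercept-only least-squares fit.  Wider than the
    confidence interval for the mean by the sqrt(1 + 1/n) vs sqrt(1/n)
    factor: it must absorb the noise of the future draw itself.
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("insufficient sample: need n >= 2")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return PredictionInterval(mean, 0.0, n, confidence, mean, mean, degenerate=True)
    half = stats.t.ppf((1.0 + confidence) / 2.0, n - 1) * sd * math.sqrt(1.0 + 1.0 / n)
    return PredictionInterval(mean, sd, n, confidence, mean - half, mean + half)


def inclusion_audit(
    probe_mm: float,
    interval: PredictionInterval,
    specimen_id: str = "",
    group: str = "",
) -> InclusionAudit:
    """Closed-interval membership of the probe, with signed exceedance:
    0 when included, distance beyond the violated limit otherwise (positive
    above the upper limit, negative below the lower)."""
    if probe_mm > interval.upper_mm:
        exceed = probe_mm - interval.upper_mm
        included = False
    elif probe_mm < interval.lower_mm:
        exceed = probe_mm - interval.lower_mm
        included = False
    else:
        exceed = 0.0
        included = True
    return InclusionAudit(
        specimen_id=specimen_id or interval.specimen_id,
        reference_modality=interval.modality,
        probe_value_mm=probe_mm,
        included=included,
        signed_exceedance_mm=exceed,
        group=group,
    )


@dataclass
class ValidationReport:
    comparisons: list[ComparisonResult]
    intervals: list[PredictionInterval]
    audits: list[InclusionAudit]
    summary: dict
    warnings: list[str] = field(default_factory=list)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": c.specimen_id,
                "modality_1": c.modality_1,
                "modality_2": c.modality_2,
                "n1": c.n1,
                "n2": c.n2,
                "statistic": round(c.statistic, 2),
                "df": c.df,
                "p": c.p,
                "p_adj": c.p_adj,
                "p_rounded": round(c.p, 2),
                "p_adj_rounded": round(c.p_adj, 2),
                "significance": c.significance,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)

    def intervals_frame(self) -> pd.DataFrame:
        audit_by_key = {(a.specimen_id, a.reference_modality): a for a in self.audits}
        rows = []
        for pi in self.intervals:
            a = audit_by_key.get((pi.specimen_id, pi.modality))
            rows.append(
                {
                    "specimen_id": pi.specimen_id,
                    "modality": pi.modality,
                    "n": pi.n,
                    "mean_mm": round(pi.mean_mm, 2),
                    "lower_mm": round(pi.lower_mm, 2),
                    "upper_mm": round(pi.upper_mm, 2),
                    "microscribe_mm": None if a is None else a.probe_value_mm,
                    "included": None if a is None else a.included,
                    "signed_exceedance_mm": (
                        None if a is None else round(a.signed_exceedance_mm, 2)
                    ),
                }
            )
        return pd.DataFrame(rows)


def summarize_audits(audits: list[InclusionAudit]) -> dict:
    """Inclusion counts per reference modality and group, plus min/max
    exceedance magnitude (and direction) per group x modality among misses."""
    by_modality: dict[str, dict] = {}
    by_group: dict[str, dict] = {}
    exceedance: dict[str, dict] = {}
    for a in audits:
        m = by_modality.setdefault(a.reference_modality, {"true": 0, "total": 0})
        m["total"] += 1
        m["true"] += int(a.included)
        g = by_group.setdefault(a.group or "all", {"true": 0, "total": 0})
        g["total"] += 1
        g["true"] += int(a.included)
        if not a.included:
            key = f"{a.group or 'all'}/{a.reference_modality}"
            e = exceedance.setdefault(key, [])
            e.append(a.signed_exceedance_mm)
    exceedance_ranges = {
        key: {
            "min_mm": round(min(v, key=abs), 2),
            "max_mm": round(max(v, key=abs), 2),
            "direction": "above" if max(v, key=abs) > 0 else "below",
        }
        for key, v in exceedance.items()
    }
    return {
        "n_inclusions_true": sum(int(a.included) for a in audits),
        "n_inclusions_total": len(audits),
        "inclusions_by_modality": by_modality,
        "inclusions_by_group": by_group,
        "exceedance_ranges": exceedance_ranges,
    }


def run_validation(
    table: MeasurementTable,
    confidence: float = 0.99,
    m: Optional[int] = None,
) -> ValidationReport:
    """The full pipeline: all within-specimen paired tests, all prediction
    intervals, and the Microscribe inclusion audit.

    The multiplicity parameter m defaults to the total number of comparisons
    actually run (the study design has 40: 10 + 15 + 15).  Specimens without
    a Microscribe value are excluded from the audit with a logged warning;
    degenerate pairings are reported as warnings and the run continues.
    """
    comparisons: list[ComparisonResult] = []
    intervals: list[PredictionInterval] = []
    audits: list[InclusionAudit] = []
    warnings: list[str] = []

    for spec in table.specimens():
        group = table.group_of(spec)
        mods = table.modalities(spec)
        for m1, m2 in combinations(mods, 2):
            x = table.replicates(spec, m1)
            y = table.replicates(spec, m2)
            try:
                t, df_, p = paired_t(x, y)
            except DegeneratePairingError:
                warnings.append(f"{spec}: degenerate pairing {m1} vs {m2}, skipped")
                continue
            comparisons.append(
                ComparisonResult(spec, m1, m2, len(x), len(y), t, df_, p)
            )
        for mod in mods:
            pi = prediction_interval(table.replicates(spec, mod), confidence)
            pi.specimen_id = spec
            pi.modality = mod
            intervals.append(pi)
            if pi.degenerate:
                warnings.append(f"{spec}/{mod}: zero-variance replicates")
        probe = table.replicates(spec, MICROSCRIBE)
        if len(probe) == 0:
            warnings.append(f"{spec}: no Microscribe value, excluded from audit")
            continue
        for pi in intervals:
            if pi.specimen_id == spec:
                audits.append(inclusion_audit(float(probe[0]), pi, spec, group))

    if comparisons:
        adjusted = adjust_p([c.p for c in comparisons], m)
        for c, pa in zip(comparisons, adjusted):
            c.p_adj = pa
            c.significance = significance_label(pa)

    summary = summarize_audits(audits)
    summary["n_comparisons"] = len(comparisons)
    summary["m_comparisons"] = m if m is not None else len(comparisons)
    summary["n_significant"] = sum(c.significance != "ns" for c in comparisons)
    return ValidationReport(comparisons, intervals, audits, summary, warnings)


def write_reports(report: ValidationReport, outdir) -> dict[str, Path]:
    """Write the comparison CSV, interval/inclusion CSV and summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "comparisons": outdir / "comparisons.csv",
        "intervals": outdir / "prediction_intervals.csv",
        "summary": outdir / "summary.json",
    }
    report.comparisons_frame().to_csv(paths["comparisons"], index=False)
    report.intervals_frame().to_csv(paths["intervals"], index=False)
    paths["summary"].write_text(json.dumps(report.summary, indent=2) + "\n")
    return paths
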