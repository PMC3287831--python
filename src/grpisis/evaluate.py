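"""Scoring selections against simulation truth: NTP, NFP, FDP.

NTP counts selected genes that are causal, NFP counts selected genes that
are not, and FDP = 100 * NFP / (NTP + NFP) percent (defined as 0 for an
empty selection).  Multi-dataset comparisons are summarized as mean (sd) per
method, with FDP averaged per dataset rather than pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .simulate import SimulationTruth


@dataclass
class EvaluationRecord:
    method: str
    ntp: int
    nfp: int
    fdp: float  # percent

    def __post_init__(self):
        if not 0.0 <= self.fdp <= 100.0:
            raise InputError("FDP must be a percentage in [0, 100]")


def score_selection(selected_genes, truth: SimulationTruth, method: str = "") -> EvaluationRecord:
    """Count true/false-positive genes and the false discovery proportion."""
    selected = list(dict.fromkeys(selected_genes))
    causal = set(truth.causal_genes)
    ntp = sum(1 for g in selected if g in causal)
    nfp = len(selected) - ntp
    fdp = 100.0 * nfp / len(selected) if selected else 0.0
    return EvaluationRecord(method=method, ntp=ntp, nfp=nfp, fdp=fdp)


def summarize_over_datasets(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Per-method mean and sd of NTP/NFP/FDP across datasets.

    Expects at least two records overall; the result has one row per method
    and columns ``(metric, stat)`` for metric in NTP/NFP/FDP(%).
    """
    if len(records) < 2:
        raise InputError("need at least two records to summarize")
    df = pd.DataFrame(
        {
            "method": [r.method for r in records],
            "NTP": [r.ntp for r in records],
            "NFP": [r.nfp for r in records],
            "FDP (%)": [r.fdp for r in records],
        }
    )
    grouped = df.groupby("method", sort=False).agg(["mean", "std"])
    return grouped


def write_summary(summary: pd.DataFrame, path, sep="\t") -> None:
    flat = summary.copy()
    flat.columns = [f"{metric} {stat}" for metric, stat in summary.columns]
    flat.to_csv(path, sep=sep)
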