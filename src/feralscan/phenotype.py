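"""Exact phenotype-side calculators: germination summaries and qPCR.

Germination assays score radicle protrusion daily over a fixed window
(typically 50 seeds per dish, 30 days); the summaries are the germination
ratio and a germination-time statistic. qPCR relative expression uses the
2^-ddCt method against a reference gene and a calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GerminationRecord:
    """Daily new-germination counts for one dish."""

    dish_id: str
    population: str
    temperature: float
    n_seeds: int
    days: tuple
    new_germinated: tuple

    def __post_init__(self) -> None:
        if len(self.days) != len(self.new_germinated):
            raise ValueError("days and counts differ in length")
        if any(c < 0 for c in self.new_germinated):
            raise ValueError("negative germination count")
        if sum(self.new_germinated) > self.n_seeds:
            raise ValueError("more germinated seeds than sown")


def read_germination(path: str | Path) -> list[GerminationRecord]:
    """Read a germination TSV: dish, population, temp, day, new_germinated,
    n_seeds (one row per dish per day with germination activity)."""
    df = pd.read_csv(path, sep="\t")
    recs = []
    for (dish, pop, temp, n), sub in df.groupby(
        ["dish", "population", "temp", "n_seeds"], sort=False
    ):
        sub = sub.sort_values("day")
        recs.append(
            GerminationRecord(
                str(dish), str(pop), float(temp), int(n),
                tuple(sub["day"]), tuple(sub["new_germinated"]),
            )
        )
    return recs


def germination_ratio(rec: GerminationRecord, day_cutoff: float | None = None) -> float:
    """Fraction of sown seeds germinated by ``day_cutoff`` (default: all)."""
    total = sum(
        c for d, c in zip(rec.days, rec.new_germinated)
        if day_cutoff is None or d <= day_cutoff
    )
    return total / rec.n_seeds


def mean_germination_time(rec: GerminationRecord) -> float:
    """Count-weighted mean day of germination, sum(n_i t_i) / sum(n_i)."""
    total = sum(rec.new_germinated)
    if total == 0:
        raise ValueError("no germinated seeds; germination time undefined")
    return sum(d * c for d, c in zip(rec.days, rec.new_germinated)) / total


def median_germination_time(rec: GerminationRecord) -> float:
    """Day by which half of the germinating seeds have germinated."""
    total = sum(rec.new_germinated)
    if total == 0:
        raise ValueError("no germinated seeds; germination time undefined")
    order = sorted(zip(rec.days, rec.new_germinated))
    cum = 0
    for d, c in order:
        cum += c
        if cum >= total / 2:
            return float(d)
    return float(order[-1][0])


def first_germination_time(rec: GerminationRecord) -> float:
    """First day with any germination."""
    for d, c in sorted(zip(rec.days, rec.new_germinated)):
        if c > 0:
            return float(d)
    raise ValueError("no germinated seeds; germination time undefined")


GERMINATION_TIME_METRICS = {
    "mean": mean_germination_time,
    "median": median_germination_time,
    "first": first_germination_time,
}


def summarize_germination(
    recs: list[GerminationRecord], time_metric: str = "mean"
) -> pd.DataFrame:
    """Per-dish ratio and germination time, long format."""
    metric = GERMINATION_TIME_METRICS[time_metric]
    rows = []
    for r in recs:
        germinated = sum(r.new_germinated)
        rows.append(
            {
                "dish": r.dish_id,
                "population": r.population,
                "temp": r.temperature,
                "germination_ratio": germination_ratio(r),
                "germination_time": metric(r) if germinated else np.nan,
            }
        )
    return pd.DataFrame(rows)


def relative_expression(
    records: pd.DataFrame, calibrator: str
) -> pd.DataFrame:
    """2^-ddCt relative expression per (sample, gene).

    ``records`` columns: sample, gene, role in {target, reference}, Ct,
    replicate. Technical replicates are averaged on the Ct scale first;
    dCt = Ct_target - Ct_reference; ddCt subtracts the calibrator sample's
    dCt for the same gene. The calibrator's relative expression is 1 by
    construction, and the result is invariant to adding a constant to all
    Ct values.
    """
    req = {"sample", "gene", "role", "Ct"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if not np.isfinite(records["Ct"]).all() or (records["Ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    ref = records[records["role"] == "reference"]
    tgt = records[records["role"] == "target"]
    if tgt.empty:
        raise ValueError("no target-gene Ct records")
    ref_ct = ref.groupby("sample")["Ct"].mean()
    dct = tgt.groupby(["sample", "gene"])["Ct"].mean().reset_index()
    dct["ref_Ct"] = dct["sample"].map(ref_ct)
    if dct["ref_Ct"].isna().any():
        missing = dct.loc[dct["ref_Ct"].isna(), "sample"].unique()
        raise ValueError(f"missing reference-gene Ct for samples: {list(missing)}")
    dct["dCt"] = dct["Ct"] - dct["ref_Ct"]
    cal = dct[dct["sample"] == calibrator].set_index("gene")["dCt"]
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator!r} absent")
    dct["ddCt"] = dct["dCt"] - dct["gene"].map(cal).to_numpy()
    if dct["ddCt"].isna().any():
        raise ValueError("calibrator lacks Ct for some gene")
    dct["relative_expression"] = 2.0 ** (-dct["ddCt"])
    return dct[["sample", "gene", "dCt", "ddCt", "relative_expression"]]
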