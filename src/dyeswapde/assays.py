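"""Companion assay quantifications: qPCR, growth, viability, concordance.

Relative qPCR uses the efficiency-free 2^-dCt model: the arbitrary-units
ratio of a target in a sample is 2 raised to minus the difference between the
mean target Ct and the mean reference-gene Ct (HMBS by default). Doubling
time assumes exponential growth between the two measured timepoints; MTT
viability is the reference-corrected absorbance as a percent of untreated;
platform concordance is the Pearson correlation of microarray and qPCR fold
changes (on the log2 scale by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, PipelineError

DEFAULT_REFERENCE_GENE = "HMBS"


@dataclass
class QpcrRecord:
    """Replicate Ct values for one target in one sample, plus its reference."""

    sample_id: str
    gene: str
    ct_values: Sequence[float]
    reference_ct_values: Sequence[float]
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def validate(self) -> None:
        for name, vals in (("ct_values", self.ct_values),
                           ("reference_ct_values", self.reference_ct_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size < 1:
                raise ParseError(f"{self.sample_id}/{self.gene}: empty {name}")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ParseError(
                    f"{self.sample_id}/{self.gene}: {name} must be finite "
                    "and > 0"
                )


def qpcr_relative_quantity(
    rec: QpcrRecord, efficiency: float = 2.0, collapse: str = "mean"
) -> float:
    """Arbitrary-units ratio E^-(mean Ct_target - mean Ct_reference).

    ``efficiency`` defaults to 2 (perfect doubling per cycle); replicate Ct
    values collapse by the mean (or median).
    """
    rec.validate()
    if collapse not in ("mean", "median"):
        raise PipelineError(f"unknown Ct collapse rule {collapse!r}")
    agg = np.mean if collapse == "mean" else np.median
    delta_ct = float(agg(rec.ct_values)) - float(agg(rec.reference_ct_values))
    return float(efficiency ** -delta_ct)


def fold_change_vs_control(
    sample_au: Sequence[float], control_au: Sequence[float]
) -> float:
    """Mean sample AU over mean control AU (controls map to 1)."""
    control_mean = float(np.mean(control_au))
    if control_mean <= 0:
        raise PipelineError("control mean must be > 0")
    return float(np.mean(sample_au)) / control_mean


def platform_concordance(
    fc_array: Sequence[float],
    fc_qpcr: Sequence[float],
    log2_scale: bool = True,
) -> float:
    """Pearson correlation of per-gene fold changes from the two platforms."""
    x = np.asarray(fc_array, dtype=float)
    y = np.asarray(fc_qpcr, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise PipelineError("need >= 3 shared genes with matching order")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PipelineError("fold changes must be finite")
    if log2_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise PipelineError("fold changes must be > 0 on the log2 scale")
        x, y = np.log2(x), np.log2(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise PipelineError("zero variance; Pearson r undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class GrowthMeasurement:
    """Viable-cell signal at two timepoints of an exponential culture."""

    sample_id: str
    signal_t0: float
    signal_t1: float
    interval_h: float = 72.0

    def validate(self) -> None:
        if self.signal_t0 <= 0 or self.signal_t1 <= 0:
            raise ParseError(f"{self.sample_id}: signals must be > 0")
        if self.interval_h <= 0:
            raise ParseError(f"{self.sample_id}: interval must be > 0")


def doubling_time(g: GrowthMeasurement) -> float:
    """Hours per population doubling: interval * ln2 / ln(t1/t0).

    Assumes exponential growth between the two timepoints (the only model
    identifiable from two points); undefined without net growth.
    """
    g.validate()
    ratio = g.signal_t1 / g.signal_t0
    if ratio <= 1.0:
        raise PipelineError(
            f"{g.sample_id}: no net growth; doubling time undefined"
        )
    return float(g.interval_h * np.log(2.0) / np.log(ratio))


def viability_percent(
    treated_od550: float,
    treated_od620: float,
    untreated_od550: float,
    untreated_od620: float,
) -> float:
    """MTT viability: reference-corrected OD as percent of untreated."""
    denom = untreated_od550 - untreated_od620
    if denom <= 0:
        raise PipelineError("untreated corrected OD must be > 0")
    return 100.0 * (treated_od550 - treated_od620) / denom


def normalize_cpm_to_dna(cpm: float, dna_od260: float) -> float:
    """Incorporated counts per minute normalized to DNA content (OD 260)."""
    if dna_od260 <= 0:
        raise PipelineError("DNA OD260 must be > 0")
    return cpm / dna_od260


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "t_unpaired_two_tailed",
) -> tuple[float, float]:
    """Two-group comparison: unpaired two-tailed t or Mann-Whitney."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "t_unpaired_two_tailed":
        if a.size < 2 or b.size < 2:
            raise PipelineError("t test needs >= 2 values per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise PipelineError("zero pooled variance; t undefined")
        res = stats.ttest_ind(a, b, equal_var=True)
    elif method == "mann_whitney_two_tailed":
        if a.size < 1 or b.size < 1:
            raise PipelineError("Mann-Whitney needs >= 1 value per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise PipelineError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# -- CSV dialects -----------------------------------------------------------

def read_qpcr(path, reference_gene: str = DEFAULT_REFERENCE_GENE) -> list[QpcrRecord]:
    """qPCR CSV (sample_id, gene, ct, is_reference) -> records per target.

    ``is_reference`` marks the reference-gene rows of each sample; every
    sample must include them.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct", "is_reference"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    records = []
    truthy = df["is_reference"].astype(str).str.lower().isin(
        ("1", "true", "yes"))
    for sample_id, grp in df.groupby("sample_id", sort=True):
        ref = grp.loc[truthy.loc[grp.index], "ct"]
        if ref.empty:
            raise ParseError(
                f"{path}: sample {sample_id!r} has no reference-gene rows"
            )
        for gene, tgt in grp.loc[~truthy.loc[grp.index]].groupby("gene",
                                                                 sort=True):
            records.append(QpcrRecord(
                sample_id=str(sample_id),
                gene=str(gene),
                ct_values=tgt["ct"].tolist(),
                reference_ct_values=ref.tolist(),
                reference_gene=reference_gene,
            ))
    return records


def read_growth(path) -> list[GrowthMeasurement]:
    """Growth CSV: sample_id, signal_t0, signal_t1, interval_h."""
    df = pd.read_csv(path)
    required = {"sample_id", "signal_t0", "signal_t1", "interval_h"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return [
        GrowthMeasurement(
            sample_id=str(r.sample_id),
            signal_t0=float(r.signal_t0),
            signal_t1=float(r.signal_t1),
            interval_h=float(r.interval_h),
        )
        for r in df.itertuples()
    ]


def read_viability(path) -> pd.DataFrame:
    """Viability CSV: sample_id, condition, od550, od620."""
    df = pd.read_csv(path)
    required = {"sample_id", "condition", "od550", "od620"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return df
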