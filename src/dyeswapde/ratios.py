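"""Dye-swap orientation, concordance filtering and per-patient aggregation.

Each patient is hybridized against the pooled reference twice with the dyes
exchanged. After normalization:

* ratios are oriented to patient/reference regardless of which dye carried
  the patient sample (sign flip when the patient was in channel 2);
* duplicate spots of a gene are collapsed (mean of unflagged duplicates);
* within each swap pair, delta = log2(R1/R2) = oriented1 - oriented2 is
  computed per gene, and genes whose centered delta exceeds ``k_sd`` standard
  deviations are discarded as replicate-discordant;
* the per-patient summary is the log2 of the geometric mean of R1 and R2,
  i.e. the arithmetic mean of the two oriented log2 ratios;
* genes are kept only when they have a value in every patient and the sign of
  that value agrees strictly across all patients (a zero has no sign and
  drops the gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PipelineError
from .io import ExperimentDesign
from .preprocess import NormalizedSlide

STATUS_KEPT = "kept"
STATUS_CONCORDANCE = "dropped_concordance"
STATUS_MISSING = "dropped_missing"
STATUS_PATTERN = "dropped_pattern"


@dataclass
class PairRatios:
    """Oriented per-gene ratios for the two slides of one dye-swap pair.

    ``table`` is indexed by gene_id with columns ``o1``/``o2`` (oriented
    log2 patient/reference ratios from each slide), ``delta`` (o1 - o2, i.e.
    log2(R1/R2)) and, after filtering, the boolean ``concordant``.
    """

    pair_id: str
    patient_id: str
    table: pd.DataFrame

    @property
    def r1(self) -> pd.Series:
        return np.exp2(self.table["o1"])

    @property
    def r2(self) -> pd.Series:
        return np.exp2(self.table["o2"])


@dataclass
class RatioMatrix:
    """Genes x patients summarized log2 ratios plus per-gene provenance.

    ``values`` rows cover every gene seen on the arrays; ``status`` says
    whether the gene was kept or at which filter it was dropped.
    """

    values: pd.DataFrame
    status: pd.Series

    @property
    def kept(self) -> pd.DataFrame:
        return self.values.loc[self.status == STATUS_KEPT]

    def direction(self) -> pd.Series:
        """'up'/'down' per kept gene from the (consistent) value sign."""
        kept = self.kept
        return pd.Series(
            np.where(kept.mean(axis=1) > 0, "up", "down"), index=kept.index
        )


def orient_and_collapse(
    norm_slides: dict[str, NormalizedSlide],
    design: ExperimentDesign,
    collapse: str = "mean",
) -> pd.DataFrame:
    """Per-gene oriented log2 ratios, one column per slide.

    Duplicate spots are collapsed by the mean (or median) of their unflagged
    M_norm values; a gene is NaN on a slide when all its spots are flagged.
    """
    if collapse not in ("mean", "median"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    cols = {}
    for slide_id in design.slide_ids:
        if slide_id not in norm_slides:
            raise PipelineError(f"slide {slide_id!r} missing from inputs")
        norm = norm_slides[slide_id]
        sign = design.orientation_sign(slide_id)
        ok = norm.unflagged
        grouped = ok.groupby("gene_id")["M_norm"]
        collapsed = grouped.mean() if collapse == "mean" else grouped.median()
        cols[slide_id] = sign * collapsed
    all_genes = sorted(
        set().union(*(norm.data["gene_id"] for norm in norm_slides.values()))
    )
    return pd.DataFrame(cols, index=pd.Index(all_genes, name="gene_id"))


def pair_ratios(oriented: pd.DataFrame, design: ExperimentDesign) -> list[PairRatios]:
    """Split the oriented slide matrix into per-pair R1/R2 tables."""
    out = []
    for pair_id in design.pair_ids:
        grp = design.data.loc[design.data["pair_id"] == pair_id]
        s1, s2 = grp["slide_id"].iloc[0], grp["slide_id"].iloc[1]
        table = pd.DataFrame({
            "o1": oriented[s1],
            "o2": oriented[s2],
        })
        table["delta"] = table["o1"] - table["o2"]
        out.append(PairRatios(
            pair_id=pair_id,
            patient_id=grp["patient_id"].iloc[0],
            table=table,
        ))
    return out


def concordance_filter(pair: PairRatios, k_sd: float = 3.0) -> PairRatios:
    """Flag replicate-discordant genes by the centered log2(R1/R2) rule.

    The SD is taken over all defined deltas of the pair (outliers included);
    a gene is discordant when |delta - mean| strictly exceeds ``k_sd`` * SD.
    With SD = 0 nothing strictly exceeds the bound, so all genes are kept.
    """
    delta = pair.table["delta"]
    defined = delta.dropna()
    if len(defined) < 2:
        raise PipelineError(
            f"pair {pair.pair_id!r}: fewer than 2 genes with both replicates; "
            "SD undefined"
        )
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1))
    # NaN deltas compare False, so genes missing a replicate stay unflagged
    # here and surface later as dropped_missing.
    concordant = ((delta - mean).abs() <= k_sd * sd).fillna(False)
    table = pair.table.copy()
    table["concordant"] = concordant
    return PairRatios(pair_id=pair.pair_id, patient_id=pair.patient_id,
                      table=table)


def summarize_patient(pair: PairRatios) -> pd.Series:
    """Log2 of the geometric mean of R1 and R2 for concordant genes.

    Equivalently the arithmetic mean of the two oriented log2 ratios; NaN for
    discordant genes and genes missing either replicate.
    """
    if "concordant" not in pair.table.columns:
        raise PipelineError(
            f"pair {pair.pair_id!r}: concordance filter not applied"
        )
    value = (pair.table["o1"] + pair.table["o2"]) / 2.0
    value.loc[~pair.table["concordant"]] = np.nan
    value.name = pair.patient_id
    return value


def build_ratio_matrix(
    pairs: list[PairRatios], summaries: list[pd.Series]
) -> RatioMatrix:
    """Assemble the genes x patients matrix and per-gene drop provenance.

    A patient with several pairs contributes the mean of the pair summaries.
    Status precedence: discordant in any pair -> dropped_concordance; missing
    any patient value -> dropped_missing; remaining genes await the pattern
    filter (marked kept here).
    """
    by_patient: dict[str, list[pd.Series]] = {}
    for s in summaries:
        by_patient.setdefault(str(s.name), []).append(s)
    values = pd.DataFrame({
        pid: pd.concat(cols, axis=1).mean(axis=1)
        for pid, cols in by_patient.items()
    })
    values.index.name = "gene_id"

    discordant = pd.Series(False, index=values.index)
    for pair in pairs:
        flags = ~pair.table["concordant"] & pair.table["delta"].notna()
        discordant |= flags.reindex(values.index, fill_value=False)

    status = pd.Series(STATUS_KEPT, index=values.index, name="status")
    missing = values.isna().any(axis=1)
    status[missing] = STATUS_MISSING
    status[discordant] = STATUS_CONCORDANCE
    return RatioMatrix(values=values, status=status)


def pattern_consistency_filter(matrix: RatioMatrix) -> RatioMatrix:
    """Keep only genes whose value sign agrees strictly across all patients.

    Applies to genes still marked kept; a zero value has no sign and drops
    the gene as pattern-inconsistent.
    """
    status = matrix.status.copy()
    candidates = status == STATUS_KEPT
    vals = matrix.values.loc[candidates]
    signs = np.sign(vals.to_numpy())
    all_up = (signs > 0).all(axis=1)
    all_down = (signs < 0).all(axis=1)
    consistent = pd.Series(all_up | all_down, index=vals.index)
    drop = consistent.index[~consistent]
    status[drop] = STATUS_PATTERN
    return RatioMatrix(values=matrix.values, status=status)


def write_ratio_matrix(matrix: RatioMatrix, path) -> None:
    out = matrix.values.copy()
    out["status"] = matrix.status
    direction = pd.Series("", index=out.index)
    kept = matrix.status == STATUS_KEPT
    if kept.any():
        direction[kept] = matrix.direction()
    out["direction"] = direction
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_ratio_matrix(path) -> RatioMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    status = df.pop("status")
    df = df.drop(columns=["direction"], errors="ignore")
    return RatioMatrix(values=df, status=status)
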