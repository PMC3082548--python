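"""Readers and writers for the plain-text formats the pipeline touches.

Slide tables and the experiment design are tab-separated with fixed headers;
gene sets use the GMT dialect (set id, description, then members). All writers
emit a canonical form so that write(read(x)) is byte-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)

SLIDE_COLUMNS = ["spot_id", "gene_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]
INTENSITY_COLUMNS = ["ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]

DESIGN_COLUMNS = ["slide_id", "patient_id", "pair_id", "orientation"]
ORIENT_PATIENT_CH1 = "patient_in_ch1"
ORIENT_PATIENT_CH2 = "patient_in_ch2"
ORIENTATIONS = (ORIENT_PATIENT_CH1, ORIENT_PATIENT_CH2)

_FLOAT_FORMAT = "%.6f"


@dataclass
class SlideTable:
    """Per-spot two-channel raw intensities for one hybridization.

    ``data`` holds one row per spot with columns ``spot_id, gene_id,
    ch1_fg, ch1_bg, ch2_fg, ch2_bg``. Spot ids are unique within a slide;
    genes are typically spotted in duplicate so each gene id recurs.
    """

    slide_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SLIDE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(
                f"slide {self.slide_id!r}: missing column(s) {missing}"
            )
        if self.data["spot_id"].duplicated().any():
            dup = self.data["spot_id"][self.data["spot_id"].duplicated()].iloc[0]
            raise ParseError(
                f"slide {self.slide_id!r}: duplicate spot_id {dup!r}"
            )
        intens = self.data[INTENSITY_COLUMNS].to_numpy(dtype=float)
        bad = ~np.isfinite(intens) | (intens < 0)
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0][0])
            raise ParseError(
                f"slide {self.slide_id!r}: non-finite or negative intensity "
                f"at data row {row + 1} (spot "
                f"{self.data['spot_id'].iloc[row]!r})"
            )

    @property
    def n_spots(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene_id"].to_numpy()


@dataclass
class ExperimentDesign:
    """Maps slides to patients, dye-swap pairs and dye orientation.

    Each ``pair_id`` names the two hybridizations of a dye swap: the same
    patient-vs-pooled-reference comparison run twice with the fluorophores
    exchanged, so each pair must contain exactly two slides with opposite
    ``orientation`` values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"design: missing column(s) {missing}")
        bad = ~self.data["orientation"].isin(ORIENTATIONS)
        if bad.any():
            raise ParseError(
                "design: unknown orientation "
                f"{self.data['orientation'][bad].iloc[0]!r} "
                f"(expected one of {ORIENTATIONS})"
            )
        if self.data["slide_id"].duplicated().any():
            raise ParseError("design: duplicate slide_id")
        for pair_id, grp in self.data.groupby("pair_id"):
            if len(grp) != 2:
                raise ParseError(
                    f"design: pair {pair_id!r} has {len(grp)} slides, expected 2"
                )
            if set(grp["orientation"]) != set(ORIENTATIONS):
                raise ParseError(
                    f"design: pair {pair_id!r} does not have opposite "
                    "dye orientations"
                )
            if grp["patient_id"].nunique() != 1:
                raise ParseError(
                    f"design: pair {pair_id!r} spans multiple patients"
                )

    @property
    def slide_ids(self) -> list[str]:
        return list(self.data["slide_id"])

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["patient_id"]))

    @property
    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["pair_id"]))

    def orientation_sign(self, slide_id: str) -> int:
        """+1 if the patient sample is in channel 1 on this slide, else -1."""
        row = self.data.loc[self.data["slide_id"] == slide_id]
        if row.empty:
            raise ParseError(f"design: slide {slide_id!r} not in design")
        return 1 if row["orientation"].iloc[0] == ORIENT_PATIENT_CH1 else -1


@dataclass
class GeneSet:
    description: str
    members: list[str] = field(default_factory=list)


class GeneSetCollection(dict):
    """Mapping set_id -> GeneSet with de-duplicated, non-empty member lists."""

    def universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self.values():
            out.update(gs.members)
        return out


def read_slide_table(path: str | Path, slide_id: str | None = None) -> SlideTable:
    """Read one slide's spot table from a TSV file.

    The slide id defaults to the file stem. Malformed rows raise
    :class:`~dyeswapde.errors.ParseError` naming the offending line.
    """
    path = Path(path)
    sid = slide_id if slide_id is not None else path.stem
    try:
        df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "gene_id": str})
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse slide table: {exc}") from exc
    return SlideTable(slide_id=sid, data=df)


def write_slide_table(table: SlideTable, path: str | Path) -> None:
    table.data.to_csv(
        path, sep="\t", index=False, columns=SLIDE_COLUMNS,
        float_format=_FLOAT_FORMAT,
    )


def read_design(path: str | Path) -> ExperimentDesign:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse design table: {exc}") from exc
    return ExperimentDesign(data=df)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.data.to_csv(path, sep="\t", index=False, columns=DESIGN_COLUMNS)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT-style gene-set file.

    Each line is ``set_id<TAB>description<TAB>member...``. Duplicate members
    within a set are dropped (order preserved) with a logged warning.
    """
    coll = GeneSetCollection()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "%s:%d: set %r has %d duplicate member(s); de-duplicated",
                    path, lineno, set_id, len(members) - len(deduped),
                )
            if not deduped:
                raise ParseError(f"{path}:{lineno}: set {set_id!r} is empty")
            coll[set_id] = GeneSet(description=desc, members=deduped)
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, gs in coll.items():
            fh.write("\t".join([set_id, gs.description, *gs.members]) + "\n")
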