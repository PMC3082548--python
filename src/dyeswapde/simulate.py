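"""Synthetic two-channel dye-swap experiments with planted ground truth.

The generator emulates the structure of a spotted two-color study: each of
``n_patients`` patients is co-hybridized against a pooled reference on two
slides with the dyes exchanged (one swap pair per patient), every gene is
spotted in duplicate, and four kinds of structure are planted:

* differential expression: a fraction of genes carries a true
  patient/reference log2 ratio of +-``de_log2fc`` in every patient;
* intensity-dependent dye bias: a polynomial in A added to M on every slide
  with the same sign, i.e. the bias follows the dye (channel), not the
  sample — which is exactly what a dye-swap design exists to cancel;
* low-intensity spots: a fraction of spot positions forced to near-background
  brightness on all slides;
* replicate-discordant genes: a large additive shift applied to the oriented
  ratio on exactly one slide of one swap pair.

Intensities are generated on the log2 scale and exponentiated (a log-normal
brightness model chosen for convenience, not a platform claim); backgrounds
are a low constant plus jitter, recorded per spot so background subtraction
recovers the signal exactly. All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    ORIENT_PATIENT_CH1,
    ORIENT_PATIENT_CH2,
    ExperimentDesign,
    GeneSet,
    GeneSetCollection,
    SlideTable,
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the emulated design: 4 patients x 2 dye-swap slides,
    2000 genes in duplicate, 5% planted DE at |log2FC| = 1, spot noise SD
    0.25, dye bias M = 0.5*A - 5, 1% discordant genes, 2% low-intensity
    spots, mean log2 brightness uniform on [8, 14].
    """

    n_genes: int = 2000
    n_patients: int = 4
    duplicates_per_gene: int = 2
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    noise_sd: float = 0.25
    dye_bias_coeffs: tuple[float, ...] = (0.5, -5.0)  # np.polyval order
    low_intensity_fraction: float = 0.02
    discordant_fraction: float = 0.01
    discordant_shift: float = 6.0
    baseline_log_intensity_range: tuple[float, float] = (8.0, 14.0)
    background_level: float = 64.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_fraction", "low_intensity_fraction",
                     "discordant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_patients < 1:
            raise ConfigError(
                f"n_patients must be >= 1, got {self.n_patients}")
        if self.duplicates_per_gene < 1:
            raise ConfigError(
                "duplicates_per_gene must be >= 1, got "
                f"{self.duplicates_per_gene}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.baseline_log_intensity_range
        if not lo < hi:
            raise ConfigError(
                "baseline_log_intensity_range must be an increasing "
                f"interval, got {self.baseline_log_intensity_range}")
        if self.background_level <= 0:
            raise ConfigError(
                f"background_level must be > 0, got {self.background_level}")


@dataclass
class GroundTruth:
    """Planted structure of one synthetic experiment."""

    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    planted_discordant: set[tuple[str, str]] = field(default_factory=set)
    planted_low_intensity: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return self.de_up | self.de_down

    def truth_class(self, gene_id: str) -> str:
        if gene_id in self.de_up:
            return "de_up"
        if gene_id in self.de_down:
            return "de_down"
        return "null"


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[SlideTable], ExperimentDesign, GroundTruth]:
    """Generate slide tables, a design and ground truth for one experiment.

    Returns 2 * n_patients slides (one dye-swap pair per patient, opposite
    orientations within a pair); reproducible for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    dup = config.duplicates_per_gene
    n_spots = config.n_genes * dup
    gene_of_spot = np.repeat(np.arange(config.n_genes), dup)
    spot_ids = np.array([f"s{i:06d}" for i in range(1, n_spots + 1)])

    # planted differential expression (exact count, split up/down)
    n_de = int(round(config.n_genes * config.de_fraction))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]
    tau = np.zeros(config.n_genes)
    tau[up_idx] = config.de_log2fc
    tau[down_idx] = -config.de_log2fc

    # per-gene baseline brightness, shared across slides and duplicates
    lo, hi = config.baseline_log_intensity_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)

    # low-intensity spot positions (same physical spots on every slide)
    n_low = int(round(n_spots * config.low_intensity_fraction))
    low_spots = rng.choice(n_spots, size=n_low, replace=False)
    low_mask = np.zeros(n_spots, dtype=bool)
    low_mask[low_spots] = True
    low_A = rng.uniform(2.0, 4.0, size=n_low)

    # discordant genes: one random pair, one random slide of it, random sign
    n_disc = int(round(config.n_genes * config.discordant_fraction))
    disc_gene_idx = rng.choice(config.n_genes, size=n_disc, replace=False)
    disc_pair = rng.integers(0, config.n_patients, size=n_disc)
    disc_slide_of_pair = rng.integers(0, 2, size=n_disc)
    disc_sign = rng.choice([-1.0, 1.0], size=n_disc)

    design_rows = []
    slides: list[SlideTable] = []
    truth = GroundTruth(
        de_up=set(genes[up_idx]),
        de_down=set(genes[down_idx]),
        planted_low_intensity=set(spot_ids[low_mask]),
    )

    slide_no = 0
    for p in range(config.n_patients):
        patient_id = f"PT{p + 1}"
        pair_id = f"pair{p + 1}"
        for k, orientation in enumerate(
            (ORIENT_PATIENT_CH1, ORIENT_PATIENT_CH2)
        ):
            slide_no += 1
            slide_id = f"slide{slide_no:02d}"
            sign = 1.0 if orientation == ORIENT_PATIENT_CH1 else -1.0

            A = baseline[gene_of_spot].copy()
            if config.noise_sd > 0:
                A = A + rng.normal(0.0, config.noise_sd / 2.0, size=n_spots)
            A[low_mask] = low_A

            M = sign * tau[gene_of_spot]
            # discordant shift applies to the oriented ratio, so in M it
            # carries the orientation sign of this slide
            for j in range(n_disc):
                if disc_pair[j] == p and disc_slide_of_pair[j] == k:
                    spots_j = gene_of_spot == disc_gene_idx[j]
                    M[spots_j] += sign * disc_sign[j] * config.discordant_shift
                    truth.planted_discordant.add(
                        (genes[disc_gene_idx[j]], pair_id)
                    )
            M = M + np.polyval(config.dye_bias_coeffs, A)
            if config.noise_sd > 0:
                M = M + rng.normal(0.0, config.noise_sd, size=n_spots)

            sig1 = np.exp2(A + M / 2.0)
            sig2 = np.exp2(A - M / 2.0)
            bg1 = config.background_level * rng.uniform(0.9, 1.1, size=n_spots)
            bg2 = config.background_level * rng.uniform(0.9, 1.1, size=n_spots)

            slides.append(SlideTable(
                slide_id=slide_id,
                data=pd.DataFrame({
                    "spot_id": spot_ids,
                    "gene_id": genes[gene_of_spot],
                    "ch1_fg": sig1 + bg1,
                    "ch1_bg": bg1,
                    "ch2_fg": sig2 + bg2,
                    "ch2_bg": bg2,
                }),
            ))
            design_rows.append({
                "slide_id": slide_id,
                "patient_id": patient_id,
                "pair_id": pair_id,
                "orientation": orientation,
            })

    design = ExperimentDesign(data=pd.DataFrame(design_rows))
    return slides, design, truth


def simulate_gene_sets(
    genes: np.ndarray | list[str],
    truth: GroundTruth,
    n_sets: int = 10,
    set_size: int = 40,
    enriched_sets: int = 2,
    enriched_fraction: float = 0.5,
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic flat gene-set annotations for enrichment testing.

    ``enriched_sets`` sets draw ``enriched_fraction`` of their members from
    the planted DE genes (so over-representation is detectable); remaining
    sets are uniform draws from all genes.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(genes)
    de = np.array(sorted(truth.de_genes))
    coll = GeneSetCollection()
    for i in range(n_sets):
        if i < enriched_sets and de.size > 0:
            n_de = min(int(round(set_size * enriched_fraction)), de.size)
            members = list(rng.choice(de, size=n_de, replace=False))
            rest = rng.choice(
                np.setdiff1d(genes, de), size=set_size - n_de, replace=False
            )
            members.extend(rest)
            desc = "synthetic set enriched in planted DE genes"
        else:
            members = list(rng.choice(genes, size=min(set_size, genes.size),
                                      replace=False))
            desc = "synthetic random set"
        coll[f"SET{i + 1:02d}"] = GeneSet(
            description=desc, members=sorted(dict.fromkeys(members))
        )
    return coll


def write_ground_truth(truth: GroundTruth, genes, path) -> None:
    """Ground-truth TSV: gene_id, truth_class."""
    rows = [{"gene_id": g, "truth_class": truth.truth_class(g)} for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_experiment(
    outdir: str | Path,
    slides: list[SlideTable],
    design: ExperimentDesign,
    truth: GroundTruth,
    gene_sets: GeneSetCollection | None = None,
) -> None:
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for slide in slides:
        _io.write_slide_table(slide, outdir / f"{slide.slide_id}.tsv")
    _io.write_design(design, outdir / "design.tsv")
    genes = sorted(set(slides[0].data["gene_id"]))
    write_ground_truth(truth, genes, outdir / "truth.tsv")
    if gene_sets is not None:
        _io.write_gene_sets(gene_sets, outdir / "gene_sets.gmt")
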