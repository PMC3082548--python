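"""Per-slide spot quality filtering and intensity balancing.

Two stages, applied independently to every hybridization:

1. *Low-intensity removal.* Working intensities (foreground minus background,
   floored at 1, or raw foreground if background subtraction is disabled) are
   log2-transformed and z-scored per channel; a spot is flagged when its
   z-score falls below the threshold in either channel. Flagged spots take no
   part in normalization or any later stage of that slide.
2. *LOWESS balancing.* The intensity-dependent dye bias shows up as a trend of
   M = log2(ch1'/ch2') on A = (log2 ch1' + log2 ch2')/2. A robust local
   linear fit of M on A over the surviving spots is subtracted
   (M_norm = M_raw - fit(A)). Outlying spots are handled by the robust
   reweighting of the fit itself (``outlier_policy="downweight"``, the
   default): they cannot drag the bias curve but keep their normalized value,
   so genuinely regulated genes — which *are* M outliers — survive. The
   stricter ``outlier_policy="discard"`` additionally flags spots whose final
   residual exceeds ``outlier_k`` robust standard deviations and withholds
   their M_norm.

Spots are only ever flagged, never deleted, so provenance stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import PipelineError
from .io import SlideTable

NORMALIZED_COLUMNS = [
    "spot_id", "gene_id", "A", "M_raw", "M_norm",
    "low_intensity", "lowess_outlier",
]


@dataclass
class NormalizedSlide:
    """Outcome of filtering + balancing one slide.

    ``data`` has one row per spot: spot_id, gene_id, A, M_raw, M_norm and the
    boolean flags ``low_intensity`` and ``lowess_outlier``. ``M_norm`` is NaN
    wherever any flag is set.
    """

    slide_id: str
    data: pd.DataFrame

    @property
    def unflagged(self) -> pd.DataFrame:
        keep = ~(self.data["low_intensity"] | self.data["lowess_outlier"])
        return self.data.loc[keep]


def working_intensities(
    slide: SlideTable, background: str = "subtract", floor: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Channel intensities after the background policy.

    ``background="subtract"`` uses max(fg - bg, floor); ``"ignore"`` uses the
    raw foreground floored at the same value. The floor keeps logs finite.
    """
    if background not in ("subtract", "ignore"):
        raise ValueError(f"unknown background policy {background!r}")
    ch1 = slide.data["ch1_fg"].to_numpy(dtype=float)
    ch2 = slide.data["ch2_fg"].to_numpy(dtype=float)
    if background == "subtract":
        ch1 = ch1 - slide.data["ch1_bg"].to_numpy(dtype=float)
        ch2 = ch2 - slide.data["ch2_bg"].to_numpy(dtype=float)
    return np.maximum(ch1, floor), np.maximum(ch2, floor)


def _zscore(x: np.ndarray) -> np.ndarray:
    # Zero channel variance is degenerate input, not a reason to flag
    # everything: define z = 0 there.
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def filter_low_intensity(
    slide: SlideTable,
    z_threshold: float = -2.0,
    background: str = "subtract",
) -> np.ndarray:
    """Boolean flag per spot: True where the spot is low-intensity.

    A spot is flagged when its per-channel log2 working-intensity z-score is
    below ``z_threshold`` in either channel ("removed from both channels"
    means the spot is dropped entirely as soon as one channel is dim).
    """
    if slide.n_spots == 0:
        raise PipelineError(f"slide {slide.slide_id!r}: empty slide")
    ch1, ch2 = working_intensities(slide, background=background)
    z1 = _zscore(np.log2(ch1))
    z2 = _zscore(np.log2(ch2))
    flags = (z1 < z_threshold) | (z2 < z_threshold)
    if flags.all():
        raise PipelineError(
            f"slide {slide.slide_id!r}: no spots survive intensity filter"
        )
    return flags


def lowess_normalize(
    slide: SlideTable,
    span: float = 0.3,
    robust_iters: int = 3,
    outlier_k: float = 3.0,
    z_threshold: float = -2.0,
    background: str = "subtract",
    min_spots: int = 30,
    outlier_policy: str = "downweight",
) -> NormalizedSlide:
    """Filter low-intensity spots, then balance M against A with LOWESS.

    Parameters
    ----------
    span : float
        LOWESS smoothing fraction (share of spots in each local window).
    robust_iters : int
        Robustifying reweighting iterations of the local fits.
    outlier_k : float
        Under ``outlier_policy="discard"``, residuals beyond ``outlier_k``
        robust SDs (1.4826 * MAD) flag the spot as a LOWESS outlier and its
        M_norm is withheld. Ignored under ``"downweight"``, where outliers
        are only suppressed inside the robust fit.
    min_spots : int
        Minimum surviving spots required for a trustworthy fit.
    """
    if outlier_policy not in ("downweight", "discard"):
        raise ValueError(f"unknown outlier policy {outlier_policy!r}")
    low = filter_low_intensity(slide, z_threshold=z_threshold,
                               background=background)
    ch1, ch2 = working_intensities(slide, background=background)
    l1, l2 = np.log2(ch1), np.log2(ch2)
    A = (l1 + l2) / 2.0
    M_raw = l1 - l2

    n_ok = int((~low).sum())
    if n_ok < min_spots:
        raise PipelineError(
            f"slide {slide.slide_id!r}: only {n_ok} spots survive the "
            f"intensity filter (< {min_spots})"
        )

    fit = np.full(len(A), np.nan)
    a_ok, m_ok = A[~low], M_raw[~low]
    fitted = _sm_lowess(
        m_ok, a_ok, frac=span, it=robust_iters, return_sorted=False
    )
    if not np.all(np.isfinite(fitted)):
        raise PipelineError(
            f"slide {slide.slide_id!r}: non-finite LOWESS fit"
        )
    fit[~low] = fitted

    resid = M_raw - fit
    outlier = np.zeros(len(A), dtype=bool)
    if outlier_policy == "discard":
        r_ok = resid[~low]
        mad = np.median(np.abs(r_ok - np.median(r_ok)))
        robust_sd = 1.4826 * mad
        if robust_sd == 0:
            robust_sd = float(np.std(r_ok))
        if robust_sd > 0:
            outlier[~low] = np.abs(r_ok) > outlier_k * robust_sd

    M_norm = resid.copy()
    M_norm[low | outlier] = np.nan

    data = pd.DataFrame({
        "spot_id": slide.data["spot_id"].to_numpy(),
        "gene_id": slide.data["gene_id"].to_numpy(),
        "A": A,
        "M_raw": M_raw,
        "M_norm": M_norm,
        "low_intensity": low,
        "lowess_outlier": outlier,
    })
    return NormalizedSlide(slide_id=slide.slide_id, data=data)


def write_normalized(norm: NormalizedSlide, path) -> None:
    norm.data.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_normalized(path, slide_id: str | None = None) -> NormalizedSlide:
    import pathlib

    p = pathlib.Path(path)
    df = pd.read_csv(p, sep="\t", dtype={"spot_id": str, "gene_id": str})
    sid = slide_id if slide_id is not None else p.stem
    return NormalizedSlide(slide_id=sid, data=df)
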