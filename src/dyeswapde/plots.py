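"""Diagnostic plots: MA plots before/after balancing, SAM quantile plot."""

from __future__ import annotations

import numpy as np

from .preprocess import NormalizedSlide


def ma_plot(norm: NormalizedSlide, normalized: bool = True, ax=None):
    """MA scatter of one slide; flagged spots are drawn in their own colors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = norm.data
    y = df["M_norm"] if normalized else df["M_raw"]
    ok = ~(df["low_intensity"] | df["lowess_outlier"])
    ax.scatter(df.loc[ok, "A"], y[ok], s=4, alpha=0.5, label="spots")
    ax.scatter(df.loc[df["low_intensity"], "A"],
               df.loc[df["low_intensity"], "M_raw"],
               s=6, color="tab:orange", label="low intensity")
    ax.scatter(df.loc[df["lowess_outlier"], "A"],
               df.loc[df["lowess_outlier"], "M_raw"],
               s=6, color="tab:red", label="LOWESS outlier")
    ax.axhline(0.0, color="grey", lw=1)
    ax.set_xlabel("A (mean log2 intensity)")
    ax.set_ylabel("M (normalized)" if normalized else "M (raw)")
    ax.set_title(norm.slide_id)
    ax.legend(loc="best", fontsize="small")
    return ax


def fold_change_concordance_plot(fc_array, fc_qpcr, ax=None):
    """Microarray-vs-qPCR log2 fold-change scatter with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = np.log2(np.asarray(fc_array)), np.log2(np.asarray(fc_qpcr))
    ax.scatter(x, y, s=15)
    lim = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lim, lim, color="grey", lw=1)
    ax.set_xlabel("microarray log2 fold change")
    ax.set_ylabel("qPCR log2 fold change")
    return ax
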