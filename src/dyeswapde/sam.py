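"""One-class Significance Analysis of Microarrays (SAM).

The model tests, per gene, whether the mean log2 ratio across replicates
(patients) differs from zero. Each gene is graded with the relative
difference

    d = x_bar / (se + s0)

where ``x_bar`` is the replicate mean, ``se`` the standard error
(sample SD / sqrt(n)) and ``s0`` a small "fudge factor" that stabilizes
genes with tiny variance. ``s0`` is chosen (when not fixed by the user) as
the percentile of the se distribution, searched over 0..100 in steps of 5,
that minimizes the coefficient of variation of the spread of d across
se-quantile windows.

The null distribution is generated by sign-flip permutations: every gene's
replicate vector is multiplied by the same +-1 sign vector (the one-class
null hypothesis is mean zero, so signs are exchangeable). With n replicates
there are 2**n sign vectors; they are enumerated exhaustively when feasible
and sampled without replacement otherwise. Expected order statistics are the
permutation means of the sorted d values.

Calling uses the classic asymmetric delta thresholds: sort observed d and
pair with the expected order statistics; for a threshold delta, the upper
cutpoint is the smallest observed d whose displacement above its expected
value reaches delta, the lower cutpoint the largest observed d displaced at
least delta below. Genes beyond the cutpoints are called; the false discovery
rate is the median, across permutations, of permuted d values beyond the
same cutpoints, divided by the number of genes called (0/0 -> 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError, PipelineError

EXHAUSTIVE_CAP = 4096
_S0_PERCENTILES = np.arange(0, 101, 5)


def sam_statistic(
    values: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative difference per gene: (x_bar, se, d) for a genes x n matrix.

    With s0 = 0 this is the classical one-sample t statistic. A zero
    denominator is tolerated only for genes with zero mean (d = 0).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    if n < 2:
        raise PipelineError("SAM needs >= 2 replicates per gene")
    if s0 < 0:
        raise PipelineError("s0 must be >= 0")
    x_bar = values.mean(axis=1)
    se = values.std(axis=1, ddof=1) / np.sqrt(n)
    denom = se + s0
    zero = denom == 0
    if np.any(zero & (x_bar != 0)):
        raise DegenerateStatisticError(
            "se + s0 = 0 with nonzero mean for at least one gene"
        )
    d = np.zeros_like(x_bar)
    np.divide(x_bar, denom, out=d, where=~zero)
    return x_bar, se, d


def choose_s0(values: np.ndarray, n_windows: int = 100) -> float:
    """Fudge-factor selection by the coefficient-of-variation criterion.

    Candidates are the 0th..100th percentiles (step 5) of the per-gene
    standard errors. For each candidate, genes are partitioned into
    se-quantile windows; the spread of d within each window is measured by
    MAD/0.64 and the candidate minimizing the coefficient of variation of
    those spreads across windows is chosen (ties -> smallest percentile).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes = values.shape[0]
    if n_genes < 2:
        raise PipelineError("s0 selection needs >= 2 genes")
    n = values.shape[1]
    x_bar = values.mean(axis=1)
    se = values.std(axis=1, ddof=1) / np.sqrt(n)

    order = np.argsort(se, kind="stable")
    nw = min(n_windows, max(1, n_genes // 2))
    windows = np.array_split(order, nw)
    candidates = np.percentile(se, _S0_PERCENTILES)

    best_s0, best_cv = float(candidates[0]), np.inf
    for cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(se + cand > 0, x_bar / (se + cand), 0.0)
        spreads = []
        for w in windows:
            dw = d[w]
            spreads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        spreads = np.asarray(spreads)
        mean_spread = spreads.mean()
        cv = 0.0 if mean_spread == 0 else spreads.std(ddof=0) / mean_spread
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


@dataclass
class PermutationNull:
    """Sign-flip null: per-permutation d values and expected order statistics."""

    signs: np.ndarray        # B x n matrix of +-1
    d_perm_sorted: np.ndarray  # B x G, each row sorted ascending
    expected: np.ndarray     # length G: mean over rows of d_perm_sorted
    exhaustive: bool


def _all_sign_vectors(n: int) -> np.ndarray:
    idx = np.arange(2 ** n)
    bits = (idx[:, None] >> np.arange(n)[None, :]) & 1
    return 1 - 2 * bits  # 0 -> +1, 1 -> -1


def permutation_null(
    values: np.ndarray,
    s0: float,
    permutations: int | str = "exhaustive",
    seed: int | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationNull:
    """Expected order statistics of d under random sign flips.

    ``permutations="exhaustive"`` enumerates all 2**n sign vectors (allowed
    while 2**n <= ``exhaustive_cap``); an integer requests that many sampled
    sign vectors (without replacement while the pool allows, otherwise
    uniform draws) with the given seed.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    total = 2 ** n
    if permutations == "exhaustive":
        if total > exhaustive_cap:
            raise PipelineError(
                f"exhaustive enumeration of {total} sign vectors exceeds the "
                f"cap ({exhaustive_cap}); pass an integer count instead"
            )
        signs = _all_sign_vectors(n)
        exhaustive = True
    else:
        n_perm = int(permutations)
        if n_perm < 1:
            raise PipelineError("number of permutations must be >= 1")
        rng = np.random.default_rng(seed)
        if total <= 2 ** 20:
            chosen = rng.choice(total, size=n_perm,
                                replace=n_perm > total)
            bits = (chosen[:, None] >> np.arange(n)[None, :]) & 1
            signs = 1 - 2 * bits
        else:
            signs = rng.choice([-1, 1], size=(n_perm, n))
        exhaustive = False

    d_rows = np.empty((signs.shape[0], values.shape[0]))
    for b, s in enumerate(signs):
        _, _, d_rows[b] = sam_statistic(values * s[None, :], s0)
    d_rows.sort(axis=1)
    return PermutationNull(
        signs=signs,
        d_perm_sorted=d_rows,
        expected=d_rows.mean(axis=0),
        exhaustive=exhaustive,
    )


def _cutpoints(
    d_sorted: np.ndarray, expected: np.ndarray, delta: float
) -> tuple[float, float]:
    """Asymmetric cut thresholds for one delta.

    Upper cutpoint: smallest observed (sorted) d with d - expected >= delta;
    lower cutpoint: largest observed d with expected - d >= delta. +-inf when
    no gene qualifies on that side.
    """
    diffs = d_sorted - expected
    up_idx = np.nonzero(diffs >= delta)[0]
    lo_idx = np.nonzero(diffs <= -delta)[0]
    cut_up = d_sorted[up_idx].min() if up_idx.size else np.inf
    cut_low = d_sorted[lo_idx].max() if lo_idx.size else -np.inf
    return float(cut_up), float(cut_low)


def fdr_table(
    d: np.ndarray,
    null: PermutationNull,
    deltas: np.ndarray | None = None,
    pi0: float = 1.0,
) -> pd.DataFrame:
    """Delta / number called / median false calls / FDR table.

    ``deltas=None`` uses every achieved displacement |d_(i) - expected_(i)|
    (plus 0), so the exact smallest delta attaining any given FDR is always a
    candidate. FDR = pi0 * median false calls / n_called, clamped to [0, 1],
    with the 0/0 -> 0 convention.
    """
    d = np.asarray(d, dtype=float)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    expected = null.expected
    if deltas is None:
        diffs = np.abs(d_sorted - expected)
        deltas = np.unique(np.concatenate([[0.0], diffs]))
    else:
        deltas = np.asarray(deltas, dtype=float)
        if deltas.size == 0:
            raise PipelineError("empty delta list")

    perm = null.d_perm_sorted  # rows sorted ascending
    B, G = perm.shape
    cuts = np.array([_cutpoints(d_sorted, expected, float(dl)) for dl in deltas])
    cut_up, cut_low = cuts[:, 0], cuts[:, 1]

    n_called = np.array([
        int(((d_sorted >= cu) | (d_sorted <= cl)).sum())
        for cu, cl in zip(cut_up, cut_low)
    ])
    # Rows are sorted, so counts beyond the cutpoints come from searchsorted
    # (inf / -inf cutpoints yield zero counts automatically). At tiny deltas
    # the two cut regions can overlap; capping at G counts each gene once.
    false_calls = np.empty((B, len(deltas)))
    for b in range(B):
        up = G - np.searchsorted(perm[b], cut_up, side="left")
        lo = np.searchsorted(perm[b], cut_low, side="right")
        false_calls[b] = np.minimum(up + lo, G)
    median_false = np.median(false_calls, axis=0) if B else np.zeros(len(deltas))

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            n_called > 0,
            np.clip(pi0 * median_false / np.maximum(n_called, 1), 0.0, 1.0),
            0.0,
        )
    return pd.DataFrame({
        "delta": deltas,
        "n_called": n_called,
        "median_false": median_false,
        "fdr": fdr,
        "cut_up": cut_up,
        "cut_low": cut_low,
    })


def call_genes(
    delta_table: pd.DataFrame,
    d: np.ndarray,
    gene_ids: np.ndarray,
    fdr_max: float = 0.0,
) -> pd.DataFrame:
    """Called genes at the smallest delta whose FDR meets ``fdr_max``.

    Returns a DataFrame (gene_id, d, direction); empty with a warning when no
    delta qualifies. Direction is the sign of d.
    """
    ok = delta_table.loc[delta_table["fdr"] <= fdr_max]
    ok = ok.loc[ok["n_called"] > 0]
    if ok.empty:
        warnings.warn(
            f"no delta reaches FDR <= {fdr_max}; empty call set",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["gene_id", "d", "direction"])
    row = ok.sort_values("delta").iloc[0]
    d = np.asarray(d, dtype=float)
    called = (d >= row["cut_up"]) | (d <= row["cut_low"])
    out = pd.DataFrame({
        "gene_id": np.asarray(gene_ids)[called],
        "d": d[called],
    })
    out["direction"] = np.where(out["d"] > 0, "up", "down")
    return out.sort_values("d", ascending=False).reset_index(drop=True)


class SAMOneClass:
    """One-class SAM model over a genes x replicates matrix.

    Parameters
    ----------
    data : DataFrame or array
        Per-gene replicate values (summarized log2 patient/reference ratios;
        rows = genes, columns = replicates). A DataFrame index supplies gene
        ids; otherwise pass ``gene_ids``.

    Examples
    --------
    >>> model = SAMOneClass(matrix)
    >>> res = model.fit(s0="auto", permutations="exhaustive", fdr_max=0.0)
    >>> res.called  # doctest: +SKIP
    """

    def __init__(self, data, gene_ids=None):
        if isinstance(data, pd.DataFrame):
            self.values = data.to_numpy(dtype=float)
            self.gene_ids = data.index.to_numpy()
        else:
            self.values = np.atleast_2d(np.asarray(data, dtype=float))
            self.gene_ids = (
                np.asarray(gene_ids) if gene_ids is not None
                else np.arange(self.values.shape[0])
            )
        if not np.all(np.isfinite(self.values)):
            raise PipelineError("SAM input contains non-finite values")
        if self.values.shape[1] < 2:
            raise PipelineError("SAM needs >= 2 replicates")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def fit(
        self,
        s0: float | str = "auto",
        permutations: int | str = "exhaustive",
        seed: int | None = None,
        deltas=None,
        fdr_max: float = 0.0,
        pi0: float = 1.0,
    ) -> "SAMResults":
        if s0 == "auto":
            s0_value = choose_s0(self.values)
        else:
            s0_value = float(s0)
            if s0_value < 0:
                raise PipelineError("s0 must be >= 0")
        x_bar, se, d = sam_statistic(self.values, s0_value)
        null = permutation_null(
            self.values, s0_value, permutations=permutations, seed=seed
        )
        table = fdr_table(d, null, deltas=deltas, pi0=pi0)
        called = call_genes(table, d, self.gene_ids, fdr_max=fdr_max)
        return SAMResults(
            model=self, s0=s0_value, x_bar=x_bar, se=se, d=d, null=null,
            delta_table=table, called=called, fdr_max=fdr_max,
        )


@dataclass
class SAMResults:
    """Fitted one-class SAM: statistics, null, delta table and call set."""

    model: SAMOneClass
    s0: float
    x_bar: np.ndarray
    se: np.ndarray
    d: np.ndarray
    null: PermutationNull
    delta_table: pd.DataFrame
    called: pd.DataFrame
    fdr_max: float
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.model.gene_ids

    @property
    def expected(self) -> np.ndarray:
        return self.null.expected

    @property
    def n_called(self) -> int:
        return len(self.called)

    @property
    def n_up(self) -> int:
        return int((self.called["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.called["direction"] == "down").sum())

    def frame(self) -> pd.DataFrame:
        """Per-gene table: x_bar, se, d, called flag and direction."""
        if self._frame is None:
            df = pd.DataFrame({
                "gene_id": self.gene_ids,
                "x_bar": self.x_bar,
                "se": self.se,
                "d": self.d,
            })
            called_set = set(self.called["gene_id"])
            df["called"] = df["gene_id"].isin(called_set)
            dirmap = dict(zip(self.called["gene_id"], self.called["direction"]))
            df["direction"] = df["gene_id"].map(dirmap).fillna("")
            self._frame = df
        return self._frame

    def summary(self) -> str:
        perm_kind = (
            f"exhaustive ({self.null.signs.shape[0]} sign vectors)"
            if self.null.exhaustive
            else f"sampled ({self.null.signs.shape[0]} sign vectors)"
        )
        lines = [
            "One-class SAM results",
            "=====================",
            f"genes:           {self.model.n_genes}",
            f"replicates:      {self.model.n_replicates}",
            f"s0 (fudge):      {self.s0:.6g}",
            f"permutations:    {perm_kind}",
            f"FDR threshold:   {self.fdr_max:g}",
            f"called:          {self.n_called} "
            f"(up {self.n_up}, down {self.n_down})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed-vs-expected order-statistic (SAM) plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d_sorted = np.sort(self.d)
        ax.scatter(self.expected, d_sorted, s=8, label="genes")
        lim = [min(self.expected.min(), d_sorted.min()),
               max(self.expected.max(), d_sorted.max())]
        ax.plot(lim, lim, color="grey", lw=1, label="identity")
        ax.set_xlabel("expected order statistic")
        ax.set_ylabel("observed d")
        ax.legend()
        return ax

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
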