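"""Adjacent-interval differential expression without replicates.

The study design — one pooled library per timepoint — leaves no within-
condition replication, so dispersion is estimated "blind": all timepoints are
treated as pseudo-replicates of one mean, which is conservative for genuinely
dynamic genes. The per-interval test is a two-sided negative-binomial exact
test conditioning on the (rounded, size-factor-normalized) sum of the two
samples; with dispersion zero it reduces to the conditional binomial test.

A gene is called differential on an interval when |log2 fold change| > 1 and
p < 0.05; the call is encoded U (up), D (down) or M (maintained), the raw
material for trajectory-pattern strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from txdyn.containers import CountMatrix, DE_COLUMNS, DERecord, de_frame
from txdyn.quantify import size_factors as _size_factors

LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05


@dataclass
class DispersionModel:
    """Blind NB dispersion estimates: per-gene alpha and a 1/mu trend.

    sharing controls the working dispersion handed to the test:

    - "fit-only" (default): the fitted trend a0/mu + a1 evaluated at the
      gene's mean. This is the standard choice for designs without
      replicates — a gene's own across-timepoint variance contains its
      biological signal, so the per-gene estimate of a genuinely dynamic
      gene is self-inflated and would veto its own call.
    - "maximum": max(alpha_hat_g, trend), the conservative variant; stricter
      type-I control, near-zero power on strongly dynamic genes.
    """

    alpha_hat: pd.Series
    mean: pd.Series
    a0: float
    a1: float
    sharing: str = "fit-only"

    def trend(self, mu: np.ndarray | float) -> np.ndarray | float:
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
        return np.maximum(self.a0 / mu + self.a1, 0.0)

    @property
    def working(self) -> pd.Series:
        trend = self.trend(self.mean.to_numpy())
        if self.sharing == "fit-only":
            w = trend
        elif self.sharing == "maximum":
            w = np.maximum(self.alpha_hat.to_numpy(), trend)
        else:
            raise ValueError(f"unknown sharing mode {self.sharing!r}")
        return pd.Series(w, index=self.alpha_hat.index, name="working_dispersion")


def _trend_fit(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha(mu) = a0/mu + a1 by iteratively trimmed least squares.

    Method-of-moments alpha estimates are heavy-tailed (dynamic genes inflate
    them), so a plain least-squares trend would be dragged upward; two rounds
    of trimming at 3 MAD of the residual give a resistant fit. Coefficients
    are clipped to be non-negative.
    """
    x = np.column_stack([1.0 / mu, np.ones_like(mu)])
    keep = np.ones(len(mu), dtype=bool)
    coef = np.zeros(2)
    for _ in range(3):
        res = optimize.nnls(x[keep], alpha[keep])
        coef = res[0]
        resid = alpha - x @ coef
        center = np.median(resid)
        mad = np.median(np.abs(resid - center))
        scale = max(1.4826 * mad, 1e-12)
        keep = np.abs(resid - center) <= 3.0 * scale
        if keep.sum() < 3:
            break
    return float(coef[0]), float(coef[1])


def fit_dispersion_blind(
    counts: CountMatrix, sf: Optional[pd.Series] = None, sharing: str = "fit-only"
) -> DispersionModel:
    """Method-of-moments dispersion across all timepoints, plus a 1/mu trend.

    alpha_hat_g = max(0, (s^2 - mu) / mu^2) on normalized counts; the trend
    alpha(mu) = a0/mu + a1 is fitted over genes with positive mean.
    """
    if len(counts.samples) < 3:
        raise ValueError("blind dispersion needs >= 3 samples")
    if sf is None:
        sf = _size_factors(counts)
    norm = counts.counts.div(sf, axis=1).to_numpy(dtype=float)
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, np.maximum((s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0), 0.0)
    positive = mu > 0
    if positive.sum() >= 3:
        a0, a1 = _trend_fit(mu[positive], alpha[positive])
    else:
        a0, a1 = 0.0, float(np.median(alpha[positive])) if positive.any() else 0.0
    index = counts.genes
    return DispersionModel(
        alpha_hat=pd.Series(alpha, index=index, name="alpha_hat"),
        mean=pd.Series(mu, index=index, name="mean"),
        a0=a0,
        a1=a1,
        sharing=sharing,
    )


def _conditional_pvalue(ka: int, kb: int, alpha: float) -> float:
    """Two-sided exact test of ka vs kb conditioning on their sum.

    Both samples are modelled with common mean (ka+kb)/2 and dispersion
    alpha; the p-value is the total conditional probability of outcomes no
    more probable than the observed split (ties included in the rejection
    mass). alpha = 0 uses Poisson components, i.e. a binomial(N, 1/2) split.
    """
    n = ka + kb
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    m = n / 2.0
    if alpha <= 0:
        logp = stats.poisson.logpmf(k, m)
    else:
        r = 1.0 / alpha
        logp = stats.nbinom.logpmf(k, r, r / (r + m))
    joint = logp + logp[::-1]
    joint -= joint.max()
    w = np.exp(joint)
    obs = w[ka]
    # small tolerance so symmetric ties are always included
    p = w[w <= obs * (1 + 1e-12)].sum() / w.sum()
    return float(min(p, 1.0))


def _status(log2fc: float, p: float) -> str:
    if p < P_THRESHOLD and log2fc > LOG2FC_THRESHOLD:
        return "U"
    if p < P_THRESHOLD and log2fc < -LOG2FC_THRESHOLD:
        return "D"
    return "M"


def test_adjacent(
    counts: CountMatrix,
    sf: pd.Series,
    model: DispersionModel,
    t: int,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """NB exact test of adjacent timepoints t and t+1 for every gene.

    log2fc = log2((n_B + c) / (n_A + c)) on size-factor-normalized counts
    with pseudocount c; p conditions on the rounded normalized sum with the
    gene's working dispersion. Returns a frame with columns gene, interval,
    log2fc, p_value, status.
    """
    if not 0 <= t < counts.n_intervals:
        raise ValueError(
            f"interval index {t} does not address two adjacent samples "
            f"(valid range 0..{counts.n_intervals - 1})"
        )
    label = counts.interval_label(t)
    sa, sb = counts.samples[t], counts.samples[t + 1]
    na = counts.counts[sa].to_numpy(dtype=float) / float(sf[sa])
    nb = counts.counts[sb].to_numpy(dtype=float) / float(sf[sb])
    working = model.working.reindex(counts.genes).to_numpy()

    log2fc = np.log2((nb + pseudocount) / (na + pseudocount))
    records = []
    for gene, a, b, fc, alpha in zip(counts.genes, na, nb, log2fc, working):
        p = _conditional_pvalue(int(round(a)), int(round(b)), float(alpha))
        records.append(DERecord(str(gene), label, float(fc), p, _status(float(fc), p)))
    return de_frame(records)


def test_all_adjacent(
    counts: CountMatrix,
    sf: Optional[pd.Series] = None,
    model: Optional[DispersionModel] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Run the adjacent-interval test on every consecutive pair of samples."""
    if sf is None:
        sf = _size_factors(counts)
    if model is None:
        model = fit_dispersion_blind(counts, sf)
    frames = [
        test_adjacent(counts, sf, model, t, pseudocount=pseudocount)
        for t in range(counts.n_intervals)
    ]
    return pd.concat(frames, ignore_index=True) if frames else de_frame([])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default in calls)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    cummin = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        cummin = min(cummin, p[i] * n / (rank + 1))
        adj[i] = cummin
    return adj


def deg_table(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate DE calls: up/down/total per interval, plus a grand total row.

    If the record frame carries an 'rna_class' column the grouping is
    (rna_class, interval) with per-class subtotals; the final 'all' row is
    the grand total either way. up + down = total on every row; totals are
    exactly additive (a gene differential on several intervals counts once
    per interval, matching per-interval DEG tallies).
    """
    group_cols = ["rna_class", "interval"] if "rna_class" in records.columns else ["interval"]
    if records.empty:
        idx = pd.Index(["all"], name=" / ".join(group_cols))
        return pd.DataFrame({"up": [0], "down": [0], "total": [0]}, index=idx)
    rows = []
    for key, grp in records.groupby(group_cols, sort=False):
        label = key if isinstance(key, str) else " / ".join(map(str, key))
        up = int((grp["status"] == "U").sum())
        down = int((grp["status"] == "D").sum())
        rows.append([label, up, down, up + down])
    table = pd.DataFrame(rows, columns=["group", "up", "down", "total"]).set_index("group")
    if "rna_class" in records.columns:
        for cls, grp in records.groupby("rna_class", sort=False):
            up = int((grp["status"] == "U").sum())
            down = int((grp["status"] == "D").sum())
            table.loc[f"{cls} / all"] = [up, down, up + down]
    all_up = int((records["status"] == "U").sum())
    all_down = int((records["status"] == "D").sum())
    table.loc["all"] = [all_up, all_down, all_up + all_down]
    table.index.name = " / ".join(group_cols)
    return table
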