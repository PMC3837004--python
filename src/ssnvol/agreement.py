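"""Method- and observer-agreement statistics for paired nodule measurements.

Implements the standard protocol for comparing two measurement methods on
the same lesions: Bland–Altman analysis (mean difference, SD of differences,
95% limits of agreement = mean ± 1.96 SD, and relative differences), paired
t-tests, and the intraclass correlation coefficient.  The default ICC form
is ICC(2,1) — two-way random effects, absolute agreement, single measure —
appropriate when interchangeable observers make absolute measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AgreementResult:
    """Bland–Altman + paired-t + ICC summary for one column pair."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_relative_diff_pct: float
    t_stat: float
    p_value: float
    icc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be equal-length vectors, got {a.shape} vs {b.shape}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values are not allowed in a compared pair")
    return a, b


def relative_differences(a, b, denom: str = "mean") -> np.ndarray:
    """Per-pair relative difference in %: 100 (a-b) / denominator.

    ``denom='mean'`` uses the pair mean (the Bland–Altman convention);
    ``denom='first'`` uses ``a``.
    """
    a, b = _as_arrays(a, b)
    if denom == "mean":
        base = (a + b) / 2.0
    elif denom == "first":
        base = a
    else:
        raise ValueError("denom must be 'mean' or 'first'")
    if np.any(base == 0):
        raise ValueError("zero denominator in relative difference")
    return 100.0 * (a - b) / base


def bland_altman(a, b, rel_denom: str = "mean") -> AgreementResult:
    """Bland–Altman differences, limits of agreement and paired t-test.

    The limits of agreement use the fixed 1.96 multiplier; the SD of
    differences is the sample SD (n-1 denominator).
    """
    a, b = _as_arrays(a, b)
    n = len(a)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    rel = relative_differences(a, b, denom=rel_denom)
    t, p = paired_t(a, b)
    return AgreementResult(
        n=n,
        mean_diff=mean_d,
        sd_diff=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        mean_relative_diff_pct=float(rel.mean()),
        t_stat=t,
        p_value=p,
    )


def paired_t(a, b) -> tuple[float, float]:
    """Paired t-test: t = mean(d) / (SD(d)/sqrt(n)), two-sided p, df = n-1.

    Degenerate cases: zero-variance nonzero differences give t = ±inf, p = 0;
    identical vectors give t = 0, p = 1.
    """
    a, b = _as_arrays(a, b)
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), min(p, 1.0)


def icc(ratings, form: str = "icc2") -> float:
    """Intraclass correlation from a (targets x raters) matrix.

    Forms (Shrout & Fleiss nomenclature, all single-measure):

    * ``icc1``  — one-way random effects, ICC(1,1)
    * ``icc2``  — two-way random effects, absolute agreement, ICC(2,1) (default)
    * ``icc3``  — two-way mixed effects, consistency, ICC(3,1)

    Computed from the two-way ANOVA mean squares: with n targets and k raters,
    MS_R (rows/targets), MS_C (columns/raters) and MS_E (residual),

        ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D targets x raters matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 targets and >= 2 raters, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("no variance in ratings")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "icc2":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    elif form == "icc3":
        denom = ms_r + (k - 1) * ms_e
    elif form == "icc1":
        ms_w = (ss_cols + ss_err) / (n * (k - 1))
        denom = ms_r + (k - 1) * ms_w
        return float((ms_r - ms_w) / denom)
    else:
        raise ValueError("form must be one of 'icc1', 'icc2', 'icc3'")
    if denom == 0:
        raise ValueError("no variance in ratings")
    return float((ms_r - ms_e) / denom)


# ---------------------------------------------------------------------------
# table-level comparison


def load_table(path: str | Path) -> pd.DataFrame:
    """One row per nodule, one column per method/observer/reading."""
    df = pd.read_csv(path)
    if df.shape[0] < 3:
        raise ValueError("measurement table needs at least 3 nodules (rows)")
    return df


def compare_methods(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    rel_denom: str = "mean",
    icc_form: str = "icc2",
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Agreement statistics for each named column pair of a measurement table.

    Returns a tidy DataFrame, one row per pair, with Bland–Altman statistics,
    paired-t results and the pairwise ICC.  Optionally writes a Bland–Altman
    plot (relative difference vs pair mean with limits of agreement) per pair
    into a single figure.
    """
    for a_col, b_col in pairs:
        for col in (a_col, b_col):
            if col not in table.columns:
                raise KeyError(
                    f"unknown column {col!r}; available: {list(table.columns)}"
                )
    rows = []
    for a_col, b_col in pairs:
        a = table[a_col].to_numpy(dtype=float)
        b = table[b_col].to_numpy(dtype=float)
        res = bland_altman(a, b, rel_denom=rel_denom)
        res.icc = icc(np.column_stack([a, b]), form=icc_form)
        rows.append({"pair": f"{a_col} vs {b_col}", **res.to_dict()})
    report = pd.DataFrame(rows)
    if plot_path is not None:
        _plot_bland_altman(table, pairs, rel_denom, plot_path)
    return report


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(orient="records"), indent=2) + "\n")
    else:
        report.to_csv(path, index=False)


def _plot_bland_altman(table, pairs, rel_denom, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(pairs), figsize=(4.5 * len(pairs), 4), squeeze=False)
    for ax, (a_col, b_col) in zip(axes[0], pairs):
        a = table[a_col].to_numpy(dtype=float)
        b = table[b_col].to_numpy(dtype=float)
        rel = relative_differences(a, b, denom=rel_denom)
        mean_ab = (a + b) / 2.0
        m, s = rel.mean(), rel.std(ddof=1)
        ax.scatter(mean_ab, rel, s=12, alpha=0.7)
        ax.axhline(m, color="k", lw=1)
        for lim in (m - 1.96 * s, m + 1.96 * s):
            ax.axhline(lim, color="k", lw=1, ls="--")
        ax.set_xlabel(f"mean of {a_col}, {b_col}")
        ax.set_ylabel("relative difference (%)")
        ax.set_title(f"{a_col} vs {b_col}")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
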