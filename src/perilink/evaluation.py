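"""Linkage-error quantification and data-quality reports.

The confusion quantities for a linkage run are derived from five known
counts: the total number of row pairs N = n_cohort × n_episodes, the
number of linked pairs L (retained above the threshold), the number of
true matches TP confirmed among them, and the maximum number of matches M
(by default the cohort register's size — the ceiling on how many true
pairs can exist).  From these,

    FP = L − TP,   FN = M − TP,   TN = N − L − FN,

giving sensitivity TP/M, PPV TP/L, specificity TN/(TN+FP) and NPV
TN/(TN+FN).  With N in the hundreds of millions and L in the thousands,
specificity and NPV are 1.0 to any printed precision; sensitivity and PPV
carry the information.

Also here: the birthweight × gestational-age concordance cross-tab that
flags clinically implausible combinations, and the between-epoch
birth-count change report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from perilink.records import RecordSet


@dataclass(frozen=True)
class ErrorCells:
    """Confusion quantities for one linkage run (all non-negative)."""

    total_pairs: int      # N
    linked: int           # L
    true_links: int       # TP
    max_matches: int      # M
    false_links: int      # FP = L - TP
    false_nonlinks: int   # FN = M - TP
    true_nonmatches: int  # TN = N - L - FN

    def __post_init__(self) -> None:
        checks = {
            "TP + FP == L": self.true_links + self.false_links == self.linked,
            "TP + FN == M": self.true_links + self.false_nonlinks == self.max_matches,
            "L + FN + TN == N": self.linked + self.false_nonlinks + self.true_nonmatches
            == self.total_pairs,
        }
        failed = [k for k, ok in checks.items() if not ok]
        if failed:
            raise ValueError(f"error-cell identities violated: {failed}")
        negative = [
            f
            for f in (
                "total_pairs",
                "linked",
                "true_links",
                "max_matches",
                "false_links",
                "false_nonlinks",
                "true_nonmatches",
            )
            if getattr(self, f) < 0
        ]
        if negative:
            raise ValueError(f"negative error cell(s): {negative}")


def error_cells(
    n_cohort: int,
    n_episodes: int,
    linked: int,
    true_links: int,
    max_matches: int | None = None,
) -> ErrorCells:
    """Derive the full confusion table from the known counts.

    ``max_matches`` defaults to ``n_cohort`` — the cohort register is the
    smaller, fully-enumerated side, so it bounds the true matches.
    """
    if max_matches is None:
        max_matches = n_cohort
    N = n_cohort * n_episodes
    if true_links > min(linked, max_matches):
        raise ValueError(
            f"true_links={true_links} exceeds linked={linked} or max_matches={max_matches}"
        )
    if linked > N:
        raise ValueError(f"linked={linked} exceeds total pairs N={N}")
    fp = linked - true_links
    fn = max_matches - true_links
    tn = N - linked - fn
    return ErrorCells(
        total_pairs=N,
        linked=linked,
        true_links=true_links,
        max_matches=max_matches,
        false_links=fp,
        false_nonlinks=fn,
        true_nonmatches=tn,
    )


@dataclass(frozen=True)
class LinkageMetrics:
    """Sensitivity, specificity, PPV and NPV of one linkage run.

    ``ppv`` is NaN when no pairs were linked (undefined ratio).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, ndigits: int = 3) -> "LinkageMetrics":
        rnd = lambda v: float("nan") if np.isnan(v) else round(v, ndigits)
        return LinkageMetrics(
            rnd(self.sensitivity), rnd(self.specificity), rnd(self.ppv), rnd(self.npv)
        )


def linkage_metrics(cells: ErrorCells) -> LinkageMetrics:
    """The four accuracy ratios from a confusion table."""
    if cells.max_matches <= 0:
        raise ValueError("max_matches must be positive")
    sens = cells.true_links / cells.max_matches
    ppv = cells.true_links / cells.linked if cells.linked > 0 else float("nan")
    tn = cells.true_nonmatches
    spec = tn / (tn + cells.false_links) if tn + cells.false_links > 0 else float("nan")
    npv = tn / (tn + cells.false_nonlinks) if tn + cells.false_nonlinks > 0 else float("nan")
    return LinkageMetrics(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv)


# ---------------------------------------------------------------------------
# Data quality: birthweight × gestational age concordance
# ---------------------------------------------------------------------------

#: Default bin edges: birth weight in 500 g bands, gestational age by week
#: to 25 then grouped, mirroring how routine perinatal data are audited.
DEFAULT_WEIGHT_BINS = [0, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000, np.inf]
DEFAULT_GA_BINS = [20, 21, 22, 23, 24, 25, 26, 30, 35, 40, np.inf]

#: For each low-birthweight band, the gestational ages that are clinically
#: plausible; combinations outside the set are flagged.  Supplied as
#: configuration — the default flags term gestations recorded with a birth
#: weight under 500 g.
DEFAULT_PLAUSIBILITY = {"[0, 500)": ("[35, 40)", "[40, inf)")}


def _bin_labels(edges) -> list[str]:
    return [
        f"[{int(a) if np.isfinite(a) else a}, {int(b) if np.isfinite(b) else 'inf'})"
        for a, b in zip(edges[:-1], edges[1:])
    ]


def concordance_table(
    rs: RecordSet,
    weight_bins=DEFAULT_WEIGHT_BINS,
    ga_bins=DEFAULT_GA_BINS,
    implausible_map: dict | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-tabulate birth weight against gestational age.

    Returns the count table (rows: weight bins plus ``missing``; columns:
    GA bins plus ``missing`` and ``total``) and, per weight bin, the
    proportion of the row's records (including those with missing GA)
    falling in the implausible GA bins named by ``implausible_map``
    (weight-bin label → tuple of GA-bin labels).
    """
    if implausible_map is None:
        implausible_map = DEFAULT_PLAUSIBILITY
    w_labels = _bin_labels(weight_bins)
    g_labels = _bin_labels(ga_bins)
    bw = pd.cut(
        pd.to_numeric(rs.df.get("birth_weight"), errors="coerce"),
        bins=weight_bins, right=False, labels=w_labels,
    ).astype(object)
    ga = pd.cut(
        pd.to_numeric(rs.df.get("gestational_age"), errors="coerce"),
        bins=ga_bins, right=False, labels=g_labels,
    ).astype(object)
    bw = pd.Series(bw).fillna("missing")
    ga = pd.Series(ga).fillna("missing")
    tab = pd.crosstab(bw, ga).reindex(
        index=w_labels + ["missing"], columns=g_labels + ["missing"], fill_value=0
    )
    tab["total"] = tab.sum(axis=1)

    flagged = {}
    for w in tab.index:
        bad_cols = [c for c in implausible_map.get(w, ()) if c in tab.columns]
        total = tab.loc[w, "total"]
        flagged[w] = float(tab.loc[w, bad_cols].sum() / total) if total else 0.0
    return tab, pd.Series(flagged, name="implausible_proportion")


def implausibility_flags(rs: RecordSet) -> pd.Series:
    """Boolean per record: birth weight < 500 g recorded at ≥ 35 weeks.

    The specific joint region the synthetic discordance injector writes
    and the concordance audit highlights.
    """
    bw = pd.to_numeric(rs.df.get("birth_weight"), errors="coerce")
    ga = pd.to_numeric(rs.df.get("gestational_age"), errors="coerce")
    return ((bw < 500) & (ga >= 35)).fillna(False)


# ---------------------------------------------------------------------------
# Population change between epochs
# ---------------------------------------------------------------------------


def population_change(
    counts_epoch1: tuple[int, int, int], counts_epoch2: tuple[int, int, int]
) -> dict:
    """Percent change in births between two epochs.

    Each argument is (live, still, unknown) counts.  Returns the totals,
    the percentage change of the total and of live births (1 dp), the
    latter NaN when its epoch-1 denominator is zero.
    """
    t1, t2 = sum(counts_epoch1), sum(counts_epoch2)
    if t1 <= 0:
        raise ValueError("epoch-1 total must be positive")
    live1, live2 = counts_epoch1[0], counts_epoch2[0]
    total_change = round(100.0 * (t2 - t1) / t1, 1)
    live_change = (
        round(100.0 * (live2 - live1) / live1, 1) if live1 > 0 else float("nan")
    )
    return {
        "total_epoch1": t1,
        "total_epoch2": t2,
        "total_pct_change": total_change,
        "live_epoch1": live1,
        "live_epoch2": live2,
        "live_pct_change": live_change,
    }


def vital_counts(rs: RecordSet) -> tuple[int, int, int]:
    """(live, still, unknown) counts from a register's vital_status."""
    vs = rs.df.get("vital_status")
    if vs is None:
        raise ValueError("register has no vital_status field")
    counts = vs.value_counts(dropna=False)
    live = int(counts.get("live", 0))
    still = int(counts.get("still", 0))
    unknown = int(len(rs) - live - still)
    return live, still, unknown


def plot_weight_density(scored_runs: dict, path) -> None:
    """Kernel-density plot of pair weights per algorithm (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(scored_runs), figsize=(4 * len(scored_runs), 3))
    if len(scored_runs) == 1:
        axes = [axes]
    for ax, (name, df) in zip(axes, scored_runs.items()):
        df["weight"].plot.kde(ax=ax)
        ax.set_title(name)
        ax.set_xlabel("weight")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
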