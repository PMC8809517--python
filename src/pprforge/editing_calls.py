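"""C-to-U editing detection from strand-specific nucleotide count tables.

Each sample is a per-site table of strand-specific base counts.  At every
reference-C site the treatment and control samples form a 2x2 table
(edited = T reads, unedited = C reads on that strand; A and G reads
reflect other error modes and are excluded).  Sites are tested with a
two-sided Fisher exact test, adjusted across all tested sites with the
Simes-Hochberg step-up procedure, and effect sizes are summarised as odds
ratios with a 0.5 pseudocount added to every cell so they stay finite.
Significant sites must clear both the adjusted-p cutoff and a log odds
ratio threshold (natural log, default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COUNT_COLUMNS",
    "OfftargetReport",
    "editing_fraction",
    "fisher_exact_site",
    "hochberg_adjust",
    "odds_ratio_pseudo",
    "call_editing",
    "read_counts_tsv",
    "write_counts_tsv",
]

COUNT_COLUMNS = ["seq_id", "pos0", "strand", "ref", "nA", "nC", "nG", "nT"]


def editing_fraction(edited: int, total: int) -> float:
    """Editing extent as a percentage, reported to two decimals.

    ``edited`` is the number of reads carrying the edited base (T at a
    reference C), ``total`` the number of informative reads at the site.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= edited <= total:
        raise ValueError("need 0 <= edited <= total")
    return round(100.0 * edited / total, 2)


def fisher_exact_site(
    edited_treat: int,
    unedited_treat: int,
    edited_ctrl: int,
    unedited_ctrl: int,
    alternative: str = "two-sided",
) -> float:
    """Fisher exact test p-value for one site's 2x2 count table."""
    cells = (edited_treat, unedited_treat, edited_ctrl, unedited_ctrl)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero table has no margin to test")
    table = [[edited_treat, unedited_treat], [edited_ctrl, unedited_ctrl]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def hochberg_adjust(p_values) -> np.ndarray:
    """Simes-Hochberg step-up adjusted p-values, in the original order.

    Equivalent to: sort ascending, set a(m) = p(m), then
    a(i) = min(a(i+1), (m-i+1) * p(i)), clip to 1, un-sort.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def odds_ratio_pseudo(
    edited_treat: int,
    unedited_treat: int,
    edited_ctrl: int,
    unedited_ctrl: int,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Pseudocounted odds ratio and its natural log for a 2x2 table.

    The pseudocount is added to all four cells, guaranteeing a finite,
    positive odds ratio for any non-negative integer table.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    a, b, c, d = edited_treat, unedited_treat, edited_ctrl, unedited_ctrl
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    p = pseudocount
    odds = ((a + p) * (d + p)) / ((b + p) * (c + p))
    return odds, float(np.log(odds))


@dataclass
class OfftargetReport:
    """All per-site editing tests plus the sites passing both thresholds."""

    tests: pd.DataFrame
    calls: pd.DataFrame
    alpha: float
    log_or_threshold: float


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a strand-specific count TSV (columns seq_id pos0 strand ref
    nA nC nG nT; '#' comment lines allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    return df[COUNT_COLUMNS].copy()


def write_counts_tsv(df: pd.DataFrame, path, header_comments: list[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _site_key_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.set_index(["seq_id", "pos0", "strand"], verify_integrity=True)


def call_editing(
    treat_counts: pd.DataFrame,
    ctrl_counts: pd.DataFrame,
    alpha: float = 0.05,
    log_or_threshold: float = 2.0,
    scores: Mapping[tuple, float] | None = None,
    pseudocount: float = 0.5,
    alternative: str = "two-sided",
) -> OfftargetReport:
    """Test every reference-C site for excess C-to-U editing vs control.

    Both tables must cover the same (seq_id, pos0, strand) universe.  At
    each ref-C site: edited = T count, unedited = C count; Fisher exact
    test treatment vs control; Simes-Hochberg adjustment across all
    tested sites; pseudocounted odds ratio.  Calls require
    ``p_adjusted < alpha`` and ``log_odds_ratio > log_or_threshold`` and
    are sorted by log odds ratio descending.  ``scores`` optionally maps
    (seq_id, pos0, strand) to a predicted binding score to join in.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = _site_key_frame(treat_counts)
    c = _site_key_frame(ctrl_counts)
    missing_in_ctrl = t.index.difference(c.index)
    missing_in_treat = c.index.difference(t.index)
    if len(missing_in_ctrl) or len(missing_in_treat):
        raise ValueError(
            "site universes differ; missing in control: "
            f"{list(missing_in_ctrl[:5])}; missing in treatment: "
            f"{list(missing_in_treat[:5])}"
        )
    ref_mismatch = t.index[(t["ref"] != c.loc[t.index, "ref"]).to_numpy()]
    if len(ref_mismatch):
        raise ValueError(f"reference base mismatch at {list(ref_mismatch[:5])}")

    sites = t[t["ref"] == "C"]
    ctrl = c.loc[sites.index]
    a = sites["nT"].to_numpy(dtype=int)
    b = sites["nC"].to_numpy(dtype=int)
    cc = ctrl["nT"].to_numpy(dtype=int)
    d = ctrl["nC"].to_numpy(dtype=int)

    cache: dict[tuple[int, int, int, int], float] = {}
    pvals = np.empty(len(a))
    for i, tab in enumerate(zip(a, b, cc, d)):
        if tab not in cache:
            # a depth-0 site in both samples carries no evidence
            cache[tab] = (
                1.0 if sum(tab) == 0
                else fisher_exact_site(*tab, alternative=alternative)
            )
        pvals[i] = cache[tab]
    padj = hochberg_adjust(pvals) if len(pvals) else np.array([])

    ors = ((a + pseudocount) * (d + pseudocount)) / (
        (b + pseudocount) * (cc + pseudocount)
    )
    with np.errstate(divide="ignore"):
        log_ors = np.log(ors)
    depth = a + b
    frac = np.where(depth > 0, 100.0 * a / np.maximum(depth, 1), np.nan)

    tests = sites.reset_index()[["seq_id", "pos0", "strand", "ref"]].copy()
    tests["edited_treat"] = a
    tests["unedited_treat"] = b
    tests["edited_ctrl"] = cc
    tests["unedited_ctrl"] = d
    tests["editing_percent_treat"] = np.round(frac, 2)
    tests["p_value"] = pvals
    tests["p_adjusted"] = padj
    tests["odds_ratio"] = ors
    tests["log_odds_ratio"] = log_ors
    if scores is not None:
        tests["raw_score"] = [
            scores.get((r.seq_id, r.pos0, r.strand), np.nan)
            for r in tests.itertuples()
        ]

    calls = tests[
        (tests["p_adjusted"] < alpha) & (tests["log_odds_ratio"] > log_or_threshold)
    ].sort_values("log_odds_ratio", ascending=False, kind="stable")
    return OfftargetReport(
        tests=tests,
        calls=calls.reset_index(drop=True),
        alpha=alpha,
        log_or_threshold=log_or_threshold,
    )
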