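"""Kd estimation from titration curves and relative binding strengths.

Binding screens here run in the ligand-depletion regime: the labelled RNA
probe concentration L is comparable to the dissociation constant Kd, so
the hyperbolic approximation P/(P+Kd) under-reports binding and the
quadratic isotherm is used instead.  The fraction of probe bound at total
protein P, probe L and dissociation constant Kd is

    f(P) = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 L)

Estimated Kd values above the assay's reliable range are capped (200 nM
for this screen, 900 nM for external comparison data); "relative binding
strength" is -log10(Kd) min-max scaled to [0, 1] across the dataset being
compared, computed after capping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CONCENTRATION_SERIES_NM",
    "BindingCurve",
    "KdEstimate",
    "SpecificityMatrix",
    "fraction_bound",
    "fit_kd",
    "cap_kd",
    "relative_binding_strength",
    "build_specificity_matrix",
    "read_curves_tsv",
]

#: The standard 12-point protein dilution series (nM) used in the screens.
CONCENTRATION_SERIES_NM = (
    0.0, 0.781, 1.6, 3.1, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0,
)

KD_BOUNDS_NM = (1e-3, 1e5)


def fraction_bound(P, L: float, Kd: float):
    """Fraction of probe bound under the quadratic ligand-depletion isotherm.

    Accepts scalar or array protein concentration ``P`` (nM).  Lies in
    [0, min(1, P/L)] and reduces to P/(P+Kd) in the dilute-probe limit.
    """
    if L <= 0:
        raise ValueError("probe concentration L must be > 0")
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("protein concentration must be >= 0")
    s = P + L + Kd
    disc = np.clip(s * s - 4.0 * P * L, 0.0, None)
    out = (s - np.sqrt(disc)) / (2.0 * L)
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingCurve:
    """One titration: signals measured over a protein dilution series."""

    protein_nM: Sequence[float]
    signals: Sequence[float]
    probe_nM: float
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        P = np.asarray(self.protein_nM, dtype=float)
        y = np.asarray(self.signals, dtype=float)
        if P.shape != y.shape:
            raise ValueError("protein_nM and signals must have equal length")
        if np.any(P < 0):
            raise ValueError("negative protein concentration")
        if self.probe_nM <= 0:
            raise ValueError("probe_nM must be > 0")
        order = np.argsort(P, kind="stable")
        self.protein_nM = P[order]
        self.signals = y[order]
        if len(np.unique(self.protein_nM)) < len(P):
            # replicate concentrations are allowed when curves are pooled
            pass


@dataclass
class KdEstimate:
    """A fitted dissociation constant with its cap and reliability state."""

    kd: float
    smax: float
    baseline: float
    rss: float
    capped: bool = False
    cap_value: float | None = None
    unreliable: bool = False

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def fit_kd(curve: BindingCurve) -> KdEstimate:
    """Least-squares fit of ``baseline + (smax - baseline) * f(P)`` for
    (Kd, smax, baseline) under the ligand-depletion isotherm.

    Bounded fit: Kd in [1e-3, 1e5] nM, smax in [0, 10*max(signal)],
    baseline in [0, max(signal)].  The estimate is flagged unreliable if
    Kd lands within 1% of a bound or the fit explains less than half the
    signal variance (rss / var(signal) > 0.5).
    """
    P = np.asarray(curve.protein_nM, dtype=float)
    y = np.asarray(curve.signals, dtype=float)
    if len(P) < 4:
        raise ValueError("need at least 4 titration points")
    if not np.any(P > 0):
        raise ValueError("need at least one nonzero protein concentration")
    L = curve.probe_nM
    ymax = float(y.max())
    if ymax <= 0:
        # flat/zero signal: nothing to fit
        return KdEstimate(
            kd=KD_BOUNDS_NM[1], smax=0.0, baseline=0.0, rss=float(np.sum(y**2)),
            unreliable=True,
        )
    smax_hi = 10.0 * ymax
    base_hi = ymax
    half = (float(y.min()) + ymax) / 2.0
    nonzero = P > 0
    kd0 = float(P[nonzero][np.argmin(np.abs(y[nonzero] - half))])
    kd0 = float(np.clip(kd0, KD_BOUNDS_NM[0] * 10, KD_BOUNDS_NM[1] / 10))
    x0 = np.array([kd0, ymax, max(float(y.min()), 0.0)])

    def resid(theta):
        kd, smax, baseline = theta
        return baseline + (smax - baseline) * fraction_bound(P, L, kd) - y

    sol = least_squares(
        resid,
        x0,
        bounds=([KD_BOUNDS_NM[0], 0.0, 0.0], [KD_BOUNDS_NM[1], smax_hi, base_hi]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    kd, smax, baseline = sol.x
    rss = float(np.sum(sol.fun**2))
    var = float(np.var(y))
    unreliable = (
        kd <= KD_BOUNDS_NM[0] * 1.01
        or kd >= KD_BOUNDS_NM[1] * 0.99
        or var == 0.0
        or rss / (var * len(y)) > 0.5
    )
    return KdEstimate(
        kd=float(kd), smax=float(smax), baseline=float(baseline), rss=rss,
        unreliable=bool(unreliable),
    )


def cap_kd(estimate: KdEstimate, cap: float = 200.0) -> KdEstimate:
    """Cap a Kd estimate at the assay's reliability ceiling (nM)."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    if estimate.kd > cap:
        return replace(estimate, kd=cap, capped=True, cap_value=cap)
    return replace(estimate, capped=False, cap_value=cap)


def relative_binding_strength(capped_kds: Iterable[float]) -> np.ndarray:
    """Min-max scale -log10(Kd) to [0, 1]: the tightest binder maps to 1.

    All-equal inputs are degenerate (no range to scale over): returns 0.5
    for every entry with a warning.
    """
    kds = np.asarray(list(capped_kds), dtype=float)
    if kds.size < 2:
        raise ValueError("need at least 2 Kd values to scale")
    if np.any(kds <= 0):
        raise ValueError("all Kd values must be > 0")
    neglog = -np.log10(kds)
    lo, hi = neglog.min(), neglog.max()
    if hi == lo:
        warnings.warn("all Kd values equal; relative strengths degenerate at 0.5")
        return np.full_like(neglog, 0.5)
    return (neglog - lo) / (hi - lo)


BASES = ("A", "C", "G", "U")


@dataclass
class SpecificityMatrix:
    """Per-variant nucleotide specificity: capped Kd and scaled strength.

    ``table`` is indexed by (fifth, last) with columns ``kd_<base>`` and
    ``strength_<base>`` plus ``preferred_base``, ``ambiguous`` and
    ``low_evidence`` (single-base rows).
    """

    table: pd.DataFrame
    cap: float

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, cap: float) -> "SpecificityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
        df = df.set_index(["fifth", "last"])
        df["ambiguous"] = df["ambiguous"].astype(bool)
        df["low_evidence"] = df["low_evidence"].astype(bool)
        return cls(table=df, cap=cap)


def build_specificity_matrix(
    estimates: Mapping[tuple[str, str], Mapping[str, float]],
    cap: float = 200.0,
) -> SpecificityMatrix:
    """Cap per-base Kds, scale strengths across the whole matrix, pick
    preferred bases.

    ``estimates`` maps (fifth, last) -> {base: Kd nM} with 1-4 bases per
    variant.  Scaling is min-max over every measured (variant, base) cell
    jointly, after capping, so strengths are comparable across the matrix.
    Variants with no measurements are dropped with a warning; single-base
    variants are flagged low-evidence; ties for the row maximum are
    flagged ambiguous (alphabetically first base reported).
    """
    rows = {}
    for pair, by_base in estimates.items():
        by_base = {b: k for b, k in by_base.items() if k is not None}
        if not by_base:
            warnings.warn(f"variant {pair} has no measurements; excluded")
            continue
        bad = set(by_base) - set(BASES)
        if bad:
            raise ValueError(f"unknown bases {sorted(bad)} for variant {pair}")
        rows[pair] = {b: min(float(k), cap) for b, k in by_base.items()}
    if not rows:
        raise ValueError("no variants with measurements")
    all_kds = np.array([k for r in rows.values() for k in r.values()])
    neglog = -np.log10(all_kds)
    lo, hi = neglog.min(), neglog.max()
    span = hi - lo

    records = []
    for (fifth, last), by_base in sorted(rows.items()):
        rec: dict = {"fifth": fifth, "last": last}
        strengths = {}
        for b in BASES:
            kd = by_base.get(b, np.nan)
            rec[f"kd_{b}"] = kd
            if np.isnan(kd):
                rec[f"strength_{b}"] = np.nan
            else:
                s = 0.5 if span == 0 else (-np.log10(kd) - lo) / span
                rec[f"strength_{b}"] = s
                strengths[b] = s
        best = max(strengths.values())
        winners = sorted(b for b, s in strengths.items() if s == best)
        rec["preferred_base"] = winners[0]
        rec["ambiguous"] = len(winners) > 1
        rec["low_evidence"] = len(strengths) == 1
        records.append(rec)
    table = pd.DataFrame(records).set_index(["fifth", "last"])
    return SpecificityMatrix(table=table, cap=cap)


def read_curves_tsv(path) -> list[BindingCurve]:
    """Read titration curves from TSV with columns
    ``protein_nM  signal  replicate  probe_nM`` ('#' comments allowed).

    Returns one BindingCurve per replicate.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["protein_nM", "signal", "replicate", "probe_nM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"curve TSV missing columns {missing}")
    curves = []
    for rep, grp in df.groupby("replicate", sort=True):
        probes = grp["probe_nM"].unique()
        if len(probes) != 1:
            raise ValueError(f"replicate {rep} mixes probe concentrations")
        curves.append(
            BindingCurve(
                protein_nM=grp["protein_nM"].to_numpy(),
                signals=grp["signal"].to_numpy(),
                probe_nM=float(probes[0]),
                replicate_id=str(rep),
            )
        )
    return curves
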