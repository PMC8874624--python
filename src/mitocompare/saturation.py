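"""Substitution-saturation diagnostics from pairwise p-distances.

For every pair of aligned sequences the proportion of transitions (A<->G,
C<->T) and transversions (everything else) is computed under pairwise
deletion of gap/ambiguous columns, stratified by codon position.  Plotting
ts and tv against total p-distance and fitting a 2nd-order polynomial shows
saturation as a flattening (negative curvature) of the transition curve —
typically strongest at third codon positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
STRATA = ("pos1", "pos2", "pos3", "all")


@dataclass(frozen=True)
class PairwiseDistance:
    taxon_a: str
    taxon_b: str
    p_ts: float
    p_tv: float
    sites_compared: int
    stratum: str = "all"

    @property
    def p_total(self) -> float:
        return self.p_ts + self.p_tv


def _stratum_slice(n: int, stratum: str) -> slice:
    if stratum == "all":
        return slice(0, n)
    if stratum in ("pos1", "pos2", "pos3"):
        return slice(int(stratum[-1]) - 1, n, 3)
    raise ValueError(f"unknown stratum {stratum!r}; use one of {STRATA}")


def pairwise_ts_tv(
    seq_a: str,
    seq_b: str,
    stratum: str = "all",
    taxon_a: str = "a",
    taxon_b: str = "b",
) -> PairwiseDistance:
    """Transition/transversion p-distances between two aligned sequences.

    Columns where either sequence has a gap or an ambiguity code are deleted
    pairwise.  Raises if no comparable site remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    sl = _stratum_slice(len(seq_a), stratum)
    ts = tv = n = 0
    for x, y in zip(seq_a.upper()[sl], seq_b.upper()[sl]):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError(f"{taxon_a}/{taxon_b}: no comparable sites in {stratum}")
    return PairwiseDistance(taxon_a, taxon_b, ts / n, tv / n, n, stratum)


def all_pairwise(
    sequences: dict[str, str], strata: tuple[str, ...] = STRATA
) -> pd.DataFrame:
    """All pairwise ts/tv distances for each requested codon-position stratum."""
    rows = []
    for (na, sa), (nb, sb) in combinations(sequences.items(), 2):
        for stratum in strata:
            d = pairwise_ts_tv(sa, sb, stratum, na, nb)
            rows.append({
                "taxon_a": na, "taxon_b": nb, "stratum": stratum,
                "p_ts": d.p_ts, "p_tv": d.p_tv, "p_total": d.p_total,
                "sites_compared": d.sites_compared,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SaturationFit:
    """Least-squares quadratic y = a0 + a1*x + a2*x^2 of ts or tv on p-distance."""

    a0: float
    a1: float
    a2: float
    r_squared: float

    @property
    def slope_at_origin(self) -> float:
        return self.a1

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a0 + self.a1 * x + self.a2 * x * x


def saturation_fit(points: list[tuple[float, float]]) -> SaturationFit:
    """Fit a 2nd-order polynomial to (total p-distance, ts-or-tv) pairs."""
    if len(points) < 4:
        raise ValueError("quadratic saturation fit needs at least 4 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(X) < 3:
        if np.ptp(y) == 0:  # flat data: constant fit is exact
            return SaturationFit(float(y[0]), 0.0, 0.0, 1.0)
        raise ValueError("degenerate design: x values do not span a quadratic")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SaturationFit(float(coef[0]), float(coef[1]), float(coef[2]), r2)


def saturation_report(distances: pd.DataFrame) -> pd.DataFrame:
    """Quadratic fits of ts and tv vs total p-distance, per stratum."""
    rows = []
    for stratum, grp in distances.groupby("stratum", sort=False):
        for kind in ("p_ts", "p_tv"):
            pts = list(zip(grp["p_total"], grp[kind]))
            if len(pts) < 4:
                continue
            fit = saturation_fit(pts)
            rows.append({
                "stratum": stratum, "response": kind,
                "a0": fit.a0, "a1": fit.a1, "a2": fit.a2,
                "r_squared": fit.r_squared,
                "slope_at_origin": fit.slope_at_origin,
            })
    return pd.DataFrame(rows)
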