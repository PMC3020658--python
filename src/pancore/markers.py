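"""Marker-gene percent identity and its regression against proteome similarity.

The marker plays the role of the 16S rRNA gene: a slowly evolving clock whose
pairwise percent identity (computed on an alignment, to the nearest 0.01%)
is regressed against two proteomic similarity measures, shared proteins
(group units) and average unique proteins (protein units). Pairs at >= 99.50%
identity are excluded before fitting, regardless of species naming, because
near-identical pairs anchor the regression line and inflate R^2; genera left
with too few pairs are reported as ND (not determined).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

IDENTITY_CUTOFF = 99.50
MIN_PAIRS_FOR_FIT = 3

# Two-sided slope significance rendering: the thresholds are this package's
# documented convention.
STAR_P, DOUBLE_STAR_P = 0.05, 0.001


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two aligned sequences, rounded half-up to 0.01.

    Columns where both sequences have a gap are excluded from the
    denominator; a gap against a residue counts as a difference.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    same = counted = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" and b == "-":
            continue
        counted += 1
        if a == b:
            same += 1
    if counted == 0:
        raise ValueError("no counted alignment columns")
    pct = Decimal(same * 100) / Decimal(counted)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MarkerPair:
    """One within-genus isolate pair with its marker and proteome measures."""

    isolate_a: str
    isolate_b: str
    identity: float  # percent, already rounded to 0.01
    shared: int      # orthologous groups
    avg_unique: float  # proteins


def filter_pairs(pairs: Iterable[MarkerPair],
                 cutoff: float = IDENTITY_CUTOFF) -> list[MarkerPair]:
    """Keep pairs with marker identity strictly below the cutoff."""
    return [p for p in pairs if p.identity < cutoff]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n_pairs: int
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    @property
    def significance(self) -> str:
        if self.p_slope < DOUBLE_STAR_P:
            return "**"
        if self.p_slope < STAR_P:
            return "*"
        return "n.s."


def least_squares_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares fit of a response on marker identity."""
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < MIN_PAIRS_FOR_FIT:
        raise ValueError(f"need >= {MIN_PAIRS_FOR_FIT} pairs for a fit")
    if len(set(x)) == 1:
        raise ValueError("zero variance in x")
    if len(set(y)) == 1:
        # constant response: flat line explains nothing
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(x),
                                (min(x), max(x)), (min(y), max(y)))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_slope=float(res.pvalue),
        n_pairs=len(x),
        x_range=(min(x), max(x)),
        y_range=(min(y), max(y)),
    )


def genus_similarity_table(pairs_by_genus: dict[str, list[MarkerPair]],
                           cutoff: float = IDENTITY_CUTOFF) -> pd.DataFrame:
    """One row per genus: marker range plus slope/R^2 for both measures.

    Genera whose filtered pair set is too small for a fit get ND cells (the
    marker range still reflects all pairs).
    """
    rows = []
    for genus in sorted(pairs_by_genus):
        pairs = pairs_by_genus[genus]
        row: dict = {"genus": genus, "n_pairs": len(pairs)}
        if pairs:
            idents = [p.identity for p in pairs]
            row["identity_min"], row["identity_max"] = min(idents), max(idents)
        else:
            row["identity_min"] = row["identity_max"] = float("nan")
        kept = filter_pairs(pairs, cutoff)
        row["n_pairs_included"] = len(kept)
        for measure, values in (
            ("shared", [float(p.shared) for p in kept]),
            ("avg_unique", [p.avg_unique for p in kept]),
        ):
            if values:
                row[f"{measure}_min"], row[f"{measure}_max"] = min(values), max(values)
            else:
                row[f"{measure}_min"] = row[f"{measure}_max"] = float("nan")
            try:
                fit = least_squares_fit([p.identity for p in kept], values)
            except ValueError:
                row[f"{measure}_slope"] = "ND"
                row[f"{measure}_r2"] = "ND"
                row[f"{measure}_sig"] = "ND"
            else:
                row[f"{measure}_slope"] = fit.slope
                row[f"{measure}_r2"] = fit.r_squared
                row[f"{measure}_sig"] = fit.significance
        rows.append(row)
    return pd.DataFrame(rows)


def marker_pairs_for_genus(marker: dict[str, str], isolates: Sequence[str],
                           shared_fn, avg_unique_fn) -> list[MarkerPair]:
    """Assemble the within-genus pair records feeding the regression."""
    pairs = []
    for i, a in enumerate(isolates):
        for b in isolates[i + 1:]:
            pairs.append(MarkerPair(
                a, b,
                identity=percent_identity(marker[a], marker[b]),
                shared=shared_fn(a, b),
                avg_unique=avg_unique_fn(a, b),
            ))
    return pairs
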