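"""Exploratory tables: outcome frequencies, joint/marginal 2x2 with odds
ratio, and chi-square covariate screening.

The joint table reports the dependence odds ratio of the two outcomes in two
variants: from the raw 2x2 counts, and from the cell probabilities rounded
to a fixed number of decimals first.  Published tables usually print rounded
probabilities, and an odds ratio recomputed from them can differ visibly
from the count-based one (with the reference counts 371/1111/280/1444 the
two variants are 1.722 and 1.729); both are exposed so the provenance of any
printed value is transparent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = ["JointTable", "joint_marginal_table", "chi_square_screen", "frequency_report"]


@dataclass
class JointTable:
    """2x2 joint distribution of (anemia, undernutrition) with marginals.

    ``counts`` rows index anemia (1, 0), columns undernutrition (1, 0);
    weighted counts are real-valued.  Marginals are always derived from the
    joint cells.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    marginals: tuple[float, float]      # (pi_anemia, pi_undernutrition)
    total: float
    or_from_counts: float
    or_from_rounded_probs: float
    rounding_digits: int = 3
    continuity_corrected: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "probabilities": self.probabilities.tolist(),
            "marginal_anemia": self.marginals[0],
            "marginal_undernutrition": self.marginals[1],
            "total": self.total,
            "or_from_counts": self.or_from_counts,
            "or_from_rounded_probs": self.or_from_rounded_probs,
            "rounding_digits": self.rounding_digits,
            "continuity_corrected": self.continuity_corrected,
            "notes": list(self.notes),
        }

    def to_frame(self) -> pd.DataFrame:
        """Printable layout: joint cells with marginals appended."""
        c = self.counts
        p = self.probabilities
        rows = []
        for i, lab in enumerate(["anemic", "not_anemic"]):
            rows.append(
                {
                    "anemia": lab,
                    "undernourished": f"{c[i, 0]:.0f} ({p[i, 0]:.3f})",
                    "nourished": f"{c[i, 1]:.0f} ({p[i, 1]:.3f})",
                    "marginal": f"{c[i].sum():.0f} ({p[i].sum():.3f})",
                }
            )
        rows.append(
            {
                "anemia": "marginal",
                "undernourished": f"{c[:, 0].sum():.0f} ({p[:, 0].sum():.3f})",
                "nourished": f"{c[:, 1].sum():.0f} ({p[:, 1].sum():.3f})",
                "marginal": f"{self.total:.0f} (1.000)",
            }
        )
        return pd.DataFrame(rows)


def joint_marginal_table(
    y,
    weights=None,
    rounding_digits: int = 3,
    expected_marginals: tuple[float, float] | None = None,
) -> JointTable:
    """Weighted joint/marginal 2x2 table of the two outcomes with both ORs.

    ``y`` is an (n, 2) table of binary (anemia, undernutrition) pairs, or an
    already-tabulated mapping {(y1, y2): count}.  With any empty cell the
    odds ratios use a 0.5 continuity correction and the result is flagged.
    ``expected_marginals``, when given, are checked against the marginals
    derived from the joint cells and discrepancies are logged (published
    tables occasionally disagree with their own margins).
    """
    if isinstance(y, dict):
        cells = {k: float(v) for k, v in y.items()}
        n11, n10 = cells.get((1, 1), 0.0), cells.get((1, 0), 0.0)
        n01, n00 = cells.get((0, 1), 0.0), cells.get((0, 0), 0.0)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
            raise ValueError("y must be a nonempty (n, 2) table")
        w = np.ones(arr.shape[0]) if weights is None else np.asarray(weights, float)
        y1, y2 = arr[:, 0], arr[:, 1]
        n11 = float(w[(y1 == 1) & (y2 == 1)].sum())
        n10 = float(w[(y1 == 1) & (y2 == 0)].sum())
        n01 = float(w[(y1 == 0) & (y2 == 1)].sum())
        n00 = float(w[(y1 == 0) & (y2 == 0)].sum())
    counts = np.array([[n11, n10], [n01, n00]])
    total = counts.sum()
    if total <= 0:
        raise ValueError("joint table is empty")
    probs = counts / total

    notes = []
    corrected = False
    c = counts
    if np.any(counts == 0):
        c = counts + 0.5
        corrected = True
        notes.append("zero cell: odds ratios use a 0.5 continuity correction")
    or_counts = float(c[0, 0] * c[1, 1] / (c[0, 1] * c[1, 0]))
    pr = np.round(c / c.sum(), rounding_digits)
    with np.errstate(divide="ignore", invalid="ignore"):
        or_rounded = float(pr[0, 0] * pr[1, 1] / (pr[0, 1] * pr[1, 0]))

    marg = (float(probs[0].sum()), float(probs[:, 0].sum()))
    if expected_marginals is not None:
        for name, got, want in (
            ("anemia", marg[0], expected_marginals[0]),
            ("undernutrition", marg[1], expected_marginals[1]),
        ):
            if abs(got - want) > 10 ** (-rounding_digits):
                msg = (
                    f"supplied {name} marginal {want} disagrees with the "
                    f"joint-cell marginal {got:.{rounding_digits}f}"
                )
                notes.append(msg)
                warnings.warn(msg, UserWarning)

    return JointTable(
        counts=counts,
        probabilities=probs,
        marginals=marg,
        total=float(total),
        or_from_counts=or_counts,
        or_from_rounded_probs=or_rounded,
        rounding_digits=rounding_digits,
        continuity_corrected=corrected,
        notes=notes,
    )


def chi_square_screen(
    records: pd.DataFrame,
    covariate_list: list[str],
    outcomes: list[str] = ("anemia", "undernutrition"),
) -> pd.DataFrame:
    """Pearson chi-square test of each covariate against each outcome.

    No continuity correction.  Returns one row per (covariate, outcome) with
    the statistic, degrees of freedom (r-1)(c-1), p-value and a low-expected
    -count flag (any expected cell below 1).
    """
    rows = []
    for cov in covariate_list:
        if cov not in records.columns:
            raise KeyError(f"covariate column not found: {cov!r}")
        if records[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} has fewer than 2 observed levels")
        for out in outcomes:
            table = pd.crosstab(records[cov], records[out])
            stat, p, dof, expected = chi2_contingency(
                table.to_numpy(), correction=False
            )
            rows.append(
                {
                    "covariate": cov,
                    "outcome": out,
                    "chi2": float(stat),
                    "df": int(dof),
                    "p_value": float(p),
                    "low_expected_count": bool((expected < 1).any()),
                    "counts": table.to_numpy().tolist(),
                    "levels": [str(v) for v in table.index],
                }
            )
    return pd.DataFrame(rows)


def _percentages_1dp(counts: np.ndarray) -> np.ndarray:
    """Percentages to 1 dp that sum to exactly 100.0 (largest remainder)."""
    tenths = 1000.0 * counts / counts.sum()
    floors = np.floor(tenths)
    shortfall = int(round(1000 - floors.sum()))
    order = np.argsort(-(tenths - floors))
    floors[order[:shortfall]] += 1
    return floors / 10.0


def frequency_report(
    records: pd.DataFrame, variables: list[str], weights=None
) -> pd.DataFrame:
    """Weighted level counts and percentages (1 dp) per variable.

    Percentages use largest-remainder rounding so each variable's levels sum
    to exactly 100.0; with few levels this coincides with plain rounding.
    """
    w = (
        np.ones(len(records))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    rows = []
    for var in variables:
        if var not in records.columns:
            raise KeyError(f"variable not found: {var!r}")
        series = records[var]
        totals = {}
        for level in dict.fromkeys(series):
            totals[level] = float(w[(series == level).to_numpy()].sum())
        pcts = _percentages_1dp(np.array(list(totals.values())))
        for (level, count), pct in zip(totals.items(), pcts):
            rows.append(
                {"variable": var, "level": str(level), "count": count,
                 "percent": float(pct)}
            )
    return pd.DataFrame(rows)
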