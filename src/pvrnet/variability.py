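"""Inter-line versus intra-line variability of membrane counts.

Donor RPE lines differ genetically; repeat experiments on one line do
not.  Comparing the coefficient of variation of membrane counts pooled
across all lines and experiments (interline) with the CV within a
single focal line (intraline) bounds the share of the observed
variability that cannot be genetic: the non-genetic fraction is
100 * CV_intra / CV_inter (it can exceed 100% and is then flagged, not
clipped — the "at least" reading presumes intra <= inter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CVReport", "coefficient_of_variation", "nongenetic_fraction", "cv_report"]


@dataclass
class CVReport:
    per_line: pd.DataFrame  # columns: line, cv_pct, n
    interline_cv_pct: float
    interline_n: int
    focal_line: str
    intraline_cv_pct: float
    intraline_n: int
    nongenetic_fraction_pct: float
    fraction_exceeds_100: bool


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV% = 100 * sample sd / mean (ddof=1 by default)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values for a CV")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return 100.0 * v.std(ddof=ddof) / mean


def nongenetic_fraction(cv_intraline: float, cv_interline: float) -> float:
    """Non-genetic share of variability, percent: 100 * intra / inter.

    Rounded to one decimal for reporting.
    """
    if cv_interline <= 0:
        raise ValueError("interline CV must be positive")
    return round(100.0 * cv_intraline / cv_interline, 1)


def cv_report(table: pd.DataFrame, focal_line: str) -> CVReport:
    """Per-line CVs, pooled interline CV, and the focal-line decomposition.

    ``table`` has columns (line, experiment, count).  The interline CV
    pools every experiment from every line into one sample; the focal
    line's intraline CV uses only its own experiments.
    """
    if focal_line not in set(table["line"]):
        raise ValueError(f"focal line {focal_line!r} not in table")
    per_line = []
    for line, grp in table.groupby("line", sort=True):
        vals = grp["count"].to_numpy(dtype=float)
        cv = coefficient_of_variation(vals) if len(vals) >= 2 else np.nan
        per_line.append({"line": line, "cv_pct": cv, "n": len(vals)})
    per_line = pd.DataFrame(per_line)

    pooled = table["count"].to_numpy(dtype=float)
    inter = coefficient_of_variation(pooled)
    focal_vals = table.loc[table["line"] == focal_line, "count"].to_numpy(dtype=float)
    if len(focal_vals) < 2:
        raise ValueError(f"focal line {focal_line!r} has < 2 experiments")
    intra = coefficient_of_variation(focal_vals)
    frac = nongenetic_fraction(intra, inter)
    return CVReport(
        per_line=per_line,
        interline_cv_pct=inter,
        interline_n=len(pooled),
        focal_line=focal_line,
        intraline_cv_pct=intra,
        intraline_n=len(focal_vals),
        nongenetic_fraction_pct=frac,
        fraction_exceeds_100=frac > 100.0,
    )
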