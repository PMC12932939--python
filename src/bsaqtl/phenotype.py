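"""Nitrogen use efficiency (NUtE), extreme-bulk selection, and trait summaries.

NUtE is whole-plant dry weight divided by whole-plant nitrogen content
(g·g⁻¹). Extreme bulks are drawn from class-qualifying lines: a low pool
from a bounded NUtE range and a high pool above a floor, filled by
within-class ranking so the contrast between pools is maximal and the
selection deterministic. Also provides distribution moments in the
SPSS-style bias-corrected convention and the 2^−ΔΔCt qPCR utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_nue(dry_weight: float, n_content: float) -> float:
    """NUtE = dry weight / nitrogen content; both inputs must be positive."""
    if dry_weight <= 0 or n_content <= 0:
        raise ValueError("dry_weight and n_content must both be positive")
    return dry_weight / n_content


@dataclass
class BulkSelection:
    low_lines: list[str]
    high_lines: list[str]
    low_range: tuple[float, float]
    high_min: float
    low_mean: float
    high_mean: float

    @property
    def ratio(self) -> float:
        """High-pool mean NUtE over low-pool mean."""
        return self.high_mean / self.low_mean


def select_extreme_bulks(
    table: pd.DataFrame,
    low_range: tuple[float, float] = (25.0, 35.0),
    high_min: float = 75.0,
    pool_size: int = 15,
) -> BulkSelection:
    """Pick the two extreme pools from a phenotype table.

    ``table`` needs ``line_id`` plus either a ``nue`` column or
    ``dry_weight_g``/``n_content_g`` from which NUtE is derived. The low
    pool takes the ``pool_size`` lowest-NUtE lines inside ``low_range``
    (inclusive); the high pool the highest above ``high_min``. Ties break
    by line id, so selection is order-invariant. A class with fewer than
    ``pool_size`` qualifying lines is an error naming the shortfall.
    """
    df = table.copy()
    if "nue" not in df.columns:
        df["nue"] = [
            compute_nue(dw, nc) for dw, nc in zip(df["dry_weight_g"], df["n_content_g"])
        ]
    df = df.sort_values(["nue", "line_id"], kind="stable")
    low_ok = df[(df["nue"] >= low_range[0]) & (df["nue"] <= low_range[1])]
    high_ok = df[df["nue"] > high_min]
    if len(low_ok) < pool_size:
        raise ValueError(
            f"low-NUtE class has only {len(low_ok)} qualifying lines, need {pool_size}"
        )
    if len(high_ok) < pool_size:
        raise ValueError(
            f"high-NUtE class has only {len(high_ok)} qualifying lines, need {pool_size}"
        )
    low = low_ok.head(pool_size)
    high = high_ok.tail(pool_size)
    return BulkSelection(
        low_lines=low["line_id"].tolist(),
        high_lines=high["line_id"].tolist(),
        low_range=low_range,
        high_min=high_min,
        low_mean=float(low["nue"].mean()),
        high_mean=float(high["nue"].mean()),
    )


def distribution_moments(values) -> dict[str, float]:
    """Mean, SD, skewness and excess kurtosis of a trait sample.

    Skewness is the adjusted Fisher–Pearson coefficient
    g1·√(n(n−1))/(n−2) and kurtosis the bias-corrected excess kurtosis —
    the conventions common statistics suites print. Requires n ≥ 4 and
    non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 values for kurtosis, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: moments undefined")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": float(stats.kurtosis(x, fisher=True, bias=False)),
    }


def relative_expression_ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by 2^−ΔΔCt.

    ΔΔCt = (Ct_target − Ct_reference) under treatment minus the same
    difference under control.
    """
    for ct in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
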