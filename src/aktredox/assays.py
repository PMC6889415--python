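"""Dose-response Hill fitting and cysteine redox-state quantification.

Two small quantitative assays:

* :func:`fit_hill` — four-parameter Hill fit of protein-lipid overlay
  dose-response data (binding of the Akt PH domain to spotted PIP3),
  ``y = Bottom + (Top - Bottom) * d^h / (EC50^h + d^h)``.
* :func:`redox_fraction` — fraction of a cysteine in the oxidized state
  from differential isotopic alkylation: free thiols carry the light
  (12C) label, previously oxidized thiols the heavy (13C) label, and the
  fraction oxidized is the pooled heavy ion abundance over the total.
  :func:`compare_bins` compares groups of fractions by the two-sided
  Wilcoxon rank-sum test (exact for small samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

#: Spotted PIP3 amounts (pmol) of the membrane overlay assay.
OVERLAY_DOSES_PMOL = (100.0, 50.0, 25.0, 10.0, 5.0, 1.0)


@dataclass
class DoseResponse:
    doses: np.ndarray
    responses: np.ndarray
    condition: str = "other"
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have the same length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "dose": self.doses,
                "response": self.responses,
                "condition": self.condition,
                "replicate": self.replicate if self.replicate is not None else "",
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponse":
        df = pd.read_csv(path)
        for col in ("dose", "response"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        cond = str(df["condition"].iloc[0]) if "condition" in df.columns else "other"
        return cls(df["dose"].to_numpy(), df["response"].to_numpy(), condition=cond)


@dataclass
class HillFit:
    ec50: float
    hillslope: float
    top: float
    bottom: float
    rss: float
    converged: bool
    condition: str = "other"

    def __post_init__(self) -> None:
        if self.converged:
            if not self.ec50 > 0:
                raise ValueError("EC50 must be > 0")
            if self.top < self.bottom:
                raise ValueError("Top must be >= Bottom")


def hill(d, ec50: float, hillslope: float, top: float = 1.0, bottom: float = 0.0):
    """Hill equation evaluated at dose(s) d."""
    d = np.asarray(d, dtype=float)
    dh = d**hillslope
    return bottom + (top - bottom) * dh / (ec50**hillslope + dh)


def fit_hill(
    data: DoseResponse,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> HillFit:
    """Nonlinear least-squares Hill fit with multi-start initialization.

    EC50 is fitted on the log scale and initialized at the dose
    quartiles; the best of the converged starts is reported. Flat data
    (no response range) leaves the Hillslope unidentifiable and returns
    a flagged result with NaN parameters.
    """
    d, y = data.doses, data.responses
    n_free = 2 + (fix_bottom is None) + (fix_top is None)
    if len(np.unique(d)) < n_free:
        raise ValueError(
            f"{len(np.unique(d))} distinct doses cannot identify {n_free} free parameters; "
            "fix the asymptotes or add doses"
        )
    y_range = np.ptp(y)
    if y_range == 0:
        return HillFit(np.nan, np.nan, np.nan, np.nan, rss=0.0, converged=False,
                       condition=data.condition)

    def unpack(theta):
        log_ec50, h = theta[0], theta[1]
        i = 2
        if fix_bottom is None:
            bottom = theta[i]
            i += 1
        else:
            bottom = fix_bottom
        top = theta[i] if fix_top is None else fix_top
        return np.exp(log_ec50), h, top, bottom

    def resid(theta):
        ec50, h, top, bottom = unpack(theta)
        return hill(d, ec50, h, top, bottom) - y

    starts = np.percentile(d, [25, 50, 75]).tolist() + [float(np.exp(np.mean(np.log(d))))]
    best = None
    for ec50_0 in starts:
        theta0 = [np.log(ec50_0), 1.0]
        if fix_bottom is None:
            theta0.append(float(np.min(y)))
        if fix_top is None:
            theta0.append(float(np.max(y)))
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.nan, rss=np.nan, converged=False,
                       condition=data.condition)
    rss, theta = best
    ec50, h, top, bottom = unpack(theta)
    if h < 0:  # equivalent parameterisation: flip slope sign and swap asymptotes
        h, top, bottom = -h, bottom, top
    if not np.isfinite(ec50) or ec50 <= 0 or top < bottom:
        return HillFit(np.nan, np.nan, np.nan, np.nan, rss=rss, converged=False,
                       condition=data.condition)
    return HillFit(float(ec50), float(h), float(top), float(bottom), rss=rss,
                   converged=True, condition=data.condition)


def hill_fits_to_tsv(fits: list[HillFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "condition": f.condition,
                "EC50": f.ec50,
                "Hillslope": f.hillslope,
                "Top": f.top,
                "Bottom": f.bottom,
                "RSS": f.rss,
                "converged": f.converged,
            }
            for f in fits
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# redox state from differential alkylation
# ---------------------------------------------------------------------------

@dataclass
class RedoxState:
    """Oxidized fraction of one cysteine in one sample/time bin."""

    cysteine: str
    peptide_abundances: list = field(default_factory=list)  # (light, heavy) pairs
    time_bin: str = ""

    @property
    def fraction_oxidized(self) -> float:
        return redox_fraction(self.peptide_abundances)


def redox_fraction(peptide_abundances) -> float:
    """Pooled oxidized fraction from 1-4 (light, heavy) ion-abundance pairs.

    Ions are pooled before the ratio (abundance-weighted), so
    ``fraction = sum(heavy) / (sum(light) + sum(heavy))``; this differs
    from averaging per-peptide fractions when peptide intensities differ.
    """
    pairs = list(peptide_abundances)
    if not 1 <= len(pairs) <= 4:
        raise ValueError("expected 1-4 peptide (light, heavy) pairs")
    light = np.array([p[0] for p in pairs], dtype=float)
    heavy = np.array([p[1] for p in pairs], dtype=float)
    if np.any(light < 0) or np.any(heavy < 0):
        raise ValueError("ion abundances must be >= 0")
    total = light.sum() + heavy.sum()
    if total == 0:
        raise ValueError("all-zero ion abundances")
    return float(heavy.sum() / total)


def compare_bins(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups of fractions.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie and continuity correction otherwise. Returns
    (U statistic of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)
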