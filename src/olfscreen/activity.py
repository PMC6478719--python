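"""Dose-response analysis and the volume-PSA potency map.

Receptor responses follow the Hill equation

    f(x) = f_max / (1 + (EC50 / x)^n)

with f_max the maximal background-corrected amplitude, EC50 the half-maximal
effective concentration and n the Hill coefficient.  Fitting is unweighted
nonlinear least squares with a geometric multi-start grid over EC50.

The potency map partitions the (molecular volume, polar surface area) plane
into nine labelled regions: four favorable high-potency regions (a1-a4),
three medium (b1-b3) and two poor (c1, c2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, InsufficientDataError


@dataclass
class DoseResponse:
    """Concentrations (uM, strictly increasing) and background-corrected responses."""

    concentrations_uM: np.ndarray
    responses: np.ndarray
    replicate: str = "r1"

    def __post_init__(self):
        self.concentrations_uM = np.asarray(self.concentrations_uM, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations_uM.shape != self.responses.shape:
            raise ConfigurationError("concentration/response length mismatch")
        if np.any(self.concentrations_uM <= 0):
            raise ConfigurationError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations_uM) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing")


def hill(x: np.ndarray, fmax: float, ec50: float, n: float) -> np.ndarray:
    """The Hill dose-response model."""
    x = np.asarray(x, float)
    return fmax / (1.0 + (ec50 / x) ** n)


@dataclass(frozen=True)
class HillFit:
    fmax: float
    ec50_uM: float
    n: float
    rss: float
    converged: bool


def fit_hill(data: DoseResponse | Sequence[DoseResponse], n_starts: int = 12) -> HillFit:
    """Hill fit by multi-start unweighted nonlinear least squares.

    Replicate curves are fitted jointly by stacking their points.  EC50 starts
    form a geometric grid spanning the observed concentration range; the best
    residual solution is returned.  Deterministic for fixed data and grid.
    """
    curves = [data] if isinstance(data, DoseResponse) else list(data)
    x = np.concatenate([c.concentrations_uM for c in curves])
    y = np.concatenate([c.responses for c in curves])
    if len(x) < 4:
        raise InsufficientDataError("Hill fitting needs at least four points")
    if x.max() / x.min() < 10.0:
        raise InsufficientDataError("concentrations must span at least one decade")

    fmax0 = max(float(y.max()), 1e-9)
    starts = np.geomspace(x.min(), x.max(), n_starts)
    best = None
    for ec0 in starts:
        try:
            popt, _ = curve_fit(
                hill, x, y,
                p0=[fmax0, float(ec0), 1.0],
                bounds=([1e-12, 1e-12, 0.05], [np.inf, np.inf, 20.0]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(((y - hill(x, *popt)) ** 2).sum())
        if best is None or rss < best[0] - 1e-15:
            best = (rss, popt)
    if best is None:
        return HillFit(fmax=fmax0, ec50_uM=float(np.median(x)), n=1.0,
                       rss=float(((y - fmax0 / 2) ** 2).sum()), converged=False)
    rss, (fmax, ec50, n) = best
    return HillFit(fmax=float(fmax), ec50_uM=float(ec50), n=float(n), rss=rss, converged=True)


# ---------------------------------------------------------------------------
# volume-PSA potency regions
# ---------------------------------------------------------------------------

_INF = float("inf")

#: (label, (v_lo, v_hi, v_lo_open, v_hi_open), (p_lo, p_hi, p_lo_open, p_hi_open), tier)
#: printed bounds are closed; ">x" bounds are open below and unbounded above
POTENCY_REGIONS: list[tuple[str, tuple, tuple, str]] = [
    ("a1", (120.0, 140.0, False, False), (20.0, 35.0, False, False), "high"),
    ("a2", (140.0, 160.0, False, False), (35.0, 40.0, False, False), "high"),
    ("a3", (160.0, _INF, True, False), (10.0, 20.0, False, False), "high"),
    ("a4", (120.0, 130.0, False, False), (42.0, 45.0, False, False), "high"),
    ("b1", (120.0, 150.0, False, False), (10.0, 20.0, False, False), "medium"),
    ("b2", (150.0, 160.0, False, False), (20.0, 30.0, False, False), "medium"),
    ("b3", (130.0, 150.0, False, False), (35.0, 40.0, False, False), "medium"),
    ("c1", (-_INF, 130.0, False, True), (45.0, 55.0, False, False), "low"),
    ("c2", (145.0, _INF, True, False), (50.0, _INF, True, False), "low"),
]

#: agonist volumes beyond this are outside the studied domain
MAX_DOMAIN_VOLUME = 300.0

TIER_BY_LABEL = {label: tier for label, _v, _p, tier in POTENCY_REGIONS}
TIER_BY_LABEL["unclassified"] = "none"


def _inside(value: float, bounds: tuple) -> bool:
    lo, hi, lo_open, hi_open = bounds
    if lo_open:
        if value <= lo:
            return False
    elif value < lo:
        return False
    if hi_open:
        if value >= hi:
            return False
    elif value > hi:
        return False
    return True


def classify_potency_region(volume: float, psa: float) -> str:
    """Potency-region label for a (molecular volume A^3, PSA A^2) pair.

    Regions are tested in the fixed precedence order a1..a4, b1..b3, c1, c2 so
    overlapping printed bounds resolve deterministically in favor of the more
    potent tier; points matching no region (or with volume beyond the studied
    domain) are unclassified.
    """
    if volume <= 0:
        raise ConfigurationError("volume must be positive")
    if psa < 0:
        raise ConfigurationError("PSA must be non-negative")
    if volume > MAX_DOMAIN_VOLUME:
        return "unclassified"
    for label, vb, pb, _tier in POTENCY_REGIONS:
        if _inside(volume, vb) and _inside(psa, pb):
            return label
    return "unclassified"


def potency_map_table(records: Sequence[tuple[str, float, float, float]]):
    """Region-assignment table for ``(id, volume, PSA, EC50_uM)`` records."""
    import pandas as pd

    rows = []
    for cid, volume, psa, ec50 in records:
        label = classify_potency_region(volume, psa)
        rows.append(
            {"id": cid, "volume": volume, "PSA": psa, "EC50_uM": ec50,
             "region": label, "tier": TIER_BY_LABEL[label]}
        )
    return pd.DataFrame(rows, columns=["id", "volume", "PSA", "EC50_uM", "region", "tier"])
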