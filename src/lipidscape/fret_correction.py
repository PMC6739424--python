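"""Spectral bleed-through estimation and corrected FRET.

Sensitized-emission FRET measured in three channels (donor D, acceptor A,
FRET F) is contaminated by donor emission and directly excited acceptor
emission bleeding into the FRET channel. Calibration series of donor-only
and acceptor-only samples at several concentrations determine the
bleed-through fractions a (donor→FRET) and b (acceptor→FRET), after which

    cFRET = F − a·D − b·A − c

isolates the sensitized emission. Two instrument variants are supported:

* ``cfp_venus`` — CFP/Venus lipid-probe assays; regressions run through the
  origin and c is fixed at 0 (reference coefficients a = 0.4238,
  b = 0.03206).
* ``trp_dansyl`` — tryptophan/Dansyl-PE membrane-binding assays; a shared
  constant offset c is estimated jointly (reference a = 0.0678 for the
  C2-domain donor or 0.2195 for the P4C donor, b = 0.3316, c = 1674).

Offsets and fractions are instrument-specific: the reference presets are
shipped for comparison but new data should always be re-estimated. The
estimator follows the sklearn fit/transform idiom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

VARIANTS = ("cfp_venus", "trp_dansyl")


@dataclass
class BleedthroughModel:
    a: float  # donor → FRET fraction
    b: float  # acceptor → FRET fraction
    c: float = 0.0  # constant offset (signal units)
    a_se: float = np.nan
    b_se: float = np.nan
    c_se: float = np.nan
    variant: str = "cfp_venus"

    def __post_init__(self):
        if not (0 <= self.a < 1 and 0 <= self.b < 1):
            raise ValueError("bleed-through fractions must be in [0, 1)")


# Reference coefficient presets measured on the original instruments.
CFP_VENUS_REFERENCE = BleedthroughModel(a=0.4238, b=0.03206, c=0.0, variant="cfp_venus")
TRP_DANSYL_C2_REFERENCE = BleedthroughModel(a=0.0678, b=0.3316, c=1674.0, variant="trp_dansyl")
TRP_DANSYL_P4C_REFERENCE = BleedthroughModel(a=0.2195, b=0.3316, c=1674.0, variant="trp_dansyl")


class BleedthroughEstimator(TransformerMixin, BaseEstimator):
    """Estimate bleed-through coefficients from calibration series.

    ``fit`` takes a table with columns ``role`` (``donor_only`` /
    ``acceptor_only`` / ``mixed``), ``D``, ``A``, ``F``; only the two
    single-fluorophore roles inform the fit. For ``cfp_venus`` the two
    regressions run through the origin; for ``trp_dansyl`` a shared
    intercept c is estimated jointly by least squares.
    """

    def __init__(self, variant: str = "cfp_venus"):
        self.variant = variant

    def fit(self, X: pd.DataFrame, y=None):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        donor = X[X["role"] == "donor_only"]
        acceptor = X[X["role"] == "acceptor_only"]
        if len(donor) < 3 or len(acceptor) < 3:
            raise ValueError("need at least 3 readings per calibration series")
        D, Fd = donor["D"].to_numpy(float), donor["F"].to_numpy(float)
        A, Fa = acceptor["A"].to_numpy(float), acceptor["F"].to_numpy(float)
        if np.ptp(D) == 0 or np.ptp(A) == 0:
            raise ValueError("calibration series are rank-deficient (single level)")
        if self.variant == "cfp_venus":
            a, a_se = _through_origin(D, Fd)
            b, b_se = _through_origin(A, Fa)
            c, c_se = 0.0, 0.0
        else:
            # joint design: donor rows (D, 0, 1), acceptor rows (0, A, 1)
            M = np.zeros((len(D) + len(A), 3))
            M[: len(D), 0] = D
            M[len(D):, 1] = A
            M[:, 2] = 1.0
            yv = np.concatenate([Fd, Fa])
            coef, res, rank, _ = np.linalg.lstsq(M, yv, rcond=None)
            a, b, c = map(float, coef)
            dof = len(yv) - 3
            s2 = float(res[0]) / dof if len(res) and dof > 0 else np.nan
            cov = s2 * np.linalg.inv(M.T @ M) if np.isfinite(s2) else np.full((3, 3), np.nan)
            a_se, b_se, c_se = (float(np.sqrt(cov[i, i])) for i in range(3))
        self.model_ = BleedthroughModel(a, b, c, a_se, b_se, c_se, self.variant)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append a ``cFRET`` column to a measurement table."""
        check_is_fitted(self, "model_")
        out = X.copy()
        out["cFRET"] = [
            corrected_fret(SpectralMeasurement(r.D, r.A, r.F, self.variant), self.model_)
            for r in X.itertuples()
        ]
        return out


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    dof = len(x) - 1
    if dof > 0:
        s2 = float(np.sum((y - slope * x) ** 2)) / dof
        se = float(np.sqrt(s2 / sxx))
    else:
        se = np.nan
    return slope, se


@dataclass
class SpectralMeasurement:
    D: float
    A: float
    F: float
    variant: str = "cfp_venus"

    def __post_init__(self):
        vals = (self.D, self.A, self.F)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("channel readings must be finite")
        if self.D < 0 or self.A < 0:
            raise ValueError("channel readings must be non-negative")


def estimate_bleedthrough(donor_only, acceptor_only, variant: str = "cfp_venus") -> BleedthroughModel:
    """Functional wrapper: (D, F) and (A, F) series → BleedthroughModel."""
    d = np.asarray(donor_only, dtype=float)
    a = np.asarray(acceptor_only, dtype=float)
    table = pd.concat(
        [
            pd.DataFrame({"role": "donor_only", "D": d[:, 0], "A": 0.0, "F": d[:, 1]}),
            pd.DataFrame({"role": "acceptor_only", "D": 0.0, "A": a[:, 0], "F": a[:, 1]}),
        ],
        ignore_index=True,
    )
    return BleedthroughEstimator(variant=variant).fit(table).model_


def corrected_fret(m: SpectralMeasurement, model: BleedthroughModel) -> float:
    """cFRET = F − a·D − b·A − c; negative values are retained."""
    if m.variant != model.variant:
        raise ValueError(
            f"measurement variant {m.variant!r} does not match model {model.variant!r}"
        )
    return float(m.F - model.a * m.D - model.b * m.A - model.c)
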