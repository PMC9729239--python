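"""Univariable inverse-variance weighted (IVW) Mendelian randomization
with correlated instruments.

The causal effect of an exposure E on an outcome Y is estimated by
generalized least squares of the outcome IV effects on the exposure IV
effects, weighting by the inverse LD matrix C:

    theta_hat = (b_E' C^-1 b_E)^-1 b_E' C^-1 b_Y

with a Delta-method standard error using the sandwich

    (b_E' C^-1 b_E)^-1 b_E' C^-1/2 Sigma C^-1/2 b_E (b_E' C^-1 b_E)^-1

where Sigma is diagonal with entries max(s^2, var(b_Yi)) and s^2 is the
C^-1-weighted residual variance of the fit. Cochran's Q heterogeneity is
computed on C^-1/2-decorrelated residuals with m-1 degrees of freedom
(reducing to the standard independent-IV Q when C = I).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import inverse_sqrt, regularized_inverse


@dataclass
class InstrumentSet:
    """Aligned IV effect vectors and LD submatrix for one pair.

    ``beta_M``/``var_M`` hold per-mediator marginal effects keyed by
    mediator ID (used by the multivariable model; may be empty).
    """

    pair_id: str
    iv_ids: list[str]
    beta_E: np.ndarray
    var_E: np.ndarray
    beta_Y: np.ndarray
    var_Y: np.ndarray
    C: np.ndarray
    beta_M: dict[str, np.ndarray] = field(default_factory=dict)
    var_M: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("beta_E", "var_E", "beta_Y", "var_Y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.C = np.asarray(self.C, dtype=float)
        m = len(self.iv_ids)
        if len(set(self.iv_ids)) != m:
            raise ValueError("instrument IDs must be unique")
        for name in ("beta_E", "var_E", "beta_Y", "var_Y"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length != number of instruments")
        if self.C.shape != (m, m):
            raise ValueError("C must be m x m")
        if not np.allclose(np.diag(self.C), 1.0, atol=1e-8):
            raise ValueError("C must have unit diagonal")

    @property
    def m(self) -> int:
        return len(self.iv_ids)


class IVWModel:
    """Univariable MR model for one exposure-outcome pair.

    Parameters
    ----------
    instruments : InstrumentSet
        Harmonized IV effects and their LD matrix.
    """

    def __init__(self, instruments: InstrumentSet):
        if instruments.m == 0:
            raise ValueError("at least one instrument required")
        self.instruments = instruments

    @classmethod
    def from_arrays(cls, beta_E, var_E, beta_Y, var_Y, C=None,
                    pair_id: str = "pair", iv_ids=None) -> "IVWModel":
        beta_E = np.asarray(beta_E, float)
        m = len(beta_E)
        if C is None:
            C = np.eye(m)
        if iv_ids is None:
            iv_ids = [f"iv{i}" for i in range(m)]
        return cls(InstrumentSet(pair_id, list(iv_ids), beta_E, var_E,
                                 beta_Y, var_Y, C))

    def fit(self) -> "IVWResults":
        iv = self.instruments
        m = iv.m
        Cinv = regularized_inverse(iv.C)
        Cmh = inverse_sqrt(iv.C)
        bE, bY = iv.beta_E, iv.beta_Y
        denom = float(bE @ Cinv @ bE)
        if denom <= 0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError("singular weighting: b_E' C^-1 b_E <= 0")
        theta = float(bE @ Cinv @ bY) / denom
        resid = bY - theta * bE
        if m > 1:
            s2 = float(resid @ Cinv @ resid) / (m - 1)
        else:
            s2 = float(iv.var_Y[0])
        sigma_diag = np.maximum(s2, iv.var_Y)
        w = Cmh @ bE
        se = float(np.sqrt((w * sigma_diag) @ w)) / denom
        # clip underflowed p-values so they stay in (0, 1]
        tiny = float(np.finfo(float).tiny)
        pvalue = (max(float(2 * stats.norm.sf(abs(theta / se))), tiny)
                  if se > 0 else tiny)
        return IVWResults(self, theta=theta, se=se, pvalue=pvalue, m=m,
                          s2=s2, sigma_diag=sigma_diag,
                          _Cinv=Cinv, _Cmh=Cmh)


@dataclass
class IVWResults:
    """Estimates and diagnostics from :meth:`IVWModel.fit`."""

    model: IVWModel
    theta: float
    se: float
    pvalue: float
    m: int
    s2: float
    sigma_diag: np.ndarray
    _Cinv: np.ndarray
    _Cmh: np.ndarray

    def q_statistic(self) -> tuple[float, int, float]:
        """Cochran's Q on decorrelated residuals, df = m - 1.

        Quantifies the deviation of per-IV causal estimates from the
        pooled IVW estimate; large values flag pleiotropic outliers.
        """
        iv = self.model.instruments
        if self.m < 2:
            raise ValueError("Q undefined for fewer than 2 instruments")
        u = self._Cmh @ (iv.beta_Y - self.theta * iv.beta_E)
        Q = float(np.sum(u ** 2 / self.sigma_diag))
        df = self.m - 1
        p = float(stats.chi2.sf(Q, df))
        return Q, df, p

    def summary(self) -> str:
        iv = self.model.instruments
        lines = [
            "Univariable IVW MR (correlated instruments)",
            f"  pair:        {iv.pair_id}",
            f"  instruments: {self.m}",
            f"  theta:       {self.theta:.6g}",
            f"  se:          {self.se:.6g}",
            f"  p-value:     {self.pvalue:.3g}",
        ]
        if self.m >= 2:
            Q, df, p = self.q_statistic()
            lines.append(f"  Q:           {Q:.4g} (df={df}, p={p:.3g})")
        return "\n".join(lines)
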