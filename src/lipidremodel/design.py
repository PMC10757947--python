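"""Least-squares machinery for the two-factor factorial RCBD design.

The experiment is genotype x temperature-treatment with blocked
replications; the model fitted here is

    y = mu + genotype + treatment + genotype:treatment + block (+ run) + e

with every term fixed. Treatment LS-means are predictions averaged over
the genotype and block (and run) levels, and Fisher's LSD at level alpha is
t(1 - alpha/2, df_error) * SE(difference); for the balanced design this
reduces to the textbook t * sqrt(2 * MSE / n_per_mean).

Blocks are fitted as fixed effects rather than random: on a balanced
design the LS-means coincide with a mixed-model fit and only the error
stratum (hence the LSD) can differ slightly. The model matrix is exposed
(``FactorialFit.X``) for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FactorialFit", "ComparisonResult", "percent_change"]


def percent_change(ot: float, ht: float) -> float:
    """100 * (HT - OT) / OT; requires a positive OT reference."""
    if ot <= 0:
        raise ValueError(f"percent change needs a positive OT value, got {ot}")
    return 100.0 * (ht - ot) / ot


@dataclass(frozen=True)
class ComparisonResult:
    """OT-vs-HT comparison of one response under the factorial model."""

    response: str
    ls_mean_ot: float
    ls_mean_ht: float
    se_ot: float
    se_ht: float
    lsd: float
    significant: bool
    mse: float
    df_error: int
    alpha: float = 0.05

    @property
    def percent_change(self) -> Optional[float]:
        if self.ls_mean_ot <= 0:
            return None
        return percent_change(self.ls_mean_ot, self.ls_mean_ht)

    @property
    def fold_change(self) -> Optional[float]:
        if self.ls_mean_ot <= 0:
            return None
        return self.ls_mean_ht / self.ls_mean_ot


class _Encoder:
    """Dummy coding (first level dropped) with a fixed level ordering, so
    prediction rows for new factor combinations are consistent."""

    def __init__(self, meta: pd.DataFrame, factors: Sequence[str]):
        self.factors = list(factors)
        self.levels = {f: sorted(pd.unique(meta[f]).tolist()) for f in factors}

    def n_columns(self) -> int:
        g, t = len(self.levels["genotype"]), len(self.levels["treatment"])
        n = 1 + (g - 1) + (t - 1) + (g - 1) * (t - 1)
        n += len(self.levels["block"]) - 1
        if "run" in self.factors:
            n += len(self.levels["run"]) - 1
        return n

    def encode(self, meta: pd.DataFrame) -> np.ndarray:
        n = len(meta)
        cols = [np.ones(n)]

        def dummies(factor):
            lv = self.levels[factor]
            vals = meta[factor].to_numpy()
            return [(vals == l).astype(float) for l in lv[1:]], lv

        gd, _ = dummies("genotype")
        td, _ = dummies("treatment")
        cols += gd + td
        for g in gd:
            for t in td:
                cols.append(g * t)
        bd, _ = dummies("block")
        cols += bd
        if "run" in self.factors:
            rd, _ = dummies("run")
            cols += rd
        return np.column_stack(cols)


class FactorialFit:
    """OLS fit of the factorial RCBD model to one or many response columns.

    Parameters
    ----------
    meta : sample metadata with columns genotype, treatment, block (+ run),
        experimental samples only.
    Y : DataFrame (samples x responses) aligned with ``meta``.
    include_run : add the experimental run as a fixed effect (runs are
        pooled by default).
    """

    def __init__(self, meta: pd.DataFrame, Y: pd.DataFrame,
                 include_run: bool = False):
        if isinstance(Y, pd.Series):
            Y = Y.to_frame()
        if len(meta) != len(Y):
            raise ValueError("meta and Y must have the same number of rows")
        for t in ("OT", "HT"):
            if not (meta["treatment"] == t).any():
                raise ValueError(f"treatment {t} has zero observations")
        factors = ["genotype", "treatment", "block"] + (
            ["run"] if include_run else [])
        self.meta = meta.reset_index(drop=True)
        self.responses = list(Y.columns)
        self._Y = Y.to_numpy(dtype=float)
        self._enc = _Encoder(self.meta, factors)
        self.X = self._enc.encode(self.meta)
        self._XtX_pinv = np.linalg.pinv(self.X.T @ self.X)
        self.beta = self._XtX_pinv @ (self.X.T @ self._Y)
        resid = self._Y - self.X @ self.beta
        self.rank = int(np.linalg.matrix_rank(self.X))
        self.df_error = self.X.shape[0] - self.rank
        if self.df_error <= 0:
            raise ValueError("saturated design: no residual degrees of freedom")
        ss = (resid ** 2).sum(axis=0)
        self.mse = pd.Series(ss / self.df_error, index=self.responses)

        self._L_treat = {t: self._treatment_row(t) for t in ("OT", "HT")}

    # -- contrast rows ----------------------------------------------------
    def _grid(self, treatment: str, genotype: Optional[str] = None) -> pd.DataFrame:
        lv = self._enc.levels
        genos = [genotype] if genotype is not None else lv["genotype"]
        rows = []
        runs = lv.get("run", [None])
        for g in genos:
            for b in lv["block"]:
                for r in runs:
                    row = {"genotype": g, "treatment": treatment, "block": b}
                    if r is not None:
                        row["run"] = r
                    rows.append(row)
        return pd.DataFrame(rows)

    def _treatment_row(self, treatment: str) -> np.ndarray:
        G = self._enc.encode(self._grid(treatment))
        return G.mean(axis=0)

    def _cell_row(self, genotype: str, treatment: str) -> np.ndarray:
        G = self._enc.encode(self._grid(treatment, genotype))
        return G.mean(axis=0)

    # -- estimates --------------------------------------------------------
    def ls_means(self) -> pd.DataFrame:
        """Treatment LS-means (rows OT/HT, one column per response)."""
        out = {t: L @ self.beta for t, L in self._L_treat.items()}
        return pd.DataFrame(out, index=self.responses).T

    def ls_mean_se(self) -> pd.DataFrame:
        out = {}
        for t, L in self._L_treat.items():
            v = float(L @ self._XtX_pinv @ L)
            out[t] = np.sqrt(np.maximum(self.mse.to_numpy() * v, 0.0))
        return pd.DataFrame(out, index=self.responses).T

    def cell_ls_means(self) -> pd.DataFrame:
        """Genotype x treatment LS-means; MultiIndex (genotype, treatment)."""
        lv = self._enc.levels
        rows, idx = [], []
        for g in lv["genotype"]:
            for t in lv["treatment"]:
                rows.append(self._cell_row(g, t) @ self.beta)
                idx.append((g, t))
        return pd.DataFrame(
            rows, index=pd.MultiIndex.from_tuples(idx, names=["genotype", "treatment"]),
            columns=self.responses)

    def lsd(self, alpha: float = 0.05) -> pd.Series:
        """Fisher's least significant difference for the OT-vs-HT contrast."""
        d = self._L_treat["HT"] - self._L_treat["OT"]
        v = float(d @ self._XtX_pinv @ d)
        tcrit = stats.t.ppf(1 - alpha / 2, self.df_error)
        return pd.Series(tcrit * np.sqrt(np.maximum(self.mse.to_numpy() * v, 0.0)),
                         index=self.responses)

    def compare(self, alpha: float = 0.05) -> list[ComparisonResult]:
        lsm, se, lsd = self.ls_means(), self.ls_mean_se(), self.lsd(alpha)
        out = []
        for r in self.responses:
            diff = lsm.loc["HT", r] - lsm.loc["OT", r]
            out.append(ComparisonResult(
                response=str(r),
                ls_mean_ot=float(lsm.loc["OT", r]),
                ls_mean_ht=float(lsm.loc["HT", r]),
                se_ot=float(se.loc["OT", r]),
                se_ht=float(se.loc["HT", r]),
                lsd=float(lsd[r]),
                significant=bool(abs(diff) > lsd[r]),
                mse=float(self.mse[r]),
                df_error=self.df_error,
                alpha=alpha,
            ))
        return out
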