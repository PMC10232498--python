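"""Shared statistical helpers: scaling, likelihood-ratio tests, effect tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def zscore(x) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def lr_test(llf_null: float, llf_full: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square and p-value for nested models."""
    chi2 = max(0.0, 2.0 * (llf_full - llf_null))
    return chi2, float(stats.chi2.sf(chi2, df))


def effect_row(model: str, term: str, estimate=np.nan, se=np.nan, lr_chi2=np.nan,
               df=np.nan, p=np.nan, aic=np.nan, engine="", note="") -> dict:
    return dict(model=model, term=term, estimate=estimate, se=se, lr_chi2=lr_chi2,
                df=df, p=p, aic=aic, engine=engine, note=note)


def effect_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["model", "term", "estimate", "se", "lr_chi2",
                                       "df", "p", "aic", "engine", "note"])


def fisher_z(rho: float) -> float:
    rho = np.clip(rho, -0.999999, 0.999999)
    return float(0.5 * np.log((1 + rho) / (1 - rho)))
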