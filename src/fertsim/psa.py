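"""Analysis of the probabilistic-sensitivity-analysis output table.

Three complementary views rank the herd-level inputs by their influence on
the modified FERTEX score:

* Spearman rank correlation of each input against mFX (non-parametric,
  because mFX is positively skewed);
* a variance partition from a multiple linear regression of ln(mFX) on the
  seven inputs — the share of an input is the reduction in residual sum of
  squares when it is added last, as a percentage of the total sum of
  squares (with mutually independent uniform inputs this is order-invariant
  up to Monte Carlo error);
* tornado deltas — the predicted change in mFX (pounds/cow/year) when one
  input moves from its distribution median to its upper quartile while the
  others sit at their medians, evaluated on the fitted regression surface
  and back-transformed from the log scale.

mFX scores at or below zero are possible (a herd can beat its fertility
targets); when any occur the log transform is applied to
``mfx - min(mfx) + 1`` and the shift undone on back-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulator import HERD_INPUT_RANGES

__all__ = [
    "INPUT_NAMES",
    "PsaRegression",
    "PsaSummary",
    "spearman_correlations",
    "variance_partition",
    "tornado",
    "summarise",
    "input_median",
    "input_upper_quartile",
]

INPUT_NAMES = tuple(HERD_INPUT_RANGES)


def input_median(name: str) -> float:
    lo, hi = HERD_INPUT_RANGES[name]
    return 0.5 * (lo + hi)


def input_upper_quartile(name: str) -> float:
    lo, hi = HERD_INPUT_RANGES[name]
    return lo + 0.75 * (hi - lo)


def spearman_correlations(
    psa_table: pd.DataFrame,
    inputs=INPUT_NAMES,
    outcome: str = "mfx",
) -> pd.Series:
    """Spearman rank correlation of each herd-level input against mFX.

    A constant column has no rank ordering; its correlation is reported as
    NaN.
    """
    if len(psa_table) < 10:
        raise ValueError("need at least 10 herds")
    y = psa_table[outcome].to_numpy(float)
    out = {}
    for name in inputs:
        x = psa_table[name].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = np.nan
        else:
            out[name] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(out, name="spearman_rho")


@dataclass
class PsaRegression:
    """ln(mFX) regression surface fitted to a PSA table."""

    model: object                 # statsmodels OLS results
    inputs: tuple[str, ...]
    shift: float                  # ln transform applied to (mfx - shift)

    def predict_mfx(self, values: dict[str, float]) -> float:
        """Back-transformed mFX prediction at one input setting."""
        row = pd.DataFrame([{n: values[n] for n in self.inputs}])
        row = sm.add_constant(row, has_constant="add")
        ln_pred = float(self.model.predict(row).iloc[0])
        return float(np.exp(ln_pred) + self.shift)


def _log_outcome(mfx: np.ndarray) -> tuple[np.ndarray, float]:
    if (mfx <= 0).any():
        shift = float(mfx.min()) - 1.0
    else:
        shift = 0.0
    return np.log(mfx - shift), shift


def variance_partition(
    psa_table: pd.DataFrame,
    inputs=INPUT_NAMES,
    outcome: str = "mfx",
) -> tuple[pd.Series, PsaRegression]:
    """Percentage of ln(mFX) variance attributable to each input.

    Fits an ordinary least-squares regression of ln(mFX) on the inputs
    (main effects) and attributes to input k the reduction in residual sum
    of squares when k is added last, as % of the total sum of squares.
    """
    y, shift = _log_outcome(psa_table[outcome].to_numpy(float))
    X = psa_table.loc[:, list(inputs)].astype(float)
    # guard against (by construction unreachable) collinearity
    rank = np.linalg.matrix_rank(np.corrcoef(X.to_numpy().T))
    if rank < len(inputs):
        raise ValueError("collinear input columns")
    full = sm.OLS(y, sm.add_constant(X)).fit()
    rss_full = float(full.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    shares = {}
    for name in inputs:
        reduced = sm.OLS(
            y, sm.add_constant(X.drop(columns=[name]))
        ).fit()
        shares[name] = 100.0 * (float(reduced.ssr) - rss_full) / tss
    return (
        pd.Series(shares, name="variance_share_pct"),
        PsaRegression(model=full, inputs=tuple(inputs), shift=shift),
    )


def tornado(
    regression: PsaRegression,
    mode: str = "regression",
    resimulate_kwargs: dict | None = None,
) -> pd.Series:
    """Predicted mFX change when each input moves median -> upper quartile.

    Positive deltas mean the mFX score increases (performance worsens).
    ``mode="regression"`` (default) evaluates the fitted ln-scale regression
    surface; ``mode="resimulate"`` re-runs the herd simulator with common
    random numbers at the median and perturbed input settings (slower,
    provided for validation — see :func:`tornado_resimulate`).
    """
    if mode == "resimulate":
        return tornado_resimulate(**(resimulate_kwargs or {}))
    if mode != "regression":
        raise ValueError("mode must be 'regression' or 'resimulate'")
    medians = {n: input_median(n) for n in regression.inputs}
    base = regression.predict_mfx(medians)
    deltas = {}
    for name in regression.inputs:
        moved = dict(medians)
        moved[name] = input_upper_quartile(name)
        deltas[name] = regression.predict_mfx(moved) - base
    return pd.Series(deltas, name="tornado_delta")


def tornado_resimulate(
    n_herds: int = 200,
    n_lactations: int = 200,
    seed: int = 0,
    inputs=INPUT_NAMES,
    **sim_kw,
) -> pd.Series:
    """Tornado deltas by direct re-simulation with common random numbers.

    For each input, ``n_herds`` replicate herds are simulated at the
    all-median setting and at the setting with that input at its upper
    quartile, sharing random-number streams; the delta is the difference in
    mean mFX.
    """
    from .simulator import (
        HerdInputs,
        LamenessDimDistribution,
        simulate_herd,
    )
    from .config import default_coefficients

    coefs = sim_kw.pop("coefs", None) or default_coefficients()
    dist = sim_kw.pop("dist", None) or LamenessDimDistribution.default()
    medians = {n: input_median(n) for n in INPUT_NAMES}

    def mean_mfx(settings):
        children = np.random.SeedSequence(seed).spawn(n_herds)
        vals = []
        for child in children:
            rng = np.random.default_rng(child)
            out = simulate_herd(
                HerdInputs(**settings), coefs, dist,
                n_lactations=n_lactations, rng=rng, **sim_kw,
            )
            vals.append(out.mfx)
        return float(np.mean(vals))

    base = mean_mfx(medians)
    deltas = {}
    for name in inputs:
        moved = dict(medians)
        moved[name] = input_upper_quartile(name)
        deltas[name] = mean_mfx(moved) - base
    return pd.Series(deltas, name="tornado_delta")


@dataclass
class PsaSummary:
    """Bundled PSA analysis: correlations, variance shares, tornado deltas."""

    spearman_rho: pd.Series
    variance_share: pd.Series
    tornado_delta: pd.Series
    n_herds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spearman_rho": self.spearman_rho,
                "variance_share_pct": self.variance_share,
                "tornado_delta_gbp": self.tornado_delta,
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "n_herds": self.n_herds,
            "spearman_rho": self.spearman_rho.to_dict(),
            "variance_share_pct": self.variance_share.to_dict(),
            "tornado_delta_gbp": self.tornado_delta.to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarise(psa_table: pd.DataFrame, inputs=INPUT_NAMES) -> PsaSummary:
    """Full analysis of a PSA table (correlations + partition + tornado)."""
    rho = spearman_correlations(psa_table, inputs)
    shares, reg = variance_partition(psa_table, inputs)
    deltas = tornado(reg)
    return PsaSummary(
        spearman_rho=rho,
        variance_share=shares,
        tornado_delta=deltas,
        n_herds=len(psa_table),
    )


def binned_scatter(
    psa_table: pd.DataFrame,
    input_name: str,
    outcome: str = "mfx",
    bins: int = 60,
) -> pd.DataFrame:
    """2-D binned counts of (input, mFX) for high-density scatterplots."""
    x = psa_table[input_name].to_numpy(float)
    y = psa_table[outcome].to_numpy(float)
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    xi, yi = np.nonzero(counts)
    return pd.DataFrame(
        {
            input_name: 0.5 * (xe[xi] + xe[xi + 1]),
            outcome: 0.5 * (ye[yi] + ye[yi + 1]),
            "count": counts[xi, yi].astype(int),
        }
    )
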