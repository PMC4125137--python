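"""Synthetic cow-level event datasets with known ground truth.

No herd-management dataset accompanies the published analysis, so this
module generates one: herds of cow-lactations whose two-day conception
outcomes are drawn from the discrete-time survival model itself, with known
coefficients and known cow/herd random effects.  The output uses exactly
the delimited-text schema the restructuring module reads, which makes the
whole pipeline testable end to end — restructuring can be checked against
the generator's internal bin walk, and model fitting against the generating
coefficients.

Structure emulated: herd sizes and herd-level lameness incidence and yield
in the ranges observed across the 39 source herds; calving dates uniform
over 2002-2008 so every calendar-year category is populated; clinical
lameness events placed through lactation by the same front-loaded DIM
distribution the herd simulator uses; censoring by a constant daily cull
hazard tuned to an annual cull rate of 22%.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DtsmCoefficients,
    LAMENESS_WINDOWS,
    default_coefficients,
)
from .restructure import (
    RISK_WINDOW_START,
    RISK_WINDOW_END,
    dedupe_lameness_events,
)
from .simulator import (
    LamenessDimDistribution,
    _draw_lameness_events,
    _draw_parity_yield,
    window_flag_matrix,
)
from scipy.special import expit

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_dataset",
           "default_truth"]


def default_truth() -> DtsmCoefficients:
    """The generating coefficient set: the published point estimates."""
    return default_coefficients()


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic dataset generator."""

    n_herds: int = 39
    cows_per_herd: int = 320
    true_coefficients: DtsmCoefficients = field(default_factory=default_truth)
    lameness_ir_range: tuple[float, float] = (0.10, 1.88)
    herd_yield_range: tuple[float, float] = (4776.0, 11008.0)
    prop_lact1: float = 0.25
    parity_decay: float = 0.75
    lameness_dim_distribution: LamenessDimDistribution | None = None
    calving_start: _dt.date = _dt.date(2002, 1, 1)
    calving_end: _dt.date = _dt.date(2008, 6, 30)
    cull_rate_year: float = 0.22
    yield_centre: float | None = None   # default: midpoint of herd_yield_range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_herds < 1:
            raise ValueError("n_herds must be >= 1")
        if self.true_coefficients.sigma2_cow < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    lactations: pd.DataFrame
    lameness_events: pd.DataFrame
    truth: dict


_SIM_BINS = np.arange(RISK_WINDOW_START, RISK_WINDOW_END, 2)  # 20..218

#: lactation number written out per parity category (">4" emitted as 5).
_LACT_NO = {"1": 1, "2": 2, "3": 3, "4": 4, ">4": 5}


def _dedupe_event_matrix(events: np.ndarray) -> np.ndarray:
    """Apply the 7-day duplicate rule to a boolean (m, 150) event matrix."""
    clean = np.zeros_like(events)
    for i in np.nonzero(events.sum(axis=1) > 0)[0]:
        dims = (np.nonzero(events[i])[0] * 2).tolist()
        for d in dedupe_lameness_events(dims):
            clean[i, d // 2] = True
    return clean


def _quarter_index(calving: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Calendar-quarter index (0-3) of calving + dim days, exact calendar."""
    dates = calving[:, None] + dims.astype("timedelta64[D]")[None, :]
    months = (
        dates.astype("datetime64[M]")
        - dates.astype("datetime64[Y]").astype("datetime64[M]")
    ).astype(int)
    return months // 3


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate a cow-event dataset from known model coefficients.

    Every lactation is walked through the two-day bins 20-218 DIM: the true
    coefficients (plus the cow's and herd's random effects) give the
    conception probability per bin, a constant two-day cull hazard may
    censor the lactation, and survivors of the whole window are recorded as
    administratively censored at 300 DIM.  Identical config and seed give
    byte-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    coefs = cfg.true_coefficients
    dist = cfg.lameness_dim_distribution or LamenessDimDistribution.default()
    yield_centre = (
        cfg.yield_centre
        if cfg.yield_centre is not None
        else 0.5 * (cfg.herd_yield_range[0] + cfg.herd_yield_range[1])
    )
    p_cens = 1.0 - (1.0 - cfg.cull_rate_year) ** (2.0 / 365.0)
    season_coefs = np.array(
        [coefs.season_coef(c) for c in
         ("Jan-Mar", "Apr-Jun", "Jul-Sep", "Oct-Dec")]
    )
    ln = np.log(_SIM_BINS.astype(float))
    base = coefs.alpha + coefs.beta_lndim * ln + coefs.beta_lndim_sq * ln**2
    n_days = (cfg.calving_end - cfg.calving_start).days + 1
    start64 = np.datetime64(cfg.calving_start.isoformat())

    lact_rows, lame_rows = [], []
    v_by_herd, u_by_cow, ir_by_herd = {}, {}, {}
    n_periods_all, outcome_all = [], []

    for h in range(cfg.n_herds):
        herd_id = f"h{h + 1:02d}"
        m = cfg.cows_per_herd
        v = rng.normal(0.0, np.sqrt(coefs.sigma2_herd))
        v_by_herd[herd_id] = v
        ir = rng.uniform(*cfg.lameness_ir_range)
        ir_by_herd[herd_id] = ir
        herd_yield = rng.uniform(*cfg.herd_yield_range)

        u = rng.normal(0.0, np.sqrt(coefs.sigma2_cow), size=m)
        parity_cats, yields = _draw_parity_yield(
            cfg.prop_lact1, herd_yield, m, rng, cfg.parity_decay
        )
        calving = start64 + rng.integers(0, n_days, size=m).astype(
            "timedelta64[D]"
        )
        events = _dedupe_event_matrix(
            _draw_lameness_events(ir, dist, m, rng)
        )
        flags = window_flag_matrix(events, _SIM_BINS, LAMENESS_WINDOWS)

        parity_coef = np.array([coefs.parity_coef(c) for c in parity_cats])
        years = calving.astype("datetime64[Y]").astype(int) + 1970
        year_coef = np.array(
            [
                coefs.year_coef(
                    "<=2002" if y <= 2002 else ("2007-8" if y >= 2007 else str(y))
                )
                for y in years
            ]
        )
        yc = (yields - yield_centre) / 1000.0
        eta = base[None, :] + (
            parity_coef + year_coef + coefs.beta_yield * yc + u + v
        )[:, None]
        eta = eta + season_coefs[_quarter_index(calving, _SIM_BINS)]
        for w in LAMENESS_WINDOWS:
            b = coefs.beta_lameness[w]
            if b != 0.0:
                eta = eta + b * flags[w]
        mu = expit(eta)

        u1 = rng.random((m, len(_SIM_BINS)))
        u2 = rng.random((m, len(_SIM_BINS)))
        conc = u1 < mu
        cens = (~conc) & (u2 < p_cens)
        ev = conc | cens
        any_ev = ev.any(axis=1)
        first = ev.argmax(axis=1)
        is_conc = conc[np.arange(m), first] & any_ev

        for i in range(m):
            cow_id = f"c{i + 1:04d}"
            u_by_cow[(herd_id, cow_id)] = u[i]
            if any_ev[i]:
                t = int(first[i])
                end_dim = int(_SIM_BINS[t]) + 1
                reason = "pregnant" if is_conc[i] else "culled"
                n_periods = t + 1
            else:
                end_dim = 300
                reason = "censored"
                n_periods = len(_SIM_BINS)
            n_periods_all.append(n_periods)
            outcome_all.append(reason == "pregnant")
            lact_rows.append(
                {
                    "herd_id": herd_id,
                    "cow_id": cow_id,
                    "lactation_no": _LACT_NO[parity_cats[i]],
                    "calving_date": str(calving[i]),
                    "yield_305d": round(float(yields[i]), 1),
                    "end_dim": end_dim,
                    "end_reason": reason,
                }
            )
            for b_idx in np.nonzero(events[i])[0]:
                lame_rows.append(
                    {
                        "herd_id": herd_id,
                        "cow_id": cow_id,
                        "lactation_no": lact_rows[-1]["lactation_no"],
                        "dim": int(b_idx * 2),
                    }
                )

    lactations = pd.DataFrame(lact_rows)
    lameness = pd.DataFrame(
        lame_rows, columns=["herd_id", "cow_id", "lactation_no", "dim"]
    )
    n_periods_arr = np.array(n_periods_all)
    truth = {
        "coefficients": coefs,
        "yield_centre": yield_centre,
        "v_by_herd": v_by_herd,
        "u_by_cow": u_by_cow,
        "lameness_ir_by_herd": ir_by_herd,
        "n_periods": n_periods_arr,
        "n_pregnant": int(np.sum(outcome_all)),
        "event_proportion": float(
            np.sum(outcome_all) / n_periods_arr.sum()
        ),
    }
    return SyntheticDataset(
        lactations=lactations, lameness_events=lameness, truth=truth
    )
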