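"""Model coefficients, category codings and configuration I/O.

The discrete-time survival model predicts the probability that a cow
conceives during a two-day risk period.  Its coefficient set is the single
object shared by the fitting, simulation and data-generation code:

* ``alpha`` — regression intercept,
* ``beta_lndim`` / ``beta_lndim_sq`` — quadratic baseline hazard in
  ln(days in milk),
* ``beta_parity`` / ``beta_year`` / ``beta_season`` / ``beta_yield`` —
  lactation- and period-level covariates (reference categories: parity 1,
  year <=2002, season Jan-Mar; yield is centred 305-day yield per 1000 L),
* ``beta_lameness`` — one coefficient per lameness time window relative to
  the risk period; windows not retained in the final model carry 0,
* ``sigma2_cow`` / ``sigma2_herd`` — variances of the cow- and herd-level
  normal random effects.

Coefficients are stored on the log-odds scale; the packaged default asset
(``data/default_coefficients.yaml``) stores odds ratios where the published
estimates are odds ratios and is converted on load.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "PARITY_CATEGORIES",
    "YEAR_CATEGORIES",
    "SEASON_CATEGORIES",
    "LAMENESS_WINDOWS",
    "WINDOW_DAY_BOUNDS",
    "DtsmCoefficients",
    "default_coefficients",
    "load_coefficients",
    "save_coefficients",
    "setup_logging",
]

PARITY_CATEGORIES = ("1", "2", "3", "4", ">4")
YEAR_CATEGORIES = ("<=2002", "2003", "2004", "2005", "2006", "2007-8")
SEASON_CATEGORIES = ("Jan-Mar", "Apr-Jun", "Jul-Sep", "Oct-Dec")

#: Lameness windows in temporal order.  Each flags whether a clinical
#: lameness event was recorded in the given day range relative to the risk
#: period (negative = before).
LAMENESS_WINDOWS = (
    "lame_71_100_before",
    "lame_43_70_before",
    "lame_15_42_before",
    "lame_within_14",
    "lame_15_42_after",
    "lame_43_70_after",
    "lame_71_100_after",
)

#: Inclusive day offsets (event DIM minus risk-period anchor DIM) per window.
WINDOW_DAY_BOUNDS: Mapping[str, tuple[int, int]] = {
    "lame_71_100_before": (-100, -71),
    "lame_43_70_before": (-70, -43),
    "lame_15_42_before": (-42, -15),
    "lame_within_14": (-14, 14),
    "lame_15_42_after": (15, 42),
    "lame_43_70_after": (43, 70),
    "lame_71_100_after": (71, 100),
}


def _zero_dict(keys) -> dict[str, float]:
    return {k: 0.0 for k in keys}


@dataclass
class DtsmCoefficients:
    """Fixed effects and random-effect variances of the conception-hazard model.

    All category coefficients are relative to the reference level (parity 1,
    year <=2002, season Jan-Mar, no lameness), whose coefficient is exactly 0
    and therefore not stored.
    """

    alpha: float = 0.0
    beta_lndim: float = 0.0
    beta_lndim_sq: float = 0.0
    beta_parity: dict[str, float] = field(
        default_factory=lambda: _zero_dict(PARITY_CATEGORIES[1:])
    )
    beta_year: dict[str, float] = field(
        default_factory=lambda: _zero_dict(YEAR_CATEGORIES[1:])
    )
    beta_season: dict[str, float] = field(
        default_factory=lambda: _zero_dict(SEASON_CATEGORIES[1:])
    )
    beta_yield: float = 0.0
    beta_lameness: dict[str, float] = field(
        default_factory=lambda: _zero_dict(LAMENESS_WINDOWS)
    )
    sigma2_cow: float = 0.0
    sigma2_herd: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_cow < 0 or self.sigma2_herd < 0:
            raise ValueError("random-effect variances must be non-negative")
        # fill unspecified categories with 0 so lookups never fail
        for cat in PARITY_CATEGORIES[1:]:
            self.beta_parity.setdefault(cat, 0.0)
        for cat in YEAR_CATEGORIES[1:]:
            self.beta_year.setdefault(cat, 0.0)
        for cat in SEASON_CATEGORIES[1:]:
            self.beta_season.setdefault(cat, 0.0)
        for w in LAMENESS_WINDOWS:
            self.beta_lameness.setdefault(w, 0.0)

    def parity_coef(self, cat: str) -> float:
        return 0.0 if cat == PARITY_CATEGORIES[0] else self.beta_parity[cat]

    def year_coef(self, cat: str) -> float:
        return 0.0 if cat == YEAR_CATEGORIES[0] else self.beta_year[cat]

    def season_coef(self, cat: str) -> float:
        return 0.0 if cat == SEASON_CATEGORIES[0] else self.beta_season[cat]

    def replace(self, **kw) -> "DtsmCoefficients":
        return replace(self, **kw)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.alpha,
            "ln_dim": self.beta_lndim,
            "ln_dim_sq": self.beta_lndim_sq,
            "odds_ratios": {
                "parity": {k: math.exp(v) for k, v in self.beta_parity.items()},
                "year": {k: math.exp(v) for k, v in self.beta_year.items()},
                "season": {k: math.exp(v) for k, v in self.beta_season.items()},
                "yield_per_1000l": math.exp(self.beta_yield),
                "lameness": {
                    k: math.exp(v) for k, v in self.beta_lameness.items()
                },
            },
            "variance": {"cow": self.sigma2_cow, "herd": self.sigma2_herd},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DtsmCoefficients":
        ors = d.get("odds_ratios", {})

        def _log(mapping):
            return {k: math.log(v) for k, v in dict(mapping or {}).items()}

        var = d.get("variance", {}) or {}
        return cls(
            alpha=float(d["intercept"]),
            beta_lndim=float(d["ln_dim"]),
            beta_lndim_sq=float(d["ln_dim_sq"]),
            beta_parity=_log(ors.get("parity")),
            beta_year=_log(ors.get("year")),
            beta_season=_log(ors.get("season")),
            beta_yield=math.log(float(ors.get("yield_per_1000l", 1.0))),
            beta_lameness=_log(ors.get("lameness")),
            sigma2_cow=float(var.get("cow", 0.0)),
            sigma2_herd=float(var.get("herd", 0.0)),
        )


def load_coefficients(path) -> DtsmCoefficients:
    """Read a coefficient file (YAML, odds-ratio schema)."""
    with open(path) as fh:
        return DtsmCoefficients.from_dict(yaml.safe_load(fh))


def save_coefficients(coefs: DtsmCoefficients, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(coefs.to_dict(), fh, sort_keys=False)


def default_coefficients() -> DtsmCoefficients:
    """The packaged default coefficient set (published point estimates)."""
    text = (
        resources.files("fertsim").joinpath("data/default_coefficients.yaml")
    ).read_text()
    return DtsmCoefficients.from_dict(yaml.safe_load(text))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
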