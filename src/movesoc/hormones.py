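"""Faecal thyroid hormone (fT3) processing.

Turns raw sample tables into model covariates: per-individual-day means, a
48-h excretion lag that pairs each behaviour day with the faecal sample
collected two days later, and the within-/between-individual decomposition
(individual mean + mean-centred deviation).  Also provides the rank
standardisation and Spearman validation utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LAG_HOURS = 48


def daily_mean(samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples within each individual-day.

    ``samples`` needs ``individual_id``, ``collection_date`` and ``ft3_ng_g``.
    """
    if (samples["ft3_ng_g"] <= 0).any():
        raise ValueError("fT3 concentrations must be positive")
    out = (
        samples.groupby(["individual_id", "collection_date"], sort=True)["ft3_ng_g"]
        .mean()
        .reset_index()
    )
    return out


def apply_lag(
    daily: pd.DataFrame,
    lag_hours: int = DEFAULT_LAG_HOURS,
    direction: str = "sample_after",
) -> pd.DataFrame:
    """Pair behaviour days with lagged hormone values.

    With the default ``sample_after`` direction, the faecal sample collected
    on day ``d + lag`` carries the physiological state of behaviour day ``d``
    (faecal metabolite levels reflect circulating hormone ~48 h earlier).
    ``sample_before`` pairs the other way.  The lag must be a whole number of
    days; unmatched behaviour days are dropped.
    """
    if lag_hours % 24 != 0:
        raise ValueError("lag must be a whole number of days")
    lag_days = lag_hours // 24
    if direction == "sample_after":
        shift = -lag_days
    elif direction == "sample_before":
        shift = lag_days
    else:
        raise ValueError("direction must be 'sample_after' or 'sample_before'")
    out = daily.copy()
    dates = pd.to_datetime(out["collection_date"])
    out["behaviour_date"] = (dates + pd.Timedelta(days=shift)).dt.date
    return out[["individual_id", "behaviour_date", "ft3_ng_g"]].rename(
        columns={"ft3_ng_g": "ft3_daily"}
    )


def decompose(lagged: pd.DataFrame) -> pd.DataFrame:
    """Split fT3 into individual mean and mean-centred deviation.

    The individual mean is taken over that individual's rows in the input —
    i.e. over model-included records — so the centred values sum to zero per
    individual within any fitted dataset.
    """
    out = lagged.copy()
    out["ft3_mean"] = out.groupby("individual_id")["ft3_daily"].transform("mean")
    out["ft3_centred"] = out["ft3_daily"] - out["ft3_mean"]
    return out


def build_energy_covariates(
    samples: pd.DataFrame,
    lag_hours: int = DEFAULT_LAG_HOURS,
    direction: str = "sample_after",
) -> pd.DataFrame:
    """Sample table -> lagged, decomposed covariate table."""
    return decompose(apply_lag(daily_mean(samples), lag_hours, direction))


def range01(values) -> np.ndarray:
    """Min-max standardisation to [0, 1]; min maps to 0 and max to 1."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("degenerate range: all values equal")
    return (v - lo) / (hi - lo)


def spearman(a, b) -> tuple[float, float, int]:
    """Tie-aware Spearman rank correlation with a two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p), len(a)


def standardized_age_ranks(age_ranks: pd.DataFrame) -> pd.DataFrame:
    """Average two observer rankings and standardise to [0, 1].

    ``age_ranks`` needs ``individual_id``, ``rank_a``, ``rank_b``; 0 is the
    youngest and 1 the oldest individual.
    """
    out = age_ranks.copy()
    mean_rank = (out["rank_a"] + out["rank_b"]) / 2.0
    out["standardized_mean_rank"] = range01(mean_rank)
    return out[["individual_id", "standardized_mean_rank"]]


def validate_age_ft3(
    age_ranks: pd.DataFrame, samples: pd.DataFrame
) -> dict:
    """Reporting utility: Spearman tests of observer agreement and age vs fT3.

    Not a pipeline dependency — mirrors the proxy-validation step (older
    individuals are expected to show lower average fT3).
    """
    rank_rho, rank_p, rank_n = spearman(age_ranks["rank_a"], age_ranks["rank_b"])
    std = standardized_age_ranks(age_ranks)
    mean_ft3 = (
        samples.groupby("individual_id")["ft3_ng_g"].mean().rename("mean_ft3")
    )
    joined = std.merge(mean_ft3, on="individual_id")
    age_rho, age_p, age_n = spearman(
        joined["standardized_mean_rank"], joined["mean_ft3"]
    )
    return {
        "observer_agreement": {"rho": rank_rho, "p": rank_p, "n": rank_n},
        "age_vs_ft3": {"rho": age_rho, "p": age_p, "n": age_n},
    }
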