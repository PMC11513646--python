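"""Joined analysis dataset and the seven-model mixed-model suite.

Assembles per-individual-day movement metrics, opportunity counts, lagged
hormone covariates, grooming totals and metadata into one table, then fits
the chained model suite: energy -> movement (models 1-4), movement -> social
opportunities (model 5) and opportunities -> grooming received/given
(models 6-7, the latter with an energy interaction).  Responses are log- or
square-root transformed as declared per model, continuous predictors are
z-transformed over each model's included rows, and every model is compared
with its control-only null by a maximum-likelihood likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import RandomTerm, fit_lmm, lrt

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset assembly

def build_dataset(
    metrics: pd.DataFrame,
    counts: pd.DataFrame,
    energy: pd.DataFrame,
    grooming: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Outer-join the four data streams on individual x date, plus metadata.

    Missing stream values stay missing; each model selects and drops rows
    for its own variable set.
    """
    df = metrics.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for other, on_date in (
        (counts, "date"),
        (grooming, "date"),
        (energy, "behaviour_date"),
    ):
        o = other.copy()
        o[on_date] = pd.to_datetime(o[on_date]).dt.date
        if on_date != "date":
            o = o.rename(columns={on_date: "date"})
        df = df.merge(o, on=["individual_id", "date"], how="outer")
    df = df.merge(metadata, on="individual_id", how="left")
    return df.sort_values(["individual_id", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed model.

    ``continuous`` predictors are z-transformed over included rows (after
    any ``predictor_transforms`` log step); ``focal`` lists the fixed-effect
    names dropped in the null model for the LRT.
    """

    name: str
    response: str
    transform: str = "identity"                 # identity | log | sqrt
    continuous: tuple = ()
    categorical: tuple = ()
    interaction: tuple | None = None            # pair of continuous names
    predictor_transforms: dict = field(default_factory=dict)
    focal: tuple = ()
    random_slope: str | None = None
    females_only: bool = False
    min_collars: int | None = None
    zscore: bool = True

    @property
    def interaction_name(self) -> str | None:
        if self.interaction is None:
            return None
        return f"{self.interaction[0]}:{self.interaction[1]}"


def default_specs(
    ft3_interaction: str = "ft3_centred",
    min_collars: int = 10,
) -> list[ModelSpec]:
    """The seven standard models (movement 1-4, opportunities 5, grooming 6-7)."""
    movement = [
        ("lmm1", "total_distance_m", "identity"),
        ("lmm2", "median_step_m", "log"),
        ("lmm3", "median_sinuosity", "log"),
        ("lmm4", "median_residence_min", "log"),
    ]
    specs = [
        ModelSpec(
            name=name,
            response=resp,
            transform=tr,
            continuous=("ft3_mean", "ft3_centred"),
            categorical=("reproductive_state",),
            focal=("ft3_mean", "ft3_centred"),
            random_slope="ft3_centred",
        )
        for name, resp, tr in movement
    ]
    specs.append(
        ModelSpec(
            name="lmm5",
            response="n_events",
            transform="sqrt",
            continuous=("residence", "daylength_h", "rank", "n_active_collars"),
            categorical=("reproductive_state",),
            predictor_transforms={"residence": ("median_residence_min", "log")},
            focal=("residence",),
            random_slope="residence",
            females_only=True,
            min_collars=min_collars,
        )
    )
    specs.append(
        ModelSpec(
            name="lmm6",
            response="receive_min",
            transform="sqrt",
            continuous=("n_opportunities", "daylength_h", "rank"),
            categorical=("reproductive_state",),
            predictor_transforms={"n_opportunities": ("n_events", "identity")},
            focal=("n_opportunities",),
            random_slope="n_opportunities",
            females_only=True,
        )
    )
    specs.append(
        ModelSpec(
            name="lmm7",
            response="give_min",
            transform="sqrt",
            continuous=("n_opportunities", ft3_interaction, "daylength_h", "rank"),
            categorical=("reproductive_state",),
            predictor_transforms={"n_opportunities": ("n_events", "identity")},
            interaction=("n_opportunities", ft3_interaction),
            focal=("n_opportunities", ft3_interaction,
                   f"n_opportunities:{ft3_interaction}"),
            random_slope="n_opportunities",
            females_only=True,
        )
    )
    return specs


# ---------------------------------------------------------------------------
# model-frame preparation

def _transform_response(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log":
        return np.log(values)
    if transform == "sqrt":
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


def prepare_frame(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Select, filter and transform the rows a model uses.

    Returns the prepared frame (response column ``_y``, transformed and
    z-scored predictors under their spec names) plus bookkeeping info
    (rows dropped for zeros under log, predictor SDs, counts).
    """
    df = data.copy()
    info: dict = {"n_input": len(df)}
    if spec.females_only and "sex" in df.columns:
        df = df[df["sex"] == "female"]
    if spec.min_collars is not None and "n_active_collars" in df.columns:
        df = df[df["n_active_collars"] >= spec.min_collars]

    # resolve source columns for each predictor
    sources = {}
    for name in spec.continuous:
        src, tr = spec.predictor_transforms.get(name, (name, "identity"))
        sources[name] = (src, tr)

    needed = (
        {spec.response, "individual_id", "date"}
        | {src for src, _ in sources.values()}
        | set(spec.categorical)
    )
    missing = needed - set(df.columns)
    if missing:
        raise KeyError(f"{spec.name}: missing columns {sorted(missing)}")
    df = df.dropna(subset=list(needed))

    # response transform; zeros under log are dropped (counted)
    y_raw = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "log":
        bad = y_raw <= 0
        info["n_dropped_nonpositive"] = int(bad.sum())
        if bad.any():
            logger.info(
                "%s: dropped %d rows with non-positive response under log",
                spec.name, int(bad.sum()),
            )
            df = df[~bad]
            y_raw = y_raw[~bad]
    frame = df.reset_index(drop=True).copy()
    frame["_y"] = _transform_response(y_raw, spec.transform)

    # predictor transforms + z-scoring over included rows
    sds, means = {}, {}
    for name, (src, tr) in sources.items():
        v = frame[src].to_numpy(dtype=float)
        if tr == "log":
            if (v <= 0).any():
                keep = v > 0
                info.setdefault("n_dropped_nonpositive_predictor", 0)
                info["n_dropped_nonpositive_predictor"] += int((~keep).sum())
                frame = frame[keep].reset_index(drop=True)
                v = v[keep]
            v = np.log(v)
        elif tr != "identity":
            raise ValueError(f"unknown predictor transform {tr!r}")
        frame[name] = v
    for name in spec.continuous:
        v = frame[name].to_numpy(dtype=float)
        means[name], sds[name] = float(v.mean()), float(v.std(ddof=0))
        if spec.zscore:
            if sds[name] == 0:
                raise ValueError(f"{spec.name}: predictor {name} is constant")
            frame[name] = (v - means[name]) / sds[name]
    info["predictor_means"], info["predictor_sds"] = means, sds
    info["n_obs"] = len(frame)
    info["n_individuals"] = frame["individual_id"].nunique()
    return frame, info


def build_design(
    frame: pd.DataFrame,
    continuous: tuple,
    categorical: tuple,
    interaction: tuple | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix: intercept, continuous terms, treatment-coded
    categoricals (first level alphabetically as reference), optional two-way
    product of continuous terms."""
    n = len(frame)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for c in continuous:
        cols.append(frame[c].to_numpy(dtype=float))
        names.append(c)
    for c in categorical:
        levels = sorted(frame[c].astype(str).unique())
        for lev in levels[1:]:
            cols.append((frame[c].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{c}[{lev}]")
    if interaction is not None:
        a, b = interaction
        cols.append(
            frame[a].to_numpy(dtype=float) * frame[b].to_numpy(dtype=float)
        )
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def vif(X: np.ndarray, names: list[str], continuous: tuple) -> dict:
    """Variance inflation factors: regress each continuous predictor on all
    other non-intercept terms; perfect collinearity reports ``inf``."""
    idx = {n: i for i, n in enumerate(names)}
    others_all = [i for n, i in idx.items() if n != "(Intercept)"]
    out = {}
    for name in continuous:
        j = idx[name]
        others = [i for i in others_all if i != j]
        if not others:
            out[name] = 1.0
            continue
        Z = np.column_stack([np.ones(X.shape[0])] + [X[:, i] for i in others])
        target = X[:, j]
        coef, _, _, _ = np.linalg.lstsq(Z, target, rcond=None)
        resid = target - Z @ coef
        tss = float(((target - target.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        if tss == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - rss / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# fitting

def _random_terms(spec: ModelSpec) -> list[RandomTerm]:
    return [
        RandomTerm("individual_id", slope=spec.random_slope),
        RandomTerm("date"),
    ]


def _slope_columns(spec: ModelSpec, frame: pd.DataFrame) -> dict:
    """Random-slope values taken from the frame so full and null models share
    an identical random structure even when the slope variable is a focal
    fixed effect absent from the null design."""
    if spec.random_slope is None:
        return {}
    return {spec.random_slope: frame[spec.random_slope].to_numpy(dtype=float)}


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    categorical_p: bool = False,
) -> dict:
    """Fit one model: REML coefficient table, ML LRT against the control-only
    null (same random structure), VIFs, and optionally an overall categorical
    term p-value (extra LRT).  Returns a JSON-able report."""
    frame, info = prepare_frame(spec, data)
    if frame["individual_id"].nunique() < 2 or frame["date"].nunique() < 2:
        return {"name": spec.name, "skipped": True, "reason": "insufficient data",
                **info}
    X, names = build_design(frame, spec.continuous, spec.categorical, spec.interaction)
    y = frame["_y"].to_numpy()
    terms = _random_terms(spec)
    slopes = _slope_columns(spec, frame)

    fit_reml = fit_lmm(y, X, names, frame, terms, slope_columns=slopes, method="REML")
    fit_ml = fit_lmm(y, X, names, frame, terms, slope_columns=slopes, method="ML")

    null_cont = tuple(c for c in spec.continuous if c not in spec.focal)
    null_inter = None if (spec.interaction_name in spec.focal) else spec.interaction
    Xn, nn = build_design(frame, null_cont, spec.categorical, null_inter)
    fit_null = fit_lmm(y, Xn, nn, frame, terms, slope_columns=slopes, method="ML")
    df_lrt, chi2, p_lrt = lrt(fit_ml, fit_null)

    cont_names = [n for n in names if n in spec.continuous or n == spec.interaction_name]
    vifs = vif(X, names, tuple(cont_names)) if len(cont_names) >= 2 else {}

    report = {
        "name": spec.name,
        "skipped": False,
        "response": spec.response,
        "transform": spec.transform,
        "coefficients": fit_reml.coef_table(),
        "lrt": {"df": int(df_lrt), "chi2": float(chi2), "p": float(p_lrt)},
        "vif": {k: float(v) for k, v in vifs.items()},
        "n_individuals": int(info["n_individuals"]),
        "n_obs": int(info["n_obs"]),
        "converged": bool(
            fit_reml.converged and fit_ml.converged and fit_null.converged
        ),
        "singular": bool(fit_reml.singular),
        "variance_components": fit_reml.vc,
        "predictor_sds": info["predictor_sds"],
    }
    if categorical_p and spec.categorical:
        cat_p = {}
        for cat in spec.categorical:
            Xc, nc = build_design(
                frame,
                spec.continuous,
                tuple(c for c in spec.categorical if c != cat),
                spec.interaction,
            )
            fit_nc = fit_lmm(y, Xc, nc, frame, terms, slope_columns=slopes, method="ML")
            _, _, p_cat = lrt(fit_ml, fit_nc)
            cat_p[cat] = p_cat
        report["categorical_p"] = cat_p
    return report


def run_suite(
    data: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    categorical_p: bool = True,
) -> dict:
    """Fit the full model suite; failed/empty models are reported, not fatal."""
    specs = specs if specs is not None else default_specs()
    out = {}
    for spec in specs:
        try:
            out[spec.name] = fit_model(spec, data, categorical_p=categorical_p)
        except (KeyError, ValueError) as exc:
            out[spec.name] = {"name": spec.name, "skipped": True, "reason": str(exc)}
    return out


def suite_table(reports: dict) -> pd.DataFrame:
    """Flatten suite reports into a summary table (one row per coefficient)."""
    rows = []
    for name, rep in reports.items():
        if rep.get("skipped"):
            continue
        for coef, stats_ in rep["coefficients"].items():
            rows.append(
                {
                    "model": name,
                    "response": rep["response"],
                    "term": coef,
                    "estimate": stats_["estimate"],
                    "se": stats_["se"],
                    "t": stats_["t"],
                    "p": stats_["p"],
                    "lrt_df": rep["lrt"]["df"],
                    "lrt_chi2": rep["lrt"]["chi2"],
                    "lrt_p": rep["lrt"]["p"],
                    "N": rep["n_individuals"],
                    "n": rep["n_obs"],
                }
            )
    return pd.DataFrame(rows)
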