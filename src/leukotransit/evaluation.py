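"""Scoring of trained surrogates against held-out simulation truth.

The headline metric is the coefficient of determination R^2 between
surrogate predictions and simulated truth.  Two forms are computed
side by side:

* ``standard``: 1 - sum((y - yhat)^2) / sum((y - ybar)^2) — bounded above
  by 1 and penalizing bias; used for all acceptance comparisons.
* ``printed``: sum((yhat - ybar)^2) / sum((y - ybar)^2) — an
  explained-variance ratio that coincides with the standard form only for
  least-squares-calibrated predictors and can exceed 1 for biased ones;
  kept for fidelity to the convention some of this literature prints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "r_squared", "fit_correlation", "evaluate_surrogate", "response_surface"]


def r_squared(pred, true, form: str = "standard") -> float:
    """Coefficient of determination between predictions and truth."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("pred and true must be equal-length non-empty arrays")
    ybar = true.mean()
    ss_tot = float(np.sum((true - ybar) ** 2))
    if ss_tot == 0.0:
        raise ValueError("true values have zero variance; R^2 undefined")
    if form == "standard":
        return 1.0 - float(np.sum((true - pred) ** 2)) / ss_tot
    if form == "printed":
        return float(np.sum((pred - ybar) ** 2)) / ss_tot
    raise ValueError(f"unknown form {form!r}; expected 'standard' or 'printed'")


def fit_correlation(pred, true) -> float:
    """Pearson correlation R between predictions and truth (the 'fit' number)."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    return float(np.corrcoef(pred, true)[0, 1])


@dataclass
class EvaluationReport:
    """Per-case and pooled accuracy of one surrogate."""

    target: str
    per_case: pd.DataFrame  # columns: Re, AR, n, r2, r2_printed, mse
    pooled_r2: float
    pooled_r2_printed: float
    pooled_mse: float
    series: dict = field(default_factory=dict)  # (Re, AR) -> (true, pred) arrays

    @property
    def min_case_r2(self) -> float:
        return float(self.per_case["r2"].min())

    def save(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def evaluate_surrogate(model, cases) -> EvaluationReport:
    """Score a surrogate on held-out simulated cases.

    ``model`` is a :class:`~leukotransit.bpnn.SurrogateModel`.  ``cases``
    is a list of dicts, one per (Re, AR) scenario:

    * time model (inputs Re, AR): ``{"Re", "AR", "transit_time"}`` — the
      scalar truths are pooled into a single R^2 across cases, per-case
      rows record the absolute prediction instead of a per-case R^2 (a
      single scalar has no variance).
    * motion models (inputs Re, AR, displacement): ``{"Re", "AR",
      "displacement": array, <target>: array}`` — R^2 per case over the
      case's displacement grid, plus pooled values.
    """
    if not cases:
        raise ValueError("empty case list")
    target = model.target_column
    arity = len(model.input_columns)
    rows, all_true, all_pred, series = [], [], [], {}
    for case in cases:
        if target not in case:
            raise ValueError(
                f"case (Re={case.get('Re')}, AR={case.get('AR')}) lacks truth column "
                f"{target!r} matching the model schema {model.input_columns} -> {target}"
            )
        re_, ar = float(case["Re"]), float(case["AR"])
        if arity == 2:
            true = np.atleast_1d(np.asarray(case[target], dtype=float))
            pred = model.predict(pd.DataFrame({"Re": [re_], "AR": [ar]}))
            rows.append(
                {"Re": re_, "AR": ar, "n": 1, "r2": np.nan, "r2_printed": np.nan,
                 "mse": float((pred[0] - true[0]) ** 2), "true": true[0], "pred": pred[0]}
            )
        elif arity == 3:
            disp = np.asarray(case["displacement"], dtype=float)
            true = np.asarray(case[target], dtype=float)
            pred = model.predict(
                pd.DataFrame({"Re": re_, "AR": ar, "displacement": disp})
            )
            rows.append(
                {"Re": re_, "AR": ar, "n": disp.size,
                 "r2": r_squared(pred, true), "r2_printed": r_squared(pred, true, "printed"),
                 "mse": float(np.mean((pred - true) ** 2))}
            )
        else:
            raise ValueError(f"unsupported input arity {arity}")
        series[(re_, ar)] = (true, pred)
        all_true.append(true)
        all_pred.append(pred)
    all_true = np.concatenate(all_true)
    all_pred = np.concatenate(all_pred)
    return EvaluationReport(
        target=target,
        per_case=pd.DataFrame(rows),
        pooled_r2=r_squared(all_pred, all_true),
        pooled_r2_printed=r_squared(all_pred, all_true, "printed"),
        pooled_mse=float(np.mean((all_pred - all_true) ** 2)),
        series=series,
    )


def response_surface(model, re_range, ar_range, resolution: int = 40):
    """Dense predicted transit-time surface over a (Re, AR) box.

    Returns a dict with the grid axes, predicted surface, per-cell
    extrapolation flags (outside the training box recorded in the model's
    normalization) and the fraction of in-box finite-difference slopes that
    are negative along each axis — the monotone-trend summary (transit gets
    slower toward low Re and toward tight pores).
    """
    if len(model.input_columns) != 2:
        raise ValueError("response_surface expects the 2-input transit-time schema")
    re_ax = np.linspace(float(re_range[0]), float(re_range[1]), resolution)
    ar_ax = np.linspace(float(ar_range[0]), float(ar_range[1]), resolution)
    RE, AR = np.meshgrid(re_ax, ar_ax, indexing="ij")
    pred = model.predict(
        pd.DataFrame({"Re": RE.ravel(), "AR": AR.ravel()})
    ).reshape(RE.shape)
    lo_re, hi_re = model.norm["Re"]
    lo_ar, hi_ar = model.norm["AR"]
    inbox = (RE >= lo_re) & (RE <= hi_re) & (AR >= lo_ar) & (AR <= hi_ar)
    d_re = np.diff(pred, axis=0)
    d_ar = np.diff(pred, axis=1)
    in_re = inbox[:-1, :] & inbox[1:, :]
    in_ar = inbox[:, :-1] & inbox[:, 1:]
    frac_neg_re = float(np.mean(d_re[in_re] < 0)) if in_re.any() else np.nan
    frac_neg_ar = float(np.mean(d_ar[in_ar] < 0)) if in_ar.any() else np.nan
    return {
        "re_axis": re_ax,
        "ar_axis": ar_ax,
        "surface": pred,
        "extrapolated": ~inbox,
        "frac_negative_slope_re": frac_neg_re,
        "frac_negative_slope_ar": frac_neg_ar,
    }
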