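"""Screen-wide application of a CVS model.

A fitted viability model is applied to every instance of a chemical
signature screen; per compound, the minimum and maximum predicted viability
at the compound's own highest tested dose summarize general versus selective
toxicity, and fixed (or percentile-derived) thresholds classify compounds as
general-toxic, selective-toxic, proliferative or neutral.  The
delta-concentration harness benchmarks predictions against an external
screen that reports a sensitivity concentration capped at the maximal tested
concentration: delta = metric - max tested (log10), with delta < 0 flagging
an effective drug.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_io import SignatureSet
from .similarity_moa import EvalReport, binary_score_eval
from .viability_model import ViabilityModel, predict

__all__ = ["predict_screen", "compound_extremes", "classify_compounds",
           "delta_concentration", "effective_from_delta",
           "external_benchmark_eval"]

#: default Achilles-scale (log-fold-change) thresholds: 5th/95th percentiles
DEFAULT_TOXIC_THR = -3.0
DEFAULT_PROLIF_THR = 1.5


def predict_screen(model: ViabilityModel, sigset: SignatureSet) -> pd.DataFrame:
    """Per-instance predictions with full metadata carried through."""
    preds = predict(model, sigset.values)
    out = sigset.row_meta.copy()
    out["predicted_viability"] = preds
    return out


def compound_extremes(predictions: pd.DataFrame,
                      restrict_to_highest_dose: bool = True) -> pd.DataFrame:
    """Min/max predicted viability per compound (at its own top dose).

    Returns one row per compound with min/max predictions and the arg-min /
    arg-max cell lines, scanning across cells and time points.
    """
    df = predictions
    if restrict_to_highest_dose:
        top = df.groupby("perturbagen_id")["dose_um"].transform("max")
        kept = df[(df["dose_um"] == top) | top.isna()]
        lost = set(df["perturbagen_id"]) - set(kept["perturbagen_id"])
        if lost:
            warnings.warn(f"{len(lost)} compounds had no top-dose instances "
                          "and were excluded", stacklevel=2)
        df = kept
    rows = []
    for pid, grp in df.groupby("perturbagen_id", sort=True):
        i_min = grp["predicted_viability"].idxmin()
        i_max = grp["predicted_viability"].idxmax()
        rows.append((pid,
                     grp.at[i_min, "predicted_viability"],
                     grp.at[i_max, "predicted_viability"],
                     grp.at[i_min, "cell_line_id"],
                     grp.at[i_max, "cell_line_id"]))
    return pd.DataFrame(rows, columns=["perturbagen_id", "min_pred",
                                       "max_pred", "argmin_cell",
                                       "argmax_cell"]).set_index("perturbagen_id")


def classify_compounds(extremes: pd.DataFrame,
                       toxic_thr: float = DEFAULT_TOXIC_THR,
                       prolif_thr: float = DEFAULT_PROLIF_THR,
                       percentile_from=None) -> pd.DataFrame:
    """Classify compounds from their prediction extremes.

    toxic if min < toxic_thr (``general_toxic`` when the max is also below
    the threshold, i.e. toxic in every screened cell line, else
    ``selective_toxic``); ``proliferative`` if not toxic and max >
    prolif_thr; otherwise ``neutral``.  When ``percentile_from`` is given,
    the thresholds are that vector's 5th and 95th percentiles instead.
    """
    if percentile_from is not None:
        v = np.asarray(percentile_from, dtype=float)
        toxic_thr = float(np.percentile(v, 5))
        prolif_thr = float(np.percentile(v, 95))
    if not toxic_thr < prolif_thr:
        raise ValueError("toxic threshold must be below proliferative threshold")
    out = extremes.copy()

    def _cls(row):
        if row["min_pred"] < toxic_thr:
            return ("general_toxic" if row["max_pred"] < toxic_thr
                    else "selective_toxic")
        if row["max_pred"] > prolif_thr:
            return "proliferative"
        return "neutral"

    out["class"] = out.apply(_cls, axis=1)
    out.attrs["toxic_thr"] = toxic_thr
    out.attrs["prolif_thr"] = prolif_thr
    return out


def delta_concentration(metric_log10_conc, max_tested_log10_conc) -> np.ndarray:
    """Sensitivity metric minus maximal tested concentration (log10 scale)."""
    m = np.asarray(metric_log10_conc, dtype=float)
    mx = np.asarray(max_tested_log10_conc, dtype=float)
    if m.shape != mx.shape:
        raise ValueError("vectors must align")
    return m - mx


def effective_from_delta(delta: np.ndarray) -> np.ndarray:
    """Effective iff the sensitivity concentration was reached: delta < 0."""
    return np.asarray(delta) < 0


def external_benchmark_eval(predictions: pd.DataFrame,
                            benchmark: pd.DataFrame) -> EvalReport:
    """ROC/PR of min-predicted-viability scores against binarized sensitivity.

    ``predictions`` carries per-instance ``predicted_viability`` with cell
    and perturbagen metadata; per (cell, compound) pair the *lowest*
    prediction is the target score.  ``benchmark`` provides either a
    pre-binarized ``effective`` column or the delta-concentration inputs
    (``metric_log10_conc`` and ``max_tested_log10_conc``).  Lower predicted
    viability means more effective, so scores enter the ROC negated.
    """
    per_pair = (predictions.groupby(["cell_line_id", "perturbagen_id"])
                ["predicted_viability"].min().rename("score"))
    bench = benchmark.copy()
    if "effective" not in bench.columns:
        bench["effective"] = effective_from_delta(delta_concentration(
            bench["metric_log10_conc"], bench["max_tested_log10_conc"]))
    bench = bench.set_index(["cell_line_id", "perturbagen_id"])
    joined = bench.join(per_pair, how="inner")
    if joined["score"].isna().any() or joined.empty:
        raise ValueError("every benchmark pair needs at least one prediction")
    return binary_score_eval(-joined["score"].to_numpy(),
                             joined["effective"].to_numpy())
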