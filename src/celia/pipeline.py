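"""End-to-end workflow: plate -> endpoints -> calibration -> quantification.

Ties the synthetic plates to the statistics: extract baseline-corrected
endpoint signals per well, fit the per-target sigmoid calibration (blanks
excluded from the fit, used only for the LoD), and invert unknown wells to
concentration estimates with censoring flags.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import (
    CalibrationModel,
    PanelEvaluation,
    fit_sigmoid,
    fold_difference,
    lod,
    quantify_endpoint,
)
from .synthetic import PlateExperiment
from .traces import endpoint_signal

__all__ = [
    "plate_endpoints",
    "calibrate_plate",
    "quantify_plate",
    "evaluate_panel",
]


def plate_endpoints(
    plate: PlateExperiment,
    channel: str = "omega",
    t_end: float | None = None,
    baseline_correct: bool = True,
) -> pd.DataFrame:
    """Per-well endpoint signal on one channel.

    The baseline (mean of the first three samples) is subtracted by default
    to remove the per-well optical offset of the noise model.
    """
    rows = []
    for well in plate.wells:
        tr = plate.trace(well.well_id, channel)
        te = t_end if t_end is not None else float(tr.times[-1])
        value = endpoint_signal(tr, te)
        if baseline_correct:
            value -= float(tr.values[: min(3, len(tr))].mean())
        s = well.sample
        rows.append(
            {
                "well_id": well.well_id,
                "sample_id": s.sample_id,
                "target": s.target,
                "kind": s.kind,
                "true_molar": s.conc_molar,
                "endpoint": value,
            }
        )
    return pd.DataFrame(rows)


def calibrate_plate(
    plate: PlateExperiment,
    channel: str = "omega",
    t_end: float | None = None,
) -> dict[str, CalibrationModel]:
    """Fit one sigmoid calibration (and LoD) per target on a standards plate."""
    df = plate_endpoints(plate, channel=channel, t_end=t_end)
    models: dict[str, CalibrationModel] = {}
    for target, grp in df.groupby("target"):
        std = grp[(grp["kind"] == "standard") & (grp["true_molar"] > 0)]
        pts = [(math.log10(c), e) for c, e in zip(std["true_molar"], std["endpoint"])]
        model = fit_sigmoid(pts)
        blanks = grp[grp["kind"] == "blank"]["endpoint"].to_numpy()
        if blanks.size >= 2:
            model = lod(model, blanks)
        models[str(target)] = model
    return models


def quantify_plate(
    plate: PlateExperiment,
    models: Mapping[str, CalibrationModel],
    channel: str = "omega",
    t_end: float | None = None,
) -> pd.DataFrame:
    """Invert every well's endpoint through its target's calibration."""
    df = plate_endpoints(plate, channel=channel, t_end=t_end)
    est, flag = [], []
    for _, row in df.iterrows():
        model = models[row["target"]]
        res = quantify_endpoint(model, row["endpoint"])
        est.append(res.estimate_molar)
        flag.append(res.flag)
    out = df.copy()
    out["estimate_molar"] = est
    out["flag"] = flag
    return out


def evaluate_panel(quantified: pd.DataFrame) -> dict[str, PanelEvaluation]:
    """Fold-difference summary per target over in-range ("ok") estimates.

    Censored estimates (below/above range or below LoD) are excluded from
    the mean and reported in ``n_censored``.
    """
    out: dict[str, PanelEvaluation] = {}
    for target, grp in quantified.groupby("target"):
        pairs = []
        for _, row in grp.iterrows():
            ok = row["flag"] == "ok"
            pairs.append((row["estimate_molar"] if ok else None, row["true_molar"]))
        out[str(target)] = fold_difference(pairs)
    return out
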