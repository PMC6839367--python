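"""Corrected-AIC model selection and Akaike weights.

For a least-squares fit with n data points, p fitted parameters and
residual sum of squares SSE, the small-sample-corrected Akaike
information criterion is

    cAIC = n ln(SSE/n) + 2K + 2K(K+1)/(n - K - 1),    K = p + 1,

where K counts the residual variance as an estimated quantity (the
least-squares AIC convention).  All five kinetic models here share the
same p, so the variance-counting convention only shifts every cAIC by the
same constant and never changes a best-model map.

Akaike weights w_m = exp(-Delta_m/2) / sum_j exp(-Delta_j/2) with
Delta_m = cAIC_m - min cAIC express the probability for model m to be
the best of the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import MODEL_ORDER

__all__ = ["caic", "akaike_weights", "ModelSelection", "select_model", "best_model_map"]


def caic(sse: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    k = p + 1
    if n <= k + 1:
        raise ValueError(f"cAIC undefined for n = {n} <= K + 1 = {k + 1}")
    if sse <= 0:
        raise ValueError("sse must be positive")
    return float(n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def akaike_weights(caics: dict) -> dict:
    """Akaike weights from a map model -> cAIC; stable for large deltas."""
    if len(caics) < 2:
        raise ValueError("need at least 2 models")
    models = list(caics)
    vals = np.array([caics[m] for m in models], dtype=float)
    delta = vals - vals.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    return dict(zip(models, (float(x) for x in w)))


@dataclass(frozen=True)
class ModelSelection:
    """Per-voxel cAIC ranking of the candidate models."""

    caic_by_model: dict
    delta_by_model: dict
    weight_by_model: dict
    best_model: str


def _tie_order(model: str) -> int:
    return MODEL_ORDER.index(model) if model in MODEL_ORDER else len(MODEL_ORDER)


def select_model(sse_by_model: dict, n: int, p_by_model: dict | int) -> ModelSelection:
    """Rank models fitted to the identical time series by cAIC.

    Ties (within floating-point equality of cAIC) go to the model with
    fewer parameters, then to the canonical model order.
    """
    if isinstance(p_by_model, int):
        p_by_model = {m: p_by_model for m in sse_by_model}
    caics = {m: caic(s, n, p_by_model[m]) for m, s in sse_by_model.items()}
    cmin = min(caics.values())
    delta = {m: c - cmin for m, c in caics.items()}
    weights = akaike_weights(caics)
    best = min(caics, key=lambda m: (caics[m], p_by_model[m], _tie_order(m)))
    return ModelSelection(
        caic_by_model=caics, delta_by_model=delta,
        weight_by_model=weights, best_model=best,
    )


def best_model_map(volume_fits, p_fitted: int | None = None):
    """Voxelwise argmin-cAIC labels and the per-model percentage summary.

    Parameters
    ----------
    volume_fits : VolumeFitResults
        Fits of several models on identical voxels and frames.
    p_fitted : int, optional
        Fitted-parameter count; defaults to 6 for dual input, 5 otherwise.

    Returns
    -------
    labels : int array of the volume shape
        Code = index into the canonical model order, -1 where no model
        was selectable (non-converged or non-enhancing everywhere).
    summary : pandas.DataFrame
        Percent of analyzable voxels per model, plus the exclusion count.
    selections : list of (voxel_index, ModelSelection or None)
    """
    models = list(volume_fits.fits)
    if p_fitted is None:
        p_fitted = 6 if volume_fits.input_mode == "dual" else 5
    labels = np.full(volume_fits.shape, -1, dtype=int)
    counts = {m: 0 for m in models}
    excluded = 0
    selections = []
    for i, idx in enumerate(volume_fits.voxels):
        sse_by_model = {}
        n_points = None
        for m in models:
            fr = volume_fits.fits[m][i]
            if fr.converged and not fr.non_enhancing and np.isfinite(fr.sse) and fr.sse > 0:
                sse_by_model[m] = fr.sse
                n_points = fr.n_points
        if not sse_by_model:
            excluded += 1
            selections.append((tuple(idx), None))
            continue
        if len(sse_by_model) == 1:
            best = next(iter(sse_by_model))
            sel = None
        else:
            sel = select_model(sse_by_model, n_points, p_fitted)
            best = sel.best_model
        labels[tuple(idx)] = MODEL_ORDER.index(best)
        counts[best] += 1
        selections.append((tuple(idx), sel))
    n_used = len(volume_fits.voxels) - excluded
    rows = [
        {"model": m, "n_best": counts[m],
         "percent": 100.0 * counts[m] / n_used if n_used else np.nan}
        for m in models
    ]
    summary = pd.DataFrame(rows)
    summary.attrs["excluded"] = excluded
    return labels, summary, selections
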