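"""Per-voxel and per-volume bound-constrained least-squares kinetic fitting.

The estimation problem is, per voxel and per model,

    minimize  SSE(theta) = sum_k [C_T^model(t_k; theta) - C_T^data(t_k)]^2

over theta = (F/V_P, PS/V_P, v_P, v_I, t_lag) for single-input modes and
theta = (..., gamma) for dual input, inside a box of physiologic bounds.
A derivative-free bound-constrained local minimizer (Powell) is run from
a seeded Latin-hypercube of starting points; the best start wins (ties
within a relative SSE tolerance go to the start that used fewer function
evaluations).  The soft constraint v_P + v_I <= 0.95 is enforced with a
quadratic penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .aif import DualInputSpec
from .kinetics import (
    MODEL_ORDER,
    DerivedParams,
    KineticFitParams,
    PhysioConstants,
    TissueCurveEngine,
    derive_parameters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "TissueKineticModel",
    "VolumeFitResults",
    "fit_voxel",
    "fit_volume",
    "DEFAULT_BOUNDS",
]

#: physiologic box bounds; config-exposed, shared by every model
DEFAULT_BOUNDS = {
    "f_over_vp": (0.01, 50.0),  # min^-1
    "ps_over_vp": (0.0, 50.0),  # min^-1
    "v_p": (0.001, 0.7),
    "v_i": (0.001, 0.7),
    "t_lag": (0.0, 0.5),  # min
    "gamma": (0.0, 1.0),
}

_PNAMES_SINGLE = ("f_over_vp", "ps_over_vp", "v_p", "v_i", "t_lag")
_PNAMES_DUAL = _PNAMES_SINGLE + ("gamma",)
_VSUM_MAX = 0.95
_PENALTY = 1e4


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the voxelwise optimisation."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_multistart: int = 8
    seed: int = 0
    max_evals: int = 700
    tie_tolerance: float = 1e-8
    engine_dt: float = 4e-3  # internal forward-model resolution, min
    xtol: float = 1e-6
    baseline_frames: int = 5
    enhancement_k_sd: float = 3.0

    def __post_init__(self):
        if self.n_multistart < 1:
            raise ValueError("n_multistart must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")


class _Candidate:
    """Duck-typed parameter record for the hot evaluation path.

    Mirrors the attributes :class:`TissueCurveEngine` reads, without the
    validation cost (and hard failures) of the frozen dataclass; penalty
    terms keep the optimizer inside the physical region.
    """

    __slots__ = ("f_over_vp", "ps_over_vp", "v_p", "v_i", "t_lag", "gamma",
                 "f_t", "ps_t", "tc")

    def __init__(self, f_over_vp, ps_over_vp, v_p, v_i, t_lag, gamma):
        self.f_over_vp = f_over_vp
        self.ps_over_vp = ps_over_vp
        self.v_p = v_p
        self.v_i = v_i
        self.t_lag = t_lag
        self.gamma = gamma
        self.f_t = f_over_vp * v_p
        self.ps_t = ps_over_vp * v_p
        self.tc = v_p / max(self.f_t, 1e-12) if self.f_t > 0 else np.inf


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters and diagnostics for one voxel x model x mode."""

    params: KineticFitParams
    sse: float
    n_points: int
    converged: bool
    n_evals: int
    input_mode: str
    non_enhancing: bool = False
    message: str = ""

    @property
    def model(self) -> str:
        return self.params.model

    @property
    def n_fitted(self) -> int:
        return 6 if self.input_mode == "dual" else 5

    def derived(self, consts: PhysioConstants = PhysioConstants()) -> DerivedParams:
        return derive_parameters(self.params, consts)

    def summary(self) -> str:
        p = self.params
        d = self.derived()
        lines = [
            f"Kinetic fit: {p.model} model, {self.input_mode} arterial input",
            "-" * 52,
            f"{'F/V_P':>12s} : {p.f_over_vp:9.4f} min^-1",
            f"{'PS/V_P':>12s} : {p.ps_over_vp:9.4f} min^-1",
            f"{'v_P':>12s} : {p.v_p:9.4f}",
            f"{'v_I':>12s} : {p.v_i:9.4f}",
            f"{'t_lag':>12s} : {p.t_lag:9.4f} min",
        ]
        if self.input_mode == "dual":
            lines.append(f"{'gamma':>12s} : {p.gamma:9.4f}")
        lines += [
            "-" * 52,
            f"{'BF':>12s} : {d.bf:9.3f} mL/min/100g",
            f"{'BV':>12s} : {d.bv:9.3f} mL/100g",
            f"{'MTT':>12s} : {d.mtt:9.3f} min",
            f"{'PS':>12s} : {d.ps:9.3f} mL/min/100g",
            f"{'KTrans':>12s} : {d.ktrans:9.5f} mL/min/mL",
            "-" * 52,
            f"{'SSE':>12s} : {self.sse:9.4g} mM^2  (n = {self.n_points}, "
            f"{self.n_evals} evals, converged = {self.converged})",
        ]
        return "\n".join(lines)


class TissueKineticModel:
    """One tissue concentration-time curve under one kinetic model.

    Parameters
    ----------
    conc : array
        Tissue concentration series, mM per mL tissue.
    times : array
        Frame times, minutes.
    inputs : DualInputSpec
        Fitted AIF parameters and input mode (pulmonary/systemic/dual).
    model : str
        One of TK, ETK, 2CX, AATH, DP.
    engine : TissueCurveEngine, optional
        Shared precomputed forward engine (reused across voxels/models).
    """

    def __init__(self, conc, times, inputs: DualInputSpec, model: str = "2CX",
                 engine: TissueCurveEngine | None = None,
                 config: FitConfig | None = None):
        self.conc = np.asarray(conc, dtype=float)
        self.times = np.asarray(times, dtype=float)
        if self.conc.shape != self.times.shape or self.conc.ndim != 1:
            raise ValueError("conc and times must be 1-D of equal length")
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("conc must be finite")
        if model not in MODEL_ORDER:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.inputs = inputs
        self.config = config or FitConfig()
        self.engine = engine or TissueCurveEngine(
            inputs, self.times, dt=self.config.engine_dt
        )
        self._pnames = _PNAMES_DUAL if inputs.mode == "dual" else _PNAMES_SINGLE

    # -- objective ---------------------------------------------------------

    def _candidate(self, x) -> _Candidate:
        if self.inputs.mode == "dual":
            f, ps, vp, vi, tl, g = x
        else:
            f, ps, vp, vi, tl = x
            g = self.inputs.fixed_gamma()
        return _Candidate(f, ps, vp, vi, tl, g)

    def predict(self, x) -> np.ndarray:
        return self.engine.evaluate(self.model, self._candidate(x))

    def sse(self, x) -> float:
        r = self.predict(x) - self.conc
        return float(r @ r)

    def _objective(self, x) -> float:
        val = self.sse(x)
        excess = x[2] + x[3] - _VSUM_MAX
        if excess > 0:
            val += _PENALTY * excess * excess
        return val

    # -- starts ------------------------------------------------------------

    def _box(self):
        b = self.config.bounds
        lo = np.array([b[n][0] for n in self._pnames])
        hi = np.array([b[n][1] for n in self._pnames])
        return lo, hi

    def _starts(self):
        lo, hi = self._box()
        n = self.config.n_multistart
        center = 0.5 * (lo + hi)
        center[0], center[1] = 2.0, 0.5  # plausible f_over_vp, ps_over_vp
        center[2], center[3] = 0.1, 0.3
        center[4] = 0.05
        starts = [np.clip(center, lo, hi)]
        if self.inputs.mode == "dual":
            # deterministic near-single-input starts: the dual optimum is
            # often adjacent to one of the gamma extremes
            for g in (0.95, 0.05):
                x = center.copy()
                x[5] = g
                starts.append(np.clip(x, lo, hi))
        # sequential draws from one seeded stream: the start set for
        # n_multistart = k is a prefix of the set for k' > k, so adding
        # starts can only improve (never worsen) the returned SSE
        rng = np.random.default_rng(self.config.seed)
        for _ in range(n - 1):
            row = rng.uniform(size=len(self._pnames))
            x = lo + row * (hi - lo)
            # flow and exchange rates sampled log-uniformly across the box
            x[0] = np.exp(np.log(max(lo[0], 1e-2)) + row[0] * (np.log(hi[0]) - np.log(max(lo[0], 1e-2))))
            x[1] = np.exp(np.log(1e-2) + row[1] * (np.log(hi[1]) - np.log(1e-2)))
            starts.append(np.clip(x, lo, hi))
        return starts

    # -- fitting -----------------------------------------------------------

    def _is_enhancing(self) -> bool:
        nb = min(self.config.baseline_frames, self.conc.size - 1)
        base_sd = float(np.std(self.conc[:nb]))
        peak = float(np.max(np.abs(self.conc)))
        if peak == 0.0:
            return False
        if base_sd == 0.0:
            return True
        return peak >= self.config.enhancement_k_sd * base_sd

    def _null_result(self) -> FitResult:
        lo, _ = self._box()
        params = KineticFitParams(
            model=self.model,
            f_over_vp=lo[0],
            ps_over_vp=lo[1],
            v_p=lo[2],
            v_i=lo[3],
            t_lag=lo[4],
            gamma=self.inputs.fixed_gamma() if self.inputs.mode != "dual" else 0.5,
        )
        return FitResult(
            params=params,
            sse=float(self.conc @ self.conc),  # SSE of the null prediction
            n_points=self.conc.size,
            converged=True,
            n_evals=1,
            input_mode=self.inputs.mode,
            non_enhancing=True,
            message="non-enhancing voxel (peak below noise threshold); not fitted",
        )

    def fit(self, x0=None) -> FitResult:
        """Run the multi-start bound-constrained fit.

        ``x0`` optionally replaces the multi-start with a single start at
        the given parameter vector (ordered as F/V_P, PS/V_P, v_P, v_I,
        t_lag[, gamma]).
        """
        cfg = self.config
        if self.conc.size < len(self._pnames) + 2:
            raise ValueError("need at least n_params + 2 time points")
        if not self._is_enhancing():
            return self._null_result()
        lo, hi = self._box()
        starts = [np.clip(np.asarray(x0, dtype=float), lo, hi)] if x0 is not None \
            else self._starts()
        bounds = list(zip(lo, hi))
        best = None  # (sse, nfev, x)
        total_evals = 0
        any_ok = False
        for xs in starts:
            try:
                sol = minimize(
                    self._objective,
                    xs,
                    method="Powell",
                    bounds=bounds,
                    options={
                        "maxfev": cfg.max_evals,
                        "xtol": cfg.xtol,
                        "ftol": 1e-12,
                    },
                )
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("start failed: %s", exc)
                continue
            any_ok = True
            total_evals += sol.nfev
            cand = (float(sol.fun), sol.nfev, sol.x)
            if best is None:
                best = cand
            else:
                rel = abs(cand[0] - best[0]) / max(best[0], 1e-300)
                if cand[0] < best[0] and rel > cfg.tie_tolerance:
                    best = cand
                elif rel <= cfg.tie_tolerance and cand[1] < best[1]:
                    best = cand
        if not any_ok or best is None:
            return FitResult(
                params=KineticFitParams(self.model, 1.0, 0.0, 0.01, 0.01),
                sse=float("inf"),
                n_points=self.conc.size,
                converged=False,
                n_evals=total_evals,
                input_mode=self.inputs.mode,
                message="optimizer failed on every start",
            )
        _, _, x = best
        x = np.clip(x, lo, hi)
        if x[2] + x[3] >= 1.0:  # keep the returned record physical
            scale = 0.999 / (x[2] + x[3])
            x[2] *= scale
            x[3] *= scale
        cand = self._candidate(x)
        params = KineticFitParams(
            model=self.model,
            f_over_vp=float(cand.f_over_vp),
            ps_over_vp=float(cand.ps_over_vp),
            v_p=float(cand.v_p),
            v_i=float(cand.v_i),
            t_lag=float(cand.t_lag),
            gamma=float(cand.gamma),
        )
        return FitResult(
            params=params,
            sse=self.sse(x),
            n_points=self.conc.size,
            converged=True,
            n_evals=total_evals,
            input_mode=self.inputs.mode,
        )


def fit_voxel(conc_t, times, inputs: DualInputSpec, model: str,
              config: FitConfig | None = None,
              engine: TissueCurveEngine | None = None,
              x0=None) -> FitResult:
    """Fit one kinetic model to one tissue concentration series."""
    return TissueKineticModel(conc_t, times, inputs, model=model,
                              engine=engine, config=config).fit(x0=x0)


@dataclass
class VolumeFitResults:
    """Per-voxel fits for every requested model on a masked volume."""

    shape: tuple
    voxels: np.ndarray  # (N, ndim) indices into the volume
    times: np.ndarray
    fits: dict  # model -> list[FitResult], aligned with voxels
    input_mode: str

    def param_maps(self, model: str,
                   consts: PhysioConstants = PhysioConstants()) -> dict:
        """3-D maps of fitting and derived parameters for one model."""
        names = ["f_over_vp", "ps_over_vp", "v_p", "v_i", "t_lag", "gamma",
                 "bf", "bf_pa", "bf_a", "bv", "mtt", "ps", "ktrans", "sse"]
        maps = {n: np.full(self.shape, np.nan) for n in names}
        maps["converged"] = np.zeros(self.shape, dtype=bool)
        for idx, fr in zip(self.voxels, self.fits[model]):
            idx = tuple(idx)
            p = fr.params
            for n in ("f_over_vp", "ps_over_vp", "v_p", "v_i", "t_lag", "gamma"):
                maps[n][idx] = getattr(p, n)
            if fr.converged and not fr.non_enhancing:
                d = fr.derived(consts)
                for n in ("bf", "bf_pa", "bf_a", "bv", "mtt", "ps", "ktrans"):
                    maps[n][idx] = getattr(d, n)
            maps["sse"][idx] = fr.sse
            maps["converged"][idx] = fr.converged
        return maps


def fit_volume(conc_4d, times, mask, inputs: DualInputSpec, models,
               config: FitConfig | None = None,
               progress: bool = False) -> VolumeFitResults:
    """Fit each requested model to every masked voxel of a 4-D volume.

    ``conc_4d`` has shape spatial + (n_frames,).  A single forward engine
    per input spec is shared across all voxels and models.  Individual
    voxel failures are recorded in their FitResult, never raised.
    """
    conc_4d = np.asarray(conc_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc_4d.shape[:-1]:
        raise ValueError("mask shape must match the spatial volume shape")
    if not mask.any():
        raise ValueError("empty mask")
    if isinstance(models, str):
        models = [models]
    config = config or FitConfig()
    times = np.asarray(times, dtype=float)
    voxels = np.argwhere(mask)
    engine = TissueCurveEngine(inputs, times, dt=config.engine_dt)
    fits = {m: [] for m in models}
    for m in models:
        for k, idx in enumerate(voxels):
            conc = conc_4d[tuple(idx)]
            fr = TissueKineticModel(conc, times, inputs, model=m,
                                    engine=engine, config=config).fit()
            fits[m].append(fr)
            if progress and (k + 1) % 25 == 0:
                logger.info("%s: fitted %d / %d voxels", m, k + 1, len(voxels))
    return VolumeFitResults(shape=mask.shape, voxels=voxels, times=times,
                            fits=fits, input_mode=inputs.mode)
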